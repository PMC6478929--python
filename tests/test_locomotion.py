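"""Unit and property tests for the six-state locomotion HMM."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boutwave.locomotion import (
    B_M,
    B_P,
    F_M,
    F_P,
    FT,
    OT,
    PERMITTED_MASK,
    HmmModel,
    ObservationSeries,
    WormTrack,
    baum_welch,
    default_model,
    direction_factor,
    elongation_from_points,
    emission_matrix,
    forward_backward,
    forward_survival,
    preprocess_track,
    r_emission,
    reversal_rate,
    segment_bouts,
)
from boutwave.synthdata import TrackSimConfig, simulate_track

from conftest import mask_from_lengths, segs_from_mask


# ---------------------------------------------------------------------------
# shape and observation preprocessing

class TestElongation:
    def test_uniform_rod_closed_form(self):
        # uniform points on a segment of length L: variance L^2/12,
        # elongation 2*sqrt(L^2/12) = L/sqrt(3)
        L = 1.2
        pts = np.column_stack([np.linspace(0, L, 2001), np.zeros(2001)])
        elong, axis, degen = elongation_from_points(pts)
        assert not degen
        assert abs(abs(axis[0]) - 1.0) < 1e-9
        assert elong == pytest.approx(L / math.sqrt(3), rel=1e-3)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 2)) * [2.0, 0.5]
        e1, a1, _ = elongation_from_points(pts)
        th = 0.73
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        e2, a2, _ = elongation_from_points(pts @ R.T)
        assert e2 == pytest.approx(e1, rel=1e-12)
        assert abs(abs(a2 @ (R @ a1)) - 1.0) < 1e-9

    def test_square_corners_degenerate(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        _, _, degen = elongation_from_points(pts)
        assert degen

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            elongation_from_points(np.array([[0, 0], [1, 1]], float))


class TestPreprocess:
    def _track(self, pos, axis, elong, dt=0.5):
        n = len(elong)
        return WormTrack("t", np.arange(n) * dt, pos, axis, elong)

    def test_constant_elongation_gives_unit_r(self):
        n = 10
        pos = np.zeros((n, 2))
        axis = np.tile([1.0, 0.0], (n, 1))
        obs = preprocess_track(self._track(pos, axis, np.full(n, 0.9)))
        assert np.allclose(obs.r, 1.0)

    def test_straight_line_projection(self):
        # 0.25 mm/s along the body axis at dt = 0.5 -> dx = 0.125 mm
        n = 20
        pos = np.column_stack([np.arange(n) * 0.125, np.zeros(n)])
        axis = np.tile([1.0, 0.0], (n, 1))
        obs = preprocess_track(self._track(pos, axis, np.ones(n)))
        assert np.allclose(obs.dx, 0.125)

    def test_perpendicular_motion_projects_to_zero(self):
        n = 10
        pos = np.column_stack([np.zeros(n), np.arange(n) * 0.2])
        axis = np.tile([1.0, 0.0], (n, 1))
        obs = preprocess_track(self._track(pos, axis, np.ones(n)))
        assert np.allclose(obs.dx, 0.0)

    def test_axis_sign_flips_are_repaired(self):
        n = 30
        rng = np.random.default_rng(1)
        pos = np.column_stack([np.arange(n) * 0.125, np.zeros(n)])
        signs = np.where(rng.random(n) < 0.4, -1.0, 1.0)
        axis = np.column_stack([signs, np.zeros(n)])
        obs = preprocess_track(self._track(pos, axis, np.ones(n)))
        # continuity restores a consistent sign: dx all equal (either sign)
        assert np.allclose(np.abs(obs.dx), 0.125)
        assert len(np.unique(np.sign(obs.dx))) == 1


# ---------------------------------------------------------------------------
# emissions

class TestEmissions:
    def test_turning_uniform_below_one(self):
        assert r_emission(0.5, "turning") == 1.0
        assert r_emission(1.0, "turning") == 1.0

    def test_crawling_peak_value(self):
        # Gaussian(1, 0.075) density at its mode
        assert r_emission(1.0, "crawling") == pytest.approx(5.3192, abs=1e-3)

    def test_crawling_symmetry(self):
        assert r_emission(1.075, "crawling") == pytest.approx(
            r_emission(0.925, "crawling"), rel=1e-12)

    def test_direction_factor_at_zero(self):
        for s in (F_P, F_M, B_P, B_M):
            assert direction_factor(0.0, 0.5, s) == pytest.approx(0.5)

    def test_direction_factor_complement(self):
        for dx in (-0.3, -0.01, 0.0, 0.02, 0.4):
            f = direction_factor(dx, 0.5, F_P) + direction_factor(dx, 0.5, F_M)
            assert f == pytest.approx(1.0, abs=1e-12)

    def test_direction_sigmoid_value(self):
        # dx/(c dt) = 1 -> (1 + erf(2))/2
        val = direction_factor(0.05, 0.5, F_P)
        assert val == pytest.approx((1 + math.erf(2.0)) / 2.0, rel=1e-12)

    def test_matrix_matches_hand_computation(self):
        model = default_model()
        obs = ObservationSeries(r=np.array([1.0, 0.9]), dx=np.array([0.05]), dt=0.5)
        E = emission_matrix(obs, model)
        sig = (1 + math.erf(2.0)) / 2.0
        g = lambda r: math.exp(-(r - 1) ** 2 / (2 * 0.075**2)) / (0.075 * math.sqrt(2 * math.pi))
        assert E[0, F_P] == pytest.approx(g(1.0) * sig)
        assert E[0, F_M] == pytest.approx(g(1.0) * (1 - sig))
        assert E[0, B_P] == pytest.approx(g(1.0) * (1 - sig))
        assert E[0, FT] == pytest.approx(1.0 * 0.5)
        # last frame: direction factor is constant across states
        assert E[1, F_P] == pytest.approx(g(0.9) * 0.5)
        assert E[1, OT] == pytest.approx(1.0 * 0.5)

    def test_per_frame_scaling_leaves_posterior_unchanged(self):
        model = default_model()
        rng = np.random.default_rng(3)
        E = rng.uniform(0.2, 1.0, size=(8, 6))
        p1 = forward_backward(E, model)
        E2 = E.copy()
        E2[3] *= 37.0
        p2 = forward_backward(E2, model)
        np.testing.assert_allclose(p1.gamma, p2.gamma, atol=1e-12)

    def test_nonfinite_frame_gets_uniform_emission(self):
        model = default_model()
        obs = ObservationSeries(r=np.array([1.0, np.nan, 1.0]),
                                dx=np.array([0.1, 0.1]), dt=0.5)
        E = emission_matrix(obs, model)
        assert np.allclose(E[1], 1.0)


# ---------------------------------------------------------------------------
# forward-backward

def _brute_force(E, A, pi):
    T, S = E.shape
    gamma = np.zeros((T, S))
    counts = np.zeros((S, S))
    total = 0.0
    for seq in itertools.product(range(S), repeat=T):
        p = pi[seq[0]] * E[0, seq[0]]
        for t in range(1, T):
            p *= A[seq[t - 1], seq[t]] * E[t, seq[t]]
        if p == 0.0:
            continue
        total += p
        for t, s in enumerate(seq):
            gamma[t, s] += p
        for t in range(1, T):
            counts[seq[t - 1], seq[t]] += p
    return gamma / total, counts / total, math.log(total)


class TestForwardBackward:
    def test_posterior_rows_normalized(self):
        model = default_model()
        E = np.random.default_rng(0).uniform(0.1, 1, (50, 6))
        post = forward_backward(E, model)
        np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=5), st.integers(min_value=0, max_value=10**6))
    def test_matches_brute_force_enumeration(self, T, seed):
        model = default_model()
        E = np.random.default_rng(seed).uniform(0.05, 1.0, size=(T, 6))
        post = forward_backward(E, model)
        g_ref, c_ref, ll_ref = _brute_force(E, model.transition, model.initial)
        np.testing.assert_allclose(post.gamma, g_ref, atol=1e-10)
        np.testing.assert_allclose(post.transition_counts, c_ref, atol=1e-10)
        assert post.log_likelihood == pytest.approx(ll_ref, abs=1e-10)

    def test_uniform_emissions_reduce_to_markov_marginals(self):
        model = default_model()
        T = 12
        E = np.full((T, 6), 0.7)
        post = forward_backward(E, model)
        marg = model.initial.copy()
        for t in range(T):
            np.testing.assert_allclose(post.gamma[t], marg, atol=1e-12)
            marg = marg @ model.transition

    def test_long_track_no_underflow(self):
        model = default_model()
        E = np.random.default_rng(5).uniform(0.05, 1.0, size=(100_000, 6))
        post = forward_backward(E, model)
        assert np.isfinite(post.log_likelihood)
        np.testing.assert_allclose(post.gamma.sum(axis=1), 1.0, atol=1e-8)


# ---------------------------------------------------------------------------
# Baum-Welch

def _random_masked_model(rng):
    A = np.where(PERMITTED_MASK, rng.uniform(0.05, 1.0, (6, 6)), 0.0)
    A /= A.sum(axis=1, keepdims=True)
    pi = rng.uniform(0.1, 1.0, 6)
    return HmmModel(transition=A, initial=pi / pi.sum())


class TestBaumWelch:
    def test_log_likelihood_monotone_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            E = rng.uniform(0.05, 1.0, size=(40, 6))
            _, _, lls = baum_welch([E], init_model=_random_masked_model(rng),
                                   max_iter=8)
            assert np.all(np.diff(lls) >= -1e-8 * np.abs(lls[:-1]))

    def test_mask_preserved_and_rows_normalized(self):
        rng = np.random.default_rng(8)
        E = rng.uniform(0.05, 1.0, size=(200, 6))
        model, _, _ = baum_welch([E], max_iter=20)
        assert np.all(model.transition[~PERMITTED_MASK] == 0.0)
        np.testing.assert_allclose(model.transition.sum(axis=1), 1.0, atol=1e-12)

    def test_init_violating_mask_rejected(self):
        A = np.full((6, 6), 1.0 / 6.0)
        bad = HmmModel(transition=A, initial=np.full(6, 1 / 6))
        with pytest.raises(ValueError):
            baum_welch([np.ones((5, 6))], init_model=bad)

    def test_recovers_known_transition_matrix(self):
        # sharply discriminative emissions: transition estimates approach
        # the empirical transition frequencies of the sampled chain
        rng = np.random.default_rng(42)
        A = np.zeros((6, 6))
        A[F_P, F_P], A[F_P, B_P], A[F_P, FT] = 0.93, 0.04, 0.03
        A[F_M, F_M], A[F_M, B_M], A[F_M, FT] = 0.93, 0.04, 0.03
        A[B_P, B_P], A[B_P, F_P], A[B_P, OT] = 0.88, 0.08, 0.04
        A[B_M, B_M], A[B_M, F_M], A[B_M, OT] = 0.88, 0.08, 0.04
        A[FT, FT], A[FT, F_P], A[FT, F_M] = 0.85, 0.075, 0.075
        A[OT, OT], A[OT, F_P], A[OT, F_M] = 0.85, 0.075, 0.075

        dx_mean = {F_P: 0.125, B_M: 0.125, F_M: -0.125, B_P: -0.125, FT: 0.0, OT: 0.0}
        ems = []
        model0 = default_model()
        for _ in range(20):
            T = 5000
            states = np.empty(T, int)
            states[0] = F_P
            for t in range(1, T):
                states[t] = rng.choice(6, p=A[states[t - 1]])
            r = np.where(np.isin(states, [FT, OT]),
                         rng.uniform(0.4, 0.95, T),
                         rng.normal(1.0, 0.075, T))
            dx = np.array([dx_mean[s] for s in states[:-1]]) + rng.normal(0, 0.02, T - 1)
            ems.append(emission_matrix(ObservationSeries(r=r, dx=dx, dt=0.5), model0))
        model, _, _ = baum_welch(ems, max_iter=100)
        assert np.abs(model.transition - A).max() < 0.02

    def test_degenerate_all_forward_input(self):
        # clean forward crawling: backward/turn occupancy below 1%
        rng = np.random.default_rng(9)
        T = 2000
        r = rng.normal(1.0, 0.075, T)
        dx = rng.normal(0.125, 0.01, T - 1)
        obs = ObservationSeries(r=r, dx=dx, dt=0.5)
        model, posts, _ = baum_welch([obs], max_iter=50)
        occ = posts[0].gamma.mean(axis=0)
        assert occ[[B_P, B_M, FT, OT]].sum() < 0.01

    def test_label_swap_symmetry(self):
        # flipping the initial forward/backward rate asymmetry swaps the
        # inferred forward and backward identities.  Turn states are
        # disabled: the omega-turn topology (backward -> omega -> forward)
        # otherwise identifies the absolute direction on its own, whereas
        # this checks the pure bout-length-asymmetry mechanism.
        cfg = TrackSimConfig(n_worms=4, duration=600.0, seed=55,
                             turn_prob_forward=0.0, omega_prob=0.0)
        tracks, _ = simulate_track(cfg)
        m1, p1, _ = baum_welch(tracks, max_iter=60)
        swapped = np.zeros((6, 6))
        swapped[F_P, F_P], swapped[F_P, B_P], swapped[F_P, FT] = 0.93, 0.05, 0.02
        swapped[F_M, F_M], swapped[F_M, B_M], swapped[F_M, FT] = 0.93, 0.05, 0.02
        swapped[B_P, B_P], swapped[B_P, F_P], swapped[B_P, OT] = 0.95, 0.01, 0.04
        swapped[B_M, B_M], swapped[B_M, F_M], swapped[B_M, OT] = 0.95, 0.01, 0.04
        swapped[FT, FT], swapped[FT, F_P], swapped[FT, F_M] = 0.90, 0.05, 0.05
        swapped[OT, OT], swapped[OT, F_P], swapped[OT, F_M] = 0.90, 0.05, 0.05
        init2 = HmmModel(transition=swapped, initial=np.full(6, 1 / 6))
        m2, p2, _ = baum_welch(tracks, init_model=init2, max_iter=60)
        occ1 = np.concatenate([p.gamma for p in p1]).mean(axis=0)
        occ2 = np.concatenate([p.gamma for p in p2]).mean(axis=0)
        fwd1 = occ1[F_P] + occ1[F_M]
        back2 = occ2[B_P] + occ2[B_M]
        assert fwd1 > 0.5  # long bouts called forward under the standard init
        assert back2 == pytest.approx(fwd1, abs=0.05)


# ---------------------------------------------------------------------------
# bout segmentation and survival

class TestSegmentation:
    def _posterior_from_pback(self, p_back):
        gamma = np.zeros((len(p_back), 6))
        gamma[:, B_P] = p_back
        gamma[:, F_P] = 1.0 - p_back
        from boutwave.locomotion import StatePosterior
        return StatePosterior(gamma, np.zeros((6, 6)), 0.0)

    def test_threshold_definition(self):
        p = np.full(30, 0.1)
        p[10:21] = 0.51
        seg = segment_bouts(self._posterior_from_pback(p))
        back = [iv for iv in seg.intervals if iv.label == "backward"]
        assert len(back) == 1
        assert (back[0].start, back[0].end) == (10, 21)

    def test_all_forward_is_one_censored_interval(self):
        seg = segment_bouts(self._posterior_from_pback(np.full(40, 0.2)))
        assert len(seg.intervals) == 1
        iv = seg.intervals[0]
        assert iv.label == "forward" and iv.censored_start and iv.censored_end

    def test_intervals_tile_track(self, decoded_cohort):
        *_, segs = decoded_cohort
        for seg in segs:
            starts = [iv.start for iv in seg.intervals]
            ends = [iv.end for iv in seg.intervals]
            assert starts[0] == 0
            assert all(e == s for e, s in zip(ends[:-1], starts[1:]))

    def test_decoding_accuracy_on_ground_truth(self, decoded_cohort):
        _, tracks, truth, _, posts, _ = decoded_cohort
        correct = total = 0
        for tr, p in zip(tracks, posts):
            true_b = truth.backward_mask(tr.track_id)
            dec_b = (p.gamma[:, B_P] + p.gamma[:, B_M]) > 0.5
            correct += (true_b == dec_b).sum()
            total += len(true_b)
        assert correct / total >= 0.90


class TestSurvival:
    def test_hand_worked_three_bout_example(self):
        mask = np.zeros(30, bool)
        # forward bouts of lengths 2, 2, 4 separated by backward frames
        # layout: B F F B F F B F F F F B ... (pad forward tail censored)
        mask[[0, 3, 6, 11]] = True
        seg = segs_from_mask(mask[:12])
        curve = forward_survival([seg])
        np.testing.assert_allclose(curve.hazard, [0.0, 2 / 3, 0.0, 1.0])
        np.testing.assert_allclose(curve.p_f, [1, 1, 1 / 3, 1 / 3, 0])

    def test_constant_hazard_geometric(self):
        rng = np.random.default_rng(11)
        p = 0.3
        lengths = rng.geometric(p, size=20_000)
        curve = forward_survival([segs_from_mask(mask_from_lengths(lengths))])
        n = np.arange(6)
        np.testing.assert_allclose(curve.p_f[:6], (1 - p) ** n, atol=0.02)

    def test_censoring_leaves_later_hazards_unchanged(self):
        mask = np.zeros(12, bool)
        mask[[0, 3, 6, 11]] = True
        base = forward_survival([segs_from_mask(mask[:12])])
        # add one extra track: a bout censored after 1 step
        extra_mask = np.zeros(2, bool)
        extra_mask[0] = True  # backward then one forward frame, lost
        extra = segs_from_mask(extra_mask)
        cens = forward_survival([segs_from_mask(mask[:12]), extra])
        np.testing.assert_allclose(cens.hazard[1:], base.hazard[1:])
        assert cens.at_risk[0] == base.at_risk[0] + 1

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(13)
        lengths = rng.integers(1, 15, size=500)
        curve = forward_survival([segs_from_mask(mask_from_lengths(lengths))])
        # p_f(n) = probability a bout survives beyond its n-th step
        for n in range(len(curve.p_f)):
            np.testing.assert_allclose(curve.p_f[n], (lengths > n).mean(),
                                       atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_kaplan_meier_oracle(self, seed):
        # independent product-limit oracle on random censored instances
        from lifelines import KaplanMeierFitter
        from boutwave.locomotion import BoutInterval, BoutSegmentation
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        lengths = rng.integers(1, 12, size=n)
        events = rng.random(n) < 0.7
        ivs = [BoutInterval(0, int(L), "forward", censored_start=False,
                            censored_end=not e)
               for L, e in zip(lengths, events)]
        curve = forward_survival([BoutSegmentation([iv], 0.5) for iv in ivs])
        km = KaplanMeierFitter().fit(lengths, events)
        for step in range(1, int(lengths.max()) + 1):
            ref = float(km.survival_function_at_times(step).iloc[0])
            assert curve.p_f[step] == pytest.approx(ref, abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            forward_survival([])


class TestReversalRate:
    def test_no_backward_gives_zero(self):
        mask = np.zeros(100, bool)
        assert reversal_rate([segs_from_mask(mask)]) == 0.0

    def test_simple_arithmetic(self):
        # 10 reversals in 5 worm-minutes -> 2 per minute
        mask = np.zeros(600, bool)  # 600 frames x 0.5 s = 5 min
        for k in range(10):
            mask[30 + 55 * k] = True
        assert reversal_rate([segs_from_mask(mask)]) == pytest.approx(2.0)

    def test_poisson_rate_recovery(self):
        cfg = TrackSimConfig(r0=0.02, delta_r=0.0, backward_rate=2.0,
                             turn_prob_forward=0.0, omega_prob=0.0,
                             n_worms=12, duration=1800.0, seed=77)
        tracks, truth = simulate_track(cfg)
        segs = [segs_from_mask(truth.backward_mask(t.track_id)) for t in tracks]
        rate = reversal_rate(segs)
        # expected 1.2/min; binomial SE on ~430 events
        n_events = sum(1 for s in segs for iv in s.intervals
                       if iv.label == "backward" and iv.start > 0)
        se = 60.0 * math.sqrt(n_events) / (12 * 1800)
        assert abs(rate - 1.2) < 3 * se + 0.05
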