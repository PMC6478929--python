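"""Six-state hidden Markov model for worm crawling behavior.

Tracks of a crawling C. elegans are reduced to two observables per frame:
the relative body elongation ``r`` (instantaneous ellipse long axis divided
by its track average; near 1 while crawling, below 1 during deep bends) and
the displacement ``dx`` projected on the body axis.  Because head and tail
are not distinguishable in low-resolution tracking, forward and backward
crawling each come in two flavors (+/-) depending on whether increasing
projected coordinate corresponds to forward movement; turns carry no sign.
The six states are::

    forward+  forward-  backward+  backward-  forward_turn  omega_turn

Transition probabilities are estimated per movie by Baum-Welch on a fixed
permitted-transition topology; emission parameters (sigma_r, c) are fixed.
Bouts of forward/backward movement are decoded by thresholding the summed
posterior probability of the backward states at 1/2, and forward-bout
durations are summarized by a censoring-aware discrete product-limit
survival estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

__all__ = [
    "STATES",
    "PERMITTED_MASK",
    "WormTrack",
    "ObservationSeries",
    "HmmModel",
    "StatePosterior",
    "BoutInterval",
    "BoutSegmentation",
    "SurvivalCurve",
    "default_model",
    "elongation_from_points",
    "preprocess_track",
    "r_emission",
    "direction_factor",
    "emission_matrix",
    "forward_backward",
    "baum_welch",
    "segment_bouts",
    "forward_survival",
    "reversal_rate",
]

STATES = (
    "forward+",
    "forward-",
    "backward+",
    "backward-",
    "forward_turn",
    "omega_turn",
)
F_P, F_M, B_P, B_M, FT, OT = range(6)
CRAWLING = (F_P, F_M, B_P, B_M)
TURNING = (FT, OT)
BACKWARD = (B_P, B_M)

SIGMA_R = 0.075   # width of the crawling elongation distribution
C_VELOCITY = 0.1  # mm/s, confidence scale for direction scoring

# Permitted transitions: self loops everywhere; reversals keep the +/- sign;
# forward turns connect only to forward crawling; omega turns occur only in
# the sequence backward -> omega -> forward (either sign, since the omega
# turn reorients the body and may flip the projection coordinate).
PERMITTED_MASK = np.zeros((6, 6), dtype=bool)
for _s in range(6):
    PERMITTED_MASK[_s, _s] = True
PERMITTED_MASK[F_P, B_P] = PERMITTED_MASK[B_P, F_P] = True
PERMITTED_MASK[F_M, B_M] = PERMITTED_MASK[B_M, F_M] = True
PERMITTED_MASK[F_P, FT] = PERMITTED_MASK[FT, F_P] = True
PERMITTED_MASK[F_M, FT] = PERMITTED_MASK[FT, F_M] = True
PERMITTED_MASK[B_P, OT] = True
PERMITTED_MASK[B_M, OT] = True
PERMITTED_MASK[OT, F_P] = True
PERMITTED_MASK[OT, F_M] = True

_EMISSION_FLOOR = 1e-15


@dataclass
class WormTrack:
    """Per-frame kinematic and shape observations for one animal.

    ``axis`` rows are unit vectors with arbitrary sign; ``elongation`` is the
    ellipse long axis in mm.  ``censored_start``/``censored_end`` mark tracks
    that begin/end because the worm was lost rather than the movie ending.
    """

    track_id: str
    time: np.ndarray          # (n,) seconds, uniform step
    position: np.ndarray      # (n, 2) mm
    axis: np.ndarray          # (n, 2) unit vectors, sign arbitrary
    elongation: np.ndarray    # (n,) mm, > 0
    censored_start: bool = True
    censored_end: bool = True

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.elongation = np.asarray(self.elongation, dtype=float)
        n = len(self.time)
        if self.position.shape != (n, 2) or self.axis.shape != (n, 2):
            raise ValueError("position/axis must have shape (n_frames, 2)")
        if self.elongation.shape != (n,):
            raise ValueError("elongation must have shape (n_frames,)")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class ObservationSeries:
    """Relative elongation and projected displacement for one track."""

    r: np.ndarray    # (n,) dimensionless, track mean 1 by construction
    dx: np.ndarray   # (n-1,) mm, displacement projected on the body axis
    dt: float        # s


@dataclass
class HmmModel:
    transition: np.ndarray            # (6, 6), rows sum to 1, respects mask
    initial: np.ndarray               # (6,)
    sigma_r: float = SIGMA_R
    c: float = C_VELOCITY
    states: tuple = STATES

    def validate(self) -> None:
        if self.transition.shape != (6, 6):
            raise ValueError("transition matrix must be 6x6")
        if np.any(self.transition[~PERMITTED_MASK] != 0.0):
            raise ValueError("transition matrix violates the permitted-transition mask")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if self.sigma_r <= 0 or self.c <= 0:
            raise ValueError("sigma_r and c must be positive")


@dataclass
class StatePosterior:
    """Forward-backward output for one track."""

    gamma: np.ndarray             # (n, 6) per-frame state probabilities
    transition_counts: np.ndarray  # (6, 6) expected transition counts
    log_likelihood: float


@dataclass
class BoutInterval:
    start: int          # frame index, inclusive
    end: int            # frame index, exclusive
    label: str          # "forward" | "backward"
    censored_start: bool = False
    censored_end: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BoutSegmentation:
    intervals: list
    dt: float


@dataclass
class SurvivalCurve:
    """Discrete survival of forward-bout durations.

    ``hazard[i]`` is the probability that a bout which has lasted i+1 steps
    ends there; ``p_f[n]`` is the probability a bout lasts at least n steps,
    ``p_f[n] = prod_{i<n}(1 - hazard[i])``.
    """

    p_f: np.ndarray        # (L+1,), p_f[0] = 1
    hazard: np.ndarray     # (L,)
    at_risk: np.ndarray    # (L,) bouts at risk per step
    events: np.ndarray     # (L,) bouts ending per step
    dt: float

    @property
    def times(self) -> np.ndarray:
        """Time grid (s) for p_f: 0, dt, 2 dt, ..."""
        return np.arange(len(self.p_f)) * self.dt


def default_model() -> HmmModel:
    """Baum-Welch initializer.

    Backward->forward exceeds forward->backward (0.05 vs 0.01 per frame):
    this asymmetry lets EM converge to the labeling where the longer bouts
    are forward, which is how the absolute direction of movement is inferred
    from the fact that backward bouts are much briefer than forward ones.
    """
    A = np.zeros((6, 6))
    A[F_P, F_P], A[F_P, B_P], A[F_P, FT] = 0.95, 0.01, 0.04
    A[F_M, F_M], A[F_M, B_M], A[F_M, FT] = 0.95, 0.01, 0.04
    A[B_P, B_P], A[B_P, F_P], A[B_P, OT] = 0.93, 0.05, 0.02
    A[B_M, B_M], A[B_M, F_M], A[B_M, OT] = 0.93, 0.05, 0.02
    A[FT, FT], A[FT, F_P], A[FT, F_M] = 0.90, 0.05, 0.05
    A[OT, OT], A[OT, F_P], A[OT, F_M] = 0.90, 0.05, 0.05
    model = HmmModel(transition=A, initial=np.full(6, 1.0 / 6.0))
    model.validate()
    return model


def elongation_from_points(points: np.ndarray):
    """Fit an ellipse to a point cloud via its inertia (second-moment) matrix.

    Returns ``(elongation, axis, degenerate)`` where elongation is
    ``2*sqrt(largest eigenvalue)`` of the per-point second central moment
    matrix and axis is the corresponding unit eigenvector.  The constant in
    front of the square root is immaterial downstream, where only relative
    elongation enters.  ``degenerate`` is True for isotropic clouds, whose
    axis is arbitrary.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 two-dimensional points")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    lam_max = evals[-1]
    if lam_max <= 0:
        raise ValueError("degenerate point cloud: all points coincide")
    degenerate = bool(np.isclose(evals[0], evals[1], rtol=1e-9, atol=0.0))
    axis = evecs[:, -1]
    return 2.0 * math.sqrt(lam_max), axis, degenerate


def preprocess_track(track: WormTrack) -> ObservationSeries:
    """Derive relative elongation and axis-projected displacement.

    The raw axis sign is arbitrary frame to frame; it is made continuous by
    flipping any frame whose axis opposes the previous frame's, so that the
    relation between changes of the projected coordinate and the direction of
    movement stays consistent along the track.  Which global sign corresponds
    to forward movement is left to the HMM.
    """
    elong = track.elongation
    if np.any(elong <= 0):
        raise ValueError("elongation must be positive")
    r = elong / elong.mean()

    axis = track.axis.copy()
    norms = np.linalg.norm(axis, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length body axis")
    axis /= norms[:, None]
    for t in range(1, len(axis)):
        if axis[t] @ axis[t - 1] < 0:
            axis[t] = -axis[t]

    disp = np.diff(track.position, axis=0)
    dx = np.einsum("ij,ij->i", disp, axis[:-1])
    return ObservationSeries(r=r, dx=dx, dt=track.dt)


def r_emission(r, kind: str, sigma: float = SIGMA_R):
    """Likelihood of relative elongation ``r`` given crawling or turning.

    Crawling: Gaussian(1, sigma) density.  Turning: uniform value 1 for
    r <= 1, decaying as the same Gaussian for r > 1 (deliberately
    unnormalized; constant factors cancel in the per-frame posterior).
    """
    r = np.asarray(r, dtype=float)
    if kind == "crawling":
        return np.exp(-((r - 1.0) ** 2) / (2.0 * sigma**2)) / (sigma * math.sqrt(2 * math.pi))
    if kind == "turning":
        return np.where(r <= 1.0, 1.0, np.exp(-((r - 1.0) ** 2) / (2.0 * sigma**2)))
    raise ValueError(f"unknown emission class {kind!r}")


def _sigmoid(x):
    return (1.0 + erf(2.0 * np.asarray(x, dtype=float))) / 2.0


def direction_factor(dx, dt: float, state: int, c: float = C_VELOCITY):
    """Probability of a state given the projected displacement.

    forward+ and backward- score high for positive dx, forward- and
    backward+ for negative dx; turning states are direction-blind (constant
    1/2, which cancels under posterior normalization).  The sigmoid scale
    ``c*dt`` demands a finite displacement before the direction is scored
    with confidence, discounting positional jitter of a resting worm.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(dx, dtype=float) / (c * dt)
    if state in (F_P, B_M):
        return _sigmoid(x)
    if state in (F_M, B_P):
        return 1.0 - _sigmoid(x)
    if state in (FT, OT):
        return np.full_like(x, 0.5)
    raise ValueError(f"unknown state index {state}")


def emission_matrix(obs: ObservationSeries, model: HmmModel) -> np.ndarray:
    """Per-frame x per-state likelihood, strictly positive.

    The last frame has no displacement; its direction factor is a constant
    (uniform across states) and drops out of the posterior.  Frames with
    non-finite observations get uniform emissions instead of breaking the
    track.
    """
    n = len(obs.r)
    if len(obs.dx) != n - 1:
        raise ValueError("dx must be one shorter than r")
    E = np.ones((n, 6))
    crawl = r_emission(obs.r, "crawling", model.sigma_r)
    turn = r_emission(obs.r, "turning", model.sigma_r)
    for s in CRAWLING:
        E[:, s] = crawl
    for s in TURNING:
        E[:, s] = turn
    dx_pad = np.concatenate([obs.dx, [0.0]])  # constant factor at last frame
    for s in range(6):
        E[:, s] *= direction_factor(dx_pad, obs.dt, s, model.c)
    bad = ~np.isfinite(obs.r)
    bad[:-1] |= ~np.isfinite(obs.dx)
    E[bad] = 1.0
    return np.maximum(E, _EMISSION_FLOOR)


def _fb_batch(E: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward over a batch of equal-length tracks.

    E: (B, T, S) strictly positive emissions.  Returns per-track posteriors
    (B, T, S), expected transition counts (B, S, S) and log-likelihoods (B,).
    """
    B, T, S = E.shape
    alpha = np.empty((B, T, S))
    c = np.empty((B, T))
    a = pi[None, :] * E[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * E[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    beta_next = np.ones((B, S))
    gamma = np.empty((B, T, S))
    gamma[:, -1] = alpha[:, -1]
    counts = np.zeros((B, S, S))
    for t in range(T - 2, -1, -1):
        eb = E[:, t + 1] * beta_next / c[:, t + 1, None]
        counts += alpha[:, t, :, None] * A[None, :, :] * eb[:, None, :]
        beta_next = eb @ A.T
        gamma[:, t] = alpha[:, t] * beta_next
    return gamma, counts, np.log(c).sum(axis=1)


def forward_backward(emissions: np.ndarray, model: HmmModel) -> StatePosterior:
    """Posterior state probabilities and expected transition counts.

    Uses scaled recursions, so tracks of 1e5+ frames pose no underflow risk.
    """
    model.validate()
    E = np.asarray(emissions, dtype=float)
    if E.ndim != 2 or E.shape[1] != 6:
        raise ValueError("emissions must have shape (n_frames, 6)")
    if np.any(E <= 0):
        raise ValueError("emissions must be strictly positive")
    gamma, counts, ll = _fb_batch(E[None], model.transition, model.initial)
    return StatePosterior(gamma=gamma[0], transition_counts=counts[0],
                          log_likelihood=float(ll[0]))


def _as_emissions(tracks, model: HmmModel):
    out = []
    for tr in tracks:
        if isinstance(tr, WormTrack):
            out.append(emission_matrix(preprocess_track(tr), model))
        elif isinstance(tr, ObservationSeries):
            out.append(emission_matrix(tr, model))
        else:
            out.append(np.asarray(tr, dtype=float))
    return out


def baum_welch(tracks, init_model: HmmModel | None = None,
               tol: float = 1e-6, max_iter: int = 200):
    """Estimate transition probabilities by EM, pooled across tracks.

    ``tracks`` may be WormTrack, ObservationSeries or raw (T, 6) emission
    arrays.  Only the transition matrix and initial distribution are
    re-estimated; emission parameters stay fixed.  Forbidden transitions
    remain exactly zero, and the total log-likelihood is non-decreasing
    across iterations.  Returns ``(model, posteriors, log_likelihoods)``.
    """
    model = init_model if init_model is not None else default_model()
    model.validate()
    ems = _as_emissions(tracks, model)
    if not ems:
        raise ValueError("no tracks provided")
    # group equal-length tracks so forward-backward runs batched
    groups: dict = {}
    for i, E in enumerate(ems):
        groups.setdefault(E.shape[0], []).append(i)
    stacked = {T: np.stack([ems[i] for i in idx]) for T, idx in groups.items()}

    A = model.transition.copy()
    pi = model.initial.copy()
    lls = []
    posteriors = [None] * len(ems)
    for _ in range(max_iter):
        total_counts = np.zeros((6, 6))
        pi_acc = np.zeros(6)
        ll = 0.0
        for T, idx in groups.items():
            gamma, counts, ll_b = _fb_batch(stacked[T], A, pi)
            total_counts += counts.sum(axis=0)
            pi_acc += gamma[:, 0].sum(axis=0)
            ll += float(ll_b.sum())
            for k, i in enumerate(idx):
                posteriors[i] = StatePosterior(gamma[k], counts[k], float(ll_b[k]))
        lls.append(ll)
        row = total_counts.sum(axis=1, keepdims=True)
        A_new = np.where(row > 0, total_counts / np.where(row > 0, row, 1.0), A)
        A_new[~PERMITTED_MASK] = 0.0
        rs = A_new.sum(axis=1, keepdims=True)
        A = A_new / np.where(rs > 0, rs, 1.0)
        pi = pi_acc / pi_acc.sum()
        if len(lls) > 1 and (lls[-1] - lls[-2]) < tol * abs(lls[-2]):
            break
    fitted = replace(model, transition=A, initial=pi)
    return fitted, posteriors, np.array(lls)


def segment_bouts(posterior: StatePosterior, dt: float = 0.5) -> BoutSegmentation:
    """Threshold the backward-state posterior at 1/2 into bout intervals.

    A frame is backward iff P(backward+) + P(backward-) > 0.5; turning
    frames therefore count as part of the surrounding forward period.
    Intervals touching the track boundary are flagged censored on that side.
    """
    p_back = posterior.gamma[:, B_P] + posterior.gamma[:, B_M]
    is_back = p_back > 0.5
    n = len(is_back)
    intervals = []
    start = 0
    for t in range(1, n + 1):
        if t == n or is_back[t] != is_back[start]:
            intervals.append(BoutInterval(
                start=start, end=t,
                label="backward" if is_back[start] else "forward",
                censored_start=(start == 0),
                censored_end=(t == n),
            ))
            start = t
    return BoutSegmentation(intervals=intervals, dt=dt)


def forward_survival(segmentations) -> SurvivalCurve:
    """Discrete product-limit estimate of forward-bout survival.

    The per-step hazard ``p_f->b(i)`` is (bouts ending after i+1 steps) /
    (bouts still at risk there); bouts whose end is censored leave the risk
    set without counting as events, and bouts whose *start* is censored are
    excluded outright because their elapsed forward time is unknown.
    """
    lengths, events = [], []
    dt = None
    for seg in segmentations:
        dt = seg.dt if dt is None else dt
        for iv in seg.intervals:
            if iv.label != "forward" or iv.censored_start:
                continue
            lengths.append(iv.length)
            events.append(not iv.censored_end)
    if not lengths:
        raise ValueError("no usable (start-observed) forward bouts")
    lengths = np.asarray(lengths, dtype=int)
    events = np.asarray(events, dtype=bool)
    L = int(lengths.max())
    ev = np.zeros(L)
    cen = np.zeros(L)
    for ln, e in zip(lengths, events):
        (ev if e else cen)[ln - 1] += 1
    # at risk at step i: bouts with length >= i+1
    tail = (ev + cen)[::-1].cumsum()[::-1]
    hazard = np.where(tail > 0, ev / np.where(tail > 0, tail, 1.0), 0.0)
    p_f = np.concatenate([[1.0], np.cumprod(1.0 - hazard)])
    return SurvivalCurve(p_f=p_f, hazard=hazard, at_risk=tail, events=ev, dt=float(dt))


def reversal_rate(segmentations) -> float:
    """Forward-to-backward transitions per worm-minute of observed track."""
    n_rev = 0
    total_s = 0.0
    for seg in segmentations:
        for iv in seg.intervals:
            total_s += iv.length * seg.dt
            if iv.label == "backward" and iv.start > 0:
                n_rev += 1
    if total_s <= 0:
        raise ValueError("no observed track time")
    return n_rev / (total_s / 60.0)
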