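"""Seeded generators for every input the pipeline consumes.

Each generator returns its outputs together with ground truth (true state
labels, event times, planted gene sets), so downstream stages can be tested
without any external data.  All generators are deterministic given
config + seed.

The track generator is the discrete-time inverse of the repetitive-reversal
hazard model: while a worm crawls forward, the per-step probability of
reversing is ``1 - exp(-r(t) dt)`` with ``r(t) = r0 + delta_r exp(-t/tau)``
and t the time since the forward period began, so the planted forward-bout
survival is analytically known.  Backward bouts end at a constant hazard,
optionally through an omega turn that reorients the body.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .locomotion import (
    B_M,
    B_P,
    F_M,
    F_P,
    FT,
    OT,
    STATES,
    WormTrack,
)

__all__ = [
    "TrackSimConfig",
    "TraceSimConfig",
    "ExprSimConfig",
    "TrackGroundTruth",
    "TraceGroundTruth",
    "MotionGroundTruth",
    "ExprGroundTruth",
    "FluorescenceTrace",
    "MotionTrace",
    "simulate_track",
    "simulate_trace_pair",
    "simulate_motion_calcium",
    "simulate_expression",
]


def _check_finite(cfg, names):
    for name in names:
        v = getattr(cfg, name)
        if isinstance(v, (int, float)) and not math.isfinite(v):
            raise ValueError(f"config field {name!r} must be finite, got {v}")


@dataclass
class TrackSimConfig:
    """Conditions of a 30-min free-crawling movie at 2 frames/s.

    Defaults are the repetitive-reversal phenotype the index is built to
    detect: baseline rate r0 = 0.02 /s with a short-time boost decaying over
    tau = 20 s whose integrated excess delta_l = tau*delta_r equals ln 2
    (repetitive index 1).  Crawl speed 0.25 mm/s is the typical velocity of
    a moving worm.
    """

    r0: float = 0.02                 # baseline forward->backward hazard, 1/s
    delta_r: float = math.log(2) / 20.0  # hazard boost at bout start, 1/s
    tau: float = 20.0                # boost decay time, s
    backward_rate: float = 0.5       # backward->forward hazard, 1/s
    turn_prob_forward: float = 0.005  # per-step probability of a forward turn
    omega_prob: float = 0.5          # backward bouts ending via omega turn
    speed: float = 0.25              # crawl speed, mm/s
    heading_sd: float = 0.15         # per-step heading diffusion, rad
    elong_mean_turn: float = 0.6     # mean relative elongation while turning
    frame_rate: float = 2.0          # frames/s
    duration: float = 1800.0         # s
    n_worms: int = 20
    seed: int = 0
    body_length: float = 1.0         # mm, sets the elongation scale
    elong_sd: float = 0.075          # sd of relative elongation while crawling
    position_noise_sd: float = 0.005  # mm, centroid jitter
    axis_flip_prob: float = 0.02     # raw axis sign flips (sign is arbitrary)
    lost_rate: float = 0.0           # 1/s, track-loss hazard (censoring splits)
    turn_continue_prob: float = 0.75  # per-step probability a turn continues

    def validate(self) -> None:
        _check_finite(self, [f.name for f in self.__dataclass_fields__.values()])
        for name in ("r0", "delta_r", "tau", "backward_rate", "speed",
                     "heading_sd", "lost_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("turn_prob_forward", "omega_prob", "axis_flip_prob",
                     "turn_continue_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not self.elong_mean_turn < 1.0:
            raise ValueError("elong_mean_turn must be < 1")
        if self.n_worms <= 0 or self.duration <= 0:
            raise ValueError("n_worms and duration must be positive")


@dataclass
class TrackGroundTruth:
    """True per-frame six-state labels, keyed like the returned tracks."""

    states: dict          # track_id -> (n,) int array indexing STATES
    worm_states: list     # per-worm full-length label arrays (pre-split)
    config: TrackSimConfig

    def backward_mask(self, track_id: str) -> np.ndarray:
        s = self.states[track_id]
        return (s == B_P) | (s == B_M)


def _forward_duration(cfg: TrackSimConfig, rng, max_frames: int) -> int:
    """Frames until reversal, drawn from the discrete planted hazard.

    Per-step reversal probability is 1 - exp(-r(i dt) dt) with
    r(t) = r0 + delta_r exp(-t/tau), so the binary forward-period durations
    follow the planted survival law exactly (up to track-end censoring).
    """
    dt = 1.0 / cfg.frame_rate
    for i in range(max_frames):
        rate = cfg.r0 + cfg.delta_r * math.exp(-(i * dt) / cfg.tau)
        if rng.random() < 1.0 - math.exp(-rate * dt):
            return i + 1
    return max_frames


def _geometric_frames(rng, p_continue: float, lo: int = 1) -> int:
    k = lo
    while rng.random() < p_continue:
        k += 1
    return k


def _simulate_worm(cfg: TrackSimConfig, rng: np.random.Generator):
    """One worm's frames: coarse state plan first, then kinematics.

    The binary forward/backward alternation is sampled directly from the
    planted hazards so its bout-duration law is exactly the closed form;
    turn states are then overlaid *within* forward periods (an omega-turn
    prefix after omega-terminated reversals, forward-turn runs in the
    interior) without altering the binary durations.
    """
    n = int(round(cfg.duration * cfg.frame_rate))
    dt = 1.0 / cfg.frame_rate
    F, B, TURN_F, TURN_O = 0, 1, 2, 3
    p_back_end = 1.0 - math.exp(-cfg.backward_rate * dt)

    coarse = np.empty(n, dtype=int)
    i = 0
    omega_pending = False
    while i < n:
        # forward period
        k = _forward_duration(cfg, rng, n - i)
        seg = np.full(k, F)
        pos0 = 0
        # the omega prefix must leave at least one crawl frame before the
        # next reversal (the state topology has no omega -> backward path)
        if omega_pending and k >= 2:
            m = min(_geometric_frames(rng, cfg.turn_continue_prob), k - 1)
            seg[:m] = TURN_O
            pos0 = m
        # forward-turn runs sit strictly inside crawl frames: one crawl frame
        # before (turns start only from forward crawling) and one after
        j = pos0 + 1
        while j < k - 1:
            if rng.random() < cfg.turn_prob_forward:
                m = min(_geometric_frames(rng, cfg.turn_continue_prob), k - 1 - j)
                seg[j:j + m] = TURN_F
                j += m + 1
            else:
                j += 1
        coarse[i:i + k] = seg
        i += k
        if i >= n:
            break
        # backward period
        kb = min(_geometric_frames(rng, 1.0 - p_back_end), n - i)
        coarse[i:i + kb] = B
        i += kb
        omega_pending = rng.random() < cfg.omega_prob

    theta = rng.uniform(0, 2 * math.pi)
    pos = rng.uniform(0, 10, size=2)   # mm, arena offset only
    raw_sign = 1.0 if rng.random() < 0.5 else -1.0
    states6 = np.empty(n, dtype=int)
    positions = np.empty((n, 2))
    axes = np.empty((n, 2))
    elong = np.empty(n)
    prev_heading = None
    orient = 1  # +1: forward movement corresponds to increasing projection
    for t in range(n):
        state = coarse[t]
        heading = np.array([math.cos(theta), math.sin(theta)])
        if prev_heading is not None and heading @ prev_heading < 0:
            orient = -orient  # body-axis continuity flips at sharp turns
        prev_heading = heading

        if state == F:
            states6[t] = F_P if orient > 0 else F_M
        elif state == B:
            states6[t] = B_P if orient > 0 else B_M
        elif state == TURN_F:
            states6[t] = FT
        else:
            states6[t] = OT

        if state in (F, B):
            rel = 1.0 + cfg.elong_sd * rng.standard_normal()
        else:
            rel = cfg.elong_mean_turn + cfg.elong_sd * rng.standard_normal()
        elong[t] = max(rel, 0.1) * cfg.body_length

        if rng.random() < cfg.axis_flip_prob:
            raw_sign = -raw_sign
        axes[t] = raw_sign * heading
        positions[t] = pos + cfg.position_noise_sd * rng.standard_normal(2)

        # advance kinematics to the next frame
        if state == F:
            pos = pos + cfg.speed * dt * heading
            theta += cfg.heading_sd * math.sqrt(dt) * rng.standard_normal()
        elif state == B:
            pos = pos - cfg.speed * dt * heading
            theta += cfg.heading_sd * math.sqrt(dt) * rng.standard_normal()
        elif state == TURN_F:
            theta += rng.normal(0.0, 0.8)
        else:  # omega turn: deep bend, net heading near-reversal at its end
            if t + 1 < n and coarse[t + 1] != TURN_O:
                theta += math.pi + rng.normal(0.0, 0.5)
            else:
                theta += rng.normal(0.0, 0.3)
    time = np.arange(n) * dt
    return time, positions, axes, elong, states6


def simulate_track(config: TrackSimConfig):
    """Simulate free-crawling worm tracks with known state labels.

    Returns ``(tracks, ground_truth)``.  With ``lost_rate > 0`` each worm's
    track is split at exponentially distributed loss times into separately
    censored tracks, exercising the censoring-aware survival estimator.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.frame_rate
    tracks = []
    states_by_id = {}
    worm_states = []
    for w in range(config.n_worms):
        time, pos, axes, elong, states6 = _simulate_worm(config, rng)
        worm_states.append(states6)
        n = len(time)
        # split points from a Poisson loss process
        cuts = [0]
        if config.lost_rate > 0:
            t_lost = rng.exponential(1.0 / config.lost_rate)
            while t_lost < config.duration:
                k = int(t_lost / dt)
                if k > cuts[-1] + 1:
                    cuts.append(k)
                t_lost += rng.exponential(1.0 / config.lost_rate)
        cuts.append(n)
        for j in range(len(cuts) - 1):
            a, b = cuts[j], cuts[j + 1]
            if b - a < 2:
                continue
            tid = f"worm{w:03d}" if len(cuts) == 2 else f"worm{w:03d}_seg{j}"
            tracks.append(WormTrack(
                track_id=tid,
                time=time[a:b],
                position=pos[a:b],
                axis=axes[a:b],
                elongation=elong[a:b],
                censored_start=(j > 0),
                censored_end=(j < len(cuts) - 2),
            ))
            states_by_id[tid] = states6[a:b]
    return tracks, TrackGroundTruth(states=states_by_id,
                                    worm_states=worm_states, config=config)


# ---------------------------------------------------------------------------
# fluorescence traces


@dataclass
class FluorescenceTrace:
    """One channel of a 1 frame/s fluorescence recording."""

    time: np.ndarray
    F: np.ndarray
    channel: str                      # "calcium" | "glutamate"
    animal_id: str = "a0"
    genotype: str = "unknown"
    cue_removal_times: tuple = ()     # start times (s) of food-cue removals
    record_duration: float = 540.0    # pre-cue spontaneous window, s


@dataclass
class TraceSimConfig:
    """Paired glutamate/calcium recording at 1 frame/s.

    ``record_duration`` is the 540 s spontaneous window during which the
    food cue is continuously present; the generated trace extends past it
    through the cue-removal cycles (defaults: 20 s and 10 s removals), which
    serve only to verify cue responsiveness.
    """

    onset_time: float = 120.0         # s, start of spontaneous activity
    transient_interval: float = 25.0  # s, mean spacing of post-onset events
    interval_jitter_sd: float = 2.0   # s
    periodic: bool = True             # periodic vs Poisson event times
    ca_amplitude: float = 1.0         # a.u.
    glu_amplitude: float = 0.5        # a.u.
    ca_rise: float = 1.5              # s
    ca_decay: float = 6.0             # s
    glu_decay: float = 2.0            # s
    glu_rise: float = 0.5             # s
    glu_lead: float = 2.0             # s, glutamate precedes calcium
    noise_sd: float = 0.02            # a.u.
    record_duration: float = 540.0    # s, pre-cue window
    cue_removals: tuple = ((560.0, 20.0), (600.0, 10.0))  # (start s, length s)
    frame_rate: float = 1.0           # 1/s
    seed: int = 0
    baseline: float = 0.1             # a.u.

    def validate(self) -> None:
        _check_finite(self, ["onset_time", "transient_interval", "ca_decay",
                             "glu_decay", "noise_sd", "record_duration"])
        if not 0.0 <= self.onset_time <= self.record_duration:
            raise ValueError("onset_time must lie within the record window")
        for name in ("ca_rise", "ca_decay", "glu_decay", "glu_rise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.transient_interval <= 0:
            raise ValueError("transient_interval must be positive")


@dataclass
class TraceGroundTruth:
    onset_time: float
    event_times: np.ndarray
    config: TraceSimConfig


def _alpha_kernel(t, rise, decay):
    """Difference-of-exponentials transient, peak-normalized to 1."""
    t = np.asarray(t, dtype=float)
    k = np.zeros_like(t)
    m = t >= 0
    if abs(decay - rise) < 1e-9:  # limit case: the classic alpha function
        k[m] = (t[m] / rise) * np.exp(1.0 - t[m] / rise)
        return k
    k[m] = np.exp(-t[m] / decay) - np.exp(-t[m] / rise)
    tp = rise * decay / (decay - rise) * math.log(decay / rise) if decay != rise else rise
    peak = math.exp(-tp / decay) - math.exp(-tp / rise)
    return k / peak


def simulate_trace_pair(config: TraceSimConfig):
    """Simulate a glutamate/calcium trace pair with known event times.

    Glutamate transients occur at the event times; calcium transients follow
    ``glu_lead`` seconds later with a slower kernel.  Baselines are flat
    before ``onset_time``; each cue removal adds one response transient.
    Events past the end of the recording are truncated, not an error.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.frame_rate
    total = config.record_duration
    if config.cue_removals:
        total = max(total, max(s + ln for s, ln in config.cue_removals) + 30.0)
    n = int(round(total * config.frame_rate))
    time = np.arange(n) * dt

    events = []
    if config.periodic:
        t = config.onset_time
        while t < config.record_duration:
            events.append(t)
            t += config.transient_interval + config.interval_jitter_sd * rng.standard_normal()
    else:
        t = config.onset_time
        while t < config.record_duration:
            events.append(t)
            t += rng.exponential(config.transient_interval)
    events = np.asarray([e for e in events if 0 <= e < total])

    glu = np.full(n, config.baseline)
    ca = np.full(n, config.baseline)
    for e in events:
        glu += config.glu_amplitude * _alpha_kernel(time - e, config.glu_rise, config.glu_decay)
        ca += config.ca_amplitude * _alpha_kernel(time - e - config.glu_lead,
                                                  config.ca_rise, config.ca_decay)
    for start, _length in config.cue_removals:
        glu += config.glu_amplitude * _alpha_kernel(time - start, config.glu_rise, config.glu_decay)
        ca += config.ca_amplitude * _alpha_kernel(time - start, config.ca_rise, config.ca_decay)
    glu = glu + config.noise_sd * rng.standard_normal(n)
    ca = ca + config.noise_sd * rng.standard_normal(n)

    cue_times = tuple(s for s, _l in config.cue_removals)
    common = dict(time=time, cue_removal_times=cue_times,
                  record_duration=config.record_duration)
    glu_trace = FluorescenceTrace(F=glu, channel="glutamate", **common)
    ca_trace = FluorescenceTrace(F=ca, channel="calcium", **common)
    return (glu_trace, ca_trace), TraceGroundTruth(
        onset_time=float(config.onset_time), event_times=events, config=config)


# ---------------------------------------------------------------------------
# head motion / calcium state association


@dataclass
class MotionTrace:
    """Head x-position at 1 frame/s, with optional known episode bounds."""

    time: np.ndarray
    x: np.ndarray


@dataclass
class MotionGroundTruth:
    episodes: list        # (start_frame, end_frame, state "high"|"low")
    motion_signs: list    # per-episode net displacement sign (+1 forward)
    phi_target: float


def simulate_motion_calcium(phi_target: float, seed: int = 0,
                            n_episodes: int = 20,
                            episode_mean_s: float = 20.0,
                            frame_rate: float = 1.0,
                            noise_sd: float = 0.02,
                            drift_mm: float = 2.0):
    """Alternating calcium high/low episodes with correlated head motion.

    Per episode the net head displacement sign agrees with the calcium state
    (high -> backward, low -> forward) with probability (1 + phi_target)/2,
    which plants an expected phi coefficient of ``phi_target``.
    Returns ``(motion, calcium_trace, ground_truth)``.
    """
    if not 0.0 <= phi_target <= 1.0:
        raise ValueError("phi_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    lengths = np.maximum(rng.poisson(episode_mean_s * frame_rate, n_episodes), 8)
    n = int(lengths.sum())
    time = np.arange(n) * dt

    ca = np.empty(n)
    x = np.empty(n)
    episodes = []
    signs = []
    pos = 0.0
    i = 0
    state_high = bool(rng.random() < 0.5)
    p_agree = (1.0 + phi_target) / 2.0
    for ln in lengths:
        ln = int(ln)
        level = 1.0 if state_high else 0.0
        ca[i:i + ln] = level
        agree = rng.random() < p_agree
        backward = agree if state_high else not agree
        sign = -1.0 if backward else 1.0
        step = sign * drift_mm / ln
        for k in range(ln):
            pos += step + 0.01 * rng.standard_normal()
            x[i + k] = pos
        episodes.append((i, i + ln, "high" if state_high else "low"))
        signs.append(int(sign))
        i += ln
        state_high = not state_high
    # smooth calcium level changes over ~2 s so derivative crossings are clean
    from scipy.ndimage import gaussian_filter1d
    ca = gaussian_filter1d(ca, 1.0 / dt, mode="nearest")
    ca += noise_sd * rng.standard_normal(n)
    motion = MotionTrace(time=time, x=x)
    trace = FluorescenceTrace(time=time, F=ca, channel="calcium",
                              record_duration=float(n * dt))
    return motion, trace, MotionGroundTruth(episodes=episodes,
                                            motion_signs=signs,
                                            phi_target=float(phi_target))


# ---------------------------------------------------------------------------
# cross-species expression tables


@dataclass
class ExprSimConfig:
    """Ortholog-linked worm/mouse expression tables with planted association.

    Worm-enriched genes have their orthologs enriched in the planted target
    mouse cell type with probability ``association_strength``; everywhere
    else enrichment is at the background rate ``enriched_fraction``.
    """

    n_worm_genes: int = 800
    n_mouse_genes: int = 1200
    n_cell_types: int = 5
    ortholog_density: float = 1.2     # expected orthologs per worm gene
    enriched_fraction: float = 0.1    # background enrichment rate per cell type
    association_strength: float = 0.5
    fe_scale: float = 3.0             # log2 FE magnitude for enriched genes
    seed: int = 0
    worm_enriched_fraction: float = 0.1
    target_cell_type: int = 0

    def validate(self) -> None:
        if min(self.n_worm_genes, self.n_mouse_genes, self.n_cell_types) <= 0:
            raise ValueError("counts must be positive")
        for name in ("enriched_fraction", "association_strength",
                     "worm_enriched_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ortholog_density < 0:
            raise ValueError("ortholog_density must be >= 0")


@dataclass
class ExprGroundTruth:
    worm_enriched: set
    mouse_enriched: dict   # cell type -> set of mouse gene ids
    target_cell_type: str
    config: ExprSimConfig


def simulate_expression(config: ExprSimConfig):
    """Generate worm/mouse fold-enrichment tables and an ortholog map.

    Returns ``(worm_table, mouse_table, ortholog_map, ground_truth)`` as
    pandas objects: FE tables indexed by gene id with one log2 FE column per
    cell type, and a two-column ortholog DataFrame.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    worm_genes = [f"WBGene{i:08d}" for i in range(config.n_worm_genes)]
    mouse_genes = [f"MGI:{100000 + i}" for i in range(config.n_mouse_genes)]
    cell_types = [f"celltype_{j}" for j in range(config.n_cell_types)]
    target = cell_types[config.target_cell_type]

    if config.ortholog_density > config.n_mouse_genes / 4:
        warnings.warn("ortholog_density too high for distinct partners; "
                      "pairs may repeat across worm genes")
    pairs = []
    for wg in worm_genes:
        k = rng.poisson(config.ortholog_density)
        if k > 0:
            for mg_idx in rng.choice(config.n_mouse_genes, size=min(k, config.n_mouse_genes),
                                     replace=False):
                pairs.append((wg, mouse_genes[mg_idx]))
    ortho = pd.DataFrame(pairs, columns=["worm_gene_id", "mouse_gene_id"])

    n_enr = max(1, int(round(config.worm_enriched_fraction * config.n_worm_genes)))
    worm_enriched = set(rng.choice(worm_genes, size=n_enr, replace=False))
    worm_fe = np.where(
        np.isin(worm_genes, list(worm_enriched)),
        config.fe_scale + 0.5 * rng.standard_normal(config.n_worm_genes),
        0.3 * rng.standard_normal(config.n_worm_genes),
    )
    worm_table = pd.DataFrame({"CEPsh": worm_fe}, index=pd.Index(worm_genes, name="gene_id"))

    ortho_of = {}
    for wg, mg in pairs:
        ortho_of.setdefault(wg, []).append(mg)
    planted = {mg for wg in worm_enriched for mg in ortho_of.get(wg, [])}
    mouse_enriched = {ct: set() for ct in cell_types}
    # in the target cell type, orthologs of worm-enriched genes are enriched
    # with probability association_strength (equal to enriched_fraction means
    # no planted signal); every other gene/cell type is at background
    for ct in cell_types:
        for i, mg in enumerate(mouse_genes):
            p = (config.association_strength
                 if (ct == target and mg in planted)
                 else config.enriched_fraction)
            if rng.random() < p:
                mouse_enriched[ct].add(mg)

    mouse_fe = pd.DataFrame(
        0.3 * rng.standard_normal((config.n_mouse_genes, config.n_cell_types)),
        index=pd.Index(mouse_genes, name="gene_id"), columns=cell_types)
    for ct in cell_types:
        idx = sorted(mouse_enriched[ct])
        mouse_fe.loc[idx, ct] = config.fe_scale + 0.5 * rng.standard_normal(len(idx))

    return worm_table, mouse_fe, ortho, ExprGroundTruth(
        worm_enriched=worm_enriched, mouse_enriched=mouse_enriched,
        target_cell_type=target, config=config)
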