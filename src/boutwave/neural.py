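"""Conditioning and time-frequency analysis of 1 Hz fluorescence traces.

Raw calcium/glutamate intensities from the AVA interneuron are smoothed
with a Gaussian low-pass filter, min/max-normalized, and differentiated;
thresholds on the derivative detect food-cue responsiveness and the onset
of spontaneous activity.  Spontaneous oscillations are decomposed with
complex Morlet wavelets

    phi(t, f) = sqrt(pi/sigma) * exp(-t^2 / 2 sigma^2) * exp(i 2 pi f t),
    sigma = xi / (2 pi f),  xi = 4,

over 0.01-0.2 Hz; per-animal time-averaged amplitude spectra are combined
into genotype means weighted by the fraction of time each animal was
spontaneously active, and genotypes are compared per frequency with a
permutation test over bootstrapped ensembles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve
from scipy.stats import pearsonr

from .synthdata import FluorescenceTrace, MotionTrace

__all__ = [
    "XI",
    "FREQ_BAND",
    "ConditionedTrace",
    "WaveletSpectrum",
    "AnimalSpectrum",
    "SpectrumComparison",
    "default_freq_grid",
    "condition_trace",
    "derivative",
    "classify_cue_response",
    "detect_onset",
    "wavelet_transform",
    "time_averaged_spectrum",
    "genotype_spectrum",
    "compare_spectra",
    "peak_crosscorr",
    "calcium_state_phi",
    "phi_from_table",
]

XI = 4.0
FREQ_BAND = (0.01, 0.2)  # Hz
ONSET_HIGH = 0.15        # single-frame derivative threshold
ONSET_LOW = 0.05         # two-consecutive-frames derivative threshold
CUE_THRESHOLD = 0.05
CUE_WINDOW = 5.0         # s around each food-cue removal
STATE_THRESHOLD = 0.1    # derivative crossing for calcium state transitions


@dataclass
class ConditionedTrace:
    """Smoothed, normalized trace with its discrete derivative.

    ``derivative[k]`` corresponds to ``time[k+1]`` and equals
    (F[k+1] - F[k]) / (2 dt) — the one-frame difference over twice the frame
    interval; the onset/responsiveness thresholds are calibrated to this
    scale, so the factor of two is deliberate and must not be "fixed".
    """

    time: np.ndarray
    f_norm: np.ndarray
    derivative: np.ndarray   # length n-1, aligned with time[1:]
    smooth_sd: float         # s
    dt: float
    normalization: str


@dataclass
class WaveletSpectrum:
    W: np.ndarray            # (n_freq, n_time) complex coefficients
    freqs: np.ndarray        # Hz
    time: np.ndarray         # s
    xi: float = XI

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.W)

    def sigma(self) -> np.ndarray:
        """Gaussian envelope widths sigma(f) = xi / (2 pi f), in seconds."""
        return self.xi / (2.0 * math.pi * self.freqs)


@dataclass
class AnimalSpectrum:
    amplitude: np.ndarray | None  # time-averaged |W| per frequency
    freqs: np.ndarray
    active_fraction: float        # weight; 0 iff no onset was detected
    animal_id: str = "a0"
    genotype: str = "unknown"


@dataclass
class SpectrumComparison:
    freqs: np.ndarray
    difference: np.ndarray      # weighted-mean A minus weighted-mean B
    p_values: np.ndarray
    mask: np.ndarray            # p < alpha per frequency
    alpha: float
    n_boot: int
    seed: int | None
    family_wise: bool = False


def default_freq_grid(n: int = 100) -> np.ndarray:
    """Log-spaced frequencies on the analyzed 0.01-0.2 Hz band.

    Log spacing matches the constant-Q wavelet family (sigma proportional
    to 1/f).
    """
    return np.geomspace(FREQ_BAND[0], FREQ_BAND[1], n)


def condition_trace(trace, smooth_sd: float = 1.0,
                    normalization: str = "minmax",
                    dt: float | None = None) -> ConditionedTrace:
    """Gaussian low-pass filter, normalize, differentiate.

    ``trace`` is a FluorescenceTrace or a plain array (then ``dt`` is
    required).  The kernel is truncated at +/-4 sd with reflect boundary
    handling.  ``minmax`` maps the smoothed trace onto [0, 1]; the
    ``unit_variance`` alternative (zero mean, unit SD) is used by the
    motion/calcium-state analysis.
    """
    if isinstance(trace, FluorescenceTrace):
        F = np.asarray(trace.F, dtype=float)
        time = np.asarray(trace.time, dtype=float)
        dt = float(time[1] - time[0])
    else:
        F = np.asarray(trace, dtype=float)
        if dt is None:
            raise ValueError("dt is required for a bare array")
        time = np.arange(len(F)) * dt
    if len(F) < 3:
        raise ValueError("trace too short")
    if smooth_sd > 0:
        F = gaussian_filter1d(F, smooth_sd / dt, mode="reflect", truncate=4.0)
    if normalization == "minmax":
        lo, hi = F.min(), F.max()
        if hi - lo <= 0:
            raise ValueError("constant trace cannot be min/max normalized")
        f_norm = (F - lo) / (hi - lo)
    elif normalization == "unit_variance":
        sd = F.std()
        if sd <= 0:
            raise ValueError("constant trace has no variance")
        f_norm = (F - F.mean()) / sd
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return ConditionedTrace(time=time, f_norm=f_norm,
                            derivative=derivative(f_norm, dt),
                            smooth_sd=smooth_sd, dt=dt,
                            normalization=normalization)


def derivative(f: np.ndarray, dt: float) -> np.ndarray:
    """Discrete derivative (F[n] - F[n-1]) / (2 dt), defined from sample 1.

    Note the one-frame difference over *twice* the frame interval: a linear
    ramp of slope m yields m/2.  The detection thresholds downstream are
    defined on this same scale.
    """
    f = np.asarray(f, dtype=float)
    if len(f) < 2:
        raise ValueError("need at least 2 samples")
    return np.diff(f) / (2.0 * dt)


def classify_cue_response(cond: ConditionedTrace, cue_removal_times,
                          threshold: float = CUE_THRESHOLD,
                          window: float = CUE_WINDOW) -> bool:
    """True if the derivative exceeds 0.05 within +/-5 s of any cue removal."""
    d_times = cond.time[1:]
    for t_cue in cue_removal_times:
        m = np.abs(d_times - t_cue) <= window
        if np.any(cond.derivative[m] > threshold):
            return True
    return False


def detect_onset(cond: ConditionedTrace,
                 record_duration: float = 540.0) -> float | None:
    """First time spontaneous activity satisfies either onset criterion.

    (i) derivative > 0.15 at any single frame, or (ii) derivative > 0.05 at
    two or more consecutive frames (the criterion is fulfilled at the second
    frame of the pair).  Only the pre-cue window [0, record_duration] is
    searched.  Returns None if neither criterion ever holds.
    """
    d_times = cond.time[1:]
    m = d_times <= record_duration
    d = cond.derivative[m]
    t = d_times[m]
    hit_i = d > ONSET_HIGH
    hit_ii = np.zeros_like(hit_i)
    hit_ii[1:] = (d[1:] > ONSET_LOW) & (d[:-1] > ONSET_LOW)
    hits = np.flatnonzero(hit_i | hit_ii)
    return float(t[hits[0]]) if len(hits) else None


def _morlet_kernel(f: float, dt: float):
    sigma = XI / (2.0 * math.pi * f)
    K = int(math.ceil(4.0 * sigma / dt))
    k = np.arange(-K, K + 1) * dt
    return math.sqrt(math.pi / sigma) * np.exp(-k**2 / (2.0 * sigma**2)) \
        * np.exp(2j * math.pi * f * k)


def wavelet_transform(signal, dt: float = 1.0,
                      freqs: np.ndarray | None = None) -> WaveletSpectrum:
    """Complex Morlet wavelet spectrum W(t, f) of a uniformly sampled signal.

    The signal mean is removed, then the signal is padded with one full
    reflected copy on each side to limit edge effects; the wavelet support
    is truncated at +/-4 sigma.  The 1/sqrt(sigma) normalization makes the
    kernel L2 norm (integral of |phi|^2 dt = pi^(3/2)) identical at every
    frequency, so coefficients are comparable across the band.
    """
    if isinstance(signal, FluorescenceTrace):
        dt = float(signal.time[1] - signal.time[0])
        x = np.asarray(signal.F, dtype=float)
    elif isinstance(signal, ConditionedTrace):
        dt = signal.dt
        x = np.asarray(signal.f_norm, dtype=float)
    else:
        x = np.asarray(signal, dtype=float)
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < FREQ_BAND[0] - 1e-12) or np.any(freqs > FREQ_BAND[1] + 1e-12):
        raise ValueError(f"frequencies must lie within {FREQ_BAND} Hz")
    n = len(x)
    x = x - x.mean()
    padded = np.concatenate([x[::-1], x, x[::-1]])
    W = np.empty((len(freqs), n), dtype=complex)
    for i, f in enumerate(freqs):
        kern = _morlet_kernel(f, dt)
        conv = fftconvolve(padded, kern, mode="same") * dt
        W[i] = conv[n:2 * n]
    return WaveletSpectrum(W=W, freqs=freqs, time=np.arange(n) * dt)


def time_averaged_spectrum(spectrum: WaveletSpectrum,
                           onset: float | None, end: float,
                           record_duration: float = 540.0,
                           animal_id: str = "a0",
                           genotype: str = "unknown") -> AnimalSpectrum:
    """Mean wavelet amplitude from onset to end, weighted by active time.

    Animals without a detected onset get weight 0 and undefined amplitudes;
    they are excluded from genotype averages.
    """
    if onset is None:
        return AnimalSpectrum(amplitude=None, freqs=spectrum.freqs,
                              active_fraction=0.0, animal_id=animal_id,
                              genotype=genotype)
    if not onset < end:
        raise ValueError("onset must precede end")
    m = (spectrum.time >= onset) & (spectrum.time <= end)
    if not m.any():
        raise ValueError("no samples in [onset, end]")
    amp = np.abs(spectrum.W[:, m]).mean(axis=1)
    return AnimalSpectrum(amplitude=amp, freqs=spectrum.freqs,
                          active_fraction=float((end - onset) / record_duration),
                          animal_id=animal_id, genotype=genotype)


def _weighted_mean(amps: np.ndarray, w: np.ndarray) -> np.ndarray:
    return (w[:, None] * amps).sum(axis=0) / w.sum()


def genotype_spectrum(animal_spectra) -> np.ndarray:
    """Activity-weighted mean amplitude spectrum of one genotype."""
    active = [a for a in animal_spectra if a.active_fraction > 0]
    if not active:
        raise ValueError("no spontaneously active animals (all weights zero)")
    amps = np.stack([a.amplitude for a in active])
    w = np.array([a.active_fraction for a in active])
    return _weighted_mean(amps, w)


def compare_spectra(group_a, group_b, n_boot: int = 10_000,
                    alpha: float = 0.05, seed: int | None = None,
                    family_wise: bool = False) -> SpectrumComparison:
    """Per-frequency permutation test from bootstrapped ensembles.

    The observed statistic is the difference of activity-weighted mean
    amplitudes.  The null is built by resampling animals with replacement
    from the pooled set and randomly re-splitting the resample into the two
    group sizes (a label permutation of the bootstrap sample), n_boot times;
    two-sided p per frequency is the fraction of null differences at least
    as large in magnitude.  ``family_wise=True`` instead compares against
    the across-frequency maximum of each null difference.
    """
    a_act = [a for a in group_a if a.active_fraction > 0]
    b_act = [a for a in group_b if a.active_fraction > 0]
    if not a_act or not b_act:
        raise ValueError("both groups need at least one active animal")
    if len(a_act) + len(b_act) < 2:
        raise ValueError("need at least 2 animals in total")
    freqs = a_act[0].freqs
    amps = np.stack([a.amplitude for a in a_act + b_act])
    w = np.array([a.active_fraction for a in a_act + b_act])
    na, n = len(a_act), len(a_act) + len(b_act)
    observed = _weighted_mean(amps[:na], w[:na]) - _weighted_mean(amps[na:], w[na:])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(freqs))
    chunk = max(1, min(n_boot, int(2e7 // (n * len(freqs)))))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        wa = w[idx]
        aa = amps[idx]                      # (b, n, n_freq)
        wsum_a = wa[:, :na].sum(axis=1)
        wsum_b = wa[:, na:].sum(axis=1)
        mean_a = np.einsum("bi,bif->bf", wa[:, :na], aa[:, :na]) / wsum_a[:, None]
        mean_b = np.einsum("bi,bif->bf", wa[:, na:], aa[:, na:]) / wsum_b[:, None]
        null = mean_a - mean_b
        if family_wise:
            exceed += (np.abs(null).max(axis=1)[:, None] >= np.abs(observed)).sum(axis=0)
        else:
            exceed += (np.abs(null) >= np.abs(observed)).sum(axis=0)
        done += b
    p = (1.0 + exceed) / (n_boot + 1.0)
    return SpectrumComparison(freqs=freqs, difference=observed, p_values=p,
                              mask=p < alpha, alpha=alpha, n_boot=n_boot,
                              seed=seed, family_wise=family_wise)


def peak_crosscorr(trace_a, trace_b, dt: float = 1.0, max_lag: float = 30.0):
    """Peak Pearson cross-correlation over integer lags within +/-max_lag.

    Positive lag means channel A leads B by that many seconds.  Returns
    ``(peak_correlation, lag_s)``.
    """
    a = np.asarray(trace_a.F if isinstance(trace_a, FluorescenceTrace) else trace_a, float)
    b = np.asarray(trace_b.F if isinstance(trace_b, FluorescenceTrace) else trace_b, float)
    if len(a) != len(b):
        raise ValueError("traces must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant trace")
    K = int(round(max_lag / dt))
    best = (-2.0, 0)
    for k in range(-K, K + 1):
        if k >= 0:
            x, y = a[:len(a) - k or None], b[k:]
        else:
            x, y = a[-k:], b[:len(b) + k]
        if len(x) < 3 or x.std() == 0 or y.std() == 0:
            continue
        c = float(pearsonr(x, y)[0])
        if c > best[0]:
            best = (c, k)
    return best[0], best[1] * dt


def phi_from_table(a: int, b: int, c: int, d: int) -> float:
    """Pearson phi of a 2x2 table [[a, b], [c, d]]."""
    denom = math.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    if denom == 0:
        raise ValueError("degenerate 2x2 table: a margin is zero")
    return (a * d - b * c) / denom


def calcium_state_phi(motion: MotionTrace, calcium: ConditionedTrace,
                      threshold: float = STATE_THRESHOLD,
                      min_frames: int = 3):
    """Association between calcium high/low states and motion direction.

    The calcium derivative's upward crossings of +0.1 start a high episode;
    downward crossings of -0.1 start a low one (calcium should be smoothed
    at 1.5 s and normalized to unit variance; the position trace at 3 s).
    Each episode's net head-position change gives forward (increase) or
    backward; phi is computed from the resulting 2x2 table.  Partial first/
    last episodes are kept if they span at least ``min_frames`` frames.
    Returns ``(phi, table)`` with table = ((high-backward, high-forward),
    (low-backward, low-forward)).
    """
    if calcium.normalization != "unit_variance":
        raise ValueError("calcium trace must be normalized to unit variance")
    d = calcium.derivative
    up = np.flatnonzero((d[1:] > threshold) & (d[:-1] <= threshold)) + 1
    down = np.flatnonzero((d[1:] < -threshold) & (d[:-1] >= -threshold)) + 1
    trans = sorted([(int(i) + 1, "high") for i in up] + [(int(i) + 1, "low") for i in down])
    # collapse runs of same-direction crossings
    events = []
    for frame, state in trans:
        if not events or events[-1][1] != state:
            events.append((frame, state))
    if len(events) < 1:
        raise ValueError("fewer than 2 episodes: no state transitions found")
    episodes = []
    first_state = "low" if events[0][1] == "high" else "high"
    bounds = [(0, events[0][0], first_state)]
    for k, (frame, state) in enumerate(events):
        end = events[k + 1][0] if k + 1 < len(events) else len(calcium.f_norm)
        bounds.append((frame, end, state))
    for start, end, state in bounds:
        if end - start >= min_frames:
            episodes.append((start, end, state))
    if len(episodes) < 2:
        raise ValueError("fewer than 2 usable episodes")
    a = b = c_lo = d_lo = 0
    x = np.asarray(motion.x, dtype=float)
    for start, end, state in episodes:
        forward = x[end - 1] - x[start] > 0
        if state == "high":
            if forward:
                b += 1
            else:
                a += 1
        else:
            if forward:
                d_lo += 1
            else:
                c_lo += 1
    return phi_from_table(a, b, c_lo, d_lo), ((a, b), (c_lo, d_lo))
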