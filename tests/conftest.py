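import numpy as np
import pytest

from boutwave.locomotion import (
    BoutInterval,
    BoutSegmentation,
    baum_welch,
    segment_bouts,
)
from boutwave.synthdata import TrackSimConfig, simulate_track


def segs_from_mask(mask, dt=0.5):
    """Binary backward mask -> BoutSegmentation (shared test helper)."""
    ivs = []
    start = 0
    n = len(mask)
    for t in range(1, n + 1):
        if t == n or mask[t] != mask[start]:
            ivs.append(BoutInterval(
                start, t, "backward" if mask[start] else "forward",
                censored_start=(start == 0), censored_end=(t == n)))
            start = t
    return BoutSegmentation(ivs, dt)


def mask_from_lengths(lengths):
    """Backward mask whose uncensored forward bouts have exactly ``lengths``.

    Layout: B F..F B F..F B ... — one backward separator frame before each
    forward bout and one after the last, so no forward bout touches a track
    boundary.
    """
    lengths = np.asarray(lengths, int)
    mask = np.zeros(int(lengths.sum() + len(lengths) + 1), bool)
    mask[0] = True
    pos = 1
    for ln in lengths:
        pos += int(ln)
        mask[pos] = True
        pos += 1
    return mask


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort reused across decoding tests."""
    cfg = TrackSimConfig(n_worms=6, duration=600.0, seed=123)
    tracks, truth = simulate_track(cfg)
    return cfg, tracks, truth


@pytest.fixture(scope="session")
def decoded_cohort(small_cohort):
    cfg, tracks, truth = small_cohort
    model, posteriors, lls = baum_welch(tracks, max_iter=100)
    segs = [segment_bouts(p, dt=tracks[0].dt) for p in posteriors]
    return cfg, tracks, truth, model, posteriors, segs
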