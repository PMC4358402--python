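import numpy as np
import pytest

from dreamchip.annotations import GeneModel
from dreamchip.signal import SignalTrack


def make_track(runs, chrom="chrI"):
    """Build a one-chromosome track from (start, end, value) triples."""
    starts = [r[0] for r in runs]
    ends = [r[1] for r in runs]
    values = [r[2] for r in runs]
    return SignalTrack({chrom: (starts, ends, values)})


def dense_values(track, chrom, length):
    """Per-base expansion of a track; NaN where uncovered (test oracle)."""
    arr = np.full(length, np.nan)
    if chrom in track.runs:
        starts, ends, values = track.runs[chrom]
        for s, e, v in zip(starts, ends, values):
            arr[max(s, 0):min(e, length)] = v
    return arr


def naive_mean(track, chrom, start, end, min_frac=0.5, length=None):
    """Per-base loop oracle for region means."""
    length = length or int(end)
    arr = dense_values(track, chrom, length)
    window = arr[max(start, 0):end]
    covered = np.isfinite(window).sum()
    if covered == 0 or covered / (end - start) < min_frac:
        return float("nan")
    return float(np.nanmean(window))


@pytest.fixture
def plus_gene():
    return GeneModel("gplus", "chrI", 10_000, 12_000, "+")


@pytest.fixture
def minus_gene():
    return GeneModel("gminus", "chrI", 8_000, 10_000, "-")


@pytest.fixture
def random_toy_track():
    """Factory: random track of unit-ish runs with gaps on a 1 kb toy chrom."""

    def _make(rng, chrom_len=1000, gap_prob=0.2):
        runs = []
        pos = 0
        while pos < chrom_len:
            w = int(rng.integers(1, 30))
            end = min(pos + w, chrom_len)
            if rng.random() > gap_prob:
                runs.append((pos, end, float(rng.normal(1.0, 2.0))))
            pos = end
        return make_track(runs)

    return _make
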