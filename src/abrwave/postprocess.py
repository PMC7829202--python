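"""From per-step probabilities to discrete characteristic-wave latencies.

The classifier emits a probability per window sample; postprocessing turns
these into at most one latency per wave:

1. threshold the probabilities (default 0.5, ``>=`` convention);
2. extract maximal runs of positive samples;
3. transitively merge runs separated by fewer than 20 samples (0.5 ms) —
   gaps within the threshold belong to the same characteristic-wave area;
4. drop regions with too little positive support (default 3 samples),
   mirroring the clinical reading that a wave without enough continuous
   identification points is not trusted;
5. each region's latency is the mean of the times of its first and last
   point; regions are assigned to waves I/III/V by clinical latency-window
   gating, earliest region first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import WINDOW_LEN, TimeGrid
from .labelgen import window_time

__all__ = [
    "PeakRegion",
    "PeakSet",
    "binarize",
    "find_runs",
    "merge_regions",
    "filter_regions",
    "assign_waves",
    "regions_from_probs",
    "DEFAULT_WAVE_WINDOWS",
]

#: clinical latency gates (ms) used to name regions, at high stimulus level
DEFAULT_WAVE_WINDOWS: dict[str, tuple[float, float]] = {
    "I": (1.0, 2.4),
    "III": (3.0, 4.6),
    "V": (4.8, 7.0),
}


@dataclass(frozen=True)
class PeakRegion:
    """A merged positive region in window coordinates (inclusive ends).

    ``support`` counts the positive samples inside the region (gap samples
    bridged by merging do not count).  ``center_time`` is the mean of the
    first and last point's times.
    """

    start: int
    end: int
    center_time: float
    support: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must not exceed end")


@dataclass
class PeakSet:
    """Sorted disjoint regions plus optional wave-identity assignments."""

    regions: list[PeakRegion] = field(default_factory=list)
    waves: dict[str, PeakRegion] = field(default_factory=dict)

    def latency(self, wave: str) -> float | None:
        region = self.waves.get(wave)
        return region.center_time if region else None

    @property
    def centers(self) -> list[float]:
        return [r.center_time for r in self.regions]


def binarize(probs: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Per-sample decision: 1 where probability >= cutoff."""
    probs = np.asarray(probs, dtype=float)
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie strictly inside (0, 1)")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return (probs >= cutoff).astype(np.int8)


def find_runs(binary: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of 1s as inclusive (start, end) pairs, sorted."""
    b = np.asarray(binary).astype(bool)
    if b.ndim != 1:
        raise ValueError("expected a 1-D binary vector")
    padded = np.concatenate([[False], b, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def merge_regions(
    runs: list[tuple[int, int]],
    threshold_samples: int = 20,
    grid: TimeGrid | None = None,
) -> list[PeakRegion]:
    """Merge runs whose inter-run gap is below the 20-sample threshold.

    The gap between consecutive runs is the count of zero samples strictly
    between them; gaps < ``threshold_samples`` merge (transitively), so
    "within 20 sampling points" bounds the largest surviving gap at 19.
    """
    if threshold_samples < 0:
        raise ValueError("threshold_samples must be non-negative")
    grid = grid or TimeGrid()
    regions: list[PeakRegion] = []
    group: list[tuple[int, int]] = []

    def _close(g: list[tuple[int, int]]) -> PeakRegion:
        start, end = g[0][0], g[-1][1]
        center = 0.5 * (window_time(start, grid) + window_time(end, grid))
        support = sum(e - s + 1 for s, e in g)
        return PeakRegion(start=start, end=end, center_time=center, support=support)

    for run in sorted(runs):
        if group and run[0] - group[-1][1] - 1 < threshold_samples:
            group.append(run)
        else:
            if group:
                regions.append(_close(group))
            group = [run]
    if group:
        regions.append(_close(group))
    return regions


def filter_regions(regions: list[PeakRegion], min_run_length: int = 3) -> list[PeakRegion]:
    """Drop regions supported by fewer than ``min_run_length`` positives."""
    return [r for r in regions if r.support >= min_run_length]


def assign_waves(
    regions: list[PeakRegion],
    wave_windows: dict[str, tuple[float, float]] | None = None,
    max_waves: int = 3,
) -> PeakSet:
    """Name regions I/III/V by latency gating, earliest region first.

    A region can carry at most one wave name and vice versa; regions
    outside every gate (or losing the tie-break) stay unlabeled but are
    retained in the set.
    """
    windows = wave_windows or DEFAULT_WAVE_WINDOWS
    ordered = sorted(regions, key=lambda r: r.center_time)
    taken: set[int] = set()
    waves: dict[str, PeakRegion] = {}
    for wave in list(windows)[:max_waves]:
        lo, hi = windows[wave]
        for idx, region in enumerate(ordered):
            if idx in taken:
                continue
            if lo <= region.center_time <= hi:
                waves[wave] = region
                taken.add(idx)
                break
    return PeakSet(regions=ordered, waves=waves)


def regions_from_probs(
    probs: np.ndarray,
    cutoff: float = 0.5,
    threshold_samples: int = 20,
    min_run_length: int = 3,
    wave_windows: dict[str, tuple[float, float]] | None = None,
    grid: TimeGrid | None = None,
) -> PeakSet:
    """Full postprocessing pipeline for one 321-step probability sequence."""
    probs = np.asarray(probs)
    if probs.shape != (WINDOW_LEN,):
        raise ValueError(f"expected {WINDOW_LEN} probabilities, got {probs.shape}")
    runs = find_runs(binarize(probs, cutoff))
    regions = filter_regions(
        merge_regions(runs, threshold_samples, grid), min_run_length
    )
    return assign_waves(regions, wave_windows)
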