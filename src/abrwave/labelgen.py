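"""Analysis-window extraction and binary per-sample label construction.

Only the 321 samples with t in [0, 8] ms enter the sequence classifier:
the pre-stimulus baseline carries no response and the late window is
frequently contaminated by myogenic artifacts and waves VI/VII.  Each
annotated wave latency marks the nearest window sample as a "feature"
point (1); all other samples are "non-feature" (0).  Because 3 positive
samples out of 321 give the optimizer almost nothing to learn from — and
manual marks carry sub-sample uncertainty anyway — the single marks are
dilated by four samples (0.1 ms) on each side into nine-sample feature
areas before training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation

from .core import (
    WINDOW_LEN,
    WINDOW_START,
    AbrRecording,
    TimeGrid,
    WaveAnnotation,
)

__all__ = [
    "WindowedTrace",
    "LabelVector",
    "extract_window",
    "annotation_to_labels",
    "augment_labels",
    "normalize_trace",
    "window_index_of",
    "window_time",
]


@dataclass
class WindowedTrace:
    """The 321 potentials (µV) at t = 0, 0.025, ..., 8 ms of one sweep."""

    values: np.ndarray
    grid: TimeGrid = field(default_factory=TimeGrid)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (WINDOW_LEN,):
            raise ValueError(f"expected {WINDOW_LEN} samples, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window values must be finite")


@dataclass
class LabelVector:
    """321 binary feature/non-feature targets over the analysis window."""

    targets: np.ndarray
    augmented: bool = False

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets)
        if self.targets.shape != (WINDOW_LEN,):
            raise ValueError(f"expected {WINDOW_LEN} targets, got {self.targets.shape}")
        if not np.isin(self.targets, (0, 1)).all():
            raise ValueError("targets must be 0/1")
        self.targets = self.targets.astype(np.int8)


def window_index_of(latency_ms: float, grid: TimeGrid | None = None) -> int:
    """Nearest window index for a latency in [0, 8] ms (ties to lower)."""
    grid = grid or TimeGrid()
    idx = grid.index_of(latency_ms) - WINDOW_START
    if not 0 <= idx < WINDOW_LEN:
        raise ValueError(f"latency {latency_ms} ms outside the analysis window")
    return idx


def window_time(index: int, grid: TimeGrid | None = None) -> float:
    """Time in ms of window sample ``index`` (window starts at t = 0)."""
    grid = grid or TimeGrid()
    return float(grid.time(WINDOW_START + index))


def extract_window(recording: AbrRecording) -> WindowedTrace:
    """Select the samples at grid indices 511..831 (t in [0, 8] ms)."""
    grid = recording.grid
    idx = grid.window_indices(0.0, 8.0)
    if idx.size != WINDOW_LEN or idx[0] != WINDOW_START:
        raise ValueError("recording is not on the canonical acquisition grid")
    return WindowedTrace(values=recording.potentials[idx], grid=grid)


def annotation_to_labels(ann: WaveAnnotation, grid: TimeGrid | None = None) -> LabelVector:
    """Un-augmented label vector: one 1 at each marked wave's nearest sample."""
    grid = grid or TimeGrid()
    targets = np.zeros(WINDOW_LEN, dtype=np.int8)
    for wave in ann.waves:
        targets[window_index_of(ann[wave], grid)] = 1
    return LabelVector(targets=targets, augmented=False)


def augment_labels(labels: LabelVector, radius: int = 4) -> LabelVector:
    """Dilate marks into symmetric ``2*radius + 1``-sample feature areas.

    The dilation is the union of the neighbourhoods (clipped at the window
    edges); overlapping areas are not double-counted.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if radius == 0:
        return LabelVector(targets=labels.targets.copy(), augmented=labels.augmented)
    dilated = binary_dilation(
        labels.targets.astype(bool), structure=np.ones(2 * radius + 1, dtype=bool)
    )
    return LabelVector(targets=dilated.astype(np.int8), augmented=True)


def normalize_trace(trace: WindowedTrace) -> np.ndarray:
    """Per-trace z-score of the window values for model ingestion.

    Recurrent training is sensitive to input scale, and absolute µV levels
    vary across subjects; raw values are preserved elsewhere for IO and
    plotting.  Constant traces map to all zeros.
    """
    v = trace.values
    sd = v.std()
    if sd < 1e-12:
        return np.zeros_like(v)
    return (v - v.mean()) / sd
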