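"""Canonical data structures for ABR sweeps.

An auditory brainstem response (ABR) sweep is a uniformly sampled scalp
potential trace evoked by a click stimulus.  The clinical acquisition grid
used throughout this package has 1,024 samples spaced 0.025 ms apart with
the stimulus onset (t = 0) falling exactly on sample 511, i.e.
``t(i) = 0.025 * (i - 511)`` ms.  This anchoring places t = 0 on-grid,
yields exactly 321 samples in the analysis window [0, 8] ms, and matches
the displayed endpoints (-12.78, 12.80 ms) after rounding to two decimals.

Latencies of the clinically marked characteristic waves I, III and V are
stored in milliseconds relative to stimulus onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeGrid",
    "CANONICAL_GRID",
    "WINDOW_START",
    "WINDOW_END",
    "WINDOW_LEN",
    "ANNOTATED_WAVES",
    "AbrRecording",
    "WaveAnnotation",
]

#: grid indices delimiting the 0-8 ms analysis window (inclusive)
WINDOW_START = 511
WINDOW_END = 831
WINDOW_LEN = 321

#: the clinically annotated characteristic waves, in latency order
ANNOTATED_WAVES = ("I", "III", "V")


@dataclass(frozen=True)
class TimeGrid:
    """Uniform acquisition grid, anchored so that stimulus onset is on-grid.

    Parameters
    ----------
    n_samples:
        Number of samples per sweep.
    dt:
        Sample spacing in ms.
    zero_index:
        Index of the sample at stimulus onset (t = 0).
    """

    n_samples: int = 1024
    dt: float = 0.025
    zero_index: int = 511

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.dt <= 0:
            raise ValueError("n_samples and dt must be positive")
        if not 0 <= self.zero_index < self.n_samples:
            raise ValueError("zero_index out of range")

    def time(self, index: int | np.ndarray) -> float | np.ndarray:
        """Time in ms of grid sample ``index``."""
        return self.dt * (np.asarray(index) - self.zero_index)

    def times(self) -> np.ndarray:
        """All sample times, shape ``(n_samples,)``."""
        return self.dt * (np.arange(self.n_samples) - self.zero_index)

    def index_of(self, t_ms: float) -> int:
        """Nearest grid index to time ``t_ms``; exact half-sample ties
        resolve to the lower index."""
        rel = t_ms / self.dt + self.zero_index
        idx = math.floor(rel + 0.5)
        if rel + 0.5 == idx:  # exact tie at the half-sample boundary
            idx -= 1
        if not 0 <= idx < self.n_samples:
            raise ValueError(f"time {t_ms} ms falls outside the grid")
        return idx

    def window_indices(self, t_lo: float = 0.0, t_hi: float = 8.0) -> np.ndarray:
        """Grid indices whose time lies in ``[t_lo, t_hi]`` inclusive."""
        t = self.times()
        eps = 1e-9
        return np.nonzero((t >= t_lo - eps) & (t <= t_hi + eps))[0]


CANONICAL_GRID = TimeGrid()


@dataclass
class AbrRecording:
    """One averaged ABR sweep on the canonical grid.

    Attributes
    ----------
    potentials:
        Scalp potentials in microvolts, one value per grid sample.
    grid:
        The acquisition grid (defaults to the canonical 1,024-point grid).
    subject_class:
        ``"normal"`` or ``"abnormal"`` hearing.
    stimulus_level:
        Click stimulus intensity in dB nHL.
    """

    potentials: np.ndarray
    grid: TimeGrid = field(default_factory=TimeGrid)
    subject_class: str = "normal"
    stimulus_level: float = 96.0

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        if self.potentials.ndim != 1 or len(self.potentials) != self.grid.n_samples:
            raise ValueError(
                f"expected {self.grid.n_samples} samples, got {self.potentials.shape}"
            )
        if not np.all(np.isfinite(self.potentials)):
            raise ValueError("potentials must be finite")
        if self.subject_class not in ("normal", "abnormal"):
            raise ValueError(f"unknown subject_class {self.subject_class!r}")


class AnnotationError(ValueError):
    """Raised for latency values that violate the wave-annotation contract."""


@dataclass
class WaveAnnotation:
    """Latencies (ms) of the marked characteristic waves.

    Any subset of waves I, III, V may be present; a missing entry means the
    wave was not identifiable in the sweep.  Present latencies must lie in
    the [0, 8] ms analysis window and strictly increase in wave order.
    """

    latencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.latencies) - set(ANNOTATED_WAVES)
        if unknown:
            raise AnnotationError(f"unknown wave keys: {sorted(unknown)}")
        for wave, lat in self.latencies.items():
            if not (0.0 <= float(lat) <= 8.0):
                raise AnnotationError(
                    f"wave {wave} latency {lat} ms outside [0, 8] ms"
                )
        present = [self.latencies[w] for w in ANNOTATED_WAVES if w in self.latencies]
        if any(b <= a for a, b in zip(present, present[1:])):
            raise AnnotationError(
                f"latencies must strictly increase in wave order, got {self.latencies}"
            )

    @property
    def waves(self) -> tuple[str, ...]:
        return tuple(w for w in ANNOTATED_WAVES if w in self.latencies)

    def __len__(self) -> int:
        return len(self.latencies)

    def __contains__(self, wave: str) -> bool:
        return wave in self.latencies

    def __getitem__(self, wave: str) -> float:
        return self.latencies[wave]
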