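"""On-disk formats for sweeps, annotations, predictions and manifests.

Formats are deliberately plain-text and human-inspectable:

* traces — CSV with header ``time_ms,potential_uv`` (µV, ms, LF endings);
* annotations / predictions — JSON;
* dataset manifests — JSON;
* experiment configs — YAML (see :mod:`abrwave.experiments`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import ANNOTATED_WAVES, AbrRecording, TimeGrid, WaveAnnotation

__all__ = [
    "FormatError",
    "DatasetManifest",
    "read_recording",
    "write_recording",
    "read_annotation",
    "write_annotation",
    "split_dataset",
]

#: spacing tolerance when validating a trace file against the grid (ms)
_SPACING_TOL = 1e-6


class FormatError(ValueError):
    """Raised when an on-disk file violates the trace/annotation format."""


def write_recording(recording: AbrRecording, path: str | Path) -> None:
    """Write a sweep as two-column CSV (``time_ms,potential_uv``)."""
    t = recording.grid.times()
    lines = ["time_ms,potential_uv"]
    lines += [
        f"{ti:.10g},{vi:.12g}" for ti, vi in zip(t, recording.potentials)
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_recording(path: str | Path, grid: TimeGrid | None = None) -> AbrRecording:
    """Read a sweep CSV and validate it against the canonical grid.

    Raises
    ------
    FormatError
        On a wrong sample count, non-uniform spacing beyond 1e-6 ms, or a
        non-numeric cell; the message names the offending row.
    """
    grid = grid or TimeGrid()
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].strip() != "time_ms,potential_uv":
        raise FormatError(f"{path}: missing 'time_ms,potential_uv' header")
    rows = [ln for ln in lines[1:] if ln.strip()]
    if len(rows) != grid.n_samples:
        raise FormatError(
            f"{path}: expected {grid.n_samples} samples, found {len(rows)}"
        )
    times = np.empty(len(rows))
    pots = np.empty(len(rows))
    for i, row in enumerate(rows):
        parts = row.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}: row {i + 2}: expected 2 columns")
        try:
            times[i] = float(parts[0])
            pots[i] = float(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}: row {i + 2}: non-numeric cell") from exc
    dt = np.diff(times)
    bad = np.nonzero(np.abs(dt - grid.dt) > _SPACING_TOL)[0]
    if bad.size:
        raise FormatError(
            f"{path}: row {bad[0] + 3}: non-uniform spacing "
            f"{dt[bad[0]]:.6g} ms (expected {grid.dt} ms)"
        )
    if abs(times[grid.zero_index]) > _SPACING_TOL:
        raise FormatError(f"{path}: stimulus onset not at sample {grid.zero_index}")
    return AbrRecording(potentials=pots, grid=grid)


def write_annotation(ann: WaveAnnotation, path: str | Path) -> None:
    """Write wave latencies as JSON, e.g. ``{"I": 1.62, "V": 5.7}``."""
    payload = {w: float(ann.latencies[w]) for w in ANNOTATED_WAVES if w in ann}
    Path(path).write_text(json.dumps(payload) + "\n", encoding="utf-8")


def read_annotation(path: str | Path) -> WaveAnnotation:
    """Read a latency JSON file; unknown keys and ordering violations are
    rejected by :class:`~abrwave.core.WaveAnnotation` validation."""
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(obj, dict):
        raise FormatError(f"{path}: annotation must be a JSON object")
    return WaveAnnotation(latencies={k: float(v) for k, v in obj.items()})


@dataclass
class DatasetManifest:
    """Paths, class labels and a train/test split for a stored dataset."""

    sweeps: list[str]
    classes: list[str]
    train: list[int] = field(default_factory=list)
    test: list[int] = field(default_factory=list)
    split_seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.sweeps) != len(self.classes):
            raise ValueError("one class label per sweep required")
        if len(set(self.sweeps)) != len(self.sweeps):
            raise ValueError("duplicate sweep paths in manifest")
        if self.train or self.test:
            if sorted(self.train + self.test) != list(range(len(self.sweeps))):
                raise ValueError("split must partition the manifest")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "sweeps": self.sweeps,
                    "classes": self.classes,
                    "train": self.train,
                    "test": self.test,
                    "split_seed": self.split_seed,
                },
                indent=1,
            ),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            sweeps=list(obj["sweeps"]),
            classes=list(obj["classes"]),
            train=list(obj.get("train", [])),
            test=list(obj.get("test", [])),
            split_seed=obj.get("split_seed"),
        )


def split_dataset(
    manifest: DatasetManifest,
    n_train: int,
    seed: int,
    stratify: bool = False,
) -> DatasetManifest:
    """Randomly split a manifest into train/test without replacement.

    Stratification by subject class is optional and off by default.  The
    split is deterministic in ``seed``.
    """
    total = len(manifest.sweeps)
    if not 0 < n_train < total:
        raise ValueError(f"n_train must be in (0, {total}), got {n_train}")
    rng = np.random.default_rng(seed)
    if stratify:
        train: list[int] = []
        frac = n_train / total
        labels = np.asarray(manifest.classes)
        for cls in sorted(set(manifest.classes)):
            idx = np.nonzero(labels == cls)[0]
            k = round(frac * idx.size)
            train.extend(rng.permutation(idx)[:k].tolist())
        # fix rounding drift so the split size is exact
        rest = [i for i in rng.permutation(total) if i not in set(train)]
        while len(train) < n_train:
            train.append(rest.pop())
        train = sorted(train[:n_train])
    else:
        train = sorted(rng.permutation(total)[:n_train].tolist())
    test = sorted(set(range(total)) - set(train))
    return DatasetManifest(
        sweeps=list(manifest.sweeps),
        classes=list(manifest.classes),
        train=train,
        test=test,
        split_seed=seed,
    )
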