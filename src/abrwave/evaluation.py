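"""Tolerance-window scoring of predicted wave latencies.

A predicted latency counts as correct when it lies within the maximum
allowable error ME of a manually marked point; accuracy is the matched
fraction of all marked points,

    ACC = r_p / p_n,

pooled over sweeps (micro-average).  ME is evaluated at the three clinical
scales 0.1, 0.15 and 0.2 ms; 0.2 ms is the scale commonly accepted for
clinically marked points.  The metric is recall-like: spurious predictions
far from every mark never lower it (they are reported separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean

import numpy as np

from .core import ANNOTATED_WAVES, WaveAnnotation
from .postprocess import PeakSet

__all__ = [
    "ToleranceSpec",
    "EvalResult",
    "STUDY_TOLERANCES_MS",
    "match_peaks",
    "accuracy",
    "repeated_kfold",
]

#: the studied maximum-allowable-error scales, in ms
STUDY_TOLERANCES_MS = (0.1, 0.15, 0.2)


@dataclass(frozen=True)
class ToleranceSpec:
    """Maximum allowable error (ME) for a latency match, in ms."""

    me: float = 0.2

    def __post_init__(self) -> None:
        if self.me <= 0:
            raise ValueError("me must be positive")


@dataclass
class EvalResult:
    """Matched-point counts and the derived accuracy."""

    r_p: int
    p_n: int
    per_wave: dict[str, tuple[int, int]] = field(default_factory=dict)
    false_positives: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.r_p <= self.p_n:
            raise ValueError("need 0 <= r_p <= p_n")

    @property
    def acc(self) -> float:
        return self.r_p / self.p_n


def match_peaks(
    predicted: PeakSet,
    truth: WaveAnnotation,
    tol: ToleranceSpec | float = 0.2,
    *,
    optimal: bool = False,
) -> list[tuple[str, float, float]]:
    """One-to-one matching of annotated waves to predicted region centers.

    Annotated waves are processed in latency order; each greedily takes
    the nearest still-unmatched predicted center within ME.  With
    ``optimal=True`` a brute-force assignment maximizing the match count
    is used instead (sensitivity analysis; identical on clean data).
    Returns ``(wave, truth_latency, predicted_latency)`` triples.
    """
    me = tol.me if isinstance(tol, ToleranceSpec) else float(tol)
    centers = list(predicted.centers)
    truths = [(w, truth[w]) for w in truth.waves]
    if not centers or not truths:
        return []
    if optimal:
        return _optimal_matching(truths, centers, me)
    matches: list[tuple[str, float, float]] = []
    used: set[int] = set()
    for wave, lat in truths:
        best, best_d = None, me
        for j, c in enumerate(centers):
            if j in used:
                continue
            d = abs(c - lat)
            if d <= best_d:
                best, best_d = j, d
        if best is not None:
            used.add(best)
            matches.append((wave, lat, centers[best]))
    return matches


def _optimal_matching(truths, centers, me):
    best: list[tuple[str, float, float]] = []
    used: set[int] = set()
    cur: list[tuple[str, float, float]] = []

    def _search(i: int) -> None:
        nonlocal best
        if len(cur) > len(best):
            best = list(cur)
        if i == len(truths):
            return
        _search(i + 1)  # leave truth i unmatched
        wave, lat = truths[i]
        for j, c in enumerate(centers):
            if j not in used and abs(c - lat) <= me:
                used.add(j)
                cur.append((wave, lat, c))
                _search(i + 1)
                cur.pop()
                used.remove(j)

    _search(0)
    return best


def accuracy(
    pairs: list[tuple[PeakSet, WaveAnnotation]],
    tol: ToleranceSpec | float = 0.2,
    *,
    optimal: bool = False,
) -> EvalResult:
    """Micro-averaged ACC over a dataset of (prediction, truth) pairs.

    ``p_n`` counts every annotated wave (sweeps with missing waves simply
    contribute fewer points); ``r_p`` counts matches within ME.
    """
    if not pairs:
        raise ValueError("dataset must be nonempty")
    r_p = 0
    p_n = 0
    fp = 0
    per_wave = {w: [0, 0] for w in ANNOTATED_WAVES}
    for pred, truth in pairs:
        matches = match_peaks(pred, truth, tol, optimal=optimal)
        matched_waves = {w for w, _, _ in matches}
        for w in truth.waves:
            per_wave[w][1] += 1
            if w in matched_waves:
                per_wave[w][0] += 1
        r_p += len(matches)
        p_n += len(truth.waves)
        fp += max(len(pred.regions) - len(matches), 0)
    if p_n == 0:
        raise ValueError("no annotated waves in the dataset")
    return EvalResult(
        r_p=r_p,
        p_n=p_n,
        per_wave={w: (m, t) for w, (m, t) in per_wave.items()},
        false_positives=fp,
    )


@dataclass
class KFoldSummary:
    """Mean/SD of fold-level ACC per tolerance, plus loss trajectories."""

    acc_mean: dict[float, float]
    acc_sd: dict[float, float]
    train_loss_mean: float
    val_loss_mean: float
    fold_results: list[dict[float, float]]


def repeated_kfold(
    dataset,
    train_fn,
    k: int = 9,
    repeats: int = 5,
    seed: int = 0,
    tolerances=STUDY_TOLERANCES_MS,
) -> KFoldSummary:
    """Repeated k-fold cross-validation of a full train/predict pipeline.

    ``dataset`` is a list of items; ``train_fn(train_items, fold_seed)``
    must return ``(predict_fn, train_loss, val_loss)`` where
    ``predict_fn(item) -> PeakSet`` and each item carries its annotation as
    ``item[1]`` (recording/trace first, truth second).  Each repeat
    reshuffles with a seed derived from the master seed, splits into ``k``
    folds (sizes differing by at most one), trains on k-1 folds and scores
    the held-out fold; fold-level ACC values are averaged per tolerance.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(dataset) < k:
        raise ValueError("dataset smaller than k")
    master = np.random.SeedSequence(seed)
    fold_results: list[dict[float, float]] = []
    tr_losses: list[float] = []
    va_losses: list[float] = []
    for rep_seq in master.spawn(repeats):
        rng = np.random.default_rng(rep_seq)
        order = rng.permutation(len(dataset))
        folds = np.array_split(order, k)
        fold_seed = int(rng.integers(2**31 - 1))
        for fi, fold in enumerate(folds):
            train_items = [dataset[i] for f in folds for i in f if f is not fold]
            test_items = [dataset[i] for i in fold]
            predict_fn, tr_loss, va_loss = train_fn(train_items, fold_seed + fi)
            pairs = [(predict_fn(item), item[1]) for item in test_items]
            fold_results.append(
                {me: accuracy(pairs, me).acc for me in tolerances}
            )
            tr_losses.append(tr_loss)
            va_losses.append(va_loss)
    acc_mean = {me: mean(r[me] for r in fold_results) for me in tolerances}
    acc_sd = {
        me: float(np.std([r[me] for r in fold_results])) for me in tolerances
    }
    return KFoldSummary(
        acc_mean=acc_mean,
        acc_sd=acc_sd,
        train_loss_mean=float(np.mean(tr_losses)),
        val_loss_mean=float(np.nanmean(va_losses)),
        fold_results=fold_results,
    )
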