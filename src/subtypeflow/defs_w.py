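"""Differential-evolution wrapper feature selection with automatic size
discovery (DEFS_W).

Candidate feature subsets are encoded as real-valued vectors of length
``upper_limit``; each entry decodes to a feature index or to a null token
(which is how subset sizes below the limit arise), and duplicate indices
are repaired by a roulette wheel over the unused features weighted by their
univariate relevance (single-feature cross-validated weight accuracy).
Fitness of a subset is the stratified cross-validated weight accuracy of a
Gaussian naive Bayes classifier with empirical priors, so small classes
count as much as large ones.  The evolution engine is scipy's
``differential_evolution`` (rand/1/bin); the best subset ever evaluated is
tracked with deterministic tie-breaking (higher wAcc, then smaller subset,
then lexicographic order).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution
from sklearn.model_selection import StratifiedKFold

from .metrics import ConfusionMatrix, weight_accuracy
from .naive_bayes import nb_fit, nb_predict

logger = logging.getLogger(__name__)


@dataclass
class DEParams:
    """Settings of the rand/1/bin differential evolution search.

    Defaults are the canonical DE choices (population 50, F = 0.5,
    CR = 0.9, 100 generations) with a 5-fold stratified wrapper CV.
    """

    population_size: int = 50
    diff_weight: float = 0.5
    crossover_rate: float = 0.9
    n_generations: int = 100
    seed: int = 0
    eval_cv_folds: int = 5
    eval_cv_repeats: int = 3

    def validate(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if not 0.0 < self.diff_weight <= 2.0:
            raise ValueError("diff_weight must lie in (0, 2]")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must lie in [0, 1]")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.eval_cv_folds < 2:
            raise ValueError("eval_cv_folds must be >= 2")
        if self.eval_cv_repeats < 1:
            raise ValueError("eval_cv_repeats must be >= 1")


@dataclass
class FeatureSelectionResult:
    """Best subset found, its cross-validated weight accuracy, the
    per-generation best-so-far trace, and (after a sweep) the per-limit
    summary table."""

    selected: list[int]
    size: int
    wacc: float
    history: np.ndarray
    per_limit: pd.DataFrame | None = None


def _resolve_folds(y: np.ndarray, folds: int) -> int:
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ValueError(f"class {counts.idxmin()!r} has fewer than 2 samples; cannot stratify")
    if counts.min() < folds:
        logger.warning("reducing CV folds from %d to %d (smallest class size)", folds, counts.min())
        return int(counts.min())
    return folds


def _make_splits(y: np.ndarray, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros((len(y), 1)), y))


def _subset_wacc(subset, X, y, splits, class_ids) -> float:
    cols = np.fromiter(subset, dtype=int)
    preds = np.empty(len(y), dtype=object)
    for train, test in splits:
        m = nb_fit(X[np.ix_(train, cols)], y[train], class_ids=class_ids)
        preds[test] = nb_predict(m, X[np.ix_(test, cols)])
    return weight_accuracy(ConfusionMatrix.from_labels(y, preds, class_ids=class_ids))


def evaluate_subset(subset, X, y, folds: int = 5, seed: int = 0, repeats: int = 1) -> float:
    """Stratified k-fold cross-validated weight accuracy of a naive Bayes
    classifier on the given feature subset.  The confusion matrix is
    accumulated over folds (each sample predicted exactly once) before
    wAcc is taken; with ``repeats > 1`` the wAcc is averaged over that many
    independent fold assignments, which damps the luck of any single
    split.  Deterministic given ``seed``."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = _resolve_folds(y, folds)
    class_ids = sorted(set(y))
    vals = [
        _subset_wacc(subset, X, y, _make_splits(y, folds, seed + rep), class_ids)
        for rep in range(repeats)
    ]
    return float(np.mean(vals))


def _decode(x: np.ndarray, n_features: int, relevance: np.ndarray, base_seed: int) -> tuple:
    """Map a real position vector to a feature subset.

    floor() of each entry is a candidate index; the value ``n_features``
    is the null token.  Duplicates are replaced by unused features drawn
    (without replacement) from a roulette wheel weighted by univariate
    relevance; the wheel's randomness is derived from the vector itself so
    decoding is a pure function of (x, base_seed).
    """
    idx = np.clip(np.floor(x).astype(int), 0, n_features)
    seen: set[int] = set()
    dups = 0
    for v in idx:
        if v == n_features:
            continue
        if v in seen:
            dups += 1
        else:
            seen.add(int(v))
    if dups:
        unused = np.setdiff1d(np.arange(n_features), np.fromiter(seen, dtype=int, count=len(seen)))
        if unused.size:
            take = min(dups, unused.size)
            w = relevance[unused] + 1e-9
            rng = np.random.default_rng((base_seed + zlib.crc32(x.tobytes())) % (2 ** 31))
            picks = rng.choice(unused, size=take, replace=False, p=w / w.sum())
            seen.update(int(v) for v in picks)
    return tuple(sorted(seen))


class _BestTracker:
    """Elitist record of the best subset evaluated so far.

    Order: higher wAcc, then smaller subset, then lexicographically
    smaller index tuple."""

    def __init__(self) -> None:
        self.wacc = -1.0
        self.subset: tuple = ()

    def offer(self, wacc: float, subset: tuple) -> None:
        if (wacc, -len(subset), tuple(-i for i in subset)) > (
                self.wacc, -len(self.subset), tuple(-i for i in self.subset)):
            self.wacc = wacc
            self.subset = subset


def defs_w_select(X, y, upper_limit: int, de: DEParams | None = None) -> FeatureSelectionResult:
    """Search for the best feature subset of size at most ``upper_limit``.

    Deterministic given ``de.seed``; the fitness history is the
    non-decreasing best-so-far wAcc at the end of each generation.
    """
    de = de or DEParams()
    de.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_features = X.shape[1]
    if upper_limit < 1:
        raise ValueError("upper_limit must be >= 1")
    if upper_limit > n_features:
        raise ValueError(f"upper_limit={upper_limit} exceeds the {n_features} available features")

    folds = _resolve_folds(y, de.eval_cv_folds)
    split_sets = [_make_splits(y, folds, de.seed + rep) for rep in range(de.eval_cv_repeats)]
    class_ids = sorted(set(y))

    cache: dict[tuple, float] = {}

    def fitness(subset: tuple) -> float:
        if subset not in cache:
            cache[subset] = float(np.mean(
                [_subset_wacc(subset, X, y, s, class_ids) for s in split_sets]))
        return cache[subset]

    # univariate relevance doubles as the first round of candidates: every
    # single-feature subset is genuinely evaluated and offered to the tracker
    tracker = _BestTracker()
    relevance = np.empty(n_features)
    for f in range(n_features):
        relevance[f] = fitness((f,))
        tracker.offer(relevance[f], (f,))
    history: list[float] = []

    def objective(x: np.ndarray) -> float:
        subset = _decode(x, n_features, relevance, de.seed)
        if not subset:
            return 1.0  # empty subset: worst possible energy (wAcc 0)
        w = fitness(subset)
        tracker.offer(w, subset)
        return -w

    rng = np.random.default_rng(de.seed)
    init = rng.uniform(0.0, n_features + 1.0, size=(de.population_size, upper_limit))
    bounds = [(0.0, n_features + 1.0 - 1e-9)] * upper_limit

    def callback(xk, convergence=0.0):
        history.append(tracker.wacc)

    differential_evolution(
        objective,
        bounds=bounds,
        strategy="rand1bin",
        maxiter=de.n_generations,
        init=init,
        mutation=de.diff_weight,
        recombination=de.crossover_rate,
        seed=int(de.seed),
        tol=0.0,
        polish=False,
        updating="immediate",
        callback=callback,
    )
    if not history:
        history.append(tracker.wacc)
    return FeatureSelectionResult(
        selected=list(tracker.subset),
        size=len(tracker.subset),
        wacc=tracker.wacc,
        history=np.asarray(history),
    )


def sweep_upper_limits(X, y, limits, de: DEParams | None = None) -> FeatureSelectionResult:
    """Run ``defs_w_select`` for each upper limit and keep the result with
    the highest cross-validated wAcc (ties: smaller subset, then smaller
    limit).  The per-limit table records every run."""
    limits = list(limits)
    if not limits:
        raise ValueError("limits must be non-empty")
    de = de or DEParams()
    rows = []
    results = []
    for i, limit in enumerate(limits):
        de_i = replace(de, seed=(de.seed + 1009 * i) % (2 ** 31))
        res = defs_w_select(X, y, upper_limit=limit, de=de_i)
        rows.append({"upper_limit": limit, "optimal_size": res.size, "mean_wacc": res.wacc})
        results.append(res)
    order = sorted(range(len(limits)),
                   key=lambda i: (-results[i].wacc, results[i].size, limits[i]))
    best = results[order[0]]
    best.per_limit = pd.DataFrame(rows)
    return best
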