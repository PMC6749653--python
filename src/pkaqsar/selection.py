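"""Genetic-algorithm descriptor selection for acid/base/amphoteric routing.

A chromosome is a bit vector over candidate continuous descriptors; its
fitness is the fivefold cross-validated multiclass balanced accuracy of a
kNN classifier restricted to the selected descriptors, minus a small
penalty per descriptor that biases the search toward compact subsets.
The cross-validation folds are fixed once per run so all chromosomes are
scored on the same partitions and fitness comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .featurize import FeatureMatrix

__all__ = ["GAConfig", "GAResult", "balanced_accuracy", "ga_select"]


def balanced_accuracy(
    true_labels: Sequence,
    predicted_labels: Sequence,
    n_classes: int | None = None,
) -> float:
    """Mean of per-class recalls.

    If ``n_classes`` is given, every expected class must appear in
    ``true_labels`` (a recall over an absent class is undefined).
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    observed = np.unique(y_true)
    if n_classes is not None and len(observed) != n_classes:
        raise ValueError(
            f"expected {n_classes} classes in true_labels, found {len(observed)}"
        )
    return float(balanced_accuracy_score(y_true, y_pred))


@dataclass
class GAConfig:
    population_size: int = 100
    generations: int = 200
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # default 1/n_features
    max_subset_size: int = 15
    cv_folds: int = 5
    tournament_size: int = 3
    elitism: int = 1
    size_penalty: float = 0.001
    knn_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass
class GAResult:
    selected_descriptors: list[str]
    fitness: float  # CV balanced accuracy of the elite subset
    penalized_fitness: float
    history: list[float] = field(default_factory=list)  # elite penalized fitness per generation


def _cv_balanced_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    k: int,
) -> float:
    cols = np.flatnonzero(mask)
    if cols.size == 0:
        return 0.0
    scores = []
    for train_idx, test_idx in folds:
        clf = KNeighborsClassifier(n_neighbors=min(k, len(train_idx)))
        clf.fit(X[np.ix_(train_idx, cols)], y[train_idx])
        pred = clf.predict(X[np.ix_(test_idx, cols)])
        scores.append(balanced_accuracy_score(y[test_idx], pred))
    return float(np.mean(scores))


def subset_cv_score(
    fm: FeatureMatrix | pd.DataFrame,
    labels: Sequence,
    columns: Sequence[str],
    cfg: GAConfig,
) -> float:
    """CV balanced accuracy of one explicit descriptor subset (used by
    exhaustive-search cross-checks; shares the GA's folds and scaling)."""
    frame = fm.frame if isinstance(fm, FeatureMatrix) else fm
    X, y, folds = _prepare(frame, labels, cfg)
    mask = np.isin(np.array(frame.columns), list(columns))
    return _cv_balanced_accuracy(X, y, mask, folds, cfg.knn_neighbors)


def _prepare(frame: pd.DataFrame, labels, cfg: GAConfig):
    X = frame.to_numpy(dtype=float)
    # z-score once over the full candidate matrix (selection heuristic)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    folds = [(tr, te) for tr, te in skf.split(X, y)]
    return X, y, folds


def ga_select(
    fm: FeatureMatrix | pd.DataFrame,
    labels: Sequence,
    cfg: GAConfig | None = None,
) -> GAResult:
    """Evolve a descriptor subset maximizing CV balanced accuracy.

    Elite-preserving loop: tournament selection, one-point crossover,
    per-bit mutation; chromosomes exceeding ``max_subset_size`` have
    random on-bits switched off.  Deterministic for a fixed seed.
    """
    cfg = cfg or GAConfig()
    frame = fm.frame if isinstance(fm, FeatureMatrix) else fm
    names = np.array(frame.columns)
    n = len(names)
    if n == 0:
        raise ValueError("no candidate descriptors")
    if len(np.unique(np.asarray(labels))) < 2:
        raise ValueError("need at least 2 classes")
    if cfg.max_subset_size >= n:
        import warnings

        warnings.warn("max_subset_size >= number of descriptors; selection is degenerate")

    X, y, folds = _prepare(frame, labels, cfg)
    rng = np.random.default_rng(cfg.seed)
    p_mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n

    def trim(mask: np.ndarray) -> np.ndarray:
        on = np.flatnonzero(mask)
        if on.size > cfg.max_subset_size:
            off = rng.choice(on, size=on.size - cfg.max_subset_size, replace=False)
            mask = mask.copy()
            mask[off] = False
        return mask

    # initial population: random subsets of size 1..max_subset_size
    pop = np.zeros((cfg.population_size, n), dtype=bool)
    for i in range(cfg.population_size):
        size = int(rng.integers(1, min(cfg.max_subset_size, n) + 1))
        pop[i, rng.choice(n, size=size, replace=False)] = True

    cache: dict[bytes, float] = {}

    def raw_fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = _cv_balanced_accuracy(X, y, mask, folds, cfg.knn_neighbors)
        return cache[key]

    def penalized(mask: np.ndarray) -> float:
        return raw_fitness(mask) - cfg.size_penalty * int(mask.sum())

    fits = np.array([penalized(ind) for ind in pop])
    history: list[float] = []
    elite_mask = pop[int(np.argmax(fits))].copy()
    elite_fit = float(np.max(fits))

    for _ in range(cfg.generations):
        new_pop = [elite_mask.copy() for _ in range(cfg.elitism)]
        while len(new_pop) < cfg.population_size:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population_size, size=cfg.tournament_size)
                parents.append(pop[contenders[np.argmax(fits[contenders])]].copy())
            a, b = parents
            if rng.random() < cfg.crossover_rate and n > 1:
                point = int(rng.integers(1, n))
                a = np.concatenate([a[:point], b[point:]])
            flip = rng.random(n) < p_mut
            child = np.logical_xor(a, flip)
            if not child.any():
                child[rng.integers(0, n)] = True
            new_pop.append(trim(child))
        pop = np.array(new_pop[: cfg.population_size])
        fits = np.array([penalized(ind) for ind in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > elite_fit:
            elite_fit = float(fits[gen_best])
            elite_mask = pop[gen_best].copy()
        history.append(elite_fit)

    return GAResult(
        selected_descriptors=[str(s) for s in names[elite_mask]],
        fitness=raw_fitness(elite_mask),
        penalized_fitness=elite_fit,
        history=history,
    )
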