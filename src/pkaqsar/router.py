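"""Ionizability check and acid/base/amphoteric kNN routing.

A prediction pipeline for pKa must first decide whether a chemical is
ionizable at all, then whether it carries an acidic site, a basic site,
or both, so the query is routed to the matching regressor.  The checker
uses hydrogen-bond donor/acceptor sites (Lipinski-style donors: any OH
or NH; standard N/O acceptors); the 3-class router is a kNN vote on a
small GA-selected descriptor subset, on z-scored features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Lipinski
from sklearn.model_selection import StratifiedKFold

from .curation import QsarStructure
from .featurize import FeatureMatrix
from .selection import balanced_accuracy

__all__ = ["RouterModel", "is_ionizable", "fit_router", "classify", "evaluate_router"]


def is_ionizable(structure: QsarStructure | str) -> bool:
    """True iff the structure has >= 1 hydrogen-bond donor or acceptor site."""
    smi = structure.canonical_smiles if isinstance(structure, QsarStructure) else structure
    mol = Chem.MolFromSmiles(smi) if smi is not None else None
    if mol is None:
        raise ValueError(f"unparsable structure: {smi!r}")
    return Lipinski.NumHDonors(mol) > 0 or Lipinski.NumHAcceptors(mol) > 0


@dataclass
class RouterModel:
    """A stored-training-set kNN classifier over selected descriptors."""

    k: int
    descriptor_subset: list[str]
    means: np.ndarray  # per-descriptor z-scoring statistics (training)
    stds: np.ndarray
    training_features: np.ndarray  # z-scored, shape (n, len(subset))
    training_labels: np.ndarray
    cv_ba: float | None = None
    train_ba: float | None = None

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        X = frame[self.descriptor_subset].to_numpy(dtype=float)
        return (X - self.means) / self.stds


def _vote(dists: np.ndarray, labels: np.ndarray, k: int) -> str:
    """Majority vote over the k nearest; ties broken by the single
    nearest neighbor's class."""
    order = np.argsort(dists, kind="stable")[:k]
    neigh = labels[order]
    classes, counts = np.unique(neigh, return_counts=True)
    winners = classes[counts == counts.max()]
    if len(winners) == 1:
        return str(winners[0])
    for lab in neigh:  # nearest first
        if lab in winners:
            return str(lab)
    return str(winners[0])  # unreachable


def classify(features, model: RouterModel) -> np.ndarray | str:
    """Route one query (1-D) or many (2-D / DataFrame) to a class."""
    if isinstance(features, pd.DataFrame):
        X = model.transform(features)
    else:
        X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    n_train = model.training_features.shape[0]
    if model.k > n_train:
        raise ValueError(f"k={model.k} exceeds training size {n_train}")
    out = []
    for x in X:
        d = np.sqrt(((model.training_features - x) ** 2).sum(axis=1))
        out.append(_vote(d, model.training_labels, model.k))
    return out[0] if single else np.array(out)


def fit_router(
    fm: FeatureMatrix | pd.DataFrame,
    labels,
    k: int | None = None,
    subset: list[str] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    k_grid: tuple[int, ...] = (1, 3, 5, 7, 9),
) -> RouterModel:
    """Fit the 3-class router; if ``k`` is None it is chosen by CV.

    Raises ValueError if fewer than two classes are present.
    """
    frame = fm.frame if isinstance(fm, FeatureMatrix) else fm
    subset = list(subset) if subset is not None else list(frame.columns)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("router training data must contain >= 2 classes")
    X = frame[subset].to_numpy(dtype=float)
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    stds[stds == 0] = 1.0
    Xz = (X - means) / stds

    def cv_ba_for(kk: int) -> float:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        scores = []
        for tr, te in skf.split(Xz, y):
            m = RouterModel(min(kk, len(tr)), subset, means, stds, Xz[tr], y[tr])
            pred = classify(Xz[te], m)
            scores.append(balanced_accuracy(y[te], pred))
        return float(np.mean(scores))

    if k is None:
        grid = [kk for kk in k_grid if kk <= len(y)]
        cv_scores = {kk: cv_ba_for(kk) for kk in grid}
        k = max(cv_scores, key=lambda kk: (cv_scores[kk], -kk))
        cv_ba = cv_scores[k]
    else:
        cv_ba = cv_ba_for(k) if cv_folds <= len(y) else None

    model = RouterModel(k, subset, means, stds, Xz, y, cv_ba=cv_ba)
    model.train_ba = balanced_accuracy(y, classify(Xz, model))
    return model


def evaluate_router(model: RouterModel, fm_test, labels_test) -> dict[str, float]:
    """Train / fivefold-CV / test balanced accuracy summary."""
    frame = fm_test.frame if isinstance(fm_test, FeatureMatrix) else fm_test
    pred = classify(model.transform(frame) if isinstance(frame, pd.DataFrame) else frame, model)
    return {
        "train_ba": model.train_ba,
        "cv_ba": model.cv_ba,
        "test_ba": balanced_accuracy(np.asarray(labels_test), pred),
    }
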