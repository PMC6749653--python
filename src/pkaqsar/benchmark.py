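"""Predictor concordance benchmarking with the ±2-pKa-unit rule.

Two prediction tables (strongest acidic / strongest basic pKa per
structure key) are compared pairwise: predictions within 2 pKa units of
each other are "concordant".  Concordant pairs can be averaged into a
benchmark table, optionally filtered to the pKa range the downstream
models were trained on, and summary statistics (R², Pearson r², RMSE)
carry percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regressors import compute_metrics

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionTable",
    "ConcordanceReport",
    "prediction_table",
    "pairwise_concordance",
    "build_benchmark",
    "range_filter",
    "bootstrap_ci",
]

#: canonical column layout of a prediction table
TABLE_COLUMNS = ["structure_key", "acidic_pka", "basic_pka"]

PredictionTable = pd.DataFrame  # columns: structure_key, acidic_pka, basic_pka (+ source)


def prediction_table(
    keys, acidic=None, basic=None, source: str = ""
) -> PredictionTable:
    """Assemble a prediction table; rows with neither class value are dropped."""
    df = pd.DataFrame({"structure_key": list(keys)})
    df["acidic_pka"] = np.nan if acidic is None else np.asarray(acidic, dtype=float)
    df["basic_pka"] = np.nan if basic is None else np.asarray(basic, dtype=float)
    df["source"] = source
    keep = df["acidic_pka"].notna() | df["basic_pka"].notna()
    return df[keep].reset_index(drop=True)


@dataclass
class ConcordanceReport:
    cls: str
    n_common: int
    n_within: int
    n_beyond: int
    r2: float | None
    pearson_r2: float | None
    rmse: float | None
    ci_r2: tuple[float, float] | None = None
    ci_rmse: tuple[float, float] | None = None
    reference: str = "a"

    def __post_init__(self) -> None:
        assert self.n_within + self.n_beyond == self.n_common


def _col(cls: str) -> str:
    if cls not in ("acidic", "basic"):
        raise ValueError("cls must be 'acidic' or 'basic'")
    return f"{cls}_pka"


def _join(a: PredictionTable, b: PredictionTable, cls: str) -> pd.DataFrame:
    col = _col(cls)
    left = a[["structure_key", col]].dropna().rename(columns={col: "pka_a"})
    right = b[["structure_key", col]].dropna().rename(columns={col: "pka_b"})
    merged = left.merge(right, on="structure_key")
    if merged.empty:
        raise ValueError(f"no structures in common with a {cls} value")
    return merged


def pairwise_concordance(
    a: PredictionTable,
    b: PredictionTable,
    cls: str,
    threshold: float = 2.0,
    n_boot: int = 0,
    seed: int = 0,
) -> tuple[ConcordanceReport, pd.DataFrame]:
    """Compare two predictors on their common structures.

    Returns the report (metrics computed with ``a`` as reference) and
    the concordant subset (|Δ| <= threshold; ties count as concordant).
    """
    merged = _join(a, b, cls)
    delta = (merged["pka_a"] - merged["pka_b"]).abs()
    within = merged[delta <= threshold].reset_index(drop=True)
    obs = merged["pka_a"].to_numpy()
    pred = merged["pka_b"].to_numpy()
    try:
        m = compute_metrics(obs, pred)
        r2, rmse = m["r2"], m["rmse"]
        pearson = float(np.corrcoef(obs, pred)[0, 1] ** 2) if len(obs) > 1 else None
    except ValueError:
        r2 = rmse = pearson = None
    report = ConcordanceReport(
        cls=cls,
        n_common=len(merged),
        n_within=len(within),
        n_beyond=len(merged) - len(within),
        r2=r2,
        pearson_r2=pearson,
        rmse=rmse,
    )
    if n_boot and rmse is not None:
        report.ci_r2 = bootstrap_ci(obs, pred, "r2", n_boot=n_boot, seed=seed)
        report.ci_rmse = bootstrap_ci(obs, pred, "rmse", n_boot=n_boot, seed=seed)
    return report, within


def build_benchmark(
    a: PredictionTable,
    b: PredictionTable,
    cls: str,
    threshold: float = 2.0,
) -> PredictionTable:
    """Average concordant predictions into a benchmark table."""
    _, within = pairwise_concordance(a, b, cls, threshold)
    col = _col(cls)
    out = pd.DataFrame(
        {
            "structure_key": within["structure_key"],
            col: (within["pka_a"] + within["pka_b"]) / 2.0,
        }
    )
    other = "basic_pka" if col == "acidic_pka" else "acidic_pka"
    out[other] = np.nan
    out["source"] = f"mean({a['source'].iloc[0] if 'source' in a else 'a'},"\
        f"{b['source'].iloc[0] if 'source' in b else 'b'})"
    return out[["structure_key", "acidic_pka", "basic_pka", "source"]].reset_index(drop=True)


def range_filter(t: PredictionTable, cls: str, lo: float, hi: float) -> PredictionTable:
    """Keep rows whose class value lies in [lo, hi]."""
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    col = _col(cls)
    vals = t[col]
    return t[(vals >= lo) & (vals <= hi)].reset_index(drop=True)


def _metric_resampled(obs: np.ndarray, pred: np.ndarray, metric: str) -> float:
    if metric == "rmse":
        return float(np.sqrt(((obs - pred) ** 2).mean()))
    if metric == "r2":
        ss_tot = ((obs - obs.mean()) ** 2).sum()
        if ss_tot == 0:
            raise ZeroDivisionError
        return float(1.0 - ((obs - pred) ** 2).sum() / ss_tot)
    if metric == "pearson_r2":
        if obs.std() == 0 or pred.std() == 0:
            raise ZeroDivisionError
        return float(np.corrcoef(obs, pred)[0, 1] ** 2)
    raise ValueError(f"unknown metric: {metric!r}")


def bootstrap_ci(
    observed,
    predicted,
    metric: str = "rmse",
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval over paired resamples.

    A resample on which the metric is undefined (zero variance) is
    redrawn.  Reproducible for a fixed seed.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    rng = np.random.default_rng(seed)
    n = obs.size
    stats = np.empty(n_boot)
    redraws = 0
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                stats[i] = _metric_resampled(obs[idx], pred[idx], metric)
                break
            except ZeroDivisionError:
                redraws += 1
                if redraws > 100 * n_boot:
                    raise ValueError("metric undefined on almost all resamples")
    if redraws:
        logger.info("redrew %d degenerate bootstrap resamples", redraws)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
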