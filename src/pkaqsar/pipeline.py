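"""End-to-end orchestration: curate → featurize → route → regress → AD.

The trained artifact is a :class:`PkaPredictor` bundling the 3-class
router, one regressor per ionization class, per-class feature scaling,
and the applicability-domain machinery.  Prediction follows the
deployment flow: the ionizability checker gates everything; the router
decides acidic / basic / amphoteric; the matching regressor(s) emit pKa
values with per-class AD fields attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from .curation import (
    build_option_dataset,
    curate_records,
    split_train_test,
    standardize,
)
from .domain import ADParams, GlobalAD, local_ad
from .featurize import ScalingSpec, apply_scaling, compute_features, fit_scaling
from .regressors import RegressorModel, evaluate_on_test, predict as predict_pka
from .router import RouterModel, classify, fit_router, is_ionizable

__all__ = ["TrainConfig", "PkaPredictor", "train_pipeline", "prepare_datasets"]


@dataclass
class TrainConfig:
    option: int = 1
    regressor: str = "svm"  # svm | xgb | dnn
    feature_families: tuple[str, ...] = ("maccs", "substructure_counts")
    router_families: tuple[str, ...] = ("continuous",)
    router_subset: list[str] | None = None
    fingerprint_family: str = "maccs"  # for the local AD
    frac_train: float = 0.75
    ad_params: ADParams = field(default_factory=ADParams)
    seed: int = 0


def prepare_datasets(records, option: int, frac_train: float = 0.75, seed: int = 0):
    """Curate raw records and build split per-option datasets."""
    cur = curate_records(records)
    datasets = build_option_dataset(cur.groups, option)
    datasets = {
        name: split_train_test(ds, frac_train=frac_train, seed=seed)
        for name, ds in datasets.items()
        if len(ds)
    }
    return cur, datasets


@dataclass
class PkaPredictor:
    """A deployable pKa prediction bundle."""

    router: RouterModel
    regressors: dict[str, RegressorModel]  # class -> model
    feature_families: tuple[str, ...]
    router_families: tuple[str, ...]
    scaling: dict[str, ScalingSpec]  # class -> training scaling
    global_ad: dict[str, GlobalAD]  # class -> leverage model
    train_pka: dict[str, np.ndarray]
    train_fp_keys: dict[str, list[str]]
    train_fps_by_class: dict[str, np.ndarray]
    train_residual_pred: dict[str, np.ndarray]
    fingerprint_family: str
    ad_params: ADParams
    config: TrainConfig | None = None

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "PkaPredictor":
        return joblib.load(path)

    # -- prediction flow ---------------------------------------------------

    def predict_smiles(self, smiles_list: Sequence[str]) -> pd.DataFrame:
        """Standardize and predict a batch of raw SMILES.

        One output row per input: ionizability, routed class, per-class
        pKa (amphoterics get both), and AD fields per predicted class.
        Non-ionizable or rejected inputs get no pKa.
        """
        return pd.DataFrame([self._predict_one(s) for s in smiles_list])

    def _predict_one(self, smiles_raw: str) -> dict:
        out: dict = {
            "smiles": smiles_raw,
            "structure_key": None,
            "ionizable": None,
            "pka_class": None,
            "acidic_pka": np.nan,
            "basic_pka": np.nan,
        }
        try:
            qs = standardize(smiles_raw)
        except ValueError:
            out["error"] = "parse_error"
            return out
        if qs.rejected:
            out["error"] = qs.rejection_reason
            return out
        out["structure_key"] = qs.structure_key
        if not is_ionizable(qs):
            out["ionizable"] = False
            return out
        out["ionizable"] = True

        rfm = compute_features([qs], families=self.router_families)
        cls = classify(rfm.frame, self.router)
        out["pka_class"] = cls if isinstance(cls, str) else cls[0]

        fm_raw = compute_features([qs], families=self.feature_families)
        fp_fm = compute_features([qs], families=(self.fingerprint_family,))

        targets = (
            ["acidic", "basic"] if out["pka_class"] == "amphoteric" else [out["pka_class"]]
        )
        for cls_name in targets:
            model = self.regressors.get(cls_name)
            if model is None:
                continue
            fm = apply_scaling(fm_raw, self.scaling[cls_name])
            out[f"{cls_name}_pka"] = float(predict_pka(model, fm)[0])
            inside, lev = self.global_ad[cls_name].check(
                fm.frame[model.feature_names].to_numpy(dtype=float)
            )
            out[f"{cls_name}_ad_global_inside"] = bool(inside[0])
            out[f"{cls_name}_ad_leverage"] = float(lev[0])
            ad = local_ad(
                self.train_fps_by_class[cls_name],
                self.train_pka[cls_name],
                fp_fm.values[0],
                self.ad_params,
                train_predicted=self.train_residual_pred.get(cls_name),
                train_keys=self.train_fp_keys[cls_name],
            )
            out[f"{cls_name}_ad_local_index"] = ad.local_index
            out[f"{cls_name}_ad_accuracy_estimate"] = ad.accuracy_estimate
            out[f"{cls_name}_ad_neighbors"] = ";".join(map(str, ad.neighbor_keys))
        return out


def train_pipeline(records, config: TrainConfig | None = None):
    """Train a full predictor from raw records.

    Returns (predictor, report); the report carries curation counts, the
    router's balanced accuracies and per-class regression metrics.
    """
    from . import regressors as R

    config = config or TrainConfig()
    trainers = {"svm": R.train_svm, "xgb": R.train_xgb, "dnn": R.train_dnn}
    train_fn = trainers[config.regressor]

    cur, datasets = prepare_datasets(records, config.option, config.frac_train, config.seed)

    # --- router training on all curated structures ------------------------
    labels = {}
    for g in cur.groups:
        if g.amphoteric:
            labels[g.structure_key] = "amphoteric"
        elif g.acidic_values:
            labels[g.structure_key] = "acidic"
        else:
            labels[g.structure_key] = "basic"
    router_keys = list(labels)
    router_fm = compute_features(
        [cur.structures[k] for k in router_keys],
        families=config.router_families,
        keys=router_keys,
    )
    y_router = np.array([labels[k] for k in router_fm.row_keys])
    router = fit_router(router_fm, y_router, subset=config.router_subset, seed=config.seed)

    # --- per-class regressors ---------------------------------------------
    regressors: dict[str, RegressorModel] = {}
    metrics_report = {}
    scaling: dict[str, ScalingSpec] = {}
    global_ads: dict[str, GlobalAD] = {}
    train_pka: dict[str, np.ndarray] = {}
    train_fps_by_class: dict[str, np.ndarray] = {}
    train_fp_keys: dict[str, list[str]] = {}
    train_residual_pred: dict[str, np.ndarray] = {}

    for cls in ("acidic", "basic"):
        ds = datasets.get(cls)
        if ds is None or not len(ds):
            continue
        keys = ds.keys
        fm = compute_features(
            [cur.structures[k] for k in keys], families=config.feature_families, keys=keys
        )
        values = dict(zip(ds.entries["structure_key"], ds.entries["pka_value"]))
        train_keys = [k for k in fm.row_keys if ds.split.get(k) == "train"]
        test_keys = [k for k in fm.row_keys if ds.split.get(k) == "test"]
        fm_train = fm.select_rows(train_keys)
        fm_test = fm.select_rows(test_keys)
        spec = fit_scaling(fm_train)
        scaling[cls] = spec
        fm_train_s = apply_scaling(fm_train, spec)
        fm_test_s = apply_scaling(fm_test, spec)
        y_train = np.array([values[k] for k in train_keys])
        y_test = np.array([values[k] for k in test_keys])
        model = train_fn(
            fm_train_s,
            y_train,
            seed=config.seed,
            target=cls,
            feature_spec={"families": config.feature_families},
        )
        evaluate_on_test(model, fm_test_s, y_test)
        regressors[cls] = model
        metrics_report[cls] = model.metrics
        global_ads[cls] = GlobalAD(fm_train_s.values, config.ad_params)

        fps = compute_features(
            [cur.structures[k] for k in train_keys],
            families=(config.fingerprint_family,),
            keys=train_keys,
        )
        train_fps_by_class[cls] = fps.values.astype(bool)
        train_fp_keys[cls] = fps.row_keys
        train_pka[cls] = y_train
        train_residual_pred[cls] = predict_pka(model, fm_train_s)

    predictor = PkaPredictor(
        router=router,
        regressors=regressors,
        feature_families=config.feature_families,
        router_families=config.router_families,
        scaling=scaling,
        global_ad=global_ads,
        train_pka=train_pka,
        train_fp_keys=train_fp_keys,
        train_fps_by_class=train_fps_by_class,
        train_residual_pred=train_residual_pred,
        fingerprint_family=config.fingerprint_family,
        ad_params=config.ad_params,
        config=config,
    )
    report = {
        "curation": {
            "n_records": cur.n_records,
            "n_unique_structures": cur.n_unique_structures,
            "n_amphoteric": cur.n_amphoteric,
            "n_rejected": dict(cur.n_rejected),
        },
        "router": {"k": router.k, "train_ba": router.train_ba, "cv_ba": router.cv_ba},
        "metrics": metrics_report,
    }
    return predictor, report
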