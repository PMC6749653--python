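"""Readers and writers for the CSV/TSV/SDF dialects the pipeline uses."""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .curation import ChemicalRecord, CurationResult, ModelingDataset

__all__ = [
    "read_records_csv",
    "read_records_sdf",
    "write_records_csv",
    "write_dataset_csv",
    "read_prediction_table",
    "write_prediction_table",
    "curation_report",
]

_CLASS_ALIASES = {"acid": "acidic", "acidic": "acidic", "base": "basic", "basic": "basic"}


def read_records_csv(path) -> list[ChemicalRecord]:
    """Read raw records from CSV/TSV with columns smiles, pka, class
    (acidic|basic) and optional method."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"smiles", "pka", "class"}
    if not required <= set(df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
    records = []
    for row in df.to_dict("records"):
        cls = _CLASS_ALIASES.get(str(row["class"]).strip().lower())
        if cls is None:
            raise ValueError(f"unknown pKa class: {row['class']!r}")
        method = row.get("method")
        if method is None or (isinstance(method, float) and math.isnan(method)):
            method = None
        records.append(
            ChemicalRecord(
                smiles_raw=str(row["smiles"]),
                pka_value=float(row["pka"]),
                pka_class=cls,
                method=method,
            )
        )
    return records


def read_records_sdf(path, pka_prop: str = "pKa", class_prop: str = "class") -> list[ChemicalRecord]:
    """Read raw records from an SDF carrying pKa value/class properties."""
    records = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None or not mol.HasProp(pka_prop) or not mol.HasProp(class_prop):
            continue
        cls = _CLASS_ALIASES.get(mol.GetProp(class_prop).strip().lower())
        if cls is None:
            continue
        records.append(
            ChemicalRecord(
                smiles_raw=Chem.MolToSmiles(mol),
                pka_value=float(mol.GetProp(pka_prop)),
                pka_class=cls,
            )
        )
    return records


def write_records_csv(records, path) -> None:
    pd.DataFrame(
        {
            "smiles": [r.smiles_raw for r in records],
            "pka": [r.pka_value for r in records],
            "class": [r.pka_class for r in records],
            "method": [r.method for r in records],
        }
    ).to_csv(path, index=False)


def write_dataset_csv(ds: ModelingDataset, path) -> None:
    df = ds.entries.copy()
    if ds.split:
        df["split"] = df["structure_key"].map(ds.split)
    df.insert(0, "option", ds.option)
    df.insert(1, "subset", ds.subset)
    df.to_csv(path, index=False)


def read_prediction_table(path, source: str | None = None) -> pd.DataFrame:
    """Read a predictor output table (structure_key, acidic_pka, basic_pka)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    if "structure_key" not in df.columns and "smiles" in df.columns:
        df = df.rename(columns={"smiles": "structure_key"})
    for col in ("acidic_pka", "basic_pka"):
        if col not in df.columns:
            df[col] = float("nan")
    df["source"] = source or path.stem
    return df[["structure_key", "acidic_pka", "basic_pka", "source"]]


def write_prediction_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def curation_report(result: CurationResult) -> dict:
    """JSON-serializable curation bookkeeping (counts + SD histogram)."""
    sd = result.sd_table()
    hist = (
        sd["sd"].round(0).astype(int).value_counts().sort_index().to_dict()
        if len(sd)
        else {}
    )
    return {
        "n_records": result.n_records,
        "n_acidic_records": result.n_acidic_records,
        "n_basic_records": result.n_basic_records,
        "n_rejected": dict(result.n_rejected),
        "n_parse_errors": result.n_parse_errors,
        "n_unique_structures": result.n_unique_structures,
        "n_acidic_structures": result.n_acidic_structures,
        "n_basic_structures": result.n_basic_structures,
        "n_amphoteric": result.n_amphoteric,
        "replicate_sd_histogram": {str(k): int(v) for k, v in hist.items()},
    }
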