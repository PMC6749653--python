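"""Standardization of raw pKa records into QSAR-ready modeling datasets.

Raw records are (SMILES, pKa value, acidic/basic label) triples, typically
exported from an experimental compilation.  Standardization strips salts,
solvents and counterions, rejects inorganics and mixtures, canonicalizes
tautomers (nitro mesomers, keto–enol pairs) and leaves zwitterions
untouched.  Deduplicated structures are grouped into per-structure
replicate groups, from which three modeling datasets ("options") are
built that differ in how replicate and amphoteric chemicals are handled:

* Option 1 — only chemicals whose every measured class (acidic/basic) has
  exactly one value; avoids replicate variability altogether.
* Option 2 — additionally admits replicate groups whose per-class sample
  standard deviation is below 2 pKa units, using the mean.
* Option 3 — admits everything: replicates with SD <= 1 are averaged,
  otherwise the strongest value is kept (minimum for acidic, maximum for
  basic).

Options 1 and 2 also yield a "combined" acidic+basic dataset from which
amphoteric chemicals are excluded.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "PkaClass",
    "ChemicalRecord",
    "QsarStructure",
    "ReplicateGroup",
    "ModelingDataset",
    "CurationResult",
    "standardize",
    "group_replicates",
    "curate_records",
    "build_option_dataset",
    "split_train_test",
]


class PkaClass(str, enum.Enum):
    ACIDIC = "acidic"
    BASIC = "basic"


@dataclass(frozen=True)
class ChemicalRecord:
    """One raw pKa measurement."""

    smiles_raw: str
    pka_value: float
    pka_class: str  # "acidic" | "basic"
    method: str | None = None
    n_averaged: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.pka_value):
            raise ValueError("pka_value must be finite")
        if self.pka_class not in ("acidic", "basic"):
            raise ValueError(f"pka_class must be 'acidic' or 'basic', got {self.pka_class!r}")


@dataclass(frozen=True)
class QsarStructure:
    """A standardized parent structure, or a rejection verdict."""

    canonical_smiles: str | None
    structure_key: str | None
    rejected: bool = False
    rejection_reason: str | None = None  # inorganic | mixture | empty_after_stripping


@dataclass
class ReplicateGroup:
    """All measurements mapping to one standardized structure."""

    structure_key: str
    acidic_values: list[float] = field(default_factory=list)
    basic_values: list[float] = field(default_factory=list)

    @property
    def amphoteric(self) -> bool:
        return bool(self.acidic_values) and bool(self.basic_values)

    def values(self, cls: str) -> list[float]:
        return self.acidic_values if cls == "acidic" else self.basic_values

    def sd(self, cls: str) -> float | None:
        """Sample standard deviation (n-1 denominator); None for <2 values."""
        v = self.values(cls)
        if len(v) < 2:
            return None
        return float(np.std(v, ddof=1))

    @property
    def acidic_sd(self) -> float | None:
        return self.sd("acidic")

    @property
    def basic_sd(self) -> float | None:
        return self.sd("basic")


@dataclass
class ModelingDataset:
    """A per-option modeling table: unique structures with one pKa each."""

    option: int
    subset: str  # acidic | basic | combined
    entries: pd.DataFrame  # columns: structure_key, pka_value, pka_class, n_replicates, amphoteric
    split: dict[str, str] = field(default_factory=dict)  # structure_key -> train|test

    def __post_init__(self) -> None:
        keys = self.entries["structure_key"]
        if keys.duplicated().any():
            raise ValueError("structure_key must be unique within a dataset")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def keys(self) -> list[str]:
        return list(self.entries["structure_key"])

    def subset_frame(self, which: str) -> pd.DataFrame:
        mask = self.entries["structure_key"].map(self.split) == which
        return self.entries[mask]


# --------------------------------------------------------------------------
# structure standardization
# --------------------------------------------------------------------------

# Fragments stripped as salts/solvents when they accompany another organic
# component.  Canonical SMILES of neutral or charged forms.
_SALT_SOLVENT_SMILES = [
    "O",  # water
    "CO",  # methanol
    "CCO",  # ethanol
    "CC(=O)O", "CC(=O)[O-]",  # acetate
    "C(=O)O", "[O-]C=O", "OC=O",  # formate
    "OC(=O)C(=O)O",  # oxalic acid
    "CS(=O)(=O)O", "CS(=O)(=O)[O-]",  # mesylate
    "Cc1ccc(S(=O)(=O)O)cc1",  # tosylate
    "OC(=O)/C=C/C(=O)O", "OC(=O)/C=C\\C(=O)O",  # fumaric/maleic
    "OC(=O)C(O)C(O)C(=O)O",  # tartaric
    "OCC(O)CO",  # glycerol
    "CC(C)=O",  # acetone
]


def _canon(smiles: str) -> str | None:
    m = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(m) if m is not None else None


_SALT_SET = {s for s in (_canon(x) for x in _SALT_SOLVENT_SMILES) if s}

_uncharger = rdMolStandardize.Uncharger()
_tautomerizer = rdMolStandardize.TautomerEnumerator()
_tautomerizer.SetMaxTransforms(500)


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def standardize(smiles_raw: str) -> QsarStructure:
    """Standardize one raw SMILES into a QSAR-ready parent structure.

    Carbon-free inputs are rejected as inorganic, multi-component inputs
    with >= 2 distinct organic parents as mixtures.  Counterions, water
    and common salt/solvent fragments are stripped.  Net-charged species
    are neutralized; zwitterions (net charge zero) are left unmodified.
    Tautomers are mapped to a canonical form.

    Raises ValueError for unparsable SMILES.
    """
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles_raw!r}")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if _has_carbon(f)]
    if not organic:
        return QsarStructure(None, None, rejected=True, rejection_reason="inorganic")

    canon = []
    for f in organic:
        try:
            Chem.SanitizeMol(f)
            canon.append(Chem.MolToSmiles(f))
        except Exception:  # noqa: BLE001 - unsalvageable fragment
            continue
    if not canon:
        return QsarStructure(None, None, rejected=True, rejection_reason="empty_after_stripping")

    distinct = sorted(set(canon))
    # strip known salt/solvent organics only if something else remains
    non_salt = [s for s in distinct if s not in _SALT_SET]
    parents = non_salt if non_salt else distinct
    if len(parents) > 1:
        return QsarStructure(None, None, rejected=True, rejection_reason="mixture")

    parent = Chem.MolFromSmiles(parents[0])
    if parent is None:
        return QsarStructure(None, None, rejected=True, rejection_reason="empty_after_stripping")

    parent = rdMolStandardize.Cleanup(parent)  # normalizes nitro mesomers etc.
    net_charge = Chem.GetFormalCharge(parent)
    if net_charge != 0:
        parent = _uncharger.uncharge(parent)
    # zwitterions (net zero with +/- sites) deliberately left as drawn
    try:
        parent = _tautomerizer.Canonicalize(parent)
    except Exception:  # noqa: BLE001 - keep pre-tautomer form on failure
        pass

    smi = Chem.MolToSmiles(parent)
    return QsarStructure(canonical_smiles=smi, structure_key=smi)


# --------------------------------------------------------------------------
# replicate grouping and curation
# --------------------------------------------------------------------------

def group_replicates(
    records: Sequence[ChemicalRecord],
    keys: Sequence[str],
) -> list[ReplicateGroup]:
    """Group standardized records by structure key, per pKa class.

    ``keys[i]`` is the structure key of ``records[i]`` (rejected records
    must already be excluded).  Deduplication is per class: a structure
    measured once as acidic and once as basic forms one amphoteric group.
    """
    if len(records) != len(keys):
        raise ValueError("records and keys must have equal length")
    groups: dict[str, ReplicateGroup] = {}
    for rec, key in zip(records, keys):
        g = groups.setdefault(key, ReplicateGroup(structure_key=key))
        g.values(rec.pka_class).append(rec.pka_value)
    return list(groups.values())


@dataclass
class CurationResult:
    """Standardized records, replicate groups and bookkeeping counts."""

    groups: list[ReplicateGroup]
    structures: dict[str, QsarStructure]  # key -> structure
    n_records: int
    n_acidic_records: int
    n_basic_records: int
    n_rejected: dict[str, int]
    n_parse_errors: int

    @property
    def n_unique_structures(self) -> int:
        return len(self.groups)

    @property
    def n_amphoteric(self) -> int:
        return sum(g.amphoteric for g in self.groups)

    @property
    def n_acidic_structures(self) -> int:
        return sum(bool(g.acidic_values) for g in self.groups)

    @property
    def n_basic_structures(self) -> int:
        return sum(bool(g.basic_values) for g in self.groups)

    def sd_table(self, min_replicates: int = 3) -> pd.DataFrame:
        """Per-class SDs for groups with >= min_replicates values."""
        rows = []
        for g in self.groups:
            for cls in ("acidic", "basic"):
                v = g.values(cls)
                if len(v) >= min_replicates:
                    rows.append((g.structure_key, cls, len(v), float(np.std(v, ddof=1))))
        return pd.DataFrame(rows, columns=["structure_key", "pka_class", "n", "sd"])


def curate_records(records: Iterable[ChemicalRecord]) -> CurationResult:
    """Standardize, deduplicate and group a raw record list."""
    records = list(records)
    cache: dict[str, QsarStructure] = {}
    kept_records: list[ChemicalRecord] = []
    kept_keys: list[str] = []
    structures: dict[str, QsarStructure] = {}
    n_rejected: dict[str, int] = {}
    n_parse = 0
    for rec in records:
        if rec.smiles_raw in cache:
            qs = cache[rec.smiles_raw]
        else:
            try:
                qs = standardize(rec.smiles_raw)
            except ValueError:
                qs = QsarStructure(None, None, rejected=True, rejection_reason="parse_error")
            cache[rec.smiles_raw] = qs
        if qs.rejected:
            if qs.rejection_reason == "parse_error":
                n_parse += 1
            else:
                n_rejected[qs.rejection_reason] = n_rejected.get(qs.rejection_reason, 0) + 1
            continue
        kept_records.append(rec)
        kept_keys.append(qs.structure_key)
        structures[qs.structure_key] = qs

    groups = group_replicates(kept_records, kept_keys)
    return CurationResult(
        groups=groups,
        structures=structures,
        n_records=len(records),
        n_acidic_records=sum(r.pka_class == "acidic" for r in records),
        n_basic_records=sum(r.pka_class == "basic" for r in records),
        n_rejected=n_rejected,
        n_parse_errors=n_parse,
    )


# --------------------------------------------------------------------------
# option datasets
# --------------------------------------------------------------------------

def _option_value(values: list[float], option: int, cls: str) -> float | None:
    """Resolve a replicate list to a single modeling value, or None."""
    m = len(values)
    if m == 0:
        return None
    if m == 1:
        return values[0]
    sd = float(np.std(values, ddof=1))
    if option == 1:
        return None
    if option == 2:
        return float(np.mean(values)) if sd < 2.0 else None
    # option 3: average tight replicates, otherwise strongest value
    if sd <= 1.0:
        return float(np.mean(values))
    return float(min(values)) if cls == "acidic" else float(max(values))


def build_option_dataset(
    groups: Sequence[ReplicateGroup],
    option: int,
) -> dict[str, ModelingDataset]:
    """Build acidic/basic (and, for Options 1-2, combined) datasets.

    Option 1 admits a chemical only if every class it was measured in has
    exactly one value.  Options 2 and 3 admit per class.  The combined
    dataset (Options 1-2 only) excludes amphoteric chemicals.
    """
    if option not in (1, 2, 3):
        raise ValueError(f"unknown option: {option!r}")

    rows: dict[str, list] = {"acidic": [], "basic": []}
    combined_rows: list = []
    for g in groups:
        resolved: dict[str, float | None] = {}
        for cls in ("acidic", "basic"):
            resolved[cls] = _option_value(g.values(cls), option, cls)
        if option == 1:
            # chemical-level admission: every measured class must be singleton
            ok = all(
                len(g.values(cls)) in (0, 1)
                for cls in ("acidic", "basic")
            )
            if not ok:
                resolved = {"acidic": None, "basic": None}
        for cls in ("acidic", "basic"):
            val = resolved[cls]
            if val is None:
                continue
            row = (g.structure_key, val, cls, len(g.values(cls)), g.amphoteric)
            rows[cls].append(row)
            if option in (1, 2) and not g.amphoteric:
                combined_rows.append(row)

    cols = ["structure_key", "pka_value", "pka_class", "n_replicates", "amphoteric"]
    out = {
        cls: ModelingDataset(option, cls, pd.DataFrame(rows[cls], columns=cols))
        for cls in ("acidic", "basic")
    }
    if option in (1, 2):
        out["combined"] = ModelingDataset(option, "combined", pd.DataFrame(combined_rows, columns=cols))
    return out


# --------------------------------------------------------------------------
# train/test split
# --------------------------------------------------------------------------

def split_train_test(
    ds: ModelingDataset,
    frac_train: float = 0.75,
    seed: int = 0,
) -> ModelingDataset:
    """Semi-random split preserving the pKa distribution.

    Entries are stratified on 1-pKa-unit bins crossed with replicate and
    amphoteric flags (and acidic/basic class for the combined subset);
    each stratum is shuffled by ``seed`` and split at ``frac_train``, so
    per-stratum train fractions track the global one and the train and
    test pKa distributions match.
    """
    if not 0.0 < frac_train < 1.0:
        raise ValueError("frac_train must lie in (0, 1)")
    if len(ds) == 0:
        raise ValueError("cannot split an empty dataset")

    df = ds.entries
    bins = np.floor(df["pka_value"]).astype(int).clip(-4, 16)
    strata = pd.DataFrame(
        {
            "bin": bins,
            "rep": (df["n_replicates"] >= 2).astype(int),
            "amph": df["amphoteric"].astype(int),
        }
    )
    if ds.subset == "combined":
        strata["cls"] = df["pka_class"]

    rng = np.random.default_rng(seed)
    split: dict[str, str] = {}
    # deterministic stratum order
    grouped = list(df.groupby([strata[c] for c in strata.columns], sort=True).groups.items())
    sizes = np.array([len(idx) for _, idx in grouped])
    # largest-remainder allocation so the global train count is exact
    quota = frac_train * sizes
    n_train_per = np.floor(quota).astype(int)
    n_total_train = int(round(frac_train * len(df)))
    remainder_order = np.argsort(-(quota - n_train_per), kind="stable")
    short = n_total_train - int(n_train_per.sum())
    for j in remainder_order[:max(short, 0)]:
        n_train_per[j] += 1
    for (_, idx), n_train in zip(grouped, n_train_per):
        idx = list(idx)
        order = rng.permutation(len(idx))
        for rank, pos in enumerate(order):
            key = df.loc[idx[pos], "structure_key"]
            split[key] = "train" if rank < int(n_train) else "test"

    return ModelingDataset(ds.option, ds.subset, df.copy(), split=split)
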