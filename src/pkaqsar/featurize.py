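"""Molecular feature computation, reduction ladder, and scaling.

Feature families (all 1D/2D; computed with RDKit):

* ``continuous``   — RDKit's physicochemical/topological descriptor set
* ``maccs``        — MACCS structural keys (166 bits)
* ``morgan``       — circular (ECFP-like) bits, radius 2, 1024 bits
* ``topological``  — RDKit path-based fingerprint, 2048 bits
* ``atom_pairs``   — hashed atom-pair occurrence counts, 1024 slots
* ``substructure_counts`` — occurrence counts for a curated SMARTS list

The reduction ladder mirrors common fingerprint pre-filtering: D1 drops
constant columns; D2 additionally drops one of each highly correlated
pair; D3 additionally drops low-variance columns.  Min-max scaling maps
training columns into [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator

from .curation import QsarStructure

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "ScalingSpec",
    "FAMILIES",
    "SUBSTRUCTURE_SMARTS",
    "compute_features",
    "reduce_features",
    "fit_scaling",
    "apply_scaling",
    "invert_scaling",
]

FAMILIES = (
    "continuous",
    "maccs",
    "morgan",
    "topological",
    "atom_pairs",
    "substructure_counts",
)

BINARY_FAMILIES = ("maccs", "morgan", "topological")
COUNT_FAMILIES = ("atom_pairs", "substructure_counts")

#: named substructure patterns whose occurrence counts form the
#: fragment-count family (ionizable groups plus common frameworks)
SUBSTRUCTURE_SMARTS: dict[str, str] = {
    "hydroxyl": "[OX2H]",
    "phenol": "[OX2H][cX3]",
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "carboxylate": "[CX3](=O)[O-]",
    "primary_amine": "[NX3;H2;!$(NC=O)]",
    "secondary_amine": "[NX3;H1;!$(NC=O)]",
    "tertiary_amine": "[NX3;H0;!$(NC=O);!$(N=*)]",
    "aromatic_n_basic": "[nX2]",
    "aromatic_nh": "[nH]",
    "amide": "[NX3][CX3](=[OX1])",
    "nitro": "[$([NX3](=O)=O),$([NX3+](=O)[O-])]",
    "nitrile": "[NX1]#[CX2]",
    "thiol": "[SX2H]",
    "sulfonic_acid": "S(=O)(=O)[OX2H,OX1-]",
    "sulfonamide": "[SX4](=O)(=O)[NX3]",
    "ester": "[CX3](=O)[OX2H0][#6]",
    "ether": "[OD2]([#6])[#6]",
    "ketone": "[#6][CX3](=O)[#6]",
    "aldehyde": "[CX3H1](=O)[#6]",
    "halogen": "[F,Cl,Br,I]",
    "fluoro": "[F]",
    "chloro": "[Cl]",
    "aromatic_ring_atom": "c",
    "aromatic_oxygen": "[o]",
    "imidazole_like": "c1cnc[nH]1",
    "pyridine_like": "c1ccncc1",
    "guanidine": "[NX3][CX3](=[NX2])[NX3]",
    "phosphate": "[PX4](=O)([OX2H,OX1-])",
    "conjugated_cc": "C=C",
    "alkyne": "C#C",
}


@dataclass
class FeatureMatrix:
    """A named feature table keyed by structure key.

    ``frame`` holds one row per structure (index = structure keys) and
    one named column per feature.  ``kind`` records the value type of the
    columns and ``reduction`` the filtering level applied so far.
    """

    frame: pd.DataFrame
    kind: str = "mixed"  # continuous | binary | count | mixed
    reduction: str = "D0"  # D0 | D1 | D2 | D3
    failed_keys: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            raise ValueError("feature column names must be unique")

    @property
    def row_keys(self) -> list[str]:
        return list(self.frame.index)

    @property
    def column_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def select_rows(self, keys: Sequence[str]) -> "FeatureMatrix":
        return replace(self, frame=self.frame.loc[list(keys)])


def _mol_from(structure: QsarStructure | str) -> Chem.Mol | None:
    smi = structure.canonical_smiles if isinstance(structure, QsarStructure) else structure
    if smi is None:
        return None
    return Chem.MolFromSmiles(smi)


_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
_rdkit_gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048)
_ap_gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=1024)
_SUBSTRUCT_MOLS = {name: Chem.MolFromSmarts(s) for name, s in SUBSTRUCTURE_SMARTS.items()}


def _featurize_one(mol: Chem.Mol, families: Sequence[str]) -> dict[str, float]:
    out: dict[str, float] = {}
    for fam in families:
        if fam == "continuous":
            for name, val in Descriptors.CalcMolDescriptors(mol).items():
                out[f"rd_{name}"] = float(val) if val is not None else np.nan
        elif fam == "maccs":
            bits = MACCSkeys.GenMACCSKeys(mol)
            for i in range(1, 167):  # bit 0 is unused padding
                out[f"maccs_{i}"] = float(bits.GetBit(i))
        elif fam == "morgan":
            fp = _morgan_gen.GetFingerprint(mol)
            on = set(fp.GetOnBits())
            for i in range(1024):
                out[f"morgan_{i}"] = float(i in on)
        elif fam == "topological":
            fp = _rdkit_gen.GetFingerprint(mol)
            on = set(fp.GetOnBits())
            for i in range(2048):
                out[f"topo_{i}"] = float(i in on)
        elif fam == "atom_pairs":
            fp = _ap_gen.GetCountFingerprint(mol)
            nz = fp.GetNonzeroElements()
            for i in range(1024):
                out[f"ap_{i}"] = float(nz.get(i, 0))
        elif fam == "substructure_counts":
            for name, patt in _SUBSTRUCT_MOLS.items():
                out[f"frag_{name}"] = float(len(mol.GetSubstructMatches(patt)))
        else:
            raise ValueError(f"unknown feature family: {fam!r}")
    return out


def compute_features(
    structures: Iterable[QsarStructure | str],
    families: Sequence[str] = ("continuous",),
    keys: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Compute the requested feature families for standardized structures.

    One row per structure; columns are family-prefixed.  Columns with any
    missing value are dropped; structures that fail featurization are
    excluded and recorded in ``failed_keys``.
    """
    families = list(families)
    for fam in families:
        if fam not in FAMILIES:
            raise ValueError(f"unknown feature family: {fam!r}; choose from {FAMILIES}")
    rows: list[dict[str, float]] = []
    row_keys: list[str] = []
    failed: list[str] = []
    structures = list(structures)
    if keys is None:
        keys = [
            s.structure_key if isinstance(s, QsarStructure) else s for s in structures
        ]
    for key, structure in zip(keys, structures):
        mol = _mol_from(structure)
        if mol is None:
            failed.append(key)
            logger.warning("featurization failed for %s", key)
            continue
        try:
            rows.append(_featurize_one(mol, families))
            row_keys.append(key)
        except Exception:  # noqa: BLE001
            failed.append(key)
            logger.warning("featurization failed for %s", key)

    frame = pd.DataFrame(rows, index=row_keys)
    n_before = frame.shape[1]
    frame = frame.dropna(axis=1, how="any")
    frame = frame.replace([np.inf, -np.inf], np.nan).dropna(axis=1, how="any")
    if frame.shape[1] < n_before:
        logger.info("dropped %d columns with missing values", n_before - frame.shape[1])

    fams = set(families)
    if fams <= {"continuous"}:
        kind = "continuous"
    elif fams <= set(BINARY_FAMILIES):
        kind = "binary"
    elif fams <= set(COUNT_FAMILIES):
        kind = "count"
    else:
        kind = "mixed"
    return FeatureMatrix(frame=frame, kind=kind, reduction="D0", failed_keys=failed)


# --------------------------------------------------------------------------
# reduction ladder
# --------------------------------------------------------------------------

def _drop_constant(frame: pd.DataFrame) -> pd.DataFrame:
    keep = frame.columns[frame.nunique(axis=0) > 1]
    return frame[keep]


def _drop_correlated(frame: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Greedy pair scan in column order: of a correlated pair, the
    later column is dropped (the earlier survivor is kept)."""
    corr = np.corrcoef(frame.to_numpy(dtype=float), rowvar=False)
    corr = np.atleast_2d(corr)
    n = corr.shape[0]
    dropped = np.zeros(n, dtype=bool)
    for i in range(n):
        if dropped[i]:
            continue
        for j in range(i + 1, n):
            if dropped[j]:
                continue
            if abs(corr[i, j]) >= threshold:
                dropped[j] = True
    return frame[frame.columns[~dropped]]


def _drop_low_variance(frame: pd.DataFrame, threshold: float) -> pd.DataFrame:
    variances = frame.to_numpy(dtype=float).var(axis=0, ddof=0)
    return frame[frame.columns[variances >= threshold]]


def reduce_features(
    fm: FeatureMatrix,
    level: str,
    corr_threshold: float = 0.95,
    var_threshold: float = 0.01,
) -> FeatureMatrix:
    """Apply the D1/D2/D3 reduction ladder.

    D1 drops constant columns; D2 = D1 then drops one of each column
    pair with |Pearson r| >= ``corr_threshold``; D3 = D2 then drops
    columns with population variance < ``var_threshold``.  Row order is
    preserved.  Raises ValueError if no column survives.
    """
    if level not in ("D1", "D2", "D3"):
        raise ValueError(f"reduction level must be D1, D2 or D3, got {level!r}")
    if fm.frame.shape[1] == 0:
        raise ValueError("feature matrix has no columns")
    frame = _drop_constant(fm.frame)
    if level in ("D2", "D3") and frame.shape[1] > 0:
        frame = _drop_correlated(frame, corr_threshold)
    if level == "D3" and frame.shape[1] > 0:
        frame = _drop_low_variance(frame, var_threshold)
    if frame.shape[1] == 0:
        raise ValueError("all columns removed by reduction")
    return replace(fm, frame=frame, reduction=level)


# --------------------------------------------------------------------------
# scaling
# --------------------------------------------------------------------------

@dataclass
class ScalingSpec:
    """Per-column min/max fit on training rows; maps them into [-1, 1]."""

    mins: pd.Series
    maxs: pd.Series

    @property
    def columns(self) -> list[str]:
        return list(self.mins.index)


def fit_scaling(fm_train: FeatureMatrix, columns: Sequence[str] | None = None) -> ScalingSpec:
    """Fit min-max statistics on the training rows only."""
    frame = fm_train.frame if columns is None else fm_train.frame[list(columns)]
    return ScalingSpec(mins=frame.min(axis=0), maxs=frame.max(axis=0))


def apply_scaling(fm: FeatureMatrix, spec: ScalingSpec) -> FeatureMatrix:
    """Rescale the spec's columns into [-1, 1] (training range).

    Zero-range columns map to 0.  Rows outside the training range map
    outside [-1, 1]; that is intentional (test-set extrapolation stays
    visible).
    """
    frame = fm.frame.copy()
    span = (spec.maxs - spec.mins).replace(0.0, np.nan)
    cols = spec.columns
    scaled = 2.0 * (frame[cols] - spec.mins) / span - 1.0
    frame[cols] = scaled.fillna(0.0)
    return replace(fm, frame=frame)


def invert_scaling(fm: FeatureMatrix, spec: ScalingSpec) -> FeatureMatrix:
    """Undo :func:`apply_scaling` (zero-range columns recover the min)."""
    frame = fm.frame.copy()
    span = spec.maxs - spec.mins
    cols = spec.columns
    frame[cols] = (frame[cols] + 1.0) / 2.0 * span + spec.mins
    return replace(fm, frame=frame)
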