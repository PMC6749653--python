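"""Synthetic pKa record sets with the statistical structure of real
experimental compilations.

Structures are built from a small template library (carboxylic acids,
phenols, amines, N-heteroaromatics, amphoterics such as amino acids)
decorated with ring substituents or growing alkyl chains.  Each
template carries a documented base pKa per ionization class and each
decoration a signed shift, so every generated structure has a
deterministic "oracle" pKa; observed values add Gaussian noise.
Replicate groups, salt forms, mixtures and inorganic species are
injected at configurable rates so the standardization, deduplication
and option-building paths are all exercised.  The oracle is
deliberately simple — it makes the regression signal learnable for
recovery tests, it is not a chemically accurate estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from rdkit import Chem

from .curation import ChemicalRecord

__all__ = ["FixtureSpec", "Fixture", "TEMPLATES", "DECORATIONS", "oracle_pka", "generate_fixture"]


@dataclass(frozen=True)
class Template:
    name: str
    smiles: str  # with one {R} substitution point
    acidic_pka: float | None = None
    basic_pka: float | None = None

    @property
    def amphoteric(self) -> bool:
        return self.acidic_pka is not None and self.basic_pka is not None


# Base values are rounded literature-style anchors; shifts below are
# stylized electronic effects (EWG lowers both acidic and basic pKa).
TEMPLATES: dict[str, Template] = {
    t.name: t
    for t in [
        Template("acetic_acid", "{R}CC(=O)O", acidic_pka=4.8),
        Template("benzoic_acid", "OC(=O)c1ccc({R})cc1", acidic_pka=4.2),
        Template("phenol", "Oc1ccc({R})cc1", acidic_pka=10.0),
        Template("benzenesulfonamide", "NS(=O)(=O)c1ccc({R})cc1", acidic_pka=10.1),
        Template("alkylamine", "{R}CCN", basic_pka=10.6),
        Template("aniline", "Nc1ccc({R})cc1", basic_pka=4.6),
        Template("pyridine", "c1cc({R})ccn1", basic_pka=5.2),
        Template("imidazole", "{R}Cc1cnc[nH]1", basic_pka=7.0),
        Template("piperidine", "{R}CC1CCNCC1", basic_pka=11.1),
        Template("amino_acid", "NC({R})C(=O)O", acidic_pka=2.3, basic_pka=9.6),
        Template("aminophenol", "Nc1ccc(O)c({R})c1", acidic_pka=9.9, basic_pka=5.5),
        Template("anthranilic", "NC(=O)c1ccc({R})cc1O", acidic_pka=8.4, basic_pka=2.1),
    ]
}

#: decoration fragment SMILES -> pKa shift (applied to both classes)
DECORATIONS: dict[str, float] = {
    "": 0.0,
    "C": 0.1,
    "CC": 0.15,
    "CCC": 0.2,
    "C(C)C": 0.2,
    "CO": -0.2,
    "OC": 0.25,
    "F": -0.6,
    "Cl": -0.8,
    "Br": -0.85,
    "C#N": -1.6,
    "[N+](=O)[O-]": -2.0,
    "C(F)(F)F": -1.3,
}

_ALKYL_SHIFT_PER_CARBON = 0.02  # homologous chains: tiny cumulative effect

_SALT_COUNTERIONS = [".[Na+]", ".[K+]", ".Cl", ".O"]
_INORGANIC_SMILES = ["[Na+].[Cl-]", "OS(=O)(=O)O", "N", "O=[N+]([O-])O", "[K+].[Br-]"]


def _variant_smiles(template: Template, decoration: str) -> str:
    return template.smiles.replace("{R}", decoration) if decoration else (
        template.smiles.replace("({R})", "").replace("{R}", "")
    )


def oracle_pka(template_name: str, decoration: str = "", cls: str | None = None) -> dict[str, float] | float:
    """Deterministic ground-truth pKa for a template + decoration.

    Returns a dict {class: value} or, when ``cls`` is given, that single
    value.  Raises KeyError for unknown templates/decorations.
    """
    t = TEMPLATES[template_name]
    if decoration in DECORATIONS:
        shift = DECORATIONS[decoration]
    elif decoration and set(decoration) == {"C"}:
        shift = _ALKYL_SHIFT_PER_CARBON * len(decoration)
    else:
        raise KeyError(f"unknown decoration: {decoration!r}")
    out = {}
    if t.acidic_pka is not None:
        out["acidic"] = float(np.clip(t.acidic_pka + shift, 0.0, 14.0))
    if t.basic_pka is not None:
        out["basic"] = float(np.clip(t.basic_pka + shift, -2.0, 12.0))
    if cls is not None:
        return out[cls]
    return out


@dataclass
class FixtureSpec:
    """Composition of a synthetic record set.

    Fractions apply to the structure count; ``replicate_profile`` maps a
    group size to its frequency; ``sd_profile`` mixes low (<1), mid
    (1–2) and high (>2 pKa units) spread for groups with >= 2 values.
    Defaults emulate a heterogeneous experimental compilation: ~20%
    amphoterics, mostly single measurements, replicate spreads
    dominated by the sub-unit band, and mild assay noise.
    """

    n_structures: int = 200
    pct_amphoteric: float = 0.2
    replicate_profile: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.70, 2: 0.15, 3: 0.10, 5: 0.05}
    )
    sd_profile: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.6, "mid": 0.25, "high": 0.15}
    )
    pct_salts: float = 0.05
    pct_mixtures: float = 0.03
    pct_inorganics: float = 0.02
    noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pct_mixtures + self.pct_inorganics > 1:
            raise ValueError("injection fractions exceed 1")
        if abs(sum(self.replicate_profile.values()) - 1.0) > 1e-6:
            raise ValueError("replicate_profile frequencies must sum to 1")
        if abs(sum(self.sd_profile.values()) - 1.0) > 1e-6:
            raise ValueError("sd_profile frequencies must sum to 1")


_SD_BANDS = {"low": (0.1, 0.9), "mid": (1.2, 1.9), "high": (2.5, 4.0)}


@dataclass
class Fixture:
    records: list[ChemicalRecord]
    truth: "pd.DataFrame"  # smiles, template, decoration, pka_class, true_pka
    spec: FixtureSpec


def _catalog(rng: np.random.Generator, n: int, amphoteric: bool) -> list[tuple[Template, str]]:
    """Enumerate n distinct (template, decoration) variants with valid SMILES."""
    pool = [t for t in TEMPLATES.values() if t.amphoteric == amphoteric]
    variants: list[tuple[Template, str]] = []
    seen: set[str] = set()
    decorations = list(DECORATIONS)
    chain_len = 4
    while len(variants) < n:
        # decoration-major order keeps template classes balanced at any n
        for d in decorations:
            for t in pool:
                smi = _variant_smiles(t, d)
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    continue
                key = Chem.MolToSmiles(mol)
                if key in seen:
                    continue
                seen.add(key)
                variants.append((t, d))
                if len(variants) >= n:
                    return variants
        # extend with longer homologous chains until we have enough
        decorations = ["C" * chain_len]
        chain_len += 1
        if chain_len > 60:
            raise ValueError(f"cannot enumerate {n} distinct variants")
    return variants


def _spread_values(rng: np.random.Generator, true: float, size: int, band: str) -> list[float]:
    """Replicate values whose sample SD is forced into the band."""
    target_sd = rng.uniform(*_SD_BANDS[band])
    z = rng.normal(size=size)
    z = z - z.mean()
    sd = z.std(ddof=1)
    if sd == 0:  # degenerate draw; use a deterministic pattern
        z = np.linspace(-1, 1, size)
        z = z - z.mean()
        sd = z.std(ddof=1)
    return list(true + z / sd * target_sd)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a deterministic record list per the spec.

    Amphoteric count is exact (round(pct × n)); salts are re-writings of
    existing records (parent survives standardization); mixtures and
    inorganics are extra records that standardization must reject.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    n_amph = int(round(spec.pct_amphoteric * spec.n_structures))
    n_mono = spec.n_structures - n_amph
    variants = _catalog(rng, n_mono, amphoteric=False) + _catalog(rng, n_amph, amphoteric=True)

    sizes = np.array(sorted(spec.replicate_profile))
    size_p = np.array([spec.replicate_profile[s] for s in sizes], dtype=float)
    bands = list(spec.sd_profile)
    band_p = np.array([spec.sd_profile[b] for b in bands], dtype=float)

    records: list[ChemicalRecord] = []
    truth_rows = []
    for t, d in variants:
        smi = _variant_smiles(t, d)
        truths = oracle_pka(t.name, d)
        group_size = int(rng.choice(sizes, p=size_p))
        for cls, true in truths.items():
            truth_rows.append((smi, t.name, d, cls, true))
            if group_size == 1:
                vals = [true + rng.normal(0.0, spec.noise_sd)]
            else:
                band = str(rng.choice(bands, p=band_p))
                vals = _spread_values(rng, true, group_size, band)
            for v in vals:
                records.append(ChemicalRecord(smi, float(v), cls))

    # salt re-writings: duplicate some records with a counterion attached
    n_salts = int(round(spec.pct_salts * len(records)))
    for i in rng.choice(len(records), size=n_salts, replace=False):
        r = records[int(i)]
        ion = _SALT_COUNTERIONS[int(rng.integers(len(_SALT_COUNTERIONS)))]
        records.append(ChemicalRecord(r.smiles_raw + ion, r.pka_value, r.pka_class))

    # mixtures: two distinct organic parents joined by '.'; avoid parents
    # on the curation salt/solvent strip list (they would be stripped,
    # not rejected)
    from .curation import _SALT_SET  # noqa: PLC0415

    def _is_salt(smi: str) -> bool:
        m = Chem.MolFromSmiles(smi)
        return m is not None and Chem.MolToSmiles(m) in _SALT_SET

    mixable = [v for v in variants if not _is_salt(_variant_smiles(*v))]
    n_mix = int(round(spec.pct_mixtures * spec.n_structures))
    for _ in range(n_mix):
        i, j = rng.choice(len(mixable), size=2, replace=False)
        smi = _variant_smiles(*mixable[int(i)]) + "." + _variant_smiles(*mixable[int(j)])
        records.append(ChemicalRecord(smi, float(rng.uniform(2, 10)), "acidic"))

    # inorganics: carbon-free species
    n_inorg = int(round(spec.pct_inorganics * spec.n_structures))
    for _ in range(n_inorg):
        smi = _INORGANIC_SMILES[int(rng.integers(len(_INORGANIC_SMILES)))]
        records.append(ChemicalRecord(smi, float(rng.uniform(0, 12)), "basic"))

    truth = pd.DataFrame(
        truth_rows, columns=["smiles", "template", "decoration", "pka_class", "true_pka"]
    )
    return Fixture(records=records, truth=truth, spec=spec)
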