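"""Structure standardization, replicate grouping, option rules, splits."""

import numpy as np
import pytest

from pkaqsar.curation import (
    ChemicalRecord,
    build_option_dataset,
    group_replicates,
    split_train_test,
    standardize,
    _option_value,
)


class TestStandardize:
    def test_counterion_stripped_to_parent_acid(self):
        qs = standardize("CC(=O)[O-].[Na+]")
        assert not qs.rejected
        assert qs.structure_key == standardize("CC(=O)O").structure_key

    def test_benzene_is_identity(self):
        qs = standardize("c1ccccc1")
        assert qs.canonical_smiles == "c1ccccc1"

    @pytest.mark.parametrize(
        "smiles,reason",
        [
            ("[Na+].[Cl-]", "inorganic"),
            ("OS(=O)(=O)O", "inorganic"),
            ("c1ccccc1O.NCCc1ccccc1", "mixture"),
        ],
    )
    def test_rejections(self, smiles, reason):
        qs = standardize(smiles)
        assert qs.rejected and qs.rejection_reason == reason
        assert qs.canonical_smiles is None

    def test_unparsable_raises(self):
        with pytest.raises(ValueError):
            standardize("not-a-smiles((")

    def test_keto_enol_tautomers_share_key(self):
        assert standardize("CC(O)=C").structure_key == standardize("CC(=O)C").structure_key

    def test_nitro_mesomers_share_key(self):
        assert (
            standardize("O=[N+]([O-])c1ccccc1").structure_key
            == standardize("O=N(=O)c1ccccc1").structure_key
        )

    def test_zwitterion_not_neutralized(self):
        qs = standardize("C(C(=O)[O-])[NH3+]")
        assert "+" in qs.canonical_smiles and "-" in qs.canonical_smiles

    @pytest.mark.parametrize(
        "smiles",
        ["CC(=O)O", "c1ccncc1", "Oc1ccc(Cl)cc1", "NC(CO)C(=O)O", "CC(=O)[O-].[Na+]"],
    )
    def test_idempotent(self, smiles):
        once = standardize(smiles)
        again = standardize(once.canonical_smiles)
        assert once.structure_key == again.structure_key


class TestReplicates:
    def test_sample_sd(self):
        recs = [
            ChemicalRecord("CC(=O)O", 4.0, "acidic"),
            ChemicalRecord("CC(=O)O", 4.2, "acidic"),
        ]
        (g,) = group_replicates(recs, ["k", "k"])
        assert g.acidic_sd == pytest.approx(0.1414, abs=1e-3)
        assert g.basic_sd is None

    def test_amphoteric_definition(self):
        recs = [
            ChemicalRecord("x", 4.0, "acidic"),
            ChemicalRecord("x", 9.0, "basic"),
        ]
        (g,) = group_replicates(recs, ["k", "k"])
        assert g.amphoteric

    def test_grouping_is_per_key(self, curated):
        keys = {g.structure_key for g in curated.groups}
        assert len(keys) == len(curated.groups)


class TestOptionRules:
    def test_option3_high_spread_takes_strongest(self):
        assert _option_value([2.0, 6.0], 3, "acidic") == 2.0
        assert _option_value([2.0, 6.0], 3, "basic") == 6.0

    def test_option2_threshold(self):
        # SD just under 2 -> mean; well over -> dropped
        assert _option_value([4.0, 6.0], 2, "acidic") == pytest.approx(5.0)  # SD~1.41
        assert _option_value([1.0, 7.0], 2, "acidic") is None  # SD~4.24

    def test_option_value_brute_force(self, rng):
        """Option 3 resolves to mean iff SD<=1 else strongest, on random groups."""
        for _ in range(200):
            vals = list(rng.uniform(0, 14, size=rng.integers(1, 6)))
            got = _option_value(vals, 3, "acidic")
            if len(vals) == 1 or np.std(vals, ddof=1) <= 1.0:
                assert got == pytest.approx(np.mean(vals))
            else:
                assert got == min(vals)

    def test_option_nesting(self, curated):
        sets = {
            opt: build_option_dataset(curated.groups, opt) for opt in (1, 2, 3)
        }
        for cls in ("acidic", "basic"):
            k1 = set(sets[1][cls].keys)
            k2 = set(sets[2][cls].keys)
            k3 = set(sets[3][cls].keys)
            assert k1 <= k2 <= k3

    def test_combined_excludes_amphoterics(self, curated):
        amph = {g.structure_key for g in curated.groups if g.amphoteric}
        for opt in (1, 2):
            ds = build_option_dataset(curated.groups, opt)
            assert not (set(ds["combined"].keys) & amph)
            assert "combined" not in build_option_dataset(curated.groups, 3)

    def test_unknown_option(self, curated):
        with pytest.raises(ValueError):
            build_option_dataset(curated.groups, 4)


class TestSplit:
    def _dataset(self, n=100, seed=0, bimodal=False):
        rng = np.random.default_rng(seed)
        if bimodal:
            vals = np.concatenate([rng.normal(3, 1, n // 2), rng.normal(10, 1, n - n // 2)])
        else:
            vals = rng.uniform(0, 14, n)
        recs = [ChemicalRecord(f"s{i}", float(v), "acidic") for i, v in enumerate(vals)]
        groups = group_replicates(recs, [f"k{i}" for i in range(n)])
        return build_option_dataset(groups, 1)["acidic"]

    def test_exact_fraction(self):
        ds = split_train_test(self._dataset(100), frac_train=0.75, seed=3)
        counts = list(ds.split.values())
        assert counts.count("train") == 75 and counts.count("test") == 25

    def test_distribution_preserved(self):
        ds = split_train_test(self._dataset(400, bimodal=True), seed=5)
        from scipy.stats import ks_2samp

        train = ds.subset_frame("train")["pka_value"]
        test = ds.subset_frame("test")["pka_value"]
        assert ks_2samp(train, test).statistic < 0.1

    def test_deterministic(self):
        ds = self._dataset(60)
        a = split_train_test(ds, seed=9).split
        b = split_train_test(ds, seed=9).split
        assert a == b

    def test_partition_complete(self, curated):
        ds = build_option_dataset(curated.groups, 2)["acidic"]
        out = split_train_test(ds, seed=1)
        assert set(out.split) == set(ds.keys)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            split_train_test(self._dataset(10), frac_train=1.5)
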