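"""Feature families, the D1/D2/D3 reduction ladder, and scaling."""

import numpy as np
import pandas as pd
import pytest

from pkaqsar.featurize import (
    FeatureMatrix,
    apply_scaling,
    compute_features,
    fit_scaling,
    invert_scaling,
    reduce_features,
)

SMILES = ["CCO", "CC(=O)O", "c1ccncc1", "Oc1ccccc1", "NCCc1ccccc1", "CCCCCC"]


@pytest.fixture(scope="module")
def fm_all():
    return compute_features(
        SMILES, families=("continuous", "maccs", "substructure_counts", "atom_pairs")
    )


def test_row_per_structure_and_prefixes(fm_all):
    assert fm_all.row_keys == SMILES
    prefixes = {c.split("_")[0] for c in fm_all.column_names}
    assert {"rd", "maccs", "frag", "ap"} <= prefixes


def test_binary_columns_are_binary():
    fm = compute_features(SMILES, families=("maccs", "morgan"))
    assert fm.kind == "binary"
    vals = fm.values
    assert np.isin(vals, [0.0, 1.0]).all()


def test_counts_are_nonnegative_integers():
    fm = compute_features(SMILES, families=("substructure_counts",))
    vals = fm.values
    assert (vals >= 0).all() and np.allclose(vals, np.round(vals))


def test_hydroxyl_count_for_ethanol():
    fm = compute_features(["CCO"], families=("substructure_counts",))
    assert fm.frame.loc["CCO", "frag_hydroxyl"] == 1


def test_failed_structures_flagged():
    fm = compute_features(["CCO", None], keys=["ok", "bad"], families=("maccs",))
    assert fm.failed_keys == ["bad"]
    assert fm.row_keys == ["ok"]


def test_deterministic(fm_all):
    again = compute_features(
        SMILES, families=("continuous", "maccs", "substructure_counts", "atom_pairs")
    )
    pd.testing.assert_frame_equal(fm_all.frame, again.frame)


class TestReduction:
    def _fm(self, arr, cols=None):
        cols = cols or [f"c{i}" for i in range(arr.shape[1])]
        return FeatureMatrix(pd.DataFrame(arr, columns=cols))

    def test_constant_column_dropped_at_d1(self):
        fm = self._fm(np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 3.0]]))
        out = reduce_features(fm, "D1")
        assert out.column_names == ["c1"] and out.reduction == "D1"

    def test_identical_columns_one_survives_d2(self):
        x = np.random.default_rng(0).normal(size=10)
        fm = self._fm(np.column_stack([x, x, np.random.default_rng(1).normal(size=10)]))
        out = reduce_features(fm, "D2")
        assert len(out.column_names) == 2 and "c0" in out.column_names

    def test_d2_matches_exhaustive_pair_scan(self, rng):
        X = rng.normal(size=(20, 10))
        X[:, 3] = X[:, 0] * 2 + rng.normal(scale=1e-6, size=20)  # force a pair
        fm = self._fm(X)
        out = reduce_features(fm, "D2", corr_threshold=0.95)
        # independent oracle: greedy scan over all pairs in column order
        corr = np.corrcoef(X, rowvar=False)
        dropped = set()
        for i in range(10):
            if i in dropped:
                continue
            for j in range(i + 1, 10):
                if j not in dropped and abs(corr[i, j]) >= 0.95:
                    dropped.add(j)
        expected = [f"c{i}" for i in range(10) if i not in dropped]
        assert out.column_names == expected

    def test_monotone_ladder(self, rng):
        X = rng.normal(size=(30, 8))
        X[:, 0] = 1.0
        X[:, 5] = X[:, 1]
        X[:, 6] = rng.normal(scale=0.01, size=30)
        fm = self._fm(X)
        cols = {"D0": set(fm.column_names)}
        for level in ("D1", "D2", "D3"):
            cols[level] = set(reduce_features(fm, level, var_threshold=0.01).column_names)
        assert cols["D3"] <= cols["D2"] <= cols["D1"] <= cols["D0"]

    def test_all_removed_errors(self):
        fm = self._fm(np.ones((4, 2)))
        with pytest.raises(ValueError):
            reduce_features(fm, "D1")

    def test_row_order_preserved(self, fm_all):
        out = reduce_features(fm_all, "D2")
        assert out.row_keys == fm_all.row_keys


class TestScaling:
    def test_endpoints(self):
        fm = FeatureMatrix(pd.DataFrame({"a": [0.0, 5.0, 10.0]}))
        spec = fit_scaling(fm)
        out = apply_scaling(fm, spec)
        assert list(out.frame["a"]) == [-1.0, 0.0, 1.0]

    def test_constant_column_maps_to_zero(self):
        fm = FeatureMatrix(pd.DataFrame({"a": [3.0, 3.0, 3.0]}))
        out = apply_scaling(fm, fit_scaling(fm))
        assert (out.frame["a"] == 0.0).all()

    def test_round_trip_identity(self, rng):
        fm = FeatureMatrix(pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde")))
        spec = fit_scaling(fm)
        back = invert_scaling(apply_scaling(fm, spec), spec)
        np.testing.assert_allclose(back.values, fm.values, atol=1e-12)

    def test_test_rows_may_exceed_range(self):
        train = FeatureMatrix(pd.DataFrame({"a": [0.0, 1.0]}))
        test = FeatureMatrix(pd.DataFrame({"a": [2.0]}))
        spec = fit_scaling(train)
        assert apply_scaling(test, spec).frame["a"].iloc[0] == 3.0
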