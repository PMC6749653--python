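"""±2-unit concordance machinery and bootstrap intervals."""

import numpy as np
import pytest

from pkaqsar.benchmark import (
    bootstrap_ci,
    build_benchmark,
    pairwise_concordance,
    prediction_table,
    range_filter,
)


def _tables():
    a = prediction_table(["k1", "k2", "k3"], acidic=[4.0, 4.0, 3.0], source="A")
    b = prediction_table(["k1", "k2", "k4"], acidic=[5.5, 7.0, 3.0], source="B")
    return a, b


class TestConcordance:
    def test_counts_on_toy_tables(self):
        a, b = _tables()
        rep, within = pairwise_concordance(a, b, "acidic")
        assert (rep.n_common, rep.n_within, rep.n_beyond) == (2, 1, 1)
        assert list(within["structure_key"]) == ["k1"]

    def test_identical_tables_fully_concordant(self):
        a, _ = _tables()
        rep, _ = pairwise_concordance(a, a, "acidic")
        assert rep.n_beyond == 0 and rep.rmse == 0.0

    def test_tie_at_threshold_counts_as_concordant(self):
        a = prediction_table(["k"], acidic=[4.0])
        b = prediction_table(["k"], acidic=[6.0])
        rep, _ = pairwise_concordance(a, b, "acidic")
        assert rep.n_within == 1

    def test_counts_symmetric(self):
        a, b = _tables()
        r1, _ = pairwise_concordance(a, b, "acidic")
        r2, _ = pairwise_concordance(b, a, "acidic")
        assert (r1.n_common, r1.n_within) == (r2.n_common, r2.n_within)

    def test_threshold_monotonicity(self, rng):
        keys = [f"k{i}" for i in range(50)]
        a = prediction_table(keys, acidic=rng.uniform(0, 14, 50))
        b = prediction_table(keys, acidic=rng.uniform(0, 14, 50))
        last = -1
        for thr in (0.5, 1.0, 2.0, 4.0, 8.0):
            rep, _ = pairwise_concordance(a, b, "acidic", threshold=thr)
            assert rep.n_within >= last
            last = rep.n_within

    def test_empty_join_errors(self):
        a = prediction_table(["k1"], acidic=[4.0])
        b = prediction_table(["k2"], acidic=[4.0])
        with pytest.raises(ValueError):
            pairwise_concordance(a, b, "acidic")


class TestBenchmarkBuild:
    def test_mean_of_pair(self):
        a = prediction_table(["k"], acidic=[4.0])
        b = prediction_table(["k"], acidic=[6.0])
        bench = build_benchmark(a, b, "acidic")
        assert bench["acidic_pka"].iloc[0] == pytest.approx(5.0)

    def test_identical_inputs_reproduce_input(self):
        a, _ = _tables()
        bench = build_benchmark(a, a, "acidic")
        np.testing.assert_allclose(bench["acidic_pka"], a["acidic_pka"])

    def test_only_concordant_rows_enter(self):
        a, b = _tables()
        bench = build_benchmark(a, b, "acidic")
        assert list(bench["structure_key"]) == ["k1"]


class TestRangeFilter:
    def test_filters_and_is_idempotent(self, rng):
        t = prediction_table([f"k{i}" for i in range(40)], acidic=rng.uniform(-5, 20, 40))
        once = range_filter(t, "acidic", 0.0, 14.0)
        assert ((once["acidic_pka"] >= 0) & (once["acidic_pka"] <= 14)).all()
        twice = range_filter(once, "acidic", 0.0, 14.0)
        assert len(once) == len(twice)

    def test_all_in_range_unchanged(self):
        t = prediction_table(["a", "b"], acidic=[3.0, 7.0])
        assert len(range_filter(t, "acidic", 0, 14)) == 2

    def test_bad_bounds(self):
        t = prediction_table(["a"], acidic=[3.0])
        with pytest.raises(ValueError):
            range_filter(t, "acidic", 5.0, 1.0)


class TestBootstrap:
    def test_perfect_predictions_give_zero_interval(self):
        obs = np.arange(20.0)
        assert bootstrap_ci(obs, obs, "rmse", n_boot=200, seed=0) == (0.0, 0.0)

    def test_deterministic_per_seed(self, rng):
        obs = rng.normal(size=40)
        pred = obs + rng.normal(scale=0.5, size=40)
        ci1 = bootstrap_ci(obs, pred, "r2", n_boot=300, seed=5)
        ci2 = bootstrap_ci(obs, pred, "r2", n_boot=300, seed=5)
        assert ci1 == ci2

    def test_coverage_near_nominal(self):
        """95% interval for RMSE covers the population value ~95% of the
        time over repeated simulations (Monte-Carlo tolerance)."""
        rng = np.random.default_rng(42)
        true_rmse = 1.0
        hits = 0
        n_sim = 120
        for i in range(n_sim):
            obs = rng.normal(5.0, 2.0, size=80)
            pred = obs + rng.normal(0.0, true_rmse, size=80)
            lo, hi = bootstrap_ci(obs, pred, "rmse", n_boot=300, seed=i)
            hits += lo <= true_rmse <= hi
        assert 0.85 <= hits / n_sim <= 0.99

    def test_interval_orders_and_brackets_point_estimate(self, rng):
        obs = rng.normal(size=60)
        pred = obs + rng.normal(scale=0.7, size=60)
        lo, hi = bootstrap_ci(obs, pred, "pearson_r2", n_boot=400, seed=9)
        point = float(np.corrcoef(obs, pred)[0, 1] ** 2)
        assert lo <= point <= hi
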