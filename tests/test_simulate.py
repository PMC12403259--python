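"""Monte Carlo engine: reproducibility, schema, and estimator behavior."""

import numpy as np
import pandas as pd
import pytest

from normcheck.normality import simulate_null_table
from normcheck.simulate import (
    DEFAULT_N_GRID,
    PowerStudyConfig,
    ScenarioSpec,
    SizeStudyConfig,
    TABLE_COLUMNS,
    estimate_rejection_rate,
    export_table,
    read_table,
    run_power_study,
    run_size_study,
    size_within_band,
)
from normcheck.fleishman import scenario_target


def _small_size_config(**kw):
    defaults = dict(tests=("SW", "JB"), n_grid=(20, 50), reps=400, seed=99)
    defaults.update(kw)
    return SizeStudyConfig(**defaults)


class TestEstimator:
    def test_alpha_one_always_rejects(self):
        sc = ScenarioSpec("normal", 30, reps=200, alpha=0.999999)
        est = estimate_rejection_rate("SW", sc, seed=1)
        assert est.proportion == 1.0

    def test_mc_se_definition(self):
        sc = ScenarioSpec("normal", 30, reps=500)
        est = estimate_rejection_rate("LF", sc, seed=2)
        p = est.proportion
        assert est.mc_se == pytest.approx(np.sqrt(p * (1 - p) / 500))

    def test_bit_reproducible(self):
        sc = ScenarioSpec("normal", 25, reps=300)
        a = estimate_rejection_rate("AD", sc, seed=7)
        b = estimate_rejection_rate("AD", sc, seed=7)
        assert a.proportion == b.proportion

    def test_infeasible_target_is_flagged_not_raised(self):
        t = scenario_target(4.0, 3.0)
        sc = ScenarioSpec("fleishman", 50, reps=200, target=t)
        est = estimate_rejection_rate("SW", sc, seed=1)
        assert est.status == "infeasible"
        assert np.isnan(est.proportion)

    def test_unsupported_n_is_flagged(self):
        sc = ScenarioSpec("normal", 15, reps=200)
        est = estimate_rejection_rate("DAP", sc, seed=1)
        assert est.status == "unsupported_n"

    def test_rough_size_sanity(self):
        """A well-calibrated test rejects ~5% of null samples."""
        sc = ScenarioSpec("normal", 100, reps=2000)
        est = estimate_rejection_rate("SW", sc, seed=3)
        assert abs(est.proportion - 0.05) < 4 * np.sqrt(0.05 * 0.95 / 2000)


class TestStudies:
    def test_size_study_grid_shape_and_schema(self):
        table = run_size_study(_small_size_config())
        assert list(table.columns) == TABLE_COLUMNS
        assert len(table) == 2 * 2 * 3  # tests x n grid x null families
        assert set(table["status"]) == {"ok"}

    def test_default_grid_is_the_study_grid(self):
        assert DEFAULT_N_GRID == (20, 30, 40, 50, 80, 100, 200)
        full = SizeStudyConfig()
        assert len(full.tests) * len(full.n_grid) * len(full.families) == 273

    def test_size_study_reproducible(self):
        t1 = run_size_study(_small_size_config())
        t2 = run_size_study(_small_size_config())
        pd.testing.assert_frame_equal(t1, t2)

    def test_power_study_mirrors_negative_skew(self):
        cfg = PowerStudyConfig(
            scenarios=((0.5, 3.0), (-0.5, 3.0)), tests=("JB",),
            n_grid=(30,), reps=300, seed=5,
        )
        table = run_power_study(cfg)
        pos = table[table["skew"] == 0.5].iloc[0]
        neg = table[table["skew"] == -0.5].iloc[0]
        assert neg["proportion"] == pos["proportion"]
        assert neg["status"] == "mirrored"

    def test_power_study_flags_infeasible_cells(self):
        cfg = PowerStudyConfig(
            scenarios=((4.0, 2.0),), tests=("SW", "RJB"), n_grid=(20, 50),
            reps=200, seed=5,
        )
        table = run_power_study(cfg)
        assert set(table["status"]) == {"infeasible"}
        assert table["proportion"].isna().all()

    def test_common_samples_shares_draws(self):
        """With common random numbers, two runs of different test subsets
        see identical draws, so a shared test gets identical estimates."""
        c1 = _small_size_config(tests=("SW", "JB"), common_samples=True)
        c2 = _small_size_config(tests=("SW", "AD"), common_samples=True)
        t1 = run_size_study(c1)
        t2 = run_size_study(c2)
        sw1 = t1[t1["test"] == "SW"]["proportion"].to_numpy()
        sw2 = t2[t2["test"] == "SW"]["proportion"].to_numpy()
        assert np.array_equal(sw1, sw2)


class TestBandAndExport:
    @pytest.mark.parametrize(
        "p,inside", [(0.050, True), (0.045, True), (0.055, True),
                     (0.0551, False), (0.021, False), (0.0647, False)]
    )
    def test_size_band_is_closed_interval(self, p, inside):
        assert size_within_band(p) is inside

    def test_export_round_trip(self, tmp_path):
        cfg = PowerStudyConfig(
            scenarios=((0.5, 3.0), (4.0, 2.0)), tests=("SW",),
            n_grid=(20,), reps=200, seed=5,
        )
        table = run_power_study(cfg)
        path = tmp_path / "table.csv"
        export_table(table, path)
        back = read_table(path)
        pd.testing.assert_frame_equal(back, table.reset_index(drop=True),
                                      check_dtype=False)

    def test_empty_table_round_trip(self, tmp_path):
        empty = run_size_study(_small_size_config(tests=(), n_grid=(20,)))
        path = tmp_path / "empty.csv"
        export_table(empty, path)
        assert list(read_table(path).columns) == TABLE_COLUMNS


class TestNullTable:
    def test_same_seed_identical(self):
        t1 = simulate_null_table("JB", 20, reps=2000, seed=8)
        t2 = simulate_null_table("JB", 20, reps=2000, seed=8)
        assert np.array_equal(t1.stats_sorted, t2.stats_sorted)

    def test_median_statistic_has_half_pvalue(self):
        t = simulate_null_table("LF", 30, reps=2000, seed=9)
        assert t.p_value(t.quantile(0.5)) == pytest.approx(0.5, abs=0.02)

    def test_jb_small_sample_chi2_approximation_is_conservative(self):
        """At n=20 the chi-square threshold 5.99 rejects too rarely: the
        null statistic's true 95th percentile lies well below it, and the
        mass above 5.99 is under 0.03."""
        t = simulate_null_table("JB", 20, reps=5000, seed=10)
        assert t.quantile(0.95) < 5.99
        assert float(np.mean(t.stats_sorted > 5.99)) < 0.03

    def test_calibrated_pvalue_used_by_run_test(self):
        from normcheck import Sample, run_test

        rng = np.random.default_rng(11)
        x = Sample(rng.standard_normal(30))
        nt = simulate_null_table("RJB", 30, reps=2000, seed=12)
        r = run_test("RJB", x, null_table=nt)
        assert 0.0 <= r.p_value <= 1.0
        assert r.p_value != run_test("RJB", x).p_value
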