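"""Defining-formula checks, hand-derived values, and shared test properties."""

import numpy as np
import pytest
from scipy import stats

from normcheck import (
    DegenerateSampleError,
    Sample,
    TEST_IDS,
    UnsupportedSampleSizeError,
    compute_moments,
    run_test,
)
from normcheck.normality import (
    _cvm_batch,
    _gmg_batch,
    _lf_batch,
    _rjb_batch,
    pchi_n_classes,
    sample_size_bounds,
)

TRIPLE = np.array([-1.0, 0.0, 1.0])


class TestHandDerivedStatistics:
    """Small-sample values evaluated by hand from the defining formulas."""

    def test_lilliefors_triple(self):
        # D+ = D- = 1/3 - Phi(-1) for this symmetric configuration
        d = _lf_batch(TRIPLE[None, :])[0][0]
        assert d == pytest.approx(1.0 / 3.0 - stats.norm.cdf(-1.0), abs=1e-9)

    def test_cvm_triple(self):
        # W = 1/36 + (Phi(-1) - 1/6)^2 + 0 + (Phi(1) - 5/6)^2; Z = W * 7/6
        w = 1.0 / 36.0 + (stats.norm.cdf(-1) - 1 / 6) ** 2 + (stats.norm.cdf(1) - 5 / 6) ** 2
        z = _cvm_batch(TRIPLE[None, :])[0][0]
        assert z == pytest.approx(w * (1 + 0.5 / 3), abs=1e-9)
        assert z == pytest.approx(0.032556, abs=5e-6)

    def test_cvm_lower_bound(self):
        rng = np.random.default_rng(0)
        for n in (4, 10, 50):
            z, _ = _cvm_batch(rng.standard_normal((20, n)))
            assert np.all(z >= (1.0 / (12 * n)) * (1 + 0.5 / n) - 1e-15)

    def test_jb_triple(self):
        r = run_test("JB", Sample(TRIPLE))
        assert r.statistic == pytest.approx(0.28125)
        assert r.p_value == pytest.approx(np.exp(-0.140625), rel=1e-10)

    def test_ajb_hand_quadruple(self):
        """{-1,0,1,2} with the exact n=4 constants assembled by hand."""
        m = compute_moments(Sample([-1.0, 0.0, 1.0, 2.0]))
        expected = m.skewness**2 / (12.0 / 35.0) + (m.kurtosis - 1.8) ** 2 / (192.0 / 1575.0)
        r = run_test("AJB", Sample([-1.0, 0.0, 1.0, 2.0]))
        assert r.statistic == pytest.approx(expected, rel=1e-12)
        assert r.p_value == pytest.approx(np.exp(-expected / 2.0), rel=1e-10)

    def test_gmg_triple_ratio(self):
        r, _ = _gmg_batch(TRIPLE[None, :])
        expected = np.sqrt(2.0 / 3.0) / (np.sqrt(np.pi / 2.0) * 2.0 / 3.0)
        assert r[0] == pytest.approx(expected, rel=1e-12)
        assert r[0] == pytest.approx(0.97721, abs=5e-6)

    def test_rjb_triple(self):
        jn = np.sqrt(np.pi / 2.0) * 2.0 / 3.0
        expected = (3.0 / 64.0) * ((2.0 / 3.0) / jn**4 - 3.0) ** 2
        r, _ = _rjb_batch(TRIPLE[None, :])
        assert r[0] == pytest.approx(expected, rel=1e-12)
        assert r[0] == pytest.approx(0.1248, abs=2e-4)

    def test_das_symmetric_sample_is_null(self):
        r = run_test("DAS", Sample(np.arange(1.0, 13.0)))
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_dap_is_sum_of_squared_transforms(self):
        rng = np.random.default_rng(3)
        x = Sample(rng.gamma(2.0, 1.0, 40))
        zs = run_test("DAS", x).statistic
        zk = run_test("DAK", x).statistic
        assert run_test("DAP", x).statistic == pytest.approx(zs**2 + zk**2, rel=1e-12)

    def test_sf_perfect_on_its_own_scores(self):
        """Data exactly linear in the Blom scores has squared correlation 1."""
        from normcheck.scores import blom_scores

        x = Sample(5.0 + 2.0 * blom_scores(30))
        r = run_test("SF", x)
        assert r.statistic == pytest.approx(1.0, abs=1e-12)

    def test_pchi_class_rule_and_conservation(self):
        assert pchi_n_classes(100) == 13
        rng = np.random.default_rng(4)
        from normcheck.normality import _pchi_batch

        x = rng.standard_normal((5, 40))
        k = pchi_n_classes(40)
        mean = x.mean(axis=1, keepdims=True)
        s = x.std(axis=1, ddof=1, keepdims=True)
        u = stats.norm.cdf((x - mean) / s)
        cls = np.clip(np.floor(k * u).astype(int), 0, k - 1)
        counts = np.array([np.bincount(c, minlength=k) for c in cls])
        assert np.all(counts.sum(axis=1) == 40)
        stat, _ = _pchi_batch(x)
        exp = 40.0 / k
        assert stat == pytest.approx(((counts - exp) ** 2 / exp).sum(axis=1))


class TestSharedProperties:
    @pytest.mark.parametrize("test_id", TEST_IDS)
    def test_affine_invariance(self, test_id):
        """Statistic and p-value are unchanged under x -> a + b x, b > 0."""
        rng = np.random.default_rng(11)
        x = rng.gamma(3.0, 2.0, 60)
        r1 = run_test(test_id, Sample(x))
        r2 = run_test(test_id, Sample(3.0 * x + 7.0))
        assert r2.statistic == pytest.approx(r1.statistic, rel=1e-10, abs=1e-10)
        assert r2.p_value == pytest.approx(r1.p_value, rel=1e-10, abs=1e-10)

    @pytest.mark.parametrize("test_id", TEST_IDS)
    def test_pvalue_range_and_decision_rule(self, test_id):
        rng = np.random.default_rng(12)
        for alpha in (0.01, 0.05, 0.5, 0.999):
            x = Sample(rng.standard_normal(50))
            r = run_test(test_id, x, alpha=alpha)
            assert 0.0 <= r.p_value <= 1.0
            assert r.reject == (r.p_value < alpha)

    @pytest.mark.parametrize("test_id", TEST_IDS)
    def test_degenerate_sample_rejected(self, test_id):
        with pytest.raises(DegenerateSampleError):
            run_test(test_id, Sample(np.full(30, 2.5)))

    @pytest.mark.parametrize(
        "test_id,bad_n",
        [("SW", 5001), ("SF", 4), ("LF", 3), ("CVM", 3), ("AD", 6),
         ("AJB", 3), ("DAS", 8), ("DAK", 4), ("DAP", 19), ("GMG", 9),
         ("RJB", 3), ("PCHI", 19)],
    )
    def test_unsupported_sizes(self, test_id, bad_n):
        rng = np.random.default_rng(bad_n)
        if bad_n > 5000:
            values = rng.standard_normal(bad_n)
        else:
            values = rng.standard_normal(max(bad_n, 3))
        with pytest.raises(UnsupportedSampleSizeError):
            run_test(test_id, Sample(values))

    def test_statistic_ranges(self):
        rng = np.random.default_rng(13)
        x = Sample(rng.standard_normal(80))
        assert 0.0 < run_test("SW", x).statistic <= 1.0
        assert 0.0 < run_test("SF", x).statistic <= 1.0
        assert 0.0 <= run_test("LF", x).statistic < 1.0
        assert run_test("CVM", x).statistic > 0.0
        assert np.isfinite(run_test("AD", x).statistic)
        for tid in ("JB", "AJB", "RJB", "DAP", "PCHI"):
            assert run_test(tid, x).statistic >= 0.0
        assert run_test("GMG", x).statistic > 0.0

    def test_gmg_tolerates_ties_at_the_median(self):
        """J_n stays positive unless every value equals the median, so a
        heavily tied sample still yields a finite result."""
        x = Sample(np.r_[np.zeros(8), 1.0, 2.0, 3.0])
        r = run_test("GMG", x)
        assert np.isfinite(r.statistic) and 0.0 <= r.p_value <= 1.0

    def test_gmg_normal_method_is_two_sided(self):
        from normcheck import gmg_test

        rng = np.random.default_rng(14)
        x = Sample(rng.standard_normal(40))
        r_t = gmg_test(x)
        r_n = gmg_test(x, method="normal")
        assert r_t.statistic == pytest.approx(r_n.statistic)
        assert r_t.p_value != r_n.p_value

    def test_sample_size_bounds_exposed(self):
        assert sample_size_bounds("SW") == (3, 5000)
        assert sample_size_bounds("DAP")[0] == 20
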