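"""Thirteen classical normality tests, computed from their defining formulas.

The tests fall into four families:

* regression/correlation: Shapiro–Wilk (SW), Shapiro–Francia (SF);
* empirical distribution function: Lilliefors (LF), Cramér–von Mises (CVM),
  Anderson–Darling (AD);
* moments: Jarque–Bera (JB), adjusted Jarque–Bera (AJB), D'Agostino skewness
  (DAS), D'Agostino kurtosis (DAK), D'Agostino–Pearson omnibus (DAP),
  Gel–Miao–Gastwirth (GMG), robust Jarque–Bera (RJB);
* chi-square: Pearson chi-square with equiprobable classes (PCHI).

Every statistic is location–scale invariant, so its null distribution
depends only on n; :func:`simulate_null_table` exploits this to provide
simulated critical values and empirical p-values as an alternative to the
analytic approximations.

Each test has two surfaces: a scalar API consuming a :class:`Sample` and
returning a :class:`TestResult`, and an internal batch kernel operating on
a (replications x n) matrix — the workhorse of the Monte Carlo engine.
Batch kernels compute wherever the formulas are defined; the scalar
wrappers enforce the documented sample-size domains.

p-value conventions
-------------------
SW and SF use Royston's normalizing transformations. LF uses the
Dallal–Wilcoxon analytic approximation, CVM and AD the piecewise tail
formulas for their modified statistics (the conventions of the R ``nortest``
family of implementations). JB, AJB, DAP, RJB and PCHI are upper-tailed
chi-square; DAS and DAK are two-sided normal; GMG, a test directed against
heavy tails, is upper-tailed with a Student-t finite-sample approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sample import (
    DegenerateSampleError,
    Sample,
    UnsupportedSampleSizeError,
    compute_moments,
)
from .scores import SW_MAX_N, blom_scores, sw_weights

__all__ = [
    "TEST_IDS",
    "TestResult",
    "run_test",
    "batch_test",
    "sample_size_bounds",
    "simulate_null_table",
    "NullTable",
    "sw_test",
    "sf_test",
    "lilliefors_test",
    "cvm_test",
    "ad_test",
    "jb_test",
    "ajb_test",
    "das_test",
    "dak_test",
    "dap_test",
    "gmg_test",
    "rjb_test",
    "pchi_test",
]

TEST_IDS = (
    "SW", "SF", "LF", "CVM", "AD",
    "JB", "AJB", "DAS", "DAK", "DAP", "GMG", "RJB",
    "PCHI",
)

# p_(i) is clamped away from {0, 1} before logarithms (AD).
_P_EPS = 1e-12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single normality test at nominal level ``alpha``."""

    test_id: str
    statistic: float
    p_value: float
    alpha: float
    reject: bool
    n: int


# ---------------------------------------------------------------------------
# shared batch helpers (x2d: shape (m, n), one sample per row)
# ---------------------------------------------------------------------------

def _plotting_positions_2d(xs: np.ndarray) -> np.ndarray:
    """Fitted-normal CDF at each sorted observation, row-wise (unbiased SD)."""
    mean = xs.mean(axis=1, keepdims=True)
    s = xs.std(axis=1, ddof=1, keepdims=True)
    return stats.norm.cdf((xs - mean) / s)


def _central_moments_2d(x2d: np.ndarray):
    xc = x2d - x2d.mean(axis=1, keepdims=True)
    m2 = np.mean(xc**2, axis=1)
    m3 = np.mean(xc**3, axis=1)
    m4 = np.mean(xc**4, axis=1)
    return m2, m3, m4


def _skew_kurt_2d(x2d: np.ndarray):
    m2, m3, m4 = _central_moments_2d(x2d)
    return m3 / m2**1.5, m4 / m2**2


# ---------------------------------------------------------------------------
# Shapiro–Wilk
# ---------------------------------------------------------------------------

def _sw_pvalue(w: np.ndarray, n: int) -> np.ndarray:
    """Royston's normalizing transformation of the W statistic."""
    w = np.asarray(w, dtype=float)
    if n == 3:
        # exact for n = 3
        p = (6.0 / np.pi) * (np.arcsin(np.sqrt(w)) - np.arcsin(np.sqrt(0.75)))
        return np.clip(p, 0.0, 1.0)
    if n <= 11:
        gamma = -2.273 + 0.459 * n
        mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
        sigma = math.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
        z = (-np.log(gamma - np.log1p(-w)) - mu) / sigma
    else:
        ln = math.log(n)
        mu = -1.5861 - 0.31082 * ln - 0.083751 * ln**2 + 0.0038915 * ln**3
        sigma = math.exp(-0.4803 - 0.082676 * ln + 0.0030302 * ln**2)
        z = (np.log1p(-w) - mu) / sigma
    return stats.norm.sf(z)


def _sw_batch(x2d: np.ndarray):
    n = x2d.shape[1]
    xs = np.sort(x2d, axis=1)
    a = sw_weights(n)
    num = (xs @ a) ** 2
    den = np.sum((xs - xs.mean(axis=1, keepdims=True)) ** 2, axis=1)
    w = np.minimum(num / den, 1.0)
    return w, _sw_pvalue(w, n)


# ---------------------------------------------------------------------------
# Shapiro–Francia
# ---------------------------------------------------------------------------

def _sf_batch(x2d: np.ndarray):
    n = x2d.shape[1]
    xs = np.sort(x2d, axis=1)
    m = blom_scores(n)  # zero-mean by antisymmetry
    xc = xs - xs.mean(axis=1, keepdims=True)
    num = (xc @ m) ** 2
    den = np.sum(xc**2, axis=1) * float(m @ m)
    w = np.minimum(num / den, 1.0)  # squared correlation with the scores
    u = math.log(n)
    v = math.log(u)
    mu = -1.2725 + 1.0521 * (v - u)
    sigma = 1.0308 - 0.26758 * (v + 2.0 / u)
    with np.errstate(divide="ignore"):
        z = (np.log1p(-w) - mu) / sigma
    return w, stats.norm.sf(z)


# ---------------------------------------------------------------------------
# Lilliefors
# ---------------------------------------------------------------------------

def _lf_pvalue(d: np.ndarray, n: int) -> np.ndarray:
    """Dallal–Wilcoxon approximation, with the Stephens form when p > 0.1."""
    d = np.asarray(d, dtype=float)
    if n > 100:
        kd = d * (n / 100.0) ** 0.49
        nd = 100.0
    else:
        kd = d
        nd = float(n)
    p = np.exp(
        -7.01256 * kd**2 * (nd + 2.78019)
        + 2.99587 * kd * np.sqrt(nd + 2.78019)
        - 0.122119
        + 0.974598 / np.sqrt(nd)
        + 1.67997 / nd
    )
    big = p > 0.1
    if np.any(big):
        kk = (math.sqrt(n) - 0.01 + 0.85 / math.sqrt(n)) * d
        st = np.select(
            [kk <= 0.302, kk <= 0.5, kk <= 0.9, kk <= 1.31],
            [
                np.ones_like(kk),
                2.76773 - 19.828315 * kk + 80.709644 * kk**2
                - 138.55152 * kk**3 + 81.218052 * kk**4,
                -4.901232 + 40.662806 * kk - 97.490286 * kk**2
                + 94.029866 * kk**3 - 32.355711 * kk**4,
                6.198765 - 19.558097 * kk + 23.186922 * kk**2
                - 12.234627 * kk**3 + 2.423045 * kk**4,
            ],
            default=0.0,
        )
        p = np.where(big, st, p)
    return np.clip(p, 0.0, 1.0)


def _lf_batch(x2d: np.ndarray):
    n = x2d.shape[1]
    xs = np.sort(x2d, axis=1)
    p = _plotting_positions_2d(xs)
    i = np.arange(1, n + 1)
    dplus = np.max(i / n - p, axis=1)
    dminus = np.max(p - (i - 1) / n, axis=1)
    d = np.maximum(dplus, dminus)
    return d, _lf_pvalue(d, n)


# ---------------------------------------------------------------------------
# Cramér–von Mises
# ---------------------------------------------------------------------------

def _cvm_pvalue(z: np.ndarray) -> np.ndarray:
    """Piecewise tail formulas for the modified statistic Z = W (1 + 0.5/n)."""
    z = np.asarray(z, dtype=float)
    p = np.select(
        [z < 0.0275, z < 0.051, z < 0.092, z < 1.1],
        [
            1.0 - np.exp(-13.953 + 775.5 * z - 12542.61 * z**2),
            1.0 - np.exp(-5.903 + 179.546 * z - 1515.29 * z**2),
            np.exp(0.886 - 31.62 * z + 10.897 * z**2),
            np.exp(1.111 - 34.242 * z + 12.832 * z**2),
        ],
        default=7.37e-10,
    )
    return np.clip(p, 0.0, 1.0)


def _cvm_batch(x2d: np.ndarray):
    n = x2d.shape[1]
    xs = np.sort(x2d, axis=1)
    p = _plotting_positions_2d(xs)
    i = np.arange(1, n + 1)
    w = 1.0 / (12.0 * n) + np.sum((p - (2.0 * i - 1.0) / (2.0 * n)) ** 2, axis=1)
    z = w * (1.0 + 0.5 / n)
    return z, _cvm_pvalue(z)


# ---------------------------------------------------------------------------
# Anderson–Darling
# ---------------------------------------------------------------------------

def _ad_pvalue(astar: np.ndarray) -> np.ndarray:
    """Piecewise p-value for the small-sample-modified statistic A*."""
    a = np.asarray(astar, dtype=float)
    p = np.select(
        [a < 0.2, a < 0.34, a < 0.6, a < 10.0],
        [
            1.0 - np.exp(-13.436 + 101.14 * a - 223.73 * a**2),
            1.0 - np.exp(-8.318 + 42.796 * a - 59.938 * a**2),
            np.exp(0.9177 - 4.279 * a - 1.38 * a**2),
            np.exp(1.2937 - 5.709 * a + 0.0186 * a**2),
        ],
        default=3.7e-24,
    )
    return np.clip(p, 0.0, 1.0)


def _ad_batch(x2d: np.ndarray):
    n = x2d.shape[1]
    xs = np.sort(x2d, axis=1)
    p = np.clip(_plotting_positions_2d(xs), _P_EPS, 1.0 - _P_EPS)
    i = np.arange(1, n + 1)
    terms = (2.0 * i - 1.0) * (np.log(p) + np.log1p(-p[:, ::-1]))
    ad = -n - np.sum(terms, axis=1) / n
    astar = ad * (1.0 + 0.75 / n + 2.25 / n**2)
    return ad, _ad_pvalue(astar)


# ---------------------------------------------------------------------------
# Jarque–Bera and adjusted Jarque–Bera
# ---------------------------------------------------------------------------

def _jb_batch(x2d: np.ndarray):
    n = x2d.shape[1]
    b1s, b2 = _skew_kurt_2d(x2d)
    b = n / 6.0 * b1s**2 + n / 24.0 * (b2 - 3.0) ** 2
    return b, stats.chi2.sf(b, 2)


def _ajb_batch(x2d: np.ndarray):
    n = x2d.shape[1]
    b1s, b2 = _skew_kurt_2d(x2d)
    var_b1 = 6.0 * (n - 2) / ((n + 1) * (n + 3))
    e_b2 = 3.0 * (n - 1) / (n + 1)
    var_b2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    ajb = b1s**2 / var_b1 + (b2 - e_b2) ** 2 / var_b2
    return ajb, stats.chi2.sf(ajb, 2)


# ---------------------------------------------------------------------------
# D'Agostino transformations
# ---------------------------------------------------------------------------

def _das_z(b1s: np.ndarray, n: int) -> np.ndarray:
    """Normalizing transformation of the sample skewness (valid for n > 8)."""
    y = b1s * math.sqrt((n + 1.0) * (n + 3.0) / (6.0 * (n - 2.0)))
    c = (
        3.0 * (n**2 + 27.0 * n - 70.0) * (n + 1.0) * (n + 3.0)
        / ((n - 2.0) * (n + 5.0) * (n + 7.0) * (n + 9.0))
    )
    w2 = -1.0 + math.sqrt(2.0 * (c - 1.0))
    b = 1.0 / math.sqrt(0.5 * math.log(w2))
    a = math.sqrt((w2 - 1.0) / 2.0)
    u = y * a  # y / sqrt(2/(w^2-1))
    return b * np.log(u + np.sqrt(u**2 + 1.0))


def _dak_z(b2: np.ndarray, n: int) -> np.ndarray:
    """Anscombe–Glynn normalizing transformation of the sample kurtosis."""
    e_b2 = 3.0 * (n - 1.0) / (n + 1.0)
    var_b2 = 24.0 * n * (n - 2.0) * (n - 3.0) / ((n + 1.0) ** 2 * (n + 3.0) * (n + 5.0))
    x = (b2 - e_b2) / math.sqrt(var_b2)
    e = (
        6.0 * (n**2 - 5.0 * n + 2.0) / ((n + 7.0) * (n + 9.0))
        * math.sqrt(6.0 * (n + 3.0) * (n + 5.0) / (n * (n - 2.0) * (n - 3.0)))
    )
    f = 6.0 + 8.0 / e * (2.0 / e + math.sqrt(1.0 + 4.0 / e**2))
    if f <= 4.0:
        raise ArithmeticError(f"kurtosis transformation undefined: f={f} <= 4")
    r = 2.0 / (9.0 * f)
    g = x * math.sqrt(2.0 / (f - 4.0))
    v = (1.0 - 2.0 / f) / (1.0 + g)
    # v may be negative in extreme samples; the real cube root is intended
    v13 = np.sign(v) * np.abs(v) ** (1.0 / 3.0)
    return (1.0 - r - v13) / math.sqrt(r)


def _das_batch(x2d: np.ndarray):
    n = x2d.shape[1]
    b1s, _ = _skew_kurt_2d(x2d)
    z = _das_z(b1s, n)
    return z, 2.0 * stats.norm.sf(np.abs(z))


def _dak_batch(x2d: np.ndarray):
    n = x2d.shape[1]
    _, b2 = _skew_kurt_2d(x2d)
    z = _dak_z(b2, n)
    return z, 2.0 * stats.norm.sf(np.abs(z))


def _dap_batch(x2d: np.ndarray):
    n = x2d.shape[1]
    b1s, b2 = _skew_kurt_2d(x2d)
    k = _das_z(b1s, n) ** 2 + _dak_z(b2, n) ** 2
    return k, stats.chi2.sf(k, 2)


# ---------------------------------------------------------------------------
# Gel–Miao–Gastwirth and robust Jarque–Bera (J_n based)
# ---------------------------------------------------------------------------

# asymptotic variance of sqrt(n) (R - 1) under normality
_GMG_VAR = (np.pi - 3.0) / 2.0


def _jn_2d(x2d: np.ndarray) -> np.ndarray:
    med = np.median(x2d, axis=1, keepdims=True)
    return math.sqrt(np.pi / 2.0) * np.mean(np.abs(x2d - med), axis=1)


def _gmg_z(x2d: np.ndarray):
    n = x2d.shape[1]
    m2, _, _ = _central_moments_2d(x2d)
    sn = np.sqrt(m2)  # ML scale, divisor n
    jn = _jn_2d(x2d)
    r = sn / jn
    z = math.sqrt(n) * (r - 1.0) / math.sqrt(_GMG_VAR)
    return r, z


def _gmg_batch(x2d: np.ndarray):
    # Directed against heavy tails (R > 1): upper-tail p-value, with a
    # Student-t(n) finite-sample approximation to the normalized ratio.
    n = x2d.shape[1]
    r, z = _gmg_z(x2d)
    return r, stats.t.sf(z, n)


def _gmg_batch_normal(x2d: np.ndarray):
    # Alternative omnibus form: two-sided asymptotic normal on sqrt(n)(R-1).
    r, z = _gmg_z(x2d)
    return r, 2.0 * stats.norm.sf(np.abs(z))


def _rjb_batch(x2d: np.ndarray):
    n = x2d.shape[1]
    _, m3, m4 = _central_moments_2d(x2d)
    jn = _jn_2d(x2d)
    rjb = n / 6.0 * (m3 / jn**3) ** 2 + n / 64.0 * (m4 / jn**4 - 3.0) ** 2
    return rjb, stats.chi2.sf(rjb, 2)


# ---------------------------------------------------------------------------
# Pearson chi-square with equiprobable classes
# ---------------------------------------------------------------------------

def pchi_n_classes(n: int) -> int:
    """Number of equiprobable classes: ceil(2 n^0.4)."""
    return int(math.ceil(2.0 * n**0.4))


def _pchi_batch(x2d: np.ndarray):
    m, n = x2d.shape
    k = pchi_n_classes(n)
    df = k - 3
    if df < 1:
        raise UnsupportedSampleSizeError(
            f"Pearson chi-square needs k - 3 >= 1 degrees of freedom (n={n} gives k={k})"
        )
    mean = x2d.mean(axis=1, keepdims=True)
    s = x2d.std(axis=1, ddof=1, keepdims=True)
    u = stats.norm.cdf((x2d - mean) / s)
    cls = np.clip(np.floor(k * u).astype(np.int64), 0, k - 1)
    idx = cls + k * np.arange(m)[:, None]
    counts = np.bincount(idx.ravel(), minlength=m * k).reshape(m, k)
    expected = n / k
    p_stat = np.sum((counts - expected) ** 2, axis=1) / expected
    return p_stat, stats.chi2.sf(p_stat, df)


# ---------------------------------------------------------------------------
# registry, scalar API, batch API
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _TestSpec:
    batch: callable
    min_n: int
    max_n: int | None
    tail: str  # 'lower' | 'upper' | 'two' — rejection direction of the statistic


_REGISTRY: dict[str, _TestSpec] = {
    "SW": _TestSpec(_sw_batch, 3, SW_MAX_N, "lower"),
    "SF": _TestSpec(_sf_batch, 5, SW_MAX_N, "lower"),
    "LF": _TestSpec(_lf_batch, 4, None, "upper"),
    "CVM": _TestSpec(_cvm_batch, 4, None, "upper"),
    "AD": _TestSpec(_ad_batch, 7, None, "upper"),
    "JB": _TestSpec(_jb_batch, 3, None, "upper"),
    "AJB": _TestSpec(_ajb_batch, 4, None, "upper"),
    "DAS": _TestSpec(_das_batch, 9, None, "two"),
    "DAK": _TestSpec(_dak_batch, 5, None, "two"),
    "DAP": _TestSpec(_dap_batch, 20, None, "upper"),
    "GMG": _TestSpec(_gmg_batch, 10, None, "upper"),
    "RJB": _TestSpec(_rjb_batch, 4, None, "upper"),
    "PCHI": _TestSpec(_pchi_batch, 20, None, "upper"),
}


def sample_size_bounds(test_id: str) -> tuple[int, int | None]:
    """Supported (min_n, max_n) for a test; max_n is None when unbounded."""
    spec = _REGISTRY[test_id]
    return spec.min_n, spec.max_n


def _check_n(test_id: str, n: int) -> None:
    spec = _REGISTRY[test_id]
    if n < spec.min_n or (spec.max_n is not None and n > spec.max_n):
        hi = spec.max_n if spec.max_n is not None else "inf"
        raise UnsupportedSampleSizeError(
            f"{test_id} supports {spec.min_n} <= n <= {hi}, got n={n}"
        )


def batch_test(test_id: str, x2d: np.ndarray, alpha: float = 0.05):
    """Apply one test to every row of ``x2d``; returns (statistic, p_value) arrays.

    Rows are assumed non-degenerate (the Monte Carlo engine guarantees this
    almost surely); sample-size bounds are enforced.
    """
    x2d = np.atleast_2d(np.asarray(x2d, dtype=float))
    _check_n(test_id, x2d.shape[1])
    stat, p = _REGISTRY[test_id].batch(x2d)
    return stat, p


def run_test(
    test_id: str,
    sample: Sample,
    alpha: float = 0.05,
    null_table: "NullTable | None" = None,
) -> TestResult:
    """Run one normality test on a sample.

    Parameters
    ----------
    test_id : one of :data:`TEST_IDS`.
    sample : the data.
    alpha : nominal significance level; ``reject`` is ``p_value < alpha``.
    null_table : optional simulated null distribution (from
        :func:`simulate_null_table`); when given, the analytic p-value is
        replaced by the empirical one.
    """
    test_id = test_id.upper()
    if test_id not in _REGISTRY:
        raise KeyError(f"unknown test id {test_id!r}; expected one of {TEST_IDS}")
    if sample.is_degenerate:
        raise DegenerateSampleError(f"{test_id}: sample has zero variance")
    _check_n(test_id, sample.n)
    if test_id in ("GMG", "RJB") and float(_jn_2d(sample.values[None, :])[0]) == 0.0:
        raise DegenerateSampleError(
            f"{test_id}: robust scale J_n is zero (more than half the sample equals the median)"
        )
    stat, p = _REGISTRY[test_id].batch(sample.values[None, :])
    statistic = float(stat[0])
    if null_table is not None:
        if null_table.test_id != test_id or null_table.n != sample.n:
            raise ValueError("null table does not match this test/sample size")
        p_value = null_table.p_value(statistic)
    else:
        p_value = float(np.clip(p[0], 0.0, 1.0))
    return TestResult(
        test_id=test_id,
        statistic=statistic,
        p_value=p_value,
        alpha=alpha,
        reject=bool(p_value < alpha),
        n=sample.n,
    )


def sw_test(sample: Sample, alpha: float = 0.05) -> TestResult:
    """Shapiro–Wilk: W = (sum a_i x_(i))^2 / sum (x_(i) - mean)^2."""
    return run_test("SW", sample, alpha)


def sf_test(sample: Sample, alpha: float = 0.05) -> TestResult:
    """Shapiro–Francia: squared correlation of sorted data with Blom scores."""
    return run_test("SF", sample, alpha)


def lilliefors_test(sample: Sample, alpha: float = 0.05) -> TestResult:
    """Lilliefors: max EDF discrepancy from the fitted normal, D = max(D+, D-)."""
    return run_test("LF", sample, alpha)


def cvm_test(sample: Sample, alpha: float = 0.05) -> TestResult:
    """Cramér–von Mises with the modified statistic Z = W (1 + 0.5/n)."""
    return run_test("CVM", sample, alpha)


def ad_test(sample: Sample, alpha: float = 0.05) -> TestResult:
    """Anderson–Darling with estimated parameters."""
    return run_test("AD", sample, alpha)


def jb_test(sample: Sample, alpha: float = 0.05) -> TestResult:
    """Jarque–Bera: (n/6) b1 + (n/24)(b2 - 3)^2, chi-square(2) upper tail."""
    return run_test("JB", sample, alpha)


def ajb_test(sample: Sample, alpha: float = 0.05) -> TestResult:
    """Adjusted Jarque–Bera with exact finite-sample moments of sqrt(b1), b2."""
    return run_test("AJB", sample, alpha)


def das_test(sample: Sample, alpha: float = 0.05) -> TestResult:
    """D'Agostino skewness: normalized transformation z_s, two-sided."""
    return run_test("DAS", sample, alpha)


def dak_test(sample: Sample, alpha: float = 0.05) -> TestResult:
    """D'Agostino kurtosis: normalized transformation z_k, two-sided."""
    return run_test("DAK", sample, alpha)


def dap_test(sample: Sample, alpha: float = 0.05) -> TestResult:
    """D'Agostino–Pearson omnibus K = z_s^2 + z_k^2, chi-square(2)."""
    return run_test("DAP", sample, alpha)


def gmg_test(
    sample: Sample,
    alpha: float = 0.05,
    null_table: "NullTable | None" = None,
    method: str = "t",
) -> TestResult:
    """Gel–Miao–Gastwirth ratio R = s_n / J_n.

    The test is directed against heavy-tailed alternatives (R > 1). The
    default p-value is the upper tail of a Student-t(n) approximation to
    sqrt(n)(R - 1)/sqrt((pi - 3)/2); ``method="normal"`` gives the two-sided
    asymptotic normal instead. Pass a ``null_table`` for a simulated-null
    (calibrated) p-value.
    """
    if method not in ("t", "normal"):
        raise ValueError("method must be 't' or 'normal'")
    if method == "normal" and null_table is None:
        if sample.is_degenerate:
            raise DegenerateSampleError("GMG: sample has zero variance")
        _check_n("GMG", sample.n)
        if float(_jn_2d(sample.values[None, :])[0]) == 0.0:
            raise DegenerateSampleError("GMG: robust scale J_n is zero")
        stat, p = _gmg_batch_normal(sample.values[None, :])
        p_value = float(np.clip(p[0], 0.0, 1.0))
        return TestResult("GMG", float(stat[0]), p_value, alpha,
                          bool(p_value < alpha), sample.n)
    return run_test("GMG", sample, alpha, null_table=null_table)


def rjb_test(
    sample: Sample, alpha: float = 0.05, null_table: "NullTable | None" = None
) -> TestResult:
    """Robust Jarque–Bera with J_n in place of the classical scale."""
    return run_test("RJB", sample, alpha, null_table=null_table)


def pchi_test(sample: Sample, alpha: float = 0.05) -> TestResult:
    """Pearson chi-square with ceil(2 n^0.4) equiprobable classes, df = k - 3."""
    return run_test("PCHI", sample, alpha)


# ---------------------------------------------------------------------------
# simulated null distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullTable:
    """Sorted null statistics of one test at one sample size.

    All thirteen statistics are location–scale invariant, so the null law
    depends only on n and can be simulated once from N(0,1) draws.
    """

    test_id: str
    n: int
    reps: int
    seed: int
    stats_sorted: np.ndarray
    tail: str

    def quantile(self, q: float) -> float:
        """Empirical quantile of the null statistic."""
        return float(np.quantile(self.stats_sorted, q))

    def p_value(self, statistic: float) -> float:
        """Empirical p-value of an observed statistic (add-one rule)."""
        m = self.reps
        n_ge = m - np.searchsorted(self.stats_sorted, statistic, side="left")
        n_le = np.searchsorted(self.stats_sorted, statistic, side="right")
        upper = (n_ge + 1) / (m + 1)
        lower = (n_le + 1) / (m + 1)
        if self.tail == "upper":
            p = upper
        elif self.tail == "lower":
            p = lower
        else:  # two-sided
            p = 2.0 * min(upper, lower)
        return float(min(p, 1.0))


def simulate_null_table(
    test_id: str, n: int, reps: int = 10_000, seed: int = 0
) -> NullTable:
    """Simulate the null distribution of a test statistic under N(0,1).

    Bit-reproducible for a given seed; requires ``reps >= 1000``.
    """
    test_id = test_id.upper()
    if reps < 1000:
        raise ValueError("need at least 1000 replications for a usable null table")
    _check_n(test_id, n)
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    chunk = max(1, min(reps, 20_000_000 // max(n, 1)))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        stat, _ = batch_test(test_id, rng.standard_normal((m, n)))
        out[done : done + m] = stat
        done += m
    out.sort()
    return NullTable(
        test_id=test_id,
        n=n,
        reps=reps,
        seed=seed,
        stats_sorted=out,
        tail=_REGISTRY[test_id].tail,
    )
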