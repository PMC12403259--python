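"""Normal scores, plotting positions, and Shapiro–Wilk weights.

The exact Shapiro–Wilk weight vector requires the covariance matrix of
normal order statistics, whose inversion is impractical; the weights here
use Royston's polynomial approximation (the AS R94 construction), valid for
3 <= n <= 5000. Approximate expected normal order statistics use Blom's
plotting position (i - 3/8)/(n + 1/4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sample import Sample, UnsupportedSampleSizeError

__all__ = ["blom_scores", "sw_weights", "plotting_positions", "PlottingPositions"]

SW_MIN_N = 3
SW_MAX_N = 5000

# Royston's corrections to the two extreme weights, polynomials in 1/sqrt(n)
# (coefficients for u^5 ... u^1, constant 0).
_POLY_AN = np.array([-2.706056, 4.434685, -2.071190, -0.147981, 0.221157, 0.0])
_POLY_AN1 = np.array([-3.582633, 5.682633, -1.752461, -0.293762, 0.042981, 0.0])


def blom_scores(n: int) -> np.ndarray:
    """Approximate expected normal order statistics m_i (Blom's scores).

    Antisymmetric about zero: m_i = -m_{n+1-i}.
    """
    i = np.arange(1, n + 1)
    return stats.norm.ppf((i - 0.375) / (n + 0.25))


def sw_weights(n: int) -> np.ndarray:
    """Shapiro–Wilk weight vector a (ascending order), normalized so sum a^2 = 1.

    Royston's approximation: the two weights at each extreme are corrected by
    polynomials in 1/sqrt(n); interior weights are rescaled Blom scores.
    """
    if not SW_MIN_N <= n <= SW_MAX_N:
        raise UnsupportedSampleSizeError(
            f"Shapiro-Wilk weights support 3 <= n <= 5000, got n={n}"
        )
    if n == 3:
        r = np.sqrt(0.5)
        return np.array([-r, 0.0, r])
    m = blom_scores(n)
    ssm = float(m @ m)
    c = m / np.sqrt(ssm)
    u = 1.0 / np.sqrt(n)
    a = np.empty(n)
    an = c[-1] + np.polyval(_POLY_AN, u)
    if n > 5:
        an1 = c[-2] + np.polyval(_POLY_AN1, u)
        phi = (ssm - 2.0 * m[-1] ** 2 - 2.0 * m[-2] ** 2) / (
            1.0 - 2.0 * an**2 - 2.0 * an1**2
        )
        a[2:-2] = m[2:-2] / np.sqrt(phi)
        a[-1], a[-2], a[0], a[1] = an, an1, -an, -an1
    else:  # n = 4 or 5
        phi = (ssm - 2.0 * m[-1] ** 2) / (1.0 - 2.0 * an**2)
        a[1:-1] = m[1:-1] / np.sqrt(phi)
        a[-1], a[0] = an, -an
    return a


@dataclass(frozen=True)
class PlottingPositions:
    """Fitted-normal CDF positions p, Blom scores m, and SW weights a.

    ``p[i] = Phi((x_(i) - mean)/s)`` with s the unbiased SD. ``a`` is None
    when n exceeds the supported Shapiro–Wilk range.
    """

    p: np.ndarray
    m: np.ndarray
    a: np.ndarray | None


def plotting_positions(sample: Sample) -> PlottingPositions:
    """Compute plotting positions, normal scores, and SW weights for a sample."""
    xs = sample.sorted()
    s = xs.std(ddof=1)
    if s == 0.0:
        from .sample import DegenerateSampleError

        raise DegenerateSampleError("sample has zero variance")
    p = stats.norm.cdf((xs - xs.mean()) / s)
    m = blom_scores(sample.n)
    a = sw_weights(sample.n) if SW_MIN_N <= sample.n <= SW_MAX_N else None
    return PlottingPositions(p=p, m=m, a=a)
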