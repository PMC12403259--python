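"""Sample container and moment summaries.

Every normality test in this package consumes a :class:`Sample` — an ordered
collection of finite real observations — and most of the moment-based tests
are driven by the summary statistics collected in :class:`MomentSet`.

Conventions (used consistently across the package):

* ``sd`` is the unbiased standard deviation (divisor ``n - 1``); it is the
  scale used to standardize data for the EDF tests.
* ``sn`` is the maximum-likelihood standard deviation (divisor ``n``); it is
  the numerator scale of the Gel–Miao–Gastwirth ratio.
* ``mu2``, ``mu3``, ``mu4`` are central moments with divisor ``n``.
* ``skewness = mu3 / mu2**1.5`` and ``kurtosis = mu4 / mu2**2`` (raw, i.e.
  3 for the normal distribution).
* ``jn`` is sqrt(pi/2) times the mean absolute deviation from the sample
  median — a robust scale estimator that is consistent for the standard
  deviation under normality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Sample",
    "MomentSet",
    "compute_moments",
    "DegenerateSampleError",
    "UnsupportedSampleSizeError",
]


class DegenerateSampleError(ValueError):
    """The sample has zero variance (or zero robust scale)."""


class UnsupportedSampleSizeError(ValueError):
    """The requested test does not support this sample size."""


@dataclass(frozen=True)
class Sample:
    """An immutable 1-D array of at least three finite observations.

    Zero-variance (degenerate) samples may be constructed but are rejected
    by every test operation; non-finite values are rejected here.
    """

    values: np.ndarray

    def __init__(self, values) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1:
            raise ValueError(f"sample must be one-dimensional, got shape {arr.shape}")
        if arr.size < 3:
            raise ValueError(f"need at least 3 observations, got {arr.size}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("sample contains NaN or infinite values")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def is_degenerate(self) -> bool:
        return bool(np.ptp(self.values) == 0.0)

    def sorted(self) -> np.ndarray:
        return np.sort(self.values)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


@dataclass(frozen=True)
class MomentSet:
    """Location, scale, and shape summaries of a sample."""

    n: int
    mean: float
    sd: float          # unbiased (divisor n - 1)
    mu2: float         # central moments, divisor n
    mu3: float
    mu4: float
    skewness: float    # mu3 / mu2**1.5
    kurtosis: float    # mu4 / mu2**2 (raw; normal = 3)
    median: float
    sn: float          # ML standard deviation (divisor n)
    jn: float          # sqrt(pi/2) * mean |x - median|


def compute_moments(sample: Sample) -> MomentSet:
    """Compute the full moment summary of ``sample``.

    Raises
    ------
    DegenerateSampleError
        If the sample has zero variance.
    """
    x = sample.values
    n = sample.n
    if sample.is_degenerate:
        raise DegenerateSampleError("sample has zero variance")
    mean = float(x.mean())
    xc = x - mean
    mu2 = float(np.mean(xc**2))
    mu3 = float(np.mean(xc**3))
    mu4 = float(np.mean(xc**4))
    median = float(np.median(x))
    jn = float(np.sqrt(np.pi / 2.0) * np.mean(np.abs(x - median)))
    return MomentSet(
        n=n,
        mean=mean,
        sd=float(np.sqrt(mu2 * n / (n - 1))),
        mu2=mu2,
        mu3=mu3,
        mu4=mu4,
        skewness=mu3 / mu2**1.5,
        kurtosis=mu4 / mu2**2,
        median=median,
        sn=float(np.sqrt(mu2)),
        jn=jn,
    )
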