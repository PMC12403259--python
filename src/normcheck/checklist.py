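"""Practical test-selection checklist indexed by n, skewness, and kurtosis.

The Monte Carlo study behind this package shows that no single normality
test dominates: the most powerful choice depends on the sample size and on
how skewed and how heavy- or light-tailed the data are. This module encodes
those findings as a lookup — classify the sample's shape, then recommend
the tests with the highest power in that regime — and provides the
end-to-end ``assess`` workflow (moments -> classification -> recommendation
-> test panel).

Shape classes use the study's anchor shapes: symmetric (skew 0), moderately
skewed (skew 0.75), and highly skewed (skew 4). Real data never sit exactly
on an anchor, so classification uses the midpoints between anchors as
cutoffs: |skew| <= 0.375 is symmetric, 0.375 < |skew| <= 2.375 moderately
skewed, above that highly skewed. Kurtosis bands are [1, 2], (2, 4], (4, 9]
(raw kurtosis of the data, as in the study's worked examples); the sample
size is anchored to the largest grid value <= n.
"""

from __future__ import annotations

from dataclasses import dataclass

from .normality import TEST_IDS, TestResult, run_test
from .sample import MomentSet, Sample, compute_moments

__all__ = [
    "ShapeClass",
    "Recommendation",
    "AssessmentReport",
    "classify_shape",
    "recommend",
    "assess",
    "ChecklistDomainError",
    "SKEW_CLASSES",
    "KURT_BANDS",
    "N_ANCHORS",
]

SKEW_CLASSES = ("symmetric", "moderately_skewed", "highly_skewed")
KURT_BANDS = ("1-2", "2-4", "4-9")
N_ANCHORS = (20, 30, 40, 50, 80, 100, 200)

# midpoints between the study's skewness anchors 0 / 0.75 / 4
_SKEW_CUT_SYMMETRIC = 0.375
_SKEW_CUT_MODERATE = 2.375


class ChecklistDomainError(ValueError):
    """The sample's (skew, kurt, n) lies outside the checklist's domain."""


@dataclass(frozen=True)
class ShapeClass:
    """A sample's cell in the recommendation grid."""

    skew_class: str
    kurt_band: str
    n_band: int


@dataclass(frozen=True)
class Recommendation:
    """Ordered best-power tests for a shape cell, with any caveat."""

    primary_tests: tuple
    note: str | None
    provenance: ShapeClass


@dataclass(frozen=True)
class AssessmentReport:
    """Full output of the assessment workflow on one dataset."""

    moments: MomentSet
    shape: ShapeClass
    recommendation: Recommendation
    results: tuple          # TestResult for each recommended test
    panel: tuple | None     # all-13-test panel when requested
    alpha: float


# Recommendation grid: (n_band, kurt_band) -> {skew_class: (tests, note)}.
# "*" rows mean any of the thirteen tests, minus the noted exceptions.
_ANY = TEST_IDS


def _cell(tests, note=None):
    return (tuple(tests), note)


def _any_except(*excluded):
    kept = tuple(t for t in _ANY if t not in excluded)
    note = "any test" + (f" except {'/'.join(excluded)}" if excluded else "")
    return (kept, note)


_GRID: dict[tuple[int, str], dict[str, tuple]] = {}

for _n in N_ANCHORS:
    if _n == 20:
        _highly = {
            "1-2": _cell(["SW"]),
            "2-4": _cell(["SW"]),
            "4-9": _cell(["SW"]),
        }
    elif _n in (30, 40, 50):
        _highly = {
            "1-2": _cell(["SW", "SF", "AD"]),
            "2-4": _cell(["SW", "SF", "AD"]),
            "4-9": _cell(["SW", "SF", "AD"]),
        }
    elif _n == 80:
        _highly = {
            "1-2": _any_except("DAK", "GMG"),
            "2-4": _any_except("DAK"),
            "4-9": _any_except("DAK"),
        }
    elif _n == 100:
        _highly = {
            "1-2": _any_except("DAK", "GMG"),
            "2-4": _any_except(),
            "4-9": _any_except(),
        }
    else:  # n = 200
        _highly = {
            "1-2": _any_except("CVM"),
            "2-4": _any_except("CVM"),
            "4-9": _any_except("CVM"),
        }
    for _band in KURT_BANDS:
        _GRID[(_n, _band)] = {
            "moderately_skewed": {
                "1-2": _cell(["DAS", "SW"]),
                "2-4": _cell(["RJB", "AJB"]),
                "4-9": _cell(["GMG", "RJB"]),
            }[_band],
            "highly_skewed": _highly[_band],
            "symmetric": {
                "1-2": _cell(["RJB", "GMG"]),
                "2-4": _cell(["RJB", "GMG"]),
                "4-9": _cell(["GMG", "RJB"]),
            }[_band],
        }


def classify_shape(skew: float, kurt: float, n: int) -> ShapeClass:
    """Map a sample's skewness, raw kurtosis, and size to a grid cell.

    Raises
    ------
    ChecklistDomainError
        If ``kurt`` is outside [1, 9] or ``n < 20`` — the grid does not
        extrapolate beyond the study's scenario range.
    """
    if n < 20:
        raise ChecklistDomainError(
            f"the checklist covers n >= 20 (got n={n}); below that, power is too "
            "low for any recommendation to be meaningful"
        )
    if not 1.0 <= kurt <= 9.0:
        raise ChecklistDomainError(
            f"the checklist covers raw kurtosis in [1, 9] (got {kurt:g})"
        )
    a = abs(skew)
    if a <= _SKEW_CUT_SYMMETRIC:
        skew_class = "symmetric"
    elif a <= _SKEW_CUT_MODERATE:
        skew_class = "moderately_skewed"
    else:
        skew_class = "highly_skewed"
    if kurt <= 2.0:
        band = "1-2"
    elif kurt <= 4.0:
        band = "2-4"
    else:
        band = "4-9"
    n_band = max(anchor for anchor in N_ANCHORS if anchor <= n)
    return ShapeClass(skew_class=skew_class, kurt_band=band, n_band=n_band)


def recommend(shape: ShapeClass) -> Recommendation:
    """Best-power tests for a shape cell (first listed = first choice)."""
    tests, note = _GRID[(shape.n_band, shape.kurt_band)][shape.skew_class]
    return Recommendation(primary_tests=tests, note=note, provenance=shape)


def assess(sample: Sample, alpha: float = 0.05, panel: bool = False) -> AssessmentReport:
    """Classify a dataset's shape, recommend tests, and run them.

    With ``panel=True`` the report additionally carries all thirteen tests'
    results. Requires n >= 20.
    """
    moments = compute_moments(sample)
    shape = classify_shape(moments.skewness, moments.kurtosis, sample.n)
    rec = recommend(shape)
    results = tuple(run_test(t, sample, alpha) for t in rec.primary_tests)
    full: tuple[TestResult, ...] | None = None
    if panel:
        full = tuple(run_test(t, sample, alpha) for t in TEST_IDS)
    return AssessmentReport(
        moments=moments, shape=shape, recommendation=rec,
        results=results, panel=full, alpha=alpha,
    )
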