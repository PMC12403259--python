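"""Monte Carlo estimation of empirical size and power over scenario grids.

The engine repeatedly draws samples — normal for size studies, Fleishman
power-method variates for power studies — applies normality tests at a
nominal level, and reports the rejection proportion per cell together with
its binomial Monte Carlo standard error sqrt(p (1 - p) / reps).

Seeding discipline: a single master seed drives the whole study. Each grid
cell derives its own independent random stream from (master seed, cell key),
so any one cell is reproducible in isolation and results are bit-identical
across reruns of the same configuration. With ``common_samples=True`` all
tests within a cell share the same draws (common random numbers, which
reduces the variance of between-test comparisons); by default every
(test, cell) pair gets fresh draws.

Results are long-format :class:`pandas.DataFrame` tables with one row per
(test, scenario) cell; infeasible Fleishman cells are flagged, never
silently skipped. Negative-skew cells are mirrored from the corresponding
positive-skew cells by default (the power method's coefficients for -skew
are a sign flip, so the power is identical in distribution).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _version
from .fleishman import (
    MomentTarget,
    draw_matrix,
    scenario_target,
    solve_fleishman,
)
from .normality import TEST_IDS, batch_test, sample_size_bounds

__all__ = [
    "ScenarioSpec",
    "RejectionEstimate",
    "SizeStudyConfig",
    "PowerStudyConfig",
    "estimate_rejection_rate",
    "run_size_study",
    "run_power_study",
    "size_within_band",
    "export_table",
    "read_table",
    "TABLE_COLUMNS",
    "DEFAULT_N_GRID",
    "NULL_FAMILIES",
]

#: sample-size grid of the reference study
DEFAULT_N_GRID = (20, 30, 40, 50, 80, 100, 200)

#: null families for size studies: N(0,1), N(3,1), N(0,0.5)
NULL_FAMILIES = (("N(0,1)", 0.0, 1.0), ("N(3,1)", 3.0, 1.0), ("N(0,0.5)", 0.0, 0.5))

#: fixed output schema (column order is part of the CSV contract)
TABLE_COLUMNS = [
    "test", "family", "n", "skew", "kurt_value", "convention",
    "alpha", "reps", "seed", "proportion", "mc_se", "status",
]

#: the study's adequacy band for the empirical type I error rate
SIZE_BAND = (0.045, 0.055)


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation cell: a sampling family, sample size, and level."""

    family: str                      # "normal" | "fleishman"
    n: int
    reps: int = 10_000
    alpha: float = 0.05
    mu: float = 0.0
    sigma: float = 1.0
    target: MomentTarget | None = None

    def __post_init__(self) -> None:
        if self.family not in ("normal", "fleishman"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "fleishman" and self.target is None:
            raise ValueError("fleishman scenario needs a MomentTarget")
        if self.reps < 100:
            raise ValueError("need at least 100 replications")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.sigma <= 0.0:
            raise ValueError("sigma must be positive")

    def label(self) -> str:
        if self.family == "normal":
            return f"N({self.mu:g},{self.sigma:g})"
        t = self.target
        return f"fleishman(skew={t.skew:g},kurt={t.kurt_value:g},{t.convention})"


@dataclass(frozen=True)
class RejectionEstimate:
    """A Monte Carlo rejection proportion with its binomial standard error."""

    test_id: str
    scenario: ScenarioSpec
    proportion: float
    mc_se: float
    reps: int
    status: str = "ok"  # "ok" | "infeasible" | "unsupported_n" | "mirrored"


def _cell_rng(master_seed: int, *key_parts) -> np.random.Generator:
    """Independent, reproducible stream for one grid cell."""
    key = zlib.crc32("|".join(str(p) for p in key_parts).encode())
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


def _draw(scenario: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    shape = (scenario.reps, scenario.n)
    if scenario.family == "normal":
        return scenario.mu + scenario.sigma * rng.standard_normal(shape)
    t = scenario.target
    coeffs = solve_fleishman(t.skew, t.excess_kurt)
    return draw_matrix(coeffs, shape, rng)


def _supports(test_id: str, n: int) -> bool:
    lo, hi = sample_size_bounds(test_id)
    return lo <= n and (hi is None or n <= hi)


def estimate_rejection_rate(
    test_id: str, scenario: ScenarioSpec, seed: int = 0
) -> RejectionEstimate:
    """Estimate one test's rejection probability under one scenario.

    Infeasible Fleishman targets yield a flagged estimate (NaN proportion),
    not an exception. Bit-reproducible for a given seed.
    """
    test_id = test_id.upper()
    if scenario.family == "fleishman" and not scenario.target.is_feasible:
        return RejectionEstimate(test_id, scenario, float("nan"), float("nan"),
                                 scenario.reps, status="infeasible")
    if not _supports(test_id, scenario.n):
        return RejectionEstimate(test_id, scenario, float("nan"), float("nan"),
                                 scenario.reps, status="unsupported_n")
    rng = _cell_rng(seed, test_id, scenario.label(), scenario.n,
                    scenario.reps, scenario.alpha)
    x = _draw(scenario, rng)
    _, p = batch_test(test_id, x, scenario.alpha)
    prop = float(np.mean(p < scenario.alpha))
    se = float(np.sqrt(prop * (1.0 - prop) / scenario.reps))
    return RejectionEstimate(test_id, scenario, prop, se, scenario.reps)


def _estimate_cell_group(
    tests, scenario: ScenarioSpec, seed: int, common_samples: bool
) -> list[RejectionEstimate]:
    """All requested tests on one scenario, optionally sharing draws."""
    out = []
    if scenario.family == "fleishman" and not scenario.target.is_feasible:
        return [
            RejectionEstimate(t, scenario, float("nan"), float("nan"),
                              scenario.reps, status="infeasible")
            for t in tests
        ]
    x_shared = None
    if common_samples:
        rng = _cell_rng(seed, "common", scenario.label(), scenario.n,
                        scenario.reps, scenario.alpha)
        x_shared = _draw(scenario, rng)
    for t in tests:
        if not _supports(t, scenario.n):
            out.append(RejectionEstimate(t, scenario, float("nan"), float("nan"),
                                         scenario.reps, status="unsupported_n"))
            continue
        if common_samples:
            _, p = batch_test(t, x_shared, scenario.alpha)
            prop = float(np.mean(p < scenario.alpha))
            se = float(np.sqrt(prop * (1.0 - prop) / scenario.reps))
            out.append(RejectionEstimate(t, scenario, prop, se, scenario.reps))
        else:
            out.append(estimate_rejection_rate(t, scenario, seed))
    return out


@dataclass(frozen=True)
class SizeStudyConfig:
    """Configuration of an empirical type-I-error study over normal nulls."""

    tests: tuple = TEST_IDS
    n_grid: tuple = DEFAULT_N_GRID
    families: tuple = NULL_FAMILIES     # (label, mu, sigma) triples
    reps: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    common_samples: bool = False


@dataclass(frozen=True)
class PowerStudyConfig:
    """Configuration of a power study over Fleishman alternatives.

    ``scenarios`` is a sequence of (skew, kurt_value) pairs interpreted under
    ``convention``; negative-skew cells are mirrored from their positive
    counterparts when ``mirror_negative_skew`` is set.
    """

    scenarios: tuple = ()
    tests: tuple = TEST_IDS
    n_grid: tuple = DEFAULT_N_GRID
    reps: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    convention: str = "excess_reproduction"
    common_samples: bool = False
    mirror_negative_skew: bool = True


def _meta_row(est: RejectionEstimate, seed: int, skew=np.nan, kurt=np.nan,
              convention="") -> dict:
    s = est.scenario
    return {
        "test": est.test_id,
        "family": s.label() if s.family == "normal" else "fleishman",
        "n": s.n,
        "skew": skew,
        "kurt_value": kurt,
        "convention": convention,
        "alpha": s.alpha,
        "reps": s.reps,
        "seed": seed,
        "proportion": est.proportion,
        "mc_se": est.mc_se,
        "status": est.status,
    }


def _finalize(rows: list[dict], config) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    df.attrs["seed"] = config.seed
    df.attrs["reps"] = config.reps
    df.attrs["version"] = _version
    return df


def run_size_study(config: SizeStudyConfig = SizeStudyConfig()) -> pd.DataFrame:
    """Empirical size of each test over the null-family x sample-size grid."""
    rows = []
    for label, mu, sigma in config.families:
        for n in config.n_grid:
            sc = ScenarioSpec("normal", n, reps=config.reps, alpha=config.alpha,
                              mu=mu, sigma=sigma)
            for est in _estimate_cell_group(config.tests, sc, config.seed,
                                            config.common_samples):
                rows.append(_meta_row(est, config.seed))
    return _finalize(rows, config)


def run_power_study(config: PowerStudyConfig) -> pd.DataFrame:
    """Power of each test over a (skew, kurt) x sample-size Fleishman grid.

    Infeasible cells carry ``status="infeasible"`` and NaN proportions;
    mirrored negative-skew cells carry ``status="mirrored"``.
    """
    if not config.scenarios:
        raise ValueError("power study needs at least one (skew, kurt) scenario")
    rows = []
    positive_cache: dict[tuple, list[dict]] = {}
    for skew, kurt in config.scenarios:
        mirror = config.mirror_negative_skew and skew < 0
        use_skew = abs(skew) if mirror else skew
        target = scenario_target(use_skew, kurt, config.convention)
        cell_rows = positive_cache.get((use_skew, kurt))
        if cell_rows is None:
            cell_rows = []
            for n in config.n_grid:
                sc = ScenarioSpec("fleishman", n, reps=config.reps,
                                  alpha=config.alpha, target=target)
                for est in _estimate_cell_group(config.tests, sc, config.seed,
                                                config.common_samples):
                    cell_rows.append(
                        _meta_row(est, config.seed, skew=use_skew, kurt=kurt,
                                  convention=config.convention)
                    )
            positive_cache[(use_skew, kurt)] = cell_rows
        for r in cell_rows:
            r = dict(r)
            if mirror:
                r["skew"] = skew
                if r["status"] == "ok":
                    r["status"] = "mirrored"
            rows.append(r)
    return _finalize(rows, config)


def size_within_band(proportion: float) -> bool:
    """Whether an empirical size falls in the adequacy band [0.045, 0.055]."""
    return SIZE_BAND[0] <= proportion <= SIZE_BAND[1]


def export_table(table: pd.DataFrame, path) -> None:
    """Write a result table as CSV with the fixed column order."""
    table.loc[:, TABLE_COLUMNS].to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a result table written by :func:`export_table`."""
    df = pd.read_csv(
        path,
        dtype={"test": str, "family": str, "convention": str, "status": str},
        keep_default_na=True,
    )
    df["convention"] = df["convention"].fillna("")
    return df.loc[:, TABLE_COLUMNS]
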