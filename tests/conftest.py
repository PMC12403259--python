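"""Shared fixtures: deterministic samples and frozen reference values.

The reference (statistic, p-value) pins for SF/LF/CVM/AD/PCHI were computed
with the R ``nortest`` package (sf.test, lillie.test, cvm.test, ad.test,
pearson.test) and for SW with R's shapiro.test, on exactly the arrays
produced by :func:`fixture_samples`; they are frozen here so the suite runs
without R. nortest reports the unmodified Cramér-von Mises statistic W,
whereas this package reports Z = W (1 + 0.5/n); the comparison accounts
for that.
"""

from __future__ import annotations

import numpy as np
import pytest

from normcheck import Sample


def fixture_samples() -> dict[str, np.ndarray]:
    """Deterministic pinned samples (regenerated, never stored)."""
    rng = np.random.default_rng(20240)
    return {
        "ramp10": np.arange(1.0, 11.0),
        "ramp20": np.arange(1.0, 21.0),
        "normal30": rng.standard_normal(30),
        "lognormal25": np.exp(rng.standard_normal(25)),
        "uniform40": rng.uniform(0.0, 1.0, 40),
    }


# (statistic, p_value) from R nortest / shapiro.test; CVM entries hold the
# unmodified W statistic.
R_PINS: dict[str, dict[str, tuple[float, float]]] = {
    "ramp10": {
        "SF": (0.98657684941, 0.995283202892),
        "LF": (0.0955193289816, 0.99817071892),
        "CVM": (0.0182004401585, 0.975608491771),
        "AD": (0.14110924786, 0.956657938468),
        "SW": (0.970164611231, 0.892367307524),
    },
    "ramp20": {
        "SF": (0.977183353012, 0.819533869622),
        "LF": (0.0765635896446, 0.990950221918),
        "CVM": (0.0290018680143, 0.851132282614),
        "AD": (0.220737841656, 0.806355061328),
        "PCHI": (1.7, 0.790717624105),
        "SW": (0.960375183106, 0.55137174304),
    },
    "normal30": {
        "SF": (0.980713889481, 0.759887219418),
        "LF": (0.0966956787003, 0.673518658024),
        "CVM": (0.0423749115104, 0.624804327799),
        "AD": (0.281338330764, 0.615351577152),
        "PCHI": (4.13333333333, 0.530383430422),
        "SW": (0.971525099757, 0.581697202728),
    },
    "lognormal25": {
        "SF": (0.724240446216, 5.21550038071e-05),
        "LF": (0.215262798584, 0.00413583351004),
        "CVM": (0.364554933274, 5.28803910297e-05),
        "AD": (2.08616307674, 1.79145368984e-05),
        "PCHI": (17.56, 0.00355153581834),
        "SW": (0.736413013887, 2.34585861868e-05),
    },
    "uniform40": {
        "SF": (0.917924000502, 0.00850922311808),
        "LF": (0.17510638846, 0.00336794383711),
        "CVM": (0.21229014739, 0.00349558086942),
        "AD": (1.37037700177, 0.00129257035033),
        "PCHI": (17.6, 0.00731356880363),
        "SW": (0.90358772228, 0.00243518500262),
    },
}


@pytest.fixture(scope="session")
def samples() -> dict[str, np.ndarray]:
    return fixture_samples()


@pytest.fixture(scope="session")
def sample_objects(samples) -> dict[str, Sample]:
    return {name: Sample(x) for name, x in samples.items()}
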