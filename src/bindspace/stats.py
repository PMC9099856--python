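"""Correlation of computed ΔG with experimental potencies; group tests.

Potencies (IC50, nM) are log10-transformed by default before the ordinary
least-squares fit (y = x * a + b) with its Pearson r; orientation
ensembles are compared with a two-sided Welch unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .structures import InputError


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    n: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "n": self.n,
        }


@dataclass
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float
    test: str = "Welch"

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def fit_dg_activity(
    dg: np.ndarray, potency: np.ndarray, transform: str = "log10"
) -> RegressionResult:
    """OLS of (transformed) potency on ΔG, with Pearson r.

    ``transform='log10'`` regresses log10(IC50) on ΔG (pharmacological
    convention); ``'identity'`` uses the raw potencies.
    """
    dg = np.asarray(dg, float)
    y = np.asarray(potency, float)
    if dg.shape != y.shape or dg.ndim != 1:
        raise InputError("fit_dg_activity: dg and potency must be equal-length 1-D")
    if len(dg) < 3:
        raise InputError("fit_dg_activity: need at least 3 points")
    if transform == "log10":
        if np.any(y <= 0):
            raise InputError("IC50 values must be positive for the log transform")
        y = np.log10(y)
    elif transform != "identity":
        raise InputError(f"unknown transform {transform!r}")
    if np.ptp(dg) == 0 or np.ptp(y) == 0:
        raise InputError("zero variance: Pearson r undefined")
    res = sps.linregress(dg, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        n=len(dg),
    )


def compare_orientations(dg_a: np.ndarray, dg_b: np.ndarray) -> GroupComparison:
    """Two-sided Welch t-test between two ΔG groups (e.g. orientations)."""
    a = np.asarray(dg_a, float)
    b = np.asarray(dg_b, float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("compare_orientations: each group needs n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=len(a),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=len(b),
        t_statistic=float(t),
        p_value=float(p),
    )
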