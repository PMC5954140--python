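"""Interaction quantification from dual-color FCCS measurements.

The relative cross-correlation amplitude (RCA) of one measurement is the
zero-lag excess amplitude of the fitted cross-correlation function divided
by that of one autocorrelation function:

    RCA = [Gc(0) - 1] / [Gr(0) - 1]   (red normalization, the default).

Under ideal conditions Gx(0) - 1 = 1/Nx for the autocorrelations and
Gc(0) - 1 = Nc / (Ng Nr) for the cross-correlation, where Nc is the number
of double-labeled complexes in the detection volume, so the red-normalized
RCA equals the bound fraction Nc/Ng of green-labeled molecules and the
green-normalized RCA equals Nc/Nr.  Amplitudes are taken from the fitted
models extrapolated to tau = 0 with the triplet factor stripped (pure
diffusion amplitude 1/N), not from raw zero-lag values, which carry shot
noise.

Group comparisons use the two-sample Student's t-test (equal variance,
two-sided; Welch available behind a flag) with the significance-star
convention *p < 0.05, **p < 0.01, ***p < 0.005, ****p < 0.001.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correlate import CorrelationCurve
from .exceptions import ConfigError, NumericalError
from .fitmodel import FitResult

__all__ = [
    "FCCSMeasurement",
    "InteractionResult",
    "GroupComparison",
    "compute_rca",
    "rca_from_fits",
    "compare_groups",
    "summarize_condition",
    "significance_stars",
]

logger = logging.getLogger(__name__)

_NORMALIZATIONS = ("red", "green", "min_amplitude")

# (threshold, stars), checked in order; matches the figure-legend convention
_STAR_LEVELS = ((0.001, "****"), (0.005, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class FCCSMeasurement:
    """The three curves and fits of one cell measurement."""

    curve_gg: CorrelationCurve
    curve_rr: CorrelationCurve
    curve_gr: CorrelationCurve
    fit_gg: FitResult
    fit_rr: FitResult
    fit_gr: FitResult
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self):
        for name in ("gg", "rr", "gr"):
            curve = getattr(self, f"curve_{name}")
            if curve.kind != name:
                raise ConfigError(f"curve_{name} has kind {curve.kind!r}")
        for name in ("gg", "rr", "gr"):
            fit = getattr(self, f"fit_{name}")
            if not fit.converged:
                raise NumericalError(f"fit_{name} did not converge")
            if not math.isfinite(fit.model.diffusion_amplitude):
                raise NumericalError(f"fit_{name} amplitude is not finite")


@dataclass(frozen=True)
class InteractionResult:
    """RCA and bound fractions of one measurement."""

    rca: float
    normalization_channel: str
    bound_fraction_nc_over_ng: float
    bound_fraction_nc_over_nr: float
    amplitude_gr: float
    amplitude_rr: float
    amplitude_gg: float
    cell_id: str = ""
    condition: str = ""


def compute_rca(
    measurement: FCCSMeasurement, normalization: str = "red"
) -> InteractionResult:
    """Relative cross-correlation amplitude of one measurement.

    ``normalization`` selects the autocorrelation amplitude in the
    denominator: ``"red"`` (the default; RCA = Nc/Ng), ``"green"``
    (RCA = Nc/Nr), or ``"min_amplitude"`` (the smaller of the two, a
    conservative upper-bounding choice).
    """
    return rca_from_fits(
        measurement.fit_gg,
        measurement.fit_rr,
        measurement.fit_gr,
        normalization=normalization,
        cell_id=measurement.cell_id,
        condition=measurement.condition,
    )


def rca_from_fits(
    fit_gg: FitResult,
    fit_rr: FitResult,
    fit_gr: FitResult,
    normalization: str = "red",
    cell_id: str = "",
    condition: str = "",
) -> InteractionResult:
    """RCA from the three fitted models alone (see :func:`compute_rca`)."""
    if normalization not in _NORMALIZATIONS:
        raise ConfigError(f"normalization must be one of {_NORMALIZATIONS}")
    for name, fit in (("gg", fit_gg), ("rr", fit_rr), ("gr", fit_gr)):
        if not fit.converged:
            raise NumericalError(f"fit_{name} did not converge")
    amp_gr = fit_gr.model.diffusion_amplitude
    amp_rr = fit_rr.model.diffusion_amplitude
    amp_gg = fit_gg.model.diffusion_amplitude
    denom = {
        "red": amp_rr,
        "green": amp_gg,
        "min_amplitude": min(amp_rr, amp_gg),
    }[normalization]
    if denom <= 0:
        raise NumericalError("no autocorrelation signal: denominator amplitude <= 0")
    return InteractionResult(
        rca=amp_gr / denom,
        normalization_channel=normalization,
        bound_fraction_nc_over_ng=amp_gr / amp_rr,
        bound_fraction_nc_over_nr=amp_gr / amp_gg,
        amplitude_gr=amp_gr,
        amplitude_rr=amp_rr,
        amplitude_gg=amp_gg,
        cell_id=cell_id,
        condition=condition,
    )


def significance_stars(p_value: float) -> str:
    """Star annotation for a p-value (ns when p >= 0.05)."""
    for threshold, stars in _STAR_LEVELS:
        if p_value < threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison of interaction amplitudes."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    stars: str
    equal_variance: bool = True


def compare_groups(
    rcas_a,
    rcas_b,
    label_a: str = "a",
    label_b: str = "b",
    equal_variance: bool = True,
) -> GroupComparison:
    """Student's t-test between two groups of interaction amplitudes.

    Equal-variance two-sided test by default (df = n_a + n_b - 2); pass
    ``equal_variance=False`` for Welch's variant.  Two identical
    zero-variance groups yield t = 0, p = 1 by convention (logged).
    """
    a = np.asarray(rcas_a, dtype=float)
    b = np.asarray(rcas_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ConfigError("groups must contain finite values only")
    pooled_var = a.var(ddof=1) + b.var(ddof=1)
    if pooled_var == 0:
        if a.mean() == b.mean():
            logger.info("zero pooled variance with equal means: p = 1 by convention")
            t_stat, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
        else:
            logger.warning("zero pooled variance with different means: p = 0")
            t_stat, p, df = math.inf, 0.0, float(len(a) + len(b) - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_variance)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t_statistic=t_stat,
        degrees_of_freedom=df,
        p_value=p,
        stars=significance_stars(p),
        equal_variance=equal_variance,
    )


def summarize_condition(
    measurements, normalization: str = "red"
) -> pd.DataFrame:
    """Per-condition mean, SD and n of the RCA.

    Accepts :class:`FCCSMeasurement` or precomputed
    :class:`InteractionResult` objects; returns a DataFrame with columns
    condition, n, mean_rca, sd_rca (NaN for single-measurement conditions).
    Conditions with no measurements are omitted with a warning.
    """
    rows = []
    for m in measurements:
        res = m if isinstance(m, InteractionResult) else compute_rca(m, normalization)
        rows.append({"condition": res.condition, "rca": res.rca})
    if not rows:
        logger.warning("no measurements to summarize")
        return pd.DataFrame(columns=["condition", "n", "mean_rca", "sd_rca"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("condition", sort=True)["rca"]
        .agg(n="size", mean_rca="mean", sd_rca=lambda x: x.std(ddof=1))
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
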