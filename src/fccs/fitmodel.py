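"""Multi-component 3D-diffusion model for FCS/FCCS correlation curves.

The model for free 3D diffusion through a 3D-Gaussian detection volume with
structure parameter s = z0/w0 is

    G(tau) = 1 + (1/N) * sum_i F_i (1 + tau/tau_i)^-1 (1 + tau/(s^2 tau_i))^-1/2
                 * [1 + T/(1-T) * exp(-tau/tau_T)],

where N is the mean particle number in the detection volume, F_i and tau_i
the fraction and diffusion time of component i (sum F_i = 1, 1-3 components),
and the bracketed factor is the optional triplet (dark-state) term with
amplitude T in [0, 0.5) and relaxation time tau_T; the factor multiplies the
fluctuation term only, so G(0) - 1 = (1/N)(1 + T/(1-T)).

Fitting is bounded weighted least squares (lmfit / scipy trust-region);
weights are the per-lag standard errors of the curve when available.  The
structure parameter is fixed during sample fits and freed only during
calibration against a reference dye of known diffusion coefficient, from
which the beam waist follows as w0 = sqrt(4 D tau_D).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .correlate import CorrelationCurve
from .exceptions import ConfigError, NumericalError

__all__ = [
    "DiffusionModel",
    "FitResult",
    "CalibrationResult",
    "model_eval",
    "fit_curve",
    "initial_guess",
    "calibrate_structure_parameter",
]

logger = logging.getLogger(__name__)

N_BOUNDS = (1e-3, 1e6)
TRIPLET_MAX = 0.5
FIT_TOL = 1e-10


@dataclass(frozen=True)
class DiffusionModel:
    """Parameter set of the multi-component diffusion model.

    ``components`` is a tuple of (fraction, diffusion_time_s) pairs, 1-3
    entries, fractions summing to 1 and diffusion times strictly increasing.
    """

    n_particles: float
    components: tuple[tuple[float, float], ...]
    structure_parameter: float
    triplet_fraction: float = 0.0
    triplet_time: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self, "components", tuple((float(f), float(t)) for f, t in self.components)
        )
        if self.n_particles <= 0:
            raise ConfigError("n_particles must be > 0")
        if not 1 <= len(self.components) <= 3:
            raise ConfigError("model supports 1 to 3 diffusion components")
        fracs = [f for f, _ in self.components]
        taus = [t for _, t in self.components]
        if any(f < 0 for f in fracs):
            raise ConfigError("fractions must be >= 0")
        if abs(sum(fracs) - 1.0) > 1e-12:
            raise ConfigError(f"fractions must sum to 1, got {sum(fracs)}")
        if any(t <= 0 for t in taus):
            raise ConfigError("diffusion times must be > 0")
        if any(taus[i] >= taus[i + 1] for i in range(len(taus) - 1)):
            raise ConfigError("diffusion times must be strictly increasing")
        if self.structure_parameter <= 0:
            raise ConfigError("structure_parameter must be > 0")
        if not 0 <= self.triplet_fraction < 1:
            raise ConfigError("triplet_fraction must be in [0, 1)")
        if self.triplet_fraction > 0 and self.triplet_time <= 0:
            raise ConfigError("triplet_time must be > 0 when triplet_fraction > 0")

    @property
    def amplitude(self) -> float:
        """G(0) - 1 = (1/N) (1 + T/(1-T)): the zero-lag excess amplitude."""
        t = self.triplet_fraction
        return (1.0 + t / (1.0 - t)) / self.n_particles

    @property
    def diffusion_amplitude(self) -> float:
        """Triplet-stripped zero-lag amplitude 1/N."""
        return 1.0 / self.n_particles


def model_eval(model: DiffusionModel, lags) -> np.ndarray:
    """Evaluate the diffusion model at the given lags (seconds, >= 0)."""
    tau = np.asarray(lags, dtype=float)
    if np.any(tau < 0):
        raise ConfigError("lags must be >= 0")
    s2 = model.structure_parameter**2
    diff = np.zeros_like(tau)
    for frac, tau_i in model.components:
        diff += frac / ((1.0 + tau / tau_i) * np.sqrt(1.0 + tau / (s2 * tau_i)))
    t = model.triplet_fraction
    if t > 0:
        diff *= 1.0 + t / (1.0 - t) * np.exp(-tau / model.triplet_time)
    return 1.0 + diff / model.n_particles


@dataclass
class FitResult:
    """Outcome of a bounded weighted least-squares fit.

    ``stderr`` maps free-parameter names to 1-sigma uncertainties from the
    covariance at the optimum (None where unavailable); ``fixed`` records
    the parameters held constant and their values.
    """

    model: DiffusionModel
    stderr: dict[str, float | None]
    fixed: dict[str, float]
    reduced_chi_square: float
    residuals: np.ndarray
    converged: bool
    n_function_evals: int
    weighted: bool = True
    warnings: tuple[str, ...] = ()
    lags: np.ndarray = field(default=None, repr=False)


def initial_guess(
    curve: CorrelationCurve,
    n_components: int = 1,
    structure_parameter: float = 5.0,
    min_lag: float = 0.0,
) -> DiffusionModel:
    """Deterministic starting model from the curve shape.

    N0 inverts the amplitude law N = 1/(G(first fitted lag) - 1); the central
    diffusion time is the lag at which G - 1 first falls below half its
    initial value; multi-component guesses spread diffusion times
    geometrically around it with uniform fractions.
    """
    mask = curve.lags > min_lag if min_lag > 0 else np.ones(len(curve), bool)
    # the zero lag carries shot noise; never use it as the amplitude anchor
    mask &= curve.lags > 0
    if not mask.any():
        raise ConfigError("no usable lags above min_lag")
    lags = curve.lags[mask]
    values = curve.values[mask]
    amplitude = values[0] - 1.0
    if amplitude <= 0:
        raise NumericalError("no correlated signal: amplitude at first lag <= 0")
    n0 = 1.0 / amplitude
    below = np.nonzero(values - 1.0 < amplitude / 2.0)[0]
    tau0 = lags[below[0]] if len(below) else lags[-1]
    k = n_components
    if not 1 <= k <= 3:
        raise ConfigError("n_components must be 1, 2 or 3")
    spreads = {1: [1.0], 2: [1 / 5, 5.0], 3: [1 / 5, 1.0, 5.0]}[k]
    components = tuple((1.0 / k, tau0 * s) for s in spreads)
    return DiffusionModel(
        n_particles=n0,
        components=components,
        structure_parameter=structure_parameter,
    )


def _build_params(
    init: DiffusionModel,
    fixed: dict[str, float],
    use_triplet: bool,
    tau_bounds: tuple[float, float],
    first_lag: float,
) -> lmfit.Parameters:
    k = len(init.components)
    p = lmfit.Parameters()

    def add(name, value, lo, hi):
        if name in fixed:
            p.add(name, value=float(fixed[name]), vary=False)
        else:
            value = min(max(value, lo * (1 + 1e-9)), hi * (1 - 1e-9))
            p.add(name, value=value, min=lo, max=hi)

    add("n_particles", init.n_particles, *N_BOUNDS)
    lo, hi = tau_bounds
    for i, (_, tau_i) in enumerate(init.components, start=1):
        add(f"tau{i}", tau_i, lo, hi)
    if k == 1:
        p.add("f1", value=1.0, vary=False)
    elif k == 2:
        add("f1", init.components[0][0], 0.0, 1.0)
        p.add("f2", expr="1 - f1")
    else:
        f1, f2 = init.components[0][0], init.components[1][0]
        add("f1", f1, 0.0, 1.0)
        # g2 parametrizes f2 as a share of the remainder so f3 stays >= 0
        add("g2", f2 / max(1.0 - f1, 1e-12), 0.0, 1.0)
        p.add("f2", expr="(1 - f1) * g2")
        p.add("f3", expr="1 - f1 - f2")
    add("structure_parameter", init.structure_parameter, 1e-2, 1e7)
    if use_triplet:
        add("triplet_fraction", max(init.triplet_fraction, 0.05), 0.0, TRIPLET_MAX - 1e-9)
        tt = init.triplet_time if init.triplet_time > 0 else first_lag
        add("triplet_time", tt, first_lag / 100.0, hi)
    return p


def _model_from_params(params: lmfit.Parameters, k: int, use_triplet: bool) -> DiffusionModel:
    comps = []
    for i in range(1, k + 1):
        comps.append((params[f"f{i}"].value, params[f"tau{i}"].value))
    # canonical ordering: diffusion times increasing
    comps.sort(key=lambda ft: ft[1])
    fracs = np.array([f for f, _ in comps], dtype=float)
    fracs = np.clip(fracs, 0.0, None)
    fracs /= fracs.sum()
    taus = [t for _, t in comps]
    # break exact ties so the ordering invariant holds
    for i in range(1, k):
        if taus[i] <= taus[i - 1]:
            taus[i] = taus[i - 1] * (1 + 1e-12)
    return DiffusionModel(
        n_particles=params["n_particles"].value,
        components=tuple((fracs[i], taus[i]) for i in range(k)),
        structure_parameter=params["structure_parameter"].value,
        triplet_fraction=params["triplet_fraction"].value if use_triplet else 0.0,
        triplet_time=params["triplet_time"].value if use_triplet else 0.0,
    )


def fit_curve(
    curve: CorrelationCurve,
    n_components: int = 1,
    fixed: dict[str, float] | None = None,
    init: DiffusionModel | None = None,
    use_triplet: bool = False,
    vary_s: bool = False,
    min_lag: float | None = None,
    max_lag: float | None = None,
) -> FitResult:
    """Fit the diffusion model to a correlation curve.

    Parameters named in ``fixed`` are held at the given values.  The
    structure parameter is fixed by default (pass it in ``fixed`` or via
    ``init``; it is freed only with ``vary_s=True``, as during calibration).
    ``min_lag`` excludes lags <= its value from the fit; by default only the
    shot-noise-dominated zero lag is excluded.  ``max_lag`` truncates the fit
    window from above (useful when the long-lag tail is known to be
    unreliable, e.g. near the finite-trace or finite-box limit).

    Weights are 1/stderr when the curve carries nonzero standard errors at
    every fitted lag; otherwise the fit is unweighted (logged).  Returns a
    :class:`FitResult`; non-convergence is reported via ``converged=False``
    with diagnostics, never silently.
    """
    fixed = dict(fixed) if fixed else {}
    if not 1 <= n_components <= 3:
        raise ConfigError("n_components must be 1, 2 or 3")
    if min_lag is None:
        min_lag = 0.0
    mask = (curve.lags > min_lag) if min_lag > 0 else (curve.lags > 0)
    if max_lag is not None:
        mask &= curve.lags <= max_lag
    lags = curve.lags[mask]
    values = curve.values[mask]
    stderr = curve.stderr[mask]
    if init is None:
        try:
            init = initial_guess(
                curve,
                n_components,
                structure_parameter=fixed.get("structure_parameter", 5.0),
                min_lag=min_lag,
            )
        except NumericalError:
            if curve.kind != "gr":
                raise
            # a non-interacting pair legitimately yields a flat cross-curve;
            # start from a near-zero amplitude and let the optimizer settle
            tau0 = math.sqrt(lags[0] * lags[-1])
            init = DiffusionModel(
                n_particles=1e4,
                components=tuple(
                    (1.0 / n_components, tau0 * s)
                    for s in ({1: [1.0], 2: [1 / 5, 5.0], 3: [1 / 5, 1.0, 5.0]}[n_components])
                ),
                structure_parameter=fixed.get("structure_parameter", 5.0),
            )
    elif len(init.components) != n_components:
        raise ConfigError("init model has a different number of components")
    if not vary_s and "structure_parameter" not in fixed:
        fixed["structure_parameter"] = init.structure_parameter

    weighted = bool(np.all(stderr > 0))
    if not weighted and np.any(stderr > 0):
        # mixed zero/nonzero errors: fall back to unweighted rather than inf-weighting
        logger.warning("curve has zero stderr at some lags; fitting unweighted")
    elif not weighted:
        logger.info("curve carries no stderr; fitting unweighted")
    tau_bounds = (curve.source_bin_time / 2 if curve.source_bin_time > 0 else lags[0] / 10,
                  lags[-1] * 100)
    params = _build_params(init, fixed, use_triplet, tau_bounds, lags[0])

    n_free = sum(1 for par in params.values() if par.vary)
    if len(lags) < 3 * n_free:
        raise ConfigError(
            f"curve has {len(lags)} usable lags; need >= 3x the {n_free} free parameters"
        )

    k = n_components

    def residual(p):
        m = DiffusionModel(
            n_particles=p["n_particles"].value,
            components=_unordered_components(p, k),
            structure_parameter=p["structure_parameter"].value,
            triplet_fraction=p["triplet_fraction"].value if use_triplet else 0.0,
            triplet_time=p["triplet_time"].value if use_triplet else 0.0,
        )
        r = model_eval(m, lags) - values
        return r / stderr if weighted else r

    result = lmfit.minimize(
        residual,
        params,
        method="least_squares",
        xtol=FIT_TOL,
        ftol=FIT_TOL,
        gtol=FIT_TOL,
        max_nfev=50_000,
    )
    if not result.success and curve.kind == "gr":
        # near-flat cross-curves can strand the optimizer; restart from the
        # vanishing-amplitude corner of the parameter space
        retry = params.copy()
        if retry["n_particles"].vary:
            retry["n_particles"].value = 1e4
        result2 = lmfit.minimize(
            residual, retry, method="least_squares",
            xtol=FIT_TOL, ftol=FIT_TOL, gtol=FIT_TOL, max_nfev=50_000,
        )
        if result2.success:
            result = result2
    model = _model_from_params(result.params, k, use_triplet)
    stderr_out = {
        name: (par.stderr if par.stderr is not None else None)
        for name, par in result.params.items()
        if par.vary
    }
    warnings = []
    if not result.success:
        warnings.append(f"optimizer did not report success: {result.message}")
    if k >= 2:
        fr = [f for f, _ in model.components]
        ta = [t for _, t in model.components]
        if max(fr) >= 0.95 or any(ta[i + 1] / ta[i] < 2.0 for i in range(k - 1)):
            warnings.append(
                "degenerate components: one fraction dominates or diffusion "
                "times are within 2x of each other"
            )
    return FitResult(
        model=model,
        stderr=stderr_out,
        fixed=fixed,
        reduced_chi_square=float(result.redchi),
        residuals=np.asarray(result.residual, dtype=float),
        converged=bool(result.success),
        n_function_evals=int(result.nfev),
        weighted=weighted,
        warnings=tuple(warnings),
        lags=lags,
    )


def _unordered_components(p: lmfit.Parameters, k: int):
    """Components straight from the parameter vector, made valid for eval.

    During optimisation the taus may cross; the model value is symmetric
    under component exchange, so evaluation sorts them on the fly.
    """
    comps = sorted(
        ((p[f"f{i}"].value, p[f"tau{i}"].value) for i in range(1, k + 1)),
        key=lambda ft: ft[1],
    )
    fracs = np.clip([f for f, _ in comps], 0.0, None)
    total = fracs.sum()
    fracs = fracs / total if total > 0 else np.full(k, 1.0 / k)
    taus = [t for _, t in comps]
    for i in range(1, k):
        if taus[i] <= taus[i - 1]:
            taus[i] = taus[i - 1] * (1 + 1e-12)
    return tuple((fracs[i], taus[i]) for i in range(k))


@dataclass(frozen=True)
class CalibrationResult:
    """Structure-parameter calibration from a reference-dye curve."""

    structure_parameter: float
    waist_w0: float
    diffusion_time: float
    fit: FitResult


def calibrate_structure_parameter(
    reference_curve: CorrelationCurve,
    known_D: float,
    init: DiffusionModel | None = None,
    max_lag: float | None = None,
) -> CalibrationResult:
    """Calibrate s and w0 from a single-species dye measurement.

    Fits a one-component model with the structure parameter free, then
    converts the fitted diffusion time to the beam waist through
    w0 = sqrt(4 D tau_D) using the dye's known diffusion coefficient.
    The returned s is meant to be fixed in all subsequent sample fits.
    """
    if known_D <= 0:
        raise ConfigError("known_D must be > 0")
    fit = fit_curve(
        reference_curve, n_components=1, init=init, vary_s=True, max_lag=max_lag
    )
    if not fit.converged:
        raise NumericalError(
            f"calibration fit did not converge: {'; '.join(fit.warnings)}"
        )
    tau_d = fit.model.components[0][1]
    w0 = math.sqrt(4.0 * known_D * tau_d)
    return CalibrationResult(
        structure_parameter=fit.model.structure_parameter,
        waist_w0=w0,
        diffusion_time=tau_d,
        fit=fit,
    )
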