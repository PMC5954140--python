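"""Desk-scale simulation studies exercising the full analysis chain.

Each function defines one self-contained synthetic experiment — fixed
optics, box, timing and species composition — runs the pipeline stages on
freshly simulated traces, and returns the measured quantities together with
their ground truth.  The same studies back both the validation test suite
and ``scripts/acceptance.py``.

Shared conventions (package choices, see docs/methods.md):

* optics: w0 = 0.25 um, z0 = 1.25 um (structure parameter s = 5), a typical
  calibrated confocal volume;
* protein-like species diffuse at D = 1 um^2/s (tau_D ~ 15.6 ms) in a
  3.0 x 3.0 x 5.0 um periodic box (radial edges 12 w0, axial edge 4 z0);
* molecular brightness 2e4 counts/s per label (~300 photons per transit);
* trace durations are several thousand diffusion times with the sampling
  interval tau_D/20, which keeps single-run parameter scatter below ~10%;
* reference-dye runs use D = 400 um^2/s in a larger 6 um box, and the fit
  window is capped at (L/4)^2 / (2 D) — the lag beyond which diffusion
  across the periodic box makes the infinite-medium model inapplicable;
* every study derives its per-run seeds from one base seed through
  ``numpy.random.SeedSequence(base, (level, replicate))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlate import correlate_direct, correlate_multitau, estimate_curve
from .fitmodel import calibrate_structure_parameter, fit_curve
from .interaction import compare_groups, rca_from_fits
from .simulate import OpticsSpec, SimulationConfig, SpeciesSpec, simulate_trace

__all__ = [
    "DEFAULT_OPTICS",
    "PROTEIN_BOX",
    "DYE_BOX",
    "derive_seed",
    "simulate_measurement",
    "amplitude_law_study",
    "recovery_grid_study",
    "rca_share_study",
    "calibration_study",
    "ttest_type1_study",
    "multitau_agreement_study",
]

DEFAULT_OPTICS = OpticsSpec(waist_radial_w0=0.25, waist_axial_z0=1.25)
PROTEIN_BOX = (3.0, 3.0, 5.0)
DYE_BOX = (6.0, 6.0, 6.0)
PROTEIN_D = 1.0  # um^2/s
BRIGHTNESS = 2.0e4  # counts/s per label at the volume centre


def derive_seed(base_seed: int, level: int, replicate: int) -> int:
    """Deterministic per-run seed below 2^31."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(level, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def _tau_d(diffusion_coefficient: float, w0: float = 0.25) -> float:
    return w0**2 / (4.0 * diffusion_coefficient)


@dataclass
class Measurement:
    """Fits of the three curves of one simulated acquisition."""

    fit_gg: object
    fit_rr: object
    fit_gr: object
    realized_counts: list

    @property
    def rca(self) -> float:
        return rca_from_fits(self.fit_gg, self.fit_rr, self.fit_gr).rca


def simulate_measurement(
    species,
    seed: int,
    duration: float = 15.0,
    bin_time: float = 2e-4,
    optics: OpticsSpec = DEFAULT_OPTICS,
    box=PROTEIN_BOX,
    n_segments: int = 10,
) -> Measurement:
    """Simulate one dual-channel acquisition and fit all three curves."""
    config = SimulationConfig(
        species=tuple(species),
        optics=optics,
        box_edge_lengths=box,
        duration=duration,
        time_step=bin_time,
        bin_time=bin_time,
        rng_seed=seed,
    )
    trace = simulate_trace(config)
    fits = {}
    for kind in ("gg", "rr", "gr"):
        curve = estimate_curve(trace, kind, n_segments=n_segments)
        fits[kind] = fit_curve(
            curve, n_components=1,
            fixed={"structure_parameter": optics.structure_parameter},
        )
    return Measurement(
        fit_gg=fits["gg"],
        fit_rr=fits["rr"],
        fit_gr=fits["gr"],
        realized_counts=trace.metadata["realized_particle_counts"],
    )


def _single_species_fit(n_eff: float, tau_d: float, seed: int,
                        duration_tau_d: float = 5000.0):
    """Simulate one green-only species at target N_eff and fit gg."""
    D = 0.25**2 / (4.0 * tau_d)
    box_volume = float(np.prod(PROTEIN_BOX))
    mean_box = n_eff * box_volume / DEFAULT_OPTICS.effective_volume
    species = SpeciesSpec(
        "green_only",
        diffusion_coefficient=D,
        mean_particle_count_in_box=mean_box,
        brightness_green=50.0 / tau_d,  # ~50 photons per transit
    )
    config = SimulationConfig(
        species=(species,),
        optics=DEFAULT_OPTICS,
        box_edge_lengths=PROTEIN_BOX,
        duration=duration_tau_d * tau_d,
        time_step=tau_d / 20.0,
        bin_time=tau_d / 20.0,
        rng_seed=seed,
    )
    trace = simulate_trace(config)
    curve = estimate_curve(trace, "gg")
    return fit_curve(curve, 1, fixed={"structure_parameter": DEFAULT_OPTICS.structure_parameter})


def amplitude_law_study(base_seed: int, n_seeds: int = 10, n_eff: float = 5.0):
    """Fitted N versus analytic N_eff for a single diffusing species.

    Returns (n_eff, fitted list): open-volume statistics make the expected
    zero-lag excess amplitude exactly 1/N_eff.
    """
    tau_d = _tau_d(PROTEIN_D)
    fitted = [
        _single_species_fit(n_eff, tau_d, derive_seed(base_seed, 20, r)).model.n_particles
        for r in range(n_seeds)
    ]
    return n_eff, fitted


def recovery_grid_study(
    base_seed: int,
    n_eff_levels=(1.0, 5.0, 20.0),
    tau_d_levels=(1e-4, 1e-3, 1e-2),
):
    """Parameter recovery across the particle-number x diffusion-time grid.

    Returns a list of dicts with the relative errors of fitted N and tau_D
    per grid cell (one independent seed per cell).
    """
    results = []
    for i, n_eff in enumerate(n_eff_levels):
        for j, tau_d in enumerate(tau_d_levels):
            seed = derive_seed(base_seed, 30 + i, j)
            fit = _single_species_fit(n_eff, tau_d, seed)
            results.append(
                {
                    "n_eff": n_eff,
                    "tau_d": tau_d,
                    "n_rel_err": fit.model.n_particles / n_eff - 1.0,
                    "tau_rel_err": fit.model.components[0][1] / tau_d - 1.0,
                }
            )
    return results


def dual_share_species(share: float, total_per_color: float = 100.0):
    """Species mixture with a given fraction of co-diffusing (dual) labels.

    ``share`` of the ``total_per_color`` molecules of each color are bound in
    double-labeled complexes; the rest diffuse as single-labeled monomers.
    The ideal bound fraction Nc/Ng therefore equals ``share``.
    """
    if not 0.0 <= share <= 1.0:
        raise ValueError("share must be in [0, 1]")
    species = []
    n_single = (1.0 - share) * total_per_color
    n_dual = share * total_per_color
    if n_single > 0:
        species.append(SpeciesSpec(
            "green_only", PROTEIN_D, n_single, brightness_green=BRIGHTNESS))
        species.append(SpeciesSpec(
            "red_only", PROTEIN_D, n_single, brightness_red=BRIGHTNESS))
    if n_dual > 0:
        species.append(SpeciesSpec(
            "dual", PROTEIN_D, n_dual,
            brightness_green=BRIGHTNESS, brightness_red=BRIGHTNESS))
    return tuple(species)


def rca_share_study(
    base_seed: int,
    shares=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_seeds: int = 10,
    duration: float = 15.0,
    level_offset: int = 0,
):
    """Measured RCA versus the simulated dual-label share.

    Returns ``{share: [rca per seed]}``; under red normalization the ideal
    RCA equals the share (the bound fraction Nc/Ng).  ``level_offset``
    shifts the seed-derivation level so separate studies use disjoint seeds.
    """
    out = {}
    for level, share in enumerate(shares):
        values = []
        for r in range(n_seeds):
            m = simulate_measurement(
                dual_share_species(share),
                derive_seed(base_seed, level_offset + level, r),
                duration=duration,
            )
            values.append(m.rca)
        out[share] = values
    return out


def calibration_study(base_seed: int, n_seeds: int = 10, known_D: float = 400.0):
    """Structure-parameter calibration against a simulated reference dye.

    A fast-diffusing dye (D = 400 um^2/s, Rhodamine-6G-like) is simulated in
    the larger dye box; a one-component fit with s free recovers s and, via
    w0 = sqrt(4 D tau_D), the beam waist.  Returns (s list, w0 list) over
    seeds; truth is s = 5, w0 = 0.25 um.
    """
    tau_d = _tau_d(known_D)
    box_volume = float(np.prod(DYE_BOX))
    mean_box = 1.0 * box_volume / DEFAULT_OPTICS.effective_volume  # N_eff = 1
    species = SpeciesSpec(
        "green_only", known_D, mean_box, brightness_green=5e5)
    max_lag = (min(DYE_BOX) / 4.0) ** 2 / (2.0 * known_D)
    s_values, w0_values = [], []
    for r in range(n_seeds):
        config = SimulationConfig(
            species=(species,),
            optics=DEFAULT_OPTICS,
            box_edge_lengths=DYE_BOX,
            duration=20000.0 * tau_d,
            time_step=tau_d / 20.0,
            bin_time=tau_d / 20.0,
            rng_seed=derive_seed(base_seed, 10, r),
        )
        trace = simulate_trace(config)
        curve = estimate_curve(trace, "gg")
        cal = calibrate_structure_parameter(curve, known_D=known_D, max_lag=max_lag)
        s_values.append(cal.structure_parameter)
        w0_values.append(cal.waist_w0)
    return s_values, w0_values


def ttest_type1_study(
    base_seed: int,
    n_replicates: int = 1000,
    n_per_group: int = 10,
    mean: float = 0.3,
    sd: float = 0.06,
    alpha: float = 0.05,
) -> float:
    """Type-I error rate of the group comparison under the null.

    Both groups are drawn from the same Gaussian null RCA distribution
    (location and spread matched to the simulated 30%-dual-share cohort);
    returns the fraction of replicates with p < alpha.
    """
    rng = np.random.default_rng(derive_seed(base_seed, 40, 0))
    rejections = 0
    for _ in range(n_replicates):
        a = rng.normal(mean, sd, n_per_group)
        b = rng.normal(mean, sd, n_per_group)
        if compare_groups(a, b).p_value < alpha:
            rejections += 1
    return rejections / n_replicates


def multitau_agreement_study(base_seed: int, n_bins: int = 10_000) -> float:
    """Worst-case relative deviation between the multi-tau and direct
    estimators at shared lags on a simulated two-species trace."""
    species = dual_share_species(0.5)
    config = SimulationConfig(
        species=species,
        optics=DEFAULT_OPTICS,
        box_edge_lengths=PROTEIN_BOX,
        duration=n_bins * 2e-4,
        time_step=2e-4,
        bin_time=2e-4,
        rng_seed=derive_seed(base_seed, 50, 0),
    )
    trace = simulate_trace(config)
    worst = 0.0
    for kind in ("gg", "rr", "gr"):
        mt = correlate_multitau(trace, kind)
        direct = correlate_direct(trace, kind, int(round(mt.lags[-1] / trace.bin_time)))
        direct_bins = np.rint(direct.lags / trace.bin_time).astype(int)
        mt_bins = np.rint(mt.lags / trace.bin_time).astype(int)
        lookup = {b: v for b, v in zip(direct_bins, direct.values)}
        for b, v in zip(mt_bins, mt.values):
            rel = abs(v - lookup[b]) / abs(lookup[b])
            worst = max(worst, rel)
    return worst
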