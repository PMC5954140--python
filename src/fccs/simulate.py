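"""Brownian-dynamics synthetic-data generator for dual-color FCCS.

Point emitters (green-labeled, red-labeled, or dual-labeled) diffuse in a
periodic box and are observed through two co-aligned 3D-Gaussian confocal
detection volumes centred at the origin.  The detection profile is

    W(x, y, z) = exp(-2 (x^2 + y^2) / w0^2 - 2 z^2 / z0^2),

with radial waist ``w0`` and axial half-length ``z0``.  The expected photon
rate in a channel is the per-molecule molecular brightness times the summed
profile weight over all particles carrying that label, optionally gated by a
two-state triplet (dark-state) telegraph process, mixed between channels by
spectral-crosstalk fractions, plus a constant background.  Photon counts per
time bin are Poisson samples of the rate integrated over the bin.

All lengths are micrometres, times are seconds, brightnesses are counts per
second per molecule at the volume centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from numba import njit

from .exceptions import ConfigError

__all__ = [
    "SpeciesSpec",
    "OpticsSpec",
    "SimulationConfig",
    "TwoChannelTrace",
    "simulate_trace",
    "effective_particle_number",
    "effective_volume",
    "apply_crosstalk",
]

_LABEL_KINDS = ("green_only", "red_only", "dual")

@dataclass(frozen=True)
class SpeciesSpec:
    """One diffusing labeled species.

    Parameters
    ----------
    label_kind : {"green_only", "red_only", "dual"}
        Which fluorophores the species carries.  Dual species co-diffuse a
        green and a red label and are what a cross-correlation amplitude
        detects.
    diffusion_coefficient : float
        Translational diffusion coefficient D in um^2/s; the diffusion time
        through the detection volume is tau_D = w0^2 / (4 D).
    mean_particle_count_in_box : float
        Mean number of molecules of this species in the simulation box.  The
        realized number is Poisson-drawn per trace (open-volume statistics)
        unless the configuration requests a fixed count.
    brightness_green, brightness_red : float
        Molecular brightness per channel, counts/s at the volume centre.
    triplet_fraction : float
        Stationary probability of the dark (triplet) state, in [0, 1).
    triplet_residence_time : float
        Mean dwell time of the dark state in seconds (required > 0 when
        ``triplet_fraction`` > 0).
    start_at_origin : bool
        Testing hook: place all particles of this species at the volume
        centre instead of uniformly in the box (used with D -> 0 to probe
        pure photon statistics).
    """

    label_kind: str
    diffusion_coefficient: float
    mean_particle_count_in_box: float
    brightness_green: float = 0.0
    brightness_red: float = 0.0
    triplet_fraction: float = 0.0
    triplet_residence_time: float = 0.0
    start_at_origin: bool = False

    def __post_init__(self):
        if self.label_kind not in _LABEL_KINDS:
            raise ConfigError(
                f"label_kind must be one of {_LABEL_KINDS}, got {self.label_kind!r}"
            )
        if not (math.isfinite(self.diffusion_coefficient) and self.diffusion_coefficient > 0):
            raise ConfigError("diffusion_coefficient must be finite and > 0")
        if self.mean_particle_count_in_box <= 0:
            raise ConfigError("mean_particle_count_in_box must be > 0")
        if self.brightness_green < 0 or self.brightness_red < 0:
            raise ConfigError("brightnesses must be >= 0")
        if self.label_kind == "green_only" and self.brightness_red != 0:
            raise ConfigError("green_only species must have brightness_red = 0")
        if self.label_kind == "red_only" and self.brightness_green != 0:
            raise ConfigError("red_only species must have brightness_green = 0")
        if self.label_kind == "dual" and (
            self.brightness_green <= 0 or self.brightness_red <= 0
        ):
            raise ConfigError("dual species must have both brightnesses > 0")
        if not 0 <= self.triplet_fraction < 1:
            raise ConfigError("triplet_fraction must be in [0, 1)")
        if self.triplet_fraction > 0 and self.triplet_residence_time <= 0:
            raise ConfigError(
                "triplet_residence_time must be > 0 when triplet_fraction > 0"
            )


@dataclass(frozen=True)
class OpticsSpec:
    """Co-aligned two-channel confocal detection geometry and noise terms.

    ``waist_radial_w0`` and ``waist_axial_z0`` are the 1/e^2 radial waist and
    axial half-length of the 3D-Gaussian detection volume (um).  The structure
    parameter is s = z0/w0 and the effective detection volume is
    V_eff = pi^(3/2) w0^2 z0.
    """

    waist_radial_w0: float
    waist_axial_z0: float
    crosstalk_green_into_red: float = 0.0
    crosstalk_red_into_green: float = 0.0
    background_rate_green: float = 0.0
    background_rate_red: float = 0.0

    def __post_init__(self):
        if self.waist_radial_w0 <= 0 or self.waist_axial_z0 <= 0:
            raise ConfigError("waists must be > 0")
        if not 0 <= self.crosstalk_green_into_red < 1:
            raise ConfigError("crosstalk_green_into_red must be in [0, 1)")
        if not 0 <= self.crosstalk_red_into_green < 1:
            raise ConfigError("crosstalk_red_into_green must be in [0, 1)")
        if self.background_rate_green < 0 or self.background_rate_red < 0:
            raise ConfigError("background rates must be >= 0")

    @property
    def structure_parameter(self) -> float:
        """Aspect ratio s = z0 / w0 of the detection volume."""
        return self.waist_axial_z0 / self.waist_radial_w0

    @property
    def effective_volume(self) -> float:
        """V_eff = pi^(3/2) w0^2 z0 in um^3."""
        return math.pi ** 1.5 * self.waist_radial_w0**2 * self.waist_axial_z0


@dataclass(frozen=True)
class SimulationConfig:
    """Complete ground-truth description of one synthetic FCCS acquisition."""

    species: tuple[SpeciesSpec, ...]
    optics: OpticsSpec
    box_edge_lengths: tuple[float, float, float]
    duration: float
    time_step: float
    bin_time: float
    rng_seed: int
    fixed_particle_count: bool = False

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "box_edge_lengths", tuple(float(e) for e in self.box_edge_lengths))
        if len(self.box_edge_lengths) != 3 or any(e <= 0 for e in self.box_edge_lengths):
            raise ConfigError("box_edge_lengths must be three positive lengths")
        if self.duration <= 0 or self.time_step <= 0 or self.bin_time <= 0:
            raise ConfigError("duration, time_step and bin_time must be > 0")
        ratio = self.bin_time / self.time_step
        if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio) or round(ratio) < 1:
            raise ConfigError(
                f"bin_time/time_step must be a positive integer, got {ratio}"
            )
        n_bins = int(self.duration / self.bin_time + 1e-9)
        if n_bins < 100:
            raise ConfigError(
                f"duration must cover at least 100 bins, got {n_bins}"
            )
        if self.box_volume < 100 * self.optics.effective_volume:
            raise ConfigError(
                "box volume must be at least 100 x V_eff "
                f"({self.box_volume:.3g} um^3 < {100 * self.optics.effective_volume:.3g} um^3)"
            )

    @property
    def box_volume(self) -> float:
        lx, ly, lz = self.box_edge_lengths
        return lx * ly * lz

    @property
    def steps_per_bin(self) -> int:
        return round(self.bin_time / self.time_step)

    @property
    def n_bins(self) -> int:
        return int(self.duration / self.bin_time + 1e-9)


@dataclass
class TwoChannelTrace:
    """Binned photon counts in the green and red channels.

    ``counts_green`` and ``counts_red`` are equal-length arrays of
    non-negative integers, one entry per time bin of width ``bin_time``
    seconds.  ``metadata`` carries an acquisition descriptor (seed, optics,
    realized particle counts, ...).
    """

    bin_time: float
    counts_green: np.ndarray
    counts_red: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts_green = np.asarray(self.counts_green)
        self.counts_red = np.asarray(self.counts_red)
        if self.bin_time <= 0:
            raise ConfigError("bin_time must be > 0")
        if self.counts_green.shape != self.counts_red.shape or self.counts_green.ndim != 1:
            raise ConfigError("both channels must be 1-D and of identical length")
        if len(self.counts_green) < 100:
            raise ConfigError("traces must contain at least 100 bins")
        for name, arr in (("counts_green", self.counts_green), ("counts_red", self.counts_red)):
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(arr == np.floor(arr)):
                    raise ConfigError(f"{name} contains non-integer counts")
                arr = arr.astype(np.int64)
            if np.any(arr < 0):
                raise ConfigError(f"{name} contains negative counts")
        self.counts_green = self.counts_green.astype(np.int64)
        self.counts_red = self.counts_red.astype(np.int64)

    def __len__(self) -> int:
        return len(self.counts_green)

    @property
    def duration(self) -> float:
        return len(self) * self.bin_time


def effective_volume(w0: float, z0: float) -> float:
    """Effective confocal detection volume V_eff = pi^(3/2) w0^2 z0 (um^3)."""
    if w0 <= 0 or z0 <= 0:
        raise ConfigError("waists must be > 0")
    return math.pi ** 1.5 * w0**2 * z0


def effective_particle_number(
    species: "SpeciesSpec | float",
    optics: OpticsSpec,
    box_edge_lengths: Sequence[float],
) -> float:
    """Mean number of particles of one species in the detection volume.

    This is the ground truth the fitted particle number N of the diffusion
    model must recover: ``mean_count_in_box * V_eff / V_box``.

    ``species`` may be a :class:`SpeciesSpec` or a bare mean box count.
    """
    count = getattr(species, "mean_particle_count_in_box", species)
    if count < 0:
        raise ConfigError("particle count must be >= 0")
    v_box = float(np.prod(np.asarray(box_edge_lengths, dtype=float)))
    if v_box <= 0:
        raise ConfigError("box volume must be > 0")
    return count * optics.effective_volume / v_box


def apply_crosstalk(
    rate_green: np.ndarray, rate_red: np.ndarray, optics: OpticsSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Redistribute expected fluorescence rates between channels.

    A fraction ``crosstalk_green_into_red`` of the green-fluorophore rate is
    detected in the red channel and vice versa.  Total expected rate is
    conserved: the mixing moves signal, it never creates it.
    """
    c_gr = optics.crosstalk_green_into_red
    c_rg = optics.crosstalk_red_into_green
    out_green = (1.0 - c_gr) * rate_green + c_rg * rate_red
    out_red = (1.0 - c_rg) * rate_red + c_gr * rate_green
    return out_green, out_red


def _telegraph_states(
    rng: np.random.Generator,
    n_particles: int,
    n_steps: int,
    dt: float,
    dark_fraction: float,
    dark_residence: float,
) -> np.ndarray:
    """Sample a (n_steps, n_particles) bright/dark matrix (1 = bright).

    Two-state Markov telegraph with stationary dark probability
    ``dark_fraction`` and mean dark dwell ``dark_residence``:
    k_on = 1/tau_T (dark->bright) and k_off = k_on * T/(1-T).
    Dwell lengths are geometric in steps with p = 1 - exp(-k dt), the exact
    discrete-time analogue of exponential dwells.
    """
    k_on = 1.0 / dark_residence
    k_off = k_on * dark_fraction / (1.0 - dark_fraction)
    p_leave = {1: -np.expm1(-k_off * dt), 0: -np.expm1(-k_on * dt)}
    states = np.empty((n_steps, n_particles), dtype=np.int8)
    initial_bright = rng.random(n_particles) >= dark_fraction
    for j in range(n_particles):
        s = 1 if initial_bright[j] else 0
        t = 0
        while t < n_steps:
            p = p_leave[s]
            dwell = int(rng.geometric(p)) if p > 0 else n_steps - t
            end = min(t + dwell, n_steps)
            states[t:end, j] = s
            t = end
            s = 1 - s
    return states


@njit(cache=True)
def _propagate_and_weigh(rng, pos, n_steps, sigma, hx, hy, hz, cw, cz, states, out):
    """Brownian propagation + detection-profile weight sum, one species.

    ``pos`` (n_particles, 3) is advanced in place by N(0, sigma^2) increments
    per coordinate and step, wrapped into the periodic box [-h, h) per axis
    (a single reflection suffices because sigma << box edge).  ``out``
    receives sum_i W(pos_i) per step, with W = exp(cw (x^2+y^2) + cz z^2),
    gated by the bright/dark ``states`` matrix when it is non-empty.
    """
    n = pos.shape[0]
    gated = states.shape[0] > 0
    for t in range(n_steps):
        s = 0.0
        for i in range(n):
            x = pos[i, 0] + sigma * rng.standard_normal()
            y = pos[i, 1] + sigma * rng.standard_normal()
            z = pos[i, 2] + sigma * rng.standard_normal()
            if x >= hx:
                x -= 2 * hx
            elif x < -hx:
                x += 2 * hx
            if y >= hy:
                y -= 2 * hy
            elif y < -hy:
                y += 2 * hy
            if z >= hz:
                z -= 2 * hz
            elif z < -hz:
                z += 2 * hz
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
            if gated and states[t, i] == 0:
                continue
            s += math.exp(cw * (x * x + y * y) + cz * z * z)
        out[t] = s
    return out


_EMPTY_STATES = np.zeros((0, 0), dtype=np.int8)


def _species_weight_trace(
    rng: np.random.Generator,
    spec: SpeciesSpec,
    config: SimulationConfig,
    n_particles: int,
    n_steps: int,
) -> np.ndarray:
    """Summed detection-profile weight per time step for one species.

    Positions are midpoint samples of the Brownian paths: because Brownian
    increments are stationary, sampling the path on any regular grid offset
    yields statistically identical weights, so consecutive positions simply
    differ by N(0, 2 D dt) per coordinate.  The box is periodic and centred
    on the detection volume.
    """
    w_sum = np.zeros(n_steps)
    if n_particles == 0:
        return w_sum
    box = np.asarray(config.box_edge_lengths)
    w0 = config.optics.waist_radial_w0
    z0 = config.optics.waist_axial_z0
    dt = config.time_step
    sigma = math.sqrt(2.0 * spec.diffusion_coefficient * dt)

    if spec.start_at_origin:
        pos = np.zeros((n_particles, 3))
    else:
        pos = (rng.random((n_particles, 3)) - 0.5) * box

    states = _EMPTY_STATES
    if spec.triplet_fraction > 0:
        states = _telegraph_states(
            rng, n_particles, n_steps, dt,
            spec.triplet_fraction, spec.triplet_residence_time,
        )

    return _propagate_and_weigh(
        rng,
        pos,
        n_steps,
        sigma,
        box[0] / 2.0,
        box[1] / 2.0,
        box[2] / 2.0,
        -2.0 / w0**2,
        -2.0 / z0**2,
        states,
        w_sum,
    )


def simulate_trace(config: SimulationConfig) -> TwoChannelTrace:
    """Simulate one two-channel photon-count trace.

    Returns a :class:`TwoChannelTrace` whose metadata records the seed, the
    optics, and the realized particle count per species.  Identical
    configurations (including the seed) produce bit-identical traces.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_bins = config.n_bins
    spb = config.steps_per_bin
    n_steps = n_bins * spb
    dt = config.time_step

    rate_green = np.zeros(n_steps)
    rate_red = np.zeros(n_steps)
    realized: list[int] = []
    for spec in config.species:
        if config.fixed_particle_count:
            n_p = int(round(spec.mean_particle_count_in_box))
        else:
            n_p = int(rng.poisson(spec.mean_particle_count_in_box))
        realized.append(n_p)
        w_sum = _species_weight_trace(rng, spec, config, n_p, n_steps)
        if spec.brightness_green > 0:
            rate_green += spec.brightness_green * w_sum
        if spec.brightness_red > 0:
            rate_red += spec.brightness_red * w_sum

    rate_green, rate_red = apply_crosstalk(rate_green, rate_red, config.optics)
    rate_green += config.optics.background_rate_green
    rate_red += config.optics.background_rate_red

    lam_green = rate_green.reshape(n_bins, spb).sum(axis=1) * dt
    lam_red = rate_red.reshape(n_bins, spb).sum(axis=1) * dt
    counts_green = rng.poisson(lam_green)
    counts_red = rng.poisson(lam_red)

    metadata = {
        "rng_seed": config.rng_seed,
        "bin_time": config.bin_time,
        "time_step": config.time_step,
        "duration": config.duration,
        "box_edge_lengths": list(config.box_edge_lengths),
        "waist_radial_w0": config.optics.waist_radial_w0,
        "waist_axial_z0": config.optics.waist_axial_z0,
        "structure_parameter": config.optics.structure_parameter,
        "realized_particle_counts": realized,
        "species_labels": [s.label_kind for s in config.species],
    }
    return TwoChannelTrace(
        bin_time=config.bin_time,
        counts_green=counts_green,
        counts_red=counts_red,
        metadata=metadata,
    )
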