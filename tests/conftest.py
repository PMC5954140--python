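import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fccs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def optics():
    """Typical calibrated confocal volume: w0 = 0.25 um, z0 = 1.25 um, s = 5."""
    return fccs.OpticsSpec(waist_radial_w0=0.25, waist_axial_z0=1.25)


def tiled_trace(pattern_green, pattern_red, reps=None, bin_time=1.0):
    """Periodic extension of a short count pattern to a valid trace length.

    For patterns repeated an integer number of times the per-lag symmetric
    normalization reproduces the single-period correlation values exactly at
    lags that are multiples of the period offset, which makes hand-computed
    examples usable despite the 100-bin minimum trace length.
    """
    pattern_green = list(pattern_green)
    pattern_red = list(pattern_red)
    if reps is None:
        reps = -(-120 // len(pattern_green))
    return fccs.TwoChannelTrace(
        bin_time=bin_time,
        counts_green=np.tile(pattern_green, reps),
        counts_red=np.tile(pattern_red, reps),
    )


@pytest.fixture(scope="session")
def single_species_trace(optics):
    """One green-only species, moderate statistics; reused across tests."""
    species = fccs.SpeciesSpec(
        "green_only",
        diffusion_coefficient=1.0,
        mean_particle_count_in_box=100.0,
        brightness_green=2e4,
    )
    config = fccs.SimulationConfig(
        species=(species,),
        optics=optics,
        box_edge_lengths=(3.0, 3.0, 5.0),
        duration=10.0,
        time_step=2e-4,
        bin_time=2e-4,
        rng_seed=1234,
    )
    return fccs.simulate_trace(config), config, species
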