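"""End-to-end orchestration: simulate -> correlate -> fit -> rca -> compare.

A :class:`PipelineConfig` describes one experiment: shared acquisition
settings (optics, box, timing), one or more named conditions (species
mixtures, number of cells each), correlator/fit/RCA settings, and pairwise
group comparisons.  :func:`run_pipeline` executes the stages in order,
writes every intermediate artifact (traces, curves, fits, the interaction
table, comparison JSONs) under an output directory, and records a manifest
with SHA-256 checksums and the exact per-cell seeds.

Every random draw flows from the single global seed through
``numpy.random.SeedSequence(global_seed, condition_index, cell_index)``;
rerunning an identical config reproduces byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .correlate import estimate_curve, segment_errors
from .exceptions import ConfigError, PipelineError
from .fitmodel import fit_curve
from .interaction import FCCSMeasurement, compare_groups, compute_rca
from .simulate import OpticsSpec, SimulationConfig, SpeciesSpec, simulate_trace

__all__ = [
    "CorrelatorSettings",
    "FitSettings",
    "RCASettings",
    "ConditionSpec",
    "PipelineConfig",
    "run_pipeline",
    "simulation_config_from_dict",
    "load_pipeline_config",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelatorSettings:
    estimator: str = "multitau"
    points_per_stage: int = 16
    n_segments: int = 10

    def __post_init__(self):
        if self.estimator not in ("multitau", "direct"):
            raise ConfigError("estimator must be 'multitau' or 'direct'")
        if self.n_segments < 3:
            raise ConfigError("n_segments must be >= 3")


@dataclass(frozen=True)
class FitSettings:
    n_components: int = 1
    structure_parameter: float | None = None  # None -> z0/w0 of the optics
    use_triplet: bool = False

    def __post_init__(self):
        if not 1 <= self.n_components <= 3:
            raise ConfigError("n_components must be 1, 2 or 3")
        if self.structure_parameter is not None and self.structure_parameter <= 0:
            raise ConfigError("structure_parameter must be > 0")


@dataclass(frozen=True)
class RCASettings:
    normalization: str = "red"

    def __post_init__(self):
        if self.normalization not in ("red", "green", "min_amplitude"):
            raise ConfigError("normalization must be red, green or min_amplitude")


@dataclass(frozen=True)
class ConditionSpec:
    name: str
    species: tuple[SpeciesSpec, ...]
    n_cells: int

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        if not self.name:
            raise ConfigError("condition name must be non-empty")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    optics: OpticsSpec
    box_edge_lengths: tuple[float, float, float]
    duration: float
    time_step: float
    bin_time: float
    conditions: tuple[ConditionSpec, ...]
    rng_seed: int
    correlator: CorrelatorSettings = field(default_factory=CorrelatorSettings)
    fit: FitSettings = field(default_factory=FitSettings)
    rca: RCASettings = field(default_factory=RCASettings)
    compare: tuple[tuple[str, str], ...] = ()
    fixed_particle_count: bool = False

    def __post_init__(self):
        object.__setattr__(self, "box_edge_lengths", tuple(float(e) for e in self.box_edge_lengths))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "compare", tuple(tuple(pair) for pair in self.compare))
        if not self.conditions:
            raise ConfigError("at least one condition is required")
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ConfigError("condition names must be unique")
        for a, b in self.compare:
            for label in (a, b):
                if label not in names:
                    raise ConfigError(f"compare references unknown condition {label!r}")
        # fail fast: every per-cell simulation config must validate
        for ci, cond in enumerate(self.conditions):
            self.simulation_config(ci, 0)

    def cell_seed(self, condition_index: int, cell_index: int) -> int:
        ss = np.random.SeedSequence(
            entropy=self.rng_seed, spawn_key=(condition_index, cell_index)
        )
        return int(ss.generate_state(1)[0] % (2**31))

    def simulation_config(self, condition_index: int, cell_index: int) -> SimulationConfig:
        cond = self.conditions[condition_index]
        return SimulationConfig(
            species=cond.species,
            optics=self.optics,
            box_edge_lengths=self.box_edge_lengths,
            duration=self.duration,
            time_step=self.time_step,
            bin_time=self.bin_time,
            rng_seed=self.cell_seed(condition_index, cell_index),
            fixed_particle_count=self.fixed_particle_count,
        )

    @property
    def effective_structure_parameter(self) -> float:
        if self.fit.structure_parameter is not None:
            return self.fit.structure_parameter
        return self.optics.structure_parameter

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["box_edge_lengths"] = list(self.box_edge_lengths)
        d["compare"] = [list(p) for p in self.compare]
        d["conditions"] = [
            {
                "name": c.name,
                "n_cells": c.n_cells,
                "species": [asdict(s) for s in c.species],
            }
            for c in self.conditions
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            return cls(
                optics=OpticsSpec(**d["optics"]),
                box_edge_lengths=tuple(d["box_edge_lengths"]),
                duration=d["duration"],
                time_step=d["time_step"],
                bin_time=d["bin_time"],
                conditions=tuple(
                    ConditionSpec(
                        name=c["name"],
                        n_cells=c["n_cells"],
                        species=tuple(SpeciesSpec(**s) for s in c["species"]),
                    )
                    for c in d["conditions"]
                ),
                rng_seed=d["rng_seed"],
                correlator=CorrelatorSettings(**d.get("correlator", {})),
                fit=FitSettings(**d.get("fit", {})),
                rca=RCASettings(**d.get("rca", {})),
                compare=tuple(tuple(p) for p in d.get("compare", ())),
                fixed_particle_count=d.get("fixed_particle_count", False),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid pipeline config: {exc}") from None

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise ConfigError("pipeline config must be a YAML mapping")
        return cls.from_dict(d)


def load_pipeline_config(path: Path | str) -> PipelineConfig:
    return PipelineConfig.from_yaml(Path(path).read_text())


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain mapping (YAML-friendly)."""
    try:
        return SimulationConfig(
            species=tuple(SpeciesSpec(**s) for s in d.get("species", ())),
            optics=OpticsSpec(**d["optics"]),
            box_edge_lengths=tuple(d["box_edge_lengths"]),
            duration=d["duration"],
            time_step=d["time_step"],
            bin_time=d["bin_time"],
            rng_seed=d["rng_seed"],
            fixed_particle_count=d.get("fixed_particle_count", False),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"invalid simulation config: {exc}") from None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    output_dir: Path
    table: "object"  # pandas.DataFrame of per-cell interaction results
    comparisons: dict
    manifest_path: Path


def run_pipeline(config: PipelineConfig, output_dir: Path | str) -> PipelineResult:
    """Execute all stages, writing artifacts and a checksum manifest.

    Any stage failure marks the manifest incomplete with the stage name and
    re-raises as :class:`PipelineError`.
    """
    import pandas as pd

    out = Path(output_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    (out / "curves").mkdir(exist_ok=True)
    (out / "fits").mkdir(exist_ok=True)

    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("fccs")
    root.addHandler(handler)

    config_yaml = config.to_yaml()
    config_hash = hashlib.sha256(config_yaml.encode()).hexdigest()
    (out / "config.yaml").write_text(config_yaml)

    manifest: dict = {
        "config_hash": config_hash,
        "status": "incomplete",
        "failed_stage": None,
        "stages": {},
        "seeds": {},
    }
    manifest_path = out / "manifest.json"

    def write_manifest():
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    from . import __version__

    logger.info("fccs %s, config hash %s", __version__, config_hash)
    s_fixed = config.effective_structure_parameter
    rows = []
    stage = "simulate"
    try:
        for ci, cond in enumerate(config.conditions):
            for j in range(cond.n_cells):
                cell_id = f"{cond.name}_{j:03d}"
                seed = config.cell_seed(ci, j)
                manifest["seeds"][cell_id] = seed

                stage = "simulate"
                t0 = time.perf_counter()
                sim_config = config.simulation_config(ci, j)
                trace = simulate_trace(sim_config)
                trace_path = fio.write_trace(trace, out / "traces" / f"{cell_id}.csv")
                logger.info(
                    "simulated %s (seed %d, particles %s) in %.2fs",
                    cell_id, seed,
                    trace.metadata["realized_particle_counts"],
                    time.perf_counter() - t0,
                )

                stage = "correlate"
                t0 = time.perf_counter()
                curves = {}
                for kind in ("gg", "rr", "gr"):
                    if config.correlator.estimator == "multitau":
                        curve = estimate_curve(
                            trace,
                            kind,
                            n_segments=config.correlator.n_segments,
                            points_per_stage=config.correlator.points_per_stage,
                        )
                    else:
                        curve = segment_errors(
                            trace, kind,
                            n_segments=config.correlator.n_segments,
                            estimator="direct",
                        )
                    curves[kind] = curve
                    fio.write_curve(
                        curve,
                        out / "curves" / f"{cell_id}_{kind}.csv",
                        estimator=config.correlator.estimator,
                    )
                logger.info("correlated %s in %.2fs", cell_id, time.perf_counter() - t0)

                stage = "fit"
                t0 = time.perf_counter()
                fits = {}
                for kind in ("gg", "rr", "gr"):
                    fits[kind] = fit_curve(
                        curves[kind],
                        n_components=config.fit.n_components,
                        fixed={"structure_parameter": s_fixed},
                        use_triplet=config.fit.use_triplet,
                    )
                    fio.write_fit(fits[kind], out / "fits" / f"{cell_id}_{kind}.json")
                logger.info("fitted %s in %.2fs", cell_id, time.perf_counter() - t0)

                stage = "rca"
                measurement = FCCSMeasurement(
                    curve_gg=curves["gg"],
                    curve_rr=curves["rr"],
                    curve_gr=curves["gr"],
                    fit_gg=fits["gg"],
                    fit_rr=fits["rr"],
                    fit_gr=fits["gr"],
                    cell_id=cell_id,
                    condition=cond.name,
                )
                res = compute_rca(measurement, config.rca.normalization)
                rows.append(
                    {
                        "cell_id": cell_id,
                        "condition": cond.name,
                        "rca": res.rca,
                        "nc_over_ng": res.bound_fraction_nc_over_ng,
                        "normalization": res.normalization_channel,
                    }
                )

        stage = "rca"
        table = pd.DataFrame(rows)
        table_path = out / "interaction_table.csv"
        table.to_csv(table_path, index=False)

        stage = "compare"
        comparisons = {}
        for a, b in config.compare:
            rcas_a = table.loc[table.condition == a, "rca"].to_numpy()
            rcas_b = table.loc[table.condition == b, "rca"].to_numpy()
            cmp_result = compare_groups(rcas_a, rcas_b, label_a=a, label_b=b)
            key = f"{a}_vs_{b}"
            comparisons[key] = asdict(cmp_result)
            cmp_path = out / f"comparison_{key}.json"
            cmp_path.write_text(
                json.dumps(comparisons[key], indent=2, sort_keys=True) + "\n"
            )
    except Exception as exc:
        manifest["failed_stage"] = stage
        _record_files(manifest, out)
        write_manifest()
        root.removeHandler(handler)
        handler.close()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    manifest["status"] = "complete"
    _record_files(manifest, out)
    write_manifest()
    root.removeHandler(handler)
    handler.close()
    return PipelineResult(
        output_dir=out,
        table=table,
        comparisons=comparisons,
        manifest_path=manifest_path,
    )


def _record_files(manifest: dict, out: Path):
    files = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name not in ("manifest.json", "pipeline.log"):
            files[str(path.relative_to(out))] = _sha256(path)
    manifest["stages"] = {
        "simulate": sorted(f for f in files if f.startswith("traces/")),
        "correlate": sorted(f for f in files if f.startswith("curves/")),
        "fit": sorted(f for f in files if f.startswith("fits/")),
        "rca": sorted(f for f in files if f.startswith("interaction_table")),
        "compare": sorted(f for f in files if f.startswith("comparison_")),
    }
    manifest["checksums"] = files
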