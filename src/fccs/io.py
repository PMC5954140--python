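"""Text file formats for traces, correlation curves and fit results.

All formats are plain text and documented in ``docs/formats.md``:

* trace: CSV ``bin_index,counts_green,counts_red`` plus a YAML sidecar
  (``<stem>.meta.yaml``) carrying ``bin_time`` and the acquisition metadata;
* curve: CSV ``lag_s,value,stderr`` preceded by ``# key: value`` comment
  lines (kind, source_bin_time, n_segments, estimator);
* fit: a single JSON object.

Numeric fields round-trip at full double precision (written with ``repr``).
Malformed files raise :class:`~fccs.exceptions.FormatError` naming the rule
violated and, where meaningful, the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .correlate import CorrelationCurve
from .exceptions import FormatError
from .fitmodel import DiffusionModel, FitResult
from .simulate import TwoChannelTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_curve",
    "write_curve",
    "read_fit",
    "write_fit",
    "trace_sidecar_path",
]


def trace_sidecar_path(path: Path | str) -> Path:
    """Metadata sidecar path for a trace file (``<stem>.meta.yaml``)."""
    path = Path(path)
    return path.with_name(path.stem + ".meta.yaml")


def write_trace(trace: TwoChannelTrace, path: Path | str) -> Path:
    """Write a trace CSV and its metadata sidecar; returns the CSV path."""
    path = Path(path)
    lines = ["bin_index,counts_green,counts_red"]
    for i, (g, r) in enumerate(zip(trace.counts_green, trace.counts_red)):
        lines.append(f"{i},{int(g)},{int(r)}")
    path.write_text("\n".join(lines) + "\n")
    meta = {"bin_time": float(trace.bin_time)}
    meta.update(_plain(trace.metadata))
    trace_sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_trace(path: Path | str) -> TwoChannelTrace:
    """Read a trace CSV plus sidecar back into a :class:`TwoChannelTrace`."""
    path = Path(path)
    sidecar = trace_sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing trace metadata sidecar {sidecar.name}")
    meta = yaml.safe_load(sidecar.read_text())
    if not isinstance(meta, dict) or "bin_time" not in meta:
        raise FormatError(f"sidecar {sidecar.name} must define bin_time")
    bin_time = float(meta.pop("bin_time"))

    lines = path.read_text().splitlines()
    if not lines or [c.strip() for c in lines[0].split(",")] != [
        "bin_index",
        "counts_green",
        "counts_red",
    ]:
        raise FormatError(
            "trace header must be 'bin_index,counts_green,counts_red'", line=1
        )
    greens: list[int] = []
    reds: list[int] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise FormatError("trace rows must have 3 columns", line=lineno)
        for value in parts[1:]:
            value = value.strip()
            try:
                as_float = float(value)
            except ValueError:
                raise FormatError(f"unparseable count {value!r}", line=lineno) from None
            if as_float != int(as_float):
                raise FormatError(f"non-integer counts {value!r}", line=lineno)
            if as_float < 0:
                raise FormatError(f"negative counts {value!r}", line=lineno)
        greens.append(int(float(parts[1])))
        reds.append(int(float(parts[2])))
    if len(greens) != len(reds):  # structurally impossible, kept for clarity
        raise FormatError("channel length mismatch")
    return TwoChannelTrace(
        bin_time=bin_time,
        counts_green=np.asarray(greens, dtype=np.int64),
        counts_red=np.asarray(reds, dtype=np.int64),
        metadata=meta,
    )


def write_curve(curve: CorrelationCurve, path: Path | str, estimator: str = "") -> Path:
    """Write a correlation curve as commented CSV."""
    path = Path(path)
    lines = [
        f"# kind: {curve.kind}",
        f"# source_bin_time: {float(curve.source_bin_time)!r}",
        f"# n_segments: {curve.n_segments}",
        f"# estimator: {estimator}",
        "lag_s,value,stderr",
    ]
    for lag, value, err in zip(curve.lags, curve.values, curve.stderr):
        lines.append(f"{float(lag)!r},{float(value)!r},{float(err)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_curve(path: Path | str) -> CorrelationCurve:
    """Read a commented-CSV correlation curve."""
    path = Path(path)
    header: dict[str, str] = {}
    lags: list[float] = []
    values: list[float] = []
    stderr: list[float] = []
    seen_columns = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            if ":" in line:
                key, _, value = line[1:].partition(":")
                header[key.strip()] = value.strip()
            continue
        if not seen_columns:
            if [c.strip() for c in line.split(",")] != ["lag_s", "value", "stderr"]:
                raise FormatError(
                    "curve column header must be 'lag_s,value,stderr'", line=lineno
                )
            seen_columns = True
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise FormatError("curve rows must have 3 columns", line=lineno)
        try:
            lag, value, err = (float(p) for p in parts)
        except ValueError:
            raise FormatError(f"unparseable curve row {line!r}", line=lineno) from None
        if lags and lag <= lags[-1]:
            raise FormatError(
                f"lag column must be strictly increasing, got {lag} after {lags[-1]}",
                line=lineno,
            )
        lags.append(lag)
        values.append(value)
        stderr.append(err)
    if "kind" not in header:
        raise FormatError("curve file must carry a '# kind:' header")
    if not lags:
        raise FormatError("curve file holds no data rows")
    return CorrelationCurve(
        kind=header["kind"],
        lags=np.asarray(lags),
        values=np.asarray(values),
        stderr=np.asarray(stderr),
        n_segments=int(header.get("n_segments", 1)),
        source_bin_time=float(header.get("source_bin_time", 0.0)),
    )


def write_fit(fit: FitResult, path: Path | str) -> Path:
    """Serialize a fit result to JSON."""
    path = Path(path)
    payload = {
        "model": {
            "n_particles": fit.model.n_particles,
            "components": [list(c) for c in fit.model.components],
            "structure_parameter": fit.model.structure_parameter,
            "triplet_fraction": fit.model.triplet_fraction,
            "triplet_time": fit.model.triplet_time,
        },
        "stderr": fit.stderr,
        "fixed": fit.fixed,
        "reduced_chi_square": fit.reduced_chi_square,
        "converged": fit.converged,
        "n_function_evals": fit.n_function_evals,
        "weighted": fit.weighted,
        "warnings": list(fit.warnings),
        "residuals": [float(r) for r in np.atleast_1d(fit.residuals)],
        "lags": [float(v) for v in np.atleast_1d(fit.lags)] if fit.lags is not None else None,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_fit(path: Path | str) -> FitResult:
    """Read a JSON fit result back into a :class:`FitResult`."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid fit JSON: {exc}") from None
    try:
        m = payload["model"]
        model = DiffusionModel(
            n_particles=m["n_particles"],
            components=tuple(tuple(c) for c in m["components"]),
            structure_parameter=m["structure_parameter"],
            triplet_fraction=m.get("triplet_fraction", 0.0),
            triplet_time=m.get("triplet_time", 0.0),
        )
        return FitResult(
            model=model,
            stderr=dict(payload["stderr"]),
            fixed=dict(payload["fixed"]),
            reduced_chi_square=payload["reduced_chi_square"],
            residuals=np.asarray(payload["residuals"], dtype=float),
            converged=payload["converged"],
            n_function_evals=payload["n_function_evals"],
            weighted=payload.get("weighted", True),
            warnings=tuple(payload.get("warnings", ())),
            lags=np.asarray(payload["lags"], dtype=float)
            if payload.get("lags") is not None
            else None,
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"fit JSON missing field: {exc}") from None


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML/JSON emission."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
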