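"""Plain-text I/O: traces, trajectories, titrations, parameter configs and
fit-result tables.

One trace-file dialect is used throughout: two whitespace-delimited columns
``time_s  signal`` preceded by ``#``-prefixed header lines carrying
``key=value`` metadata (condition, seed, config hash).  Parameter sets
travel as flat ``key = value`` config files using the canonical names
``k1, k_minus1, KD1, KD2, k3, k4, k5a, k5b, n_sites, variant, branch``.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fret import TitrationIsotherm
from .globalfit import FitResult
from .mechanism import StateTrajectory
from .params import ExperimentCondition, RateParameterSet
from .tracefit import KineticTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_trajectory",
    "write_params",
    "read_params",
    "write_titration",
    "read_titration",
    "fit_result_table",
    "write_manifest",
    "config_hash",
]

#: Table-2-style event labels for the report
EVENT_LABELS = {
    "k1": "ATP binding (distal sites)",
    "k_minus1": "ATP dissociation",
    "KD1": "",
    "KD2": "ATP binding (proximal sites)",
    "k3": "ATP hydrolysis",
    "k4": "Pi release",
    "k5a": "ADP release (two active sites/turnover)",
    "k5b": "ADP release (four active sites/turnover)",
    "n_sites": "Burst ATPase sites",
}

PARAM_KEYS = ("k1", "k_minus1", "KD1", "KD2", "k3", "k4", "k5a", "k5b",
              "n_sites")


def config_hash(mapping: dict) -> str:
    """Short deterministic hash of a flat config mapping."""
    text = "\n".join(f"{k}={mapping[k]}" for k in sorted(mapping))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _header_lines(meta: dict) -> list[str]:
    return [f"# {k}={v}" for k, v in meta.items()]


def write_trace(path, trace: KineticTrace, extra_meta: dict | None = None) -> None:
    meta: dict = {}
    if trace.condition is not None:
        meta.update(asdict(trace.condition))
    meta["n_averaged"] = trace.n_averaged
    meta["signal_kind"] = trace.signal_kind
    if trace.warnings:
        meta["warnings"] = ";".join(trace.warnings)
    if extra_meta:
        meta.update(extra_meta)
    meta["config_hash"] = config_hash({k: str(v) for k, v in meta.items()})
    lines = _header_lines(meta)
    lines.append("# time_s signal")
    for t, y in zip(trace.times, trace.signal):
        lines.append(f"{t:.9g} {y:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_headers(path) -> tuple[dict, int]:
    meta, n_header = {}, 0
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.startswith("#"):
            break
        n_header = i + 1
        body = line[1:].strip()
        if "=" in body:
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta, n_header


_COND_FIELDS = {
    "enzyme_total": float, "atp_total": float, "dna": str, "dna_conc": float,
    "chase": str, "chase_conc": float, "mant_conc": float,
    "temperature_note": str,
}


def read_trace(path) -> KineticTrace:
    meta, n_header = _parse_headers(path)
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed trace file {path}: {exc}") from exc
    if data.shape[1] != 2:
        raise ValueError(
            f"malformed trace file {path}: expected 2 columns after line "
            f"{n_header}, got {data.shape[1]}"
        )
    cond_kwargs = {
        k: cast(meta[k]) for k, cast in _COND_FIELDS.items() if k in meta
    }
    condition = ExperimentCondition(**cond_kwargs) if cond_kwargs else None
    warnings = tuple(meta["warnings"].split(";")) if "warnings" in meta else ()
    return KineticTrace(
        times=data[:, 0], signal=data[:, 1], condition=condition,
        n_averaged=int(meta.get("n_averaged", 1)),
        signal_kind=meta.get("signal_kind", "pi_concentration"),
        warnings=warnings,
    )


def write_trajectory(path, traj: StateTrajectory) -> None:
    cols = {"time_s": traj.times}
    for i, name in enumerate(traj.state_names):
        cols[f"state:{name}"] = traj.state_fractions[:, i]
    cols["pi_uM"] = traj.cumulative_pi
    cols["adp_uM"] = traj.cumulative_adp
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_params(path, params: RateParameterSet, variant: str | None = None,
                 branch: str | None = None, extra: dict | None = None) -> None:
    lines = [f"{k} = {getattr(params, k)!r}" for k in PARAM_KEYS]
    if variant is not None:
        lines.append(f"variant = {variant}")
    if branch is not None:
        lines.append(f"branch = {branch}")
    if extra:
        lines += [f"{k} = {v}" for k, v in extra.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path) -> tuple[RateParameterSet, dict]:
    """Read a parameter config; returns (params, other-keys mapping)."""
    values: dict[str, float] = {}
    other: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        k, v = (s.strip() for s in line.split("=", 1))
        if k in PARAM_KEYS:
            values[k] = float(v)
        else:
            other[k] = v
    missing = set(PARAM_KEYS) - {"KD1"} - set(values)
    if missing:
        raise ValueError(f"config missing parameters: {sorted(missing)}")
    return RateParameterSet(**values), other


def write_titration(path, iso: TitrationIsotherm) -> None:
    lines = [f"# enzyme_total={iso.enzyme_total}", "# ligand_uM efret sem"]
    sem = (iso.replicate_sem if iso.replicate_sem is not None
           else np.zeros_like(iso.efret))
    for lig, e, s in zip(iso.ligand_total, iso.efret, sem):
        lines.append(f"{lig:.9g} {e:.9g} {s:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_titration(path) -> TitrationIsotherm:
    """Read a titration table; reduced mode (ligand_uM, efret, sem) or raw
    mode (ligand_uM, f_d, f_da), detected from the header comment."""
    meta, _ = _parse_headers(path)
    data = np.loadtxt(path, comments="#", ndmin=2)
    enzyme = float(meta.get("enzyme_total", 0.0))
    header = [ln for ln in Path(path).read_text().splitlines()
              if ln.startswith("#")]
    raw_mode = any("f_da" in ln for ln in header)
    if data.shape[1] == 3 and raw_mode:
        from .fret import efret as _efret
        e = _efret(data[:, 2], data[:, 1])  # columns: ligand_uM f_d f_da
        return TitrationIsotherm(data[:, 0], e, enzyme_total=enzyme)
    if data.shape[1] == 3:
        return TitrationIsotherm(
            data[:, 0], data[:, 1], enzyme_total=enzyme,
            replicate_sem=data[:, 2],
        )
    raise ValueError(f"titration file {path} must have 3 columns")


def fit_result_table(result: FitResult) -> pd.DataFrame:
    """Flat table mirroring the published parameter-table layout."""
    rows = []
    for name, est in result.estimates.items():
        cb = result.contour_bounds.get(name)
        rows.append({
            "parameter": name,
            "estimate": est,
            "stderr": result.stderr.get(name, float("nan")),
            "lower": cb.lower if cb else float("nan"),
            "upper": cb.upper if cb else float("nan"),
            "open_lower": cb.open_lower if cb else False,
            "open_upper": cb.open_upper if cb else False,
            "event": EVENT_LABELS.get(name, ""),
        })
    return pd.DataFrame(rows)


def write_manifest(path, entries: list[dict]) -> None:
    """Key-value manifest for a generated fixture directory."""
    lines = []
    for entry in entries:
        lines += [f"{k}={v}" for k, v in entry.items()]
        lines.append("")
    Path(path).write_text("\n".join(lines))
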