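"""File formats: forcing/dataset/trajectory CSV, parameter YAML/JSON, fit JSON.

All CSV dialects are comma-separated with a header row, '.' decimal and
UTF-8.  Files open with a provenance comment block (lines starting with
'#': package version, config hash, seed) which readers skip; no
timestamps are written, so identical configurations produce bit-identical
output.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .estimation import Dataset, FitResult
from .params import ParameterSet
from .simulation import Trajectory
from .whole_body import ConstantSignal, ForcingSet, TabulatedSignal

__all__ = [
    "read_forcings_csv", "write_forcings_csv",
    "read_dataset_csv", "write_dataset_csv",
    "read_trajectory_csv", "write_trajectory_csv",
    "read_params", "write_params",
    "write_fit_result", "read_fit_result",
    "config_hash",
]

FORCING_SIGNALS = ("insulin", "EGP", "Ra", "E")


def config_hash(obj) -> str:
    """Short deterministic hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(extra: Mapping[str, object] | None = None) -> str:
    from . import __version__
    lines = [f"# glucoflux v{__version__}"]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", encoding="utf-8")
    except (ValueError, OSError) as exc:
        raise ParseError(f"cannot read CSV {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def _require_numeric(df: pd.DataFrame, cols: tuple[str, ...], path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        converted = pd.to_numeric(out[c], errors="coerce")
        bad = converted.isna() & out[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ParseError(f"{path}: non-numeric value in column {c!r} at line {line}")
        out[c] = converted
    return out


# -- forcings ---------------------------------------------------------------

def read_forcings_csv(path, Ib: float | None = None) -> ForcingSet:
    """Read a long-format forcing table (time_min, signal, value).

    Signals absent from the file default to the constant 0 (and insulin
    to Ib).  ``Ib`` defaults to the earliest tabulated insulin value.
    """
    df = _read_csv(path)
    _require_columns(df, ("time_min", "signal", "value"), path)
    df = _require_numeric(df, ("time_min", "value"), path)
    unknown = set(df["signal"].unique()) - set(FORCING_SIGNALS)
    if unknown:
        raise ParseError(f"{path}: unknown signal name(s) {sorted(unknown)}; "
                         f"expected one of {FORCING_SIGNALS}")
    signals: dict[str, object] = {}
    for name in FORCING_SIGNALS:
        sub = df[df["signal"] == name].sort_values("time_min")
        if len(sub) == 0:
            continue
        if len(sub) == 1:
            signals[name] = ConstantSignal(float(sub["value"].iloc[0]), name)
        else:
            signals[name] = TabulatedSignal(sub["time_min"].to_numpy(),
                                            sub["value"].to_numpy(), name)
    if "insulin" not in signals:
        raise ParseError(f"{path}: an insulin signal is required")
    if Ib is None:
        sub = df[df["signal"] == "insulin"].sort_values("time_min")
        Ib = float(sub["value"].iloc[0])
    return ForcingSet(
        I=signals["insulin"],
        EGP=signals.get("EGP", ConstantSignal(0.0, "EGP")),
        Ra=signals.get("Ra", ConstantSignal(0.0, "Ra")),
        E=signals.get("E", ConstantSignal(0.0, "E")),
        Ib=Ib,
    )


def write_forcings_csv(forcings: ForcingSet, path, times: np.ndarray | None = None) -> None:
    """Write forcings in long format; tabulated signals keep their own
    support, others are sampled on ``times`` (default 0..360 by 1 min)."""
    grid = np.arange(0.0, 361.0) if times is None else np.asarray(times, dtype=float)
    rows = []
    for name, sig in (("insulin", forcings.I), ("EGP", forcings.EGP),
                      ("Ra", forcings.Ra), ("E", forcings.E)):
        t = sig.times if isinstance(sig, TabulatedSignal) else grid
        v = np.asarray(sig(t), dtype=float)
        for ti, vi in zip(np.atleast_1d(t), np.atleast_1d(v)):
            rows.append((float(ti), name, float(vi)))
    df = pd.DataFrame(rows, columns=["time_min", "signal", "value"])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance({"format": "forcings", "Ib": forcings.Ib}))
        df.to_csv(fh, index=False)


# -- datasets ---------------------------------------------------------------

def read_dataset_csv(path) -> Dataset:
    df = _read_csv(path)
    _require_columns(df, Dataset.REQUIRED, path)
    df = _require_numeric(df, ("time_min", "value", "sem"), path)
    bad = ~(np.isfinite(df["sem"].to_numpy(dtype=float)) & (df["sem"].to_numpy(dtype=float) > 0))
    if bad.any():
        line = int(np.argmax(bad)) + 2
        raise ParseError(f"{path}: sem must be > 0 (line {line})")
    return Dataset(df[list(Dataset.REQUIRED)].reset_index(drop=True))


def write_dataset_csv(dataset: Dataset, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance({"format": "dataset", "n_points": dataset.N}))
        dataset.frame.to_csv(fh, index=False)


# -- trajectories -----------------------------------------------------------

def read_trajectory_csv(path) -> Trajectory:
    df = _read_csv(path)
    _require_columns(df, ("time_min",), path)
    return Trajectory(frame=df)


def write_trajectory_csv(traj: Trajectory, path, *, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        extra = {"format": "trajectory", "mode": traj.mode}
        if seed is not None:
            extra["seed"] = seed
        fh.write(_provenance(extra))
        traj.frame.to_csv(fh, index=False)


# -- parameters -------------------------------------------------------------

def read_params(path) -> ParameterSet:
    """Read a flat name->value parameter map from YAML or JSON, validated
    against the registry of model parameters."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ParseError(f"cannot parse parameter file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a flat mapping of parameter name -> value")
    return ParameterSet.from_dict(data)


def write_params(params: ParameterSet, path) -> None:
    """Canonical serialization: sorted keys, plain floats."""
    path = Path(path)
    data = {k: float(v) for k, v in sorted(params.as_dict().items())}
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")
        else:
            fh.write(_provenance({"format": "params", "hash": config_hash(data)}))
            yaml.safe_dump(data, fh, sort_keys=True)


# -- fit results ------------------------------------------------------------

def write_fit_result(result: FitResult, path, *, archive_path=None) -> None:
    """FitResult as JSON; the acceptable-set archive as a sibling CSV."""
    path = Path(path)
    if archive_path is None:
        archive_path = path.with_suffix(".archive.csv")
    archive_path = Path(archive_path)
    with open(archive_path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance({"format": "acceptable-set", "seed": result.seed}))
        result.acceptable_set.to_csv(fh, index=False)
    payload = {
        "parameters": result.params,
        "cost": result.cost,
        "df": result.df,
        "alpha": result.alpha,
        "threshold": result.threshold,
        "accepted": result.accepted,
        "seed": result.seed,
        "restarts": result.restarts,
        "n_evaluations": result.n_evaluations,
        "stage_costs": result.stage_costs,
        "archive": archive_path.name,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_fit_result(path) -> FitResult:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    archive = pd.read_csv(path.parent / payload["archive"], comment="#")
    return FitResult(
        params=payload["parameters"],
        cost=payload["cost"],
        df=payload["df"],
        alpha=payload["alpha"],
        threshold=payload["threshold"],
        accepted=payload["accepted"],
        acceptable_set=archive,
        seed=payload["seed"],
        restarts=payload["restarts"],
        n_evaluations=payload["n_evaluations"],
        stage_costs=payload.get("stage_costs", []),
    )
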