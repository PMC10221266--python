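"""Readers and writers for the toolkit's file dialects.

All formats are plain text: CSV for logs, calibration datasets, coefficient
histories and incubation series (comma-separated, UTF-8, dot decimal, units
encoded in the column names), JSON for fit records and reports.  A
``sep``/``decimal`` passthrough accommodates semicolon/comma-decimal
exports common to German lab software.  Malformed log rows are collected
into a rejects report rather than silently dropped; write -> read round
trips are lossless at full float precision.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration_fit import CalibrationDataset, LinearFit, PolynomialCalibration
from .errors import DomainError
from .gas_model import CalibrationProtocol, GasMixture

__all__ = [
    "SensorLog",
    "read_protocol",
    "write_protocol",
    "read_sensor_log",
    "write_sensor_log",
    "read_calibration_dataset",
    "write_calibration_dataset",
    "fit_to_record",
    "record_to_calibration",
    "write_fit_record",
    "read_fit_record",
    "read_coefficient_history",
    "write_coefficient_history",
    "read_incubation",
    "write_incubation",
    "config_hash",
]

VALID_SENSOR_IDS = {"pressure", "o2", "co2", "t_head", "t_soil"}

LOG_COLUMNS = ["timestamp", "sensor_id", "signal_v"]
DATASET_COLUMNS = ["point_id", "replicate_id", "signal_v", "measurand", "me_y"]
HISTORY_COLUMNS = ["date", "sensor", "a", "b", "se_a", "se_b"]


@dataclass(frozen=True)
class SensorLog:
    """Parsed sensor log plus the rows that failed to parse."""

    rows: pd.DataFrame
    rejects: pd.DataFrame  # columns: line, reason, raw


def read_sensor_log(path, sep: str = ",", decimal: str = ".") -> SensorLog:
    """Read a time-stamped sensor-signal log.

    Required columns: ``timestamp`` (ISO-8601), ``sensor_id`` (one of
    pressure/o2/co2/t_head/t_soil) and ``signal_v``.  Rows with unparseable
    timestamps, unknown sensor ids or non-finite signals are returned in
    the rejects table with their 1-based line numbers.  An empty file
    yields an empty log with a warning, not an exception.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, decimal=decimal, dtype=str, keep_default_na=False)
    missing = [c for c in LOG_COLUMNS if c not in raw.columns]
    if missing:
        raise DomainError(f"sensor log {path} is missing required columns: {missing}")
    if raw.empty:
        warnings.warn(f"sensor log {path} contains a header but no rows", stacklevel=2)
        return SensorLog(
            rows=pd.DataFrame(columns=LOG_COLUMNS),
            rejects=pd.DataFrame(columns=["line", "reason", "raw"]),
        )

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    signal = pd.to_numeric(raw["signal_v"], errors="coerce")
    sensor_ok = raw["sensor_id"].isin(VALID_SENSOR_IDS)

    reasons = np.select(
        [ts.isna(), ~sensor_ok, ~np.isfinite(signal.fillna(np.nan))],
        ["unparseable timestamp", "unknown sensor_id", "non-numeric signal"],
        default="",
    )
    bad = reasons != ""
    if bad.any():
        rejects = pd.DataFrame(
            {
                "line": (raw.index[bad] + 2).to_numpy(),  # 1-based, after the header
                "reason": reasons[bad],
                "raw": raw[bad].astype(str).agg(sep.join, axis=1).to_numpy(),
            }
        )
    else:
        rejects = pd.DataFrame(columns=["line", "reason", "raw"])

    rows = pd.DataFrame(
        {
            "timestamp": ts[~bad],
            "sensor_id": raw["sensor_id"][~bad],
            "signal_v": signal[~bad],
        }
    ).reset_index(drop=True)
    return SensorLog(rows=rows, rejects=rejects)


def write_sensor_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, index=False, columns=LOG_COLUMNS)


def write_calibration_dataset(ds: CalibrationDataset, path) -> None:
    rows = []
    for i, p in enumerate(ds.points):
        for j, z in enumerate(p.signals_v):
            rows.append(
                {
                    "point_id": i,
                    "replicate_id": j,
                    "signal_v": repr(z),
                    "measurand": repr(p.measurand),
                    "me_y": repr(p.me_y),
                }
            )
    pd.DataFrame(rows, columns=DATASET_COLUMNS).to_csv(path, index=False)


def read_calibration_dataset(
    path, sensor_kind: str = "pressure", sep: str = ",", decimal: str = "."
) -> CalibrationDataset:
    df = pd.read_csv(path, sep=sep, decimal=decimal, float_precision="round_trip")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"calibration dataset {path} missing columns: {missing}")
    from .calibration_fit import CalibrationPoint

    points = []
    for _, grp in df.groupby("point_id", sort=True):
        points.append(
            CalibrationPoint(
                signals_v=tuple(grp["signal_v"].astype(float)),
                measurand=float(grp["measurand"].iloc[0]),
                me_y=float(grp["me_y"].iloc[0]),
            )
        )
    return CalibrationDataset(points=tuple(points), sensor_kind=sensor_kind)


def fit_to_record(
    fit: LinearFit, sensor: str, date: str = "", seed: int | None = None
) -> dict:
    """JSON-serializable record of a linear calibration fit."""
    rec = {
        "sensor": sensor,
        "date": date,
        "a": fit.a,
        "b": fit.b,
        "se_a": fit.se_a,
        "se_b": fit.se_b,
        "ci_a": list(fit.ci_a),
        "ci_b": list(fit.ci_b),
        "r2": fit.r_squared,
        "sigma2": fit.sigma2,
        "dw": fit.dw,
        "df": fit.df,
    }
    if seed is not None:
        rec["seed"] = seed
    return rec


def record_to_calibration(rec: dict) -> PolynomialCalibration:
    return PolynomialCalibration(
        a=rec["a"], b=rec["b"], c=rec.get("c", 0.0), d=rec.get("d", 0.0),
        e=rec.get("e", 0.0),
    )


def write_fit_record(rec: dict, path) -> None:
    Path(path).write_text(json.dumps(rec, indent=2, allow_nan=True) + "\n")


def read_fit_record(path) -> dict:
    return json.loads(Path(path).read_text())


def write_coefficient_history(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    cols = [c for c in HISTORY_COLUMNS if c in out.columns]
    out.to_csv(path, index=False, columns=cols)


def read_coefficient_history(path, sep: str = ",", decimal: str = ".") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, decimal=decimal, float_precision="round_trip")
    for col in ("date", "a", "b"):
        if col not in df.columns:
            raise DomainError(f"coefficient history {path} missing column {col!r}")
    df["date"] = pd.to_datetime(df["date"])
    return df.sort_values("date").reset_index(drop=True)


def write_incubation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_incubation(path, sep: str = ",", decimal: str = ".") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, decimal=decimal, float_precision="round_trip")
    if "timestamp_h" not in df.columns:
        raise DomainError(f"incubation file {path} missing column 'timestamp_h'")
    return df


def _mixture_from_dict(d: dict) -> GasMixture:
    return GasMixture(
        frac_O2=d.get("frac_o2", 0.0),
        frac_CO2=d.get("frac_co2", 0.0),
        frac_N2=d.get("frac_n2", 0.0),
        rel_accuracy=d.get("rel_accuracy", 0.0),
    )


def read_protocol(path) -> CalibrationProtocol:
    """Read a calibration-protocol description from JSON.

    Schema: ``{"initial_gas": {...}, "injected_gas": {...}, "n_steps": int,
    "dP_pa": float | "removal_volume_ml": float,
    "chamber": {"P_pa": float, "T_k": float, "V_head_ml": float}}``.
    Gas dicts carry ``frac_o2``/``frac_co2``/``frac_n2`` (fractions summing
    to 1) and optionally ``rel_accuracy``.  When a removal volume is given
    instead of a pressure increment, dP is derived isothermally as
    ``P * dV / V_head``.
    """
    d = json.loads(Path(path).read_text())
    chamber = d["chamber"]
    P = float(chamber["P_pa"])
    V_head_ml = float(chamber["V_head_ml"])
    if "dP_pa" in d:
        dP = float(d["dP_pa"])
    elif "removal_volume_ml" in d:
        dP = P * float(d["removal_volume_ml"]) / V_head_ml
    else:
        raise DomainError(f"protocol {path} needs 'dP_pa' or 'removal_volume_ml'")
    return CalibrationProtocol(
        initial=_mixture_from_dict(d["initial_gas"]),
        injected=_mixture_from_dict(d["injected_gas"]),
        n_steps=int(d["n_steps"]),
        dP_pa=dP,
        P_pa=P,
        T_k=float(chamber["T_k"]),
        V_head_m3=V_head_ml * 1e-6,
    )


def write_protocol(protocol: CalibrationProtocol, path) -> None:
    d = {
        "initial_gas": {
            "frac_o2": protocol.initial.frac_O2,
            "frac_co2": protocol.initial.frac_CO2,
            "frac_n2": protocol.initial.frac_N2,
            "rel_accuracy": protocol.initial.rel_accuracy,
        },
        "injected_gas": {
            "frac_o2": protocol.injected.frac_O2,
            "frac_co2": protocol.injected.frac_CO2,
            "frac_n2": protocol.injected.frac_N2,
            "rel_accuracy": protocol.injected.rel_accuracy,
        },
        "n_steps": protocol.n_steps,
        "dP_pa": protocol.dP_pa,
        "chamber": {
            "P_pa": protocol.P_pa,
            "T_k": protocol.T_k,
            "V_head_ml": protocol.V_head_m3 * 1e6,
        },
    }
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def config_hash(obj) -> str:
    """Short SHA-256 digest of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
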