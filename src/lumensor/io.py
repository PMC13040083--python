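"""Readers/writers for traces and reports, and run-configuration handling.

Interchange is plain delimited text for auditability: one CSV per trace with
columns ``frame, time_s, I_DD, I_DA, I_AA`` plus a ground-truth/metadata
sidecar table per directory.  Unit policy (stated in every summary): times in
seconds, concentrations in uM, lengths in nm, volumes in aL.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict
from pydantic import ValidationError as PydanticValidationError

from .errors import ConfigError, DataError
from .kinetics import CalibrationCurve
from .params import PhotophysicsModel, SensorKinetics
from .trace import Trace

TRACE_COLUMNS = ["frame", "time_s", "I_DD", "I_DA", "I_AA"]
UNIT_POLICY = {"time": "s", "concentration": "uM", "length": "nm", "volume": "aL"}


# ---------------------------------------------------------------------------
# Trace round trip
# ---------------------------------------------------------------------------

def write_traces(traces: list[Trace], directory) -> list[Path]:
    """One CSV per trace plus a ``traces_metadata.csv`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    meta_rows = []
    for i, tr in enumerate(traces):
        path = directory / f"trace_{i:05d}.csv"
        tr.to_frame().to_csv(path, index=False, float_format="%.10g")
        paths.append(path)
        row = {"file": path.name, "frame_time": tr.frame_time}
        for k, v in tr.metadata.items():
            if np.isscalar(v) or v is None:
                row[k] = v
        meta_rows.append(row)
    pd.DataFrame(meta_rows).to_csv(directory / "traces_metadata.csv", index=False)
    return paths


def _read_one_trace(path: Path, frame_time: float | None, metadata: dict) -> Trace:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    for col in TRACE_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna() & df[col].notna())
        if len(bad) or coerced.isna().any():
            bad_idx = bad if len(bad) else np.flatnonzero(coerced.isna())
            # +2: one for the header line, one for 1-based numbering
            lines = ", ".join(str(i + 2) for i in bad_idx[:5])
            raise DataError(
                f"{path}: non-numeric or missing value in column {col!r} "
                f"on line(s) {lines}"
            )
        df[col] = coerced
    if frame_time is None:
        times = df["time_s"].to_numpy()
        frame_time = float(times[1] - times[0]) if len(times) > 1 else 1.0
    return Trace(
        I_DD=df["I_DD"].to_numpy(), I_DA=df["I_DA"].to_numpy(),
        I_AA=df["I_AA"].to_numpy(), frame_time=frame_time, metadata=metadata,
    )


def read_traces(path) -> list[Trace]:
    """Load a trace CSV or a directory of them (with metadata sidecar)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such path: {path}")
    if path.is_file():
        return [_read_one_trace(path, None, {})]
    sidecar = path / "traces_metadata.csv"
    meta_by_file: dict = {}
    if sidecar.exists():
        for row in pd.read_csv(sidecar).to_dict("records"):
            meta_by_file[row.pop("file")] = row
    traces = []
    for f in sorted(path.glob("trace_*.csv")):
        meta = dict(meta_by_file.get(f.name, {}))
        frame_time = meta.pop("frame_time", None)
        traces.append(_read_one_trace(f, frame_time, meta))
    if not traces:
        raise DataError(f"no trace_*.csv files under {path}")
    return traces


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KineticsConfig(_Strict):
    k_on: float = 0.29
    k_close_base: float = 1.28
    k_open: float = 2.0
    E_open: float = 0.6
    E_closed: float = 0.9
    sigma_E: float = 0.06

    def to_params(self) -> SensorKinetics:
        return SensorKinetics(**self.model_dump())


class PhotophysicsConfig(_Strict):
    total_rate_donor_exc: float = 1000.0
    total_rate_acceptor_exc: float = 1000.0
    noise_model: Literal["gaussian", "poisson"] = "gaussian"
    gaussian_sd: float = 20.0
    bleach_rate_donor: float = 0.002
    bleach_rate_acceptor: float = 0.002
    background: float = 0.0

    def to_params(self) -> PhotophysicsModel:
        return PhotophysicsModel(**self.model_dump())


class CalibrationConfig(_Strict):
    """A known calibration line (as measured once for the sensor)."""

    k_on: float = 0.29
    k_on_se: float = 0.02
    k_close_base: float = 1.28
    k_close_base_se: float = 0.05
    conc_range: tuple[float, float] = (0.0, 10.0)

    def to_curve(self) -> CalibrationCurve:
        cov = np.diag([self.k_close_base_se**2, self.k_on_se**2])
        return CalibrationCurve(
            k_on=self.k_on, k_on_se=self.k_on_se,
            k_close_base=self.k_close_base,
            k_close_base_se=self.k_close_base_se,
            covariance=cov, conc_range=self.conc_range,
        )


class RunConfig(_Strict):
    """Schema-validated configuration of a simulated transport run."""

    mode: Literal["transport"] = "transport"
    seed: int
    out_dir: Optional[str] = None
    protocol: Literal["two_event_mg_atp", "atp_edta", "mg_adp_control"] = (
        "two_event_mg_atp"
    )
    n_vesicles: int = 20000
    diameter_gsd: float = 1.15
    frame_time: float = 0.1
    n_frames_per_phase: int = 3600
    kinetics: KineticsConfig = KineticsConfig()
    photophysics: PhotophysicsConfig = PhotophysicsConfig()
    calibration: CalibrationConfig = CalibrationConfig()


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except OSError as err:
        raise ConfigError(f"cannot read config {path}: {err}") from err
    return validate_config(raw)


def validate_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except PydanticValidationError as err:
        keys = sorted(
            {".".join(str(p) for p in e["loc"]) or "<root>" for e in err.errors()}
        )
        raise ConfigError(
            f"invalid configuration; offending keys: {', '.join(keys)}"
        ) from err


def config_hash(config: RunConfig) -> str:
    """Stable hash of the configuration content (field order irrelevant)."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(report, directory) -> dict:
    """Persist a TransportReport as vesicles.csv, phases.csv, summary.json."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        report.vesicles.to_csv(directory / "vesicles.csv", index=False)
        report.phases.to_csv(directory / "phases.csv", index=False)
        summary = {
            "protocol": report.protocol,
            "seed": report.seed,
            "config_hash": report.config_hash,
            "n_vesicle_rows": int(len(report.vesicles)),
            "n_phases": int(len(report.phases)),
            "units": UNIT_POLICY,
            "extras": report.extras,
        }
        with open(directory / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    except OSError as err:
        raise DataError(f"cannot write report to {directory}: {err}") from err
    return summary


def read_report(directory):
    """Re-read a persisted report (round-trip counterpart of write_report)."""
    from .transport import TransportReport

    directory = Path(directory)
    with open(directory / "summary.json") as fh:
        summary = json.load(fh)
    vesicles = pd.read_csv(directory / "vesicles.csv")
    if "flag" in vesicles.columns:  # empty flags round-trip as NaN in CSV
        vesicles["flag"] = vesicles["flag"].fillna("")
    return TransportReport(
        vesicles=vesicles,
        phases=pd.read_csv(directory / "phases.csv"),
        protocol=summary["protocol"], seed=summary["seed"],
        config_hash=summary["config_hash"], extras=summary.get("extras", {}),
    )
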