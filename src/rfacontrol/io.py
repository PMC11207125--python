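"""File formats: time-series CSV, transfer-function JSON, config and reports.

CSV time series use the header ``time_s,voltage_V,impedance_ohm``; the
reader also tolerates spreadsheet-style exports whose column names merely
start with time/volt(age)/imp(edance), case-insensitively.  Transfer
functions serialize as ``{"num": [...], "den": [...], "domain": "s"|"z",
"Ts": seconds|null}``.  Pipeline configuration is validated with pydantic;
absent objective weights fall back to the canonical (0.5, 0.6, 0.8) and the
fallback is logged.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .lti import RationalTF
from .sysid import TimeSeries

__all__ = [
    "PipelineConfig",
    "load_timeseries",
    "save_timeseries",
    "load_tf",
    "save_tf",
    "load_config",
    "save_report",
    "save_step_series",
    "save_closed_loop_sim",
]

log = logging.getLogger("rfacontrol")

_COLUMNS = {
    "time_s": ("time",),
    "voltage_V": ("volt",),
    "impedance_ohm": ("imp",),
}


def _resolve_column(df: pd.DataFrame, canonical: str) -> str:
    if canonical in df.columns:
        return canonical
    prefixes = _COLUMNS[canonical]
    for col in df.columns:
        if str(col).strip().lower().startswith(prefixes):
            return col
    raise ValueError(
        f"CSV is missing required column '{canonical}' "
        f"(or any column starting with {prefixes[0]!r}); found {list(df.columns)}"
    )


def load_timeseries(path: str | Path) -> TimeSeries:
    """Read a voltage/impedance record from CSV with schema validation."""
    df = pd.read_csv(path)
    cols = {name: _resolve_column(df, name) for name in _COLUMNS}
    sub = df[[cols["time_s"], cols["voltage_V"], cols["impedance_ohm"]]]
    sub = sub.apply(pd.to_numeric, errors="coerce")
    bad = sub.isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"{path}: non-numeric or missing values on data line(s) "
            f"{[int(i) + 2 for i in sub.index[bad][:5]]}"
        )
    return TimeSeries(
        times=sub.iloc[:, 0].to_numpy(float),
        input_u=sub.iloc[:, 1].to_numpy(float),
        output_y=sub.iloc[:, 2].to_numpy(float),
    )


def save_timeseries(ts: TimeSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": ts.times,
            "voltage_V": ts.input_u,
            "impedance_ohm": ts.output_y,
        }
    ).to_csv(path, index=False)


def load_tf(path: str | Path) -> RationalTF:
    with open(path) as fh:
        return RationalTF.from_json_dict(json.load(fh))


def save_tf(tf: RationalTF, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(tf.to_json_dict(), fh, indent=2)


def save_step_series(series, path: str | Path) -> None:
    """Two-column CSV (time_s, value) of a simulated step response."""
    pd.DataFrame({"time_s": series.t, "value": series.y}).to_csv(path, index=False)


def save_closed_loop_sim(sim, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": sim.t, "y": sim.y, "e": sim.e, "v": sim.v}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


class SyntheticSpec(BaseModel):
    """Overrides for the phenomenological roll-off generator defaults."""

    model_config = {"extra": "forbid"}

    baseline_impedance: float = 80.0
    early_decline_fraction: float = 0.15
    rolloff_time: float = 318.0
    rolloff_sharpness: float = 0.2
    plateau_impedance: float = 1000.0
    voltage_level: float = 26.0
    noise_sd: float = 1.5
    sampling_jitter_sd: float = 0.15
    duration: float = 330.0


class WeightsSpec(BaseModel):
    model_config = {"extra": "forbid"}

    alpha: float = Field(0.5, ge=0)
    beta: float = Field(0.6, ge=0)
    gamma: float = Field(0.8, ge=0)


class SimSpec(BaseModel):
    model_config = {"extra": "forbid"}

    horizon_s: float = Field(10.0, gt=0)
    dt_s: float = Field(1e-3, gt=0)
    penalty: float = Field(1e6, gt=0)


class PSOSpec(BaseModel):
    model_config = {"extra": "forbid"}

    swarm_size: int = Field(30, ge=1)
    max_iter: int = Field(10, ge=1)
    x_min: float = 0.01
    x_max: float = 10.0
    c1: float = 2.05
    c2: float = 2.05
    omega_start: float = 0.9
    omega_end: float = 0.1


class PipelineConfig(BaseModel):
    model_config = {"extra": "forbid"}

    #: "synthetic" or a path-bearing CSV source
    source: str = "synthetic"
    estimation_csv: str | None = None
    validation_csv: str | None = None
    synthetic: SyntheticSpec = SyntheticSpec()
    resample_rate_hz: float = Field(1.0, gt=0)
    na: int = Field(20, ge=1)
    nb: int = Field(20, ge=1)
    n_poles: int = Field(9, ge=1)
    n_zeros: int = Field(8, ge=0)
    #: "as_printed" | "routh_refined" | "estimated"
    plant: str = "routh_refined"
    weights: WeightsSpec = WeightsSpec()
    sim: SimSpec = SimSpec()
    pso: PSOSpec = PSOSpec()
    runs: int = Field(1, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.source not in ("synthetic", "csv"):
            raise ValueError("source must be 'synthetic' or 'csv'")
        if self.source == "csv" and not self.estimation_csv:
            raise ValueError("source 'csv' requires estimation_csv")
        if self.plant not in ("as_printed", "routh_refined", "estimated"):
            raise ValueError("plant must be as_printed, routh_refined or estimated")
        return self


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = json.load(fh)
    if "weights" not in raw:
        log.info("objective weights absent from config; using defaults (0.5, 0.6, 0.8)")
    return PipelineConfig.model_validate(raw)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_report(report: dict, path: str | Path) -> None:
    """Write a pipeline report as JSON (deterministic for a fixed input)."""
    with open(path, "w") as fh:
        json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
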