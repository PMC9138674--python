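"""Readers and writers for the package's plain-text dialects.

Dialects (all CSV with mandatory headers, floats written with 9 significant
digits for lossless-enough round trips of instrument-scale values):

* time series:   ``time_h,well,frequency_hz,channel,value`` with channel in
  {``resistance_ohm``, ``capacitance_nf``};
* frequency scan: ``well,frequency_hz,z_real_ohm,z_imag_ohm,state``;
* RTC (micromotion): ``t_s,well,resistance_ohm`` (one frequency per file);
* plate readings: ``well,substrate,rfu_experimental,rfu_negative,rfu_positive``.

Run configuration is YAML with unknown keys rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import TimeSeriesTrace
from .micromotion import MicromotionSeries
from .model import FrequencyScan
from .physchem import PlateReadings

__all__ = [
    "ParseError",
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "read_scans",
    "write_scans",
    "read_rtc",
    "write_rtc",
    "read_plate",
    "load_config",
    "FLOAT_FMT",
]

FLOAT_FMT = "%.9g"

_CHANNEL_FOR_MODALITY = {
    "attachment_capacitance": "capacitance_nf",
    "migration_resistance": "resistance_ohm",
    "micromotion_resistance": "resistance_ohm",
}


class ParseError(ValueError):
    """A file does not conform to its dialect."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    if df.empty:
        raise ParseError(f"{path}: no records")


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

def read_timeseries(path) -> list[TimeSeriesTrace]:
    """Read a time-series CSV into traces grouped by (well, frequency, channel).

    Rows may arrive in any order; times are sorted per trace.  Duplicate
    timestamps within a trace are rejected with the offending row number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: no records") from None
    _require_columns(df, ["time_h", "well", "frequency_hz", "channel", "value"], path)
    bad = ~df["channel"].isin(_CHANNEL_FOR_MODALITY.values())
    if bad.any():
        row = int(df.index[bad][0]) + 2  # header is line 1
        raise ParseError(f"{path}: unknown channel {df['channel'][bad].iloc[0]!r} at line {row}")
    traces = []
    for (well, freq, channel), grp in df.groupby(["well", "frequency_hz", "channel"], sort=True):
        grp = grp.sort_values("time_h", kind="stable")
        dup = grp["time_h"].duplicated()
        if dup.any():
            row = int(grp.index[dup][0]) + 2
            raise ParseError(f"{path}: non-monotone (duplicate) time at line {row}")
        if channel == "capacitance_nf":
            modality = "attachment_capacitance"
        else:
            modality = "migration_resistance"
        traces.append(
            TimeSeriesTrace(
                time_h=grp["time_h"].to_numpy(float),
                values=grp["value"].to_numpy(float),
                frequency_hz=float(freq),
                modality=modality,
                well_id=str(well),
            )
        )
    return traces


def write_timeseries(traces, path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "time_h": tr.time_h,
                    "well": tr.well_id,
                    "frequency_hz": tr.frequency_hz,
                    "channel": _CHANNEL_FOR_MODALITY[tr.modality],
                    "value": tr.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# frequency scans
# ---------------------------------------------------------------------------

def read_scans(path) -> list[FrequencyScan]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: no records") from None
    _require_columns(df, ["well", "frequency_hz", "z_real_ohm", "z_imag_ohm", "state"], path)
    scans = []
    for (well, state), grp in df.groupby(["well", "state"], sort=True):
        grp = grp.sort_values("frequency_hz", kind="stable")
        scans.append(
            FrequencyScan(
                frequencies=grp["frequency_hz"].to_numpy(float),
                impedance=grp["z_real_ohm"].to_numpy(float)
                + 1j * grp["z_imag_ohm"].to_numpy(float),
                coverage_state=str(state),
                well_id=str(well),
            )
        )
    return scans


def write_scans(scans, path) -> None:
    frames = []
    for sc in scans:
        frames.append(
            pd.DataFrame(
                {
                    "well": sc.well_id,
                    "frequency_hz": sc.frequencies,
                    "z_real_ohm": sc.impedance.real,
                    "z_imag_ohm": sc.impedance.imag,
                    "state": sc.coverage_state,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# RTC / micromotion
# ---------------------------------------------------------------------------

def read_rtc(path) -> list[MicromotionSeries]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: no records") from None
    _require_columns(df, ["t_s", "well", "resistance_ohm"], path)
    out = []
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("t_s", kind="stable")
        t = grp["t_s"].to_numpy(float)
        dt = np.diff(t)
        if t.size > 1 and not np.allclose(dt, dt[0]):
            raise ParseError(f"{path}: RTC sampling interval not fixed for well {well}")
        out.append(
            MicromotionSeries(
                values=grp["resistance_ohm"].to_numpy(float),
                interval_s=float(dt[0]) if t.size > 1 else 1.0,
                well_id=str(well),
            )
        )
    return out


def write_rtc(series_list, path) -> None:
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "t_s": np.arange(s.n_points) * s.interval_s,
                    "well": s.well_id,
                    "resistance_ohm": s.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# plate readings
# ---------------------------------------------------------------------------

def read_plate(path) -> dict:
    """Read plate readings keyed by substrate -> list of PlateReadings."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: no records") from None
    _require_columns(
        df, ["well", "substrate", "rfu_experimental", "rfu_negative", "rfu_positive"], path
    )
    out: dict = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["substrate"]), []).append(
            PlateReadings(
                experimental_rfu=float(row["rfu_experimental"]),
                negative_control_rfu=float(row["rfu_negative"]),
                positive_control_rfu=float(row["rfu_positive"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of an end-to-end simulated-and-analysed run."""

    array_type: str = "8W1E"
    seed: int = 0
    wells_per_substrate: int = 4
    substrates: tuple = ("control", "collagen", "PLL", "PDL")
    noise_sd: float = 0.01
    migration_mode: str = "fast"
    scan_noise_sd: float = 0.0
    cap_thresholds: tuple | None = None  # (upper, lower); default per array
    baseline_frac: float = 0.1
    plateau_frac: float = 0.9
    fit_n_starts: int = 4
    out_dir: str = "ecisfence_run"
    include: tuple = ("attachment", "migration", "micromotion", "scan")

    def __post_init__(self) -> None:
        if self.array_type not in ("8W1E", "8W10E"):
            raise ValueError(f"unknown array type {self.array_type!r}")
        if self.wells_per_substrate < 1:
            raise ValueError("wells_per_substrate must be at least 1")


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    for key in ("substrates", "cap_thresholds", "include"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)
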