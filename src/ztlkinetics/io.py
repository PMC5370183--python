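"""CSV readers/writers and YAML run configuration.

One tabular dialect throughout: comma-separated, UTF-8, explicit header,
decimal point.  Time is always hours; a ``time_unit="s"`` flag converts
seconds at ingestion.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import AbsorbanceTrace, ProteinTimecourse
from .model import SimulationResult

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "read_traces",
    "write_traces",
    "write_simulation",
    "load_config",
    "ConfigError",
]

TIMECOURSE_COLUMNS = ("time_hr", "level", "replicate", "condition", "species")
TRACE_COLUMNS = ("time_hr", "replicate")  # plus at least one of a450/a478


class ConfigError(ValueError):
    """Invalid or unknown configuration keys."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _convert_time(values: np.ndarray, time_unit: str) -> np.ndarray:
    if time_unit == "hr":
        return values
    if time_unit == "s":
        return values / 3600.0
    raise ValueError(f"time_unit must be 'hr' or 's', got {time_unit!r}")


def read_timecourse(path, time_unit: str = "hr") -> ProteinTimecourse:
    """Read one species/condition protein time course from CSV.

    Expects columns time_hr, level, replicate, condition, species; errors
    name the offending data row (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TIMECOURSE_COLUMNS, path)
    bad = df.index[df["level"] <= 0]
    if len(bad):
        raise ValueError(
            f"{path}: non-positive level at data row {int(bad[0]) + 1}"
        )
    for col in ("condition", "species"):
        uniq = df[col].unique()
        if len(uniq) != 1:
            raise ValueError(
                f"{path}: expected a single {col} per file, found {list(uniq)}"
            )
    # times must be sorted within each replicate
    for rep, sub in df.groupby("replicate"):
        t = sub["time_hr"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            row = int(sub.index[np.flatnonzero(np.diff(t) < 0)[0] + 1]) + 1
            raise ValueError(f"{path}: unsorted times (replicate {rep}, data row {row})")
    return ProteinTimecourse(
        species=str(df["species"].iloc[0]),
        condition=str(df["condition"].iloc[0]),
        times=_convert_time(df["time_hr"].to_numpy(dtype=float), time_unit),
        levels=df["level"].to_numpy(dtype=float),
        replicates=df["replicate"].to_numpy(),
    )


def write_timecourse(tc: ProteinTimecourse, path) -> None:
    pd.DataFrame(
        {
            "time_hr": tc.times,
            "level": tc.levels,
            "replicate": tc.replicates,
            "condition": tc.condition,
            "species": tc.species,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_traces(path, time_unit: str = "hr") -> list[AbsorbanceTrace]:
    """Read absorbance recovery traces (one per replicate id) from CSV.

    Expects columns time_hr, replicate and at least one of a450/a478.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACE_COLUMNS, path)
    channels = [c for c in ("a450", "a478") if c in df.columns]
    if not channels:
        raise ValueError(f"{path}: need at least one of columns a450/a478")
    traces = []
    for rep, sub in df.groupby("replicate", sort=True):
        t = _convert_time(sub["time_hr"].to_numpy(dtype=float), time_unit)
        kwargs = {c: sub[c].to_numpy(dtype=float) for c in channels}
        traces.append(AbsorbanceTrace(times=t, replicate=rep, **kwargs))
    return traces


def write_traces(traces: list[AbsorbanceTrace], path) -> None:
    frames = []
    for tr in traces:
        d = {"time_hr": tr.times, "replicate": tr.replicate}
        for c in tr.channels:
            d[c] = tr.channel(c)
        frames.append(pd.DataFrame(d))
    out = pd.concat(frames, ignore_index=True)
    cols = ["time_hr"] + [c for c in ("a450", "a478") if c in out.columns] + ["replicate"]
    out[cols].to_csv(path, index=False, float_format="%.17g")


def write_simulation(sim: SimulationResult, path) -> None:
    sim.to_frame().to_csv(path, index=False, float_format="%.17g")


KNOWN_CONFIG_KEYS = {
    "preset", "k1", "k2", "k3", "m8", "c0", "schedule", "step", "species",
    "condition", "seed", "n_replicates", "protein_cv", "absorbance_sd",
    "channel", "free", "n_starts", "n_seeds", "t_max", "t_step", "y0",
    "amplitude", "times",
}


def load_config(path) -> dict:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ConfigError(
            f"{path}: unknown configuration key(s) {sorted(unknown)}; "
            f"known keys: {sorted(KNOWN_CONFIG_KEYS)}"
        )
    return cfg
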