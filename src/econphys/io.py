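"""Delimited-text schemas for the four input tables plus run configuration.

All tables are tab-separated with a header row; all times are seconds on
the session clock, all sizes integer drops.  Reads validate the schema and
cross-file referential integrity (every spike's unit exists in the unit
table; every trial has an event row) with named, line-located errors.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

TRIAL_COLUMNS = {
    "trial_id": int, "session_id": str, "rat_id": str,
    "blackcurrant_drops": int, "lemon_drops": int, "blackcurrant_side": str,
    "chosen_flavor": str, "chosen_side": str,
    "response_latency": float, "collection_latency": float,
    "condition": str,
}
EVENT_COLUMNS = {
    "trial_id": int, "session_id": str,
    "cue_onset": float, "choice_nosepoke": float, "reward_delivery": float,
}
SPIKE_COLUMNS = {"unit_id": int, "spike_time": float}
UNIT_COLUMNS = {"unit_id": int, "session_id": str, "region": str}


class TableFormatError(ValueError):
    """A table fails schema or referential-integrity validation."""


def _read_table(path, columns: dict, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in columns:
        if col not in df.columns:
            raise TableFormatError(
                f"{name} table {path}: missing column {col!r}")
    for col, typ in columns.items():
        if typ in (int, float):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                line = int(bad.idxmax()) + 2  # header + 1-based
                raise TableFormatError(
                    f"{name} table {path}, line {line}: non-numeric value "
                    f"in column {col!r}")
            df[col] = coerced
    return df


def read_tables(trials_path, events_path, spikes_path=None, units_path=None):
    """Read and cross-validate the session tables.

    Returns (trials, events, spikes, units); spikes/units are None when
    their paths are omitted (behavior-only runs).
    """
    trials = _read_table(trials_path, TRIAL_COLUMNS, "trial")
    events = _read_table(events_path, EVENT_COLUMNS, "event")
    missing = set(trials["trial_id"]) - set(events["trial_id"])
    if missing:
        raise TableFormatError(
            f"event table {events_path}: no events for trial ids "
            f"{sorted(missing)[:5]}")
    spikes = units = None
    if spikes_path is not None:
        if units_path is None:
            raise TableFormatError("spike table given without a unit table")
        spikes = _read_table(spikes_path, SPIKE_COLUMNS, "spike")
        units = _read_table(units_path, UNIT_COLUMNS, "unit")
        orphan = set(spikes["unit_id"]) - set(units["unit_id"])
        if orphan:
            row = int((spikes["unit_id"].isin(orphan)).idxmax()) + 2
            raise TableFormatError(
                f"spike table {spikes_path}, line {row}: unit id "
                f"{sorted(orphan)[0]} not in unit table")
    return trials, events, spikes, units


def write_tables(outdir, trials: pd.DataFrame, events: pd.DataFrame,
                 spikes: pd.DataFrame | None = None,
                 units: pd.DataFrame | None = None) -> dict:
    """Write the session tables as TSV; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("trials", trials), ("events", events),
                     ("spikes", spikes), ("units", units)):
        if df is None:
            continue
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6f")
        paths[name] = p
    return paths


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their default values.

    Defaults follow the analysis conventions documented per module: 50-ms
    bins stepped 25 ms, 500-ms pre-cue baseline, ten 500-ms epochs,
    corrected alpha 0.001, fourfold CV with five repeats, 3-s lag window
    with 50-ms smoothing and a 0.33 latency threshold, and the 12-s/5-s
    behavioral filters.
    """

    seed: int = 0
    bin_width: float = 0.050
    bin_step: float = 0.025
    baseline_s: float = 0.5
    n_epochs: int = 10
    epoch_len: float = 0.5
    alpha: float = 0.001
    response_window: tuple = (0.0, 2.0)
    svm_c: float = 1.0
    n_folds: int = 4
    n_repeats: int = 5
    lag_window: float = 3.0
    max_lag: float = 1.0
    smooth_sigma: float = 0.050
    threshold: float = 0.33
    response_filter_s: float = 12.0
    collection_filter_s: float = 5.0
    condition_col: str = "condition"
    trials_path: str | None = None
    events_path: str | None = None
    spikes_path: str | None = None
    units_path: str | None = None
    sim: dict = field(default_factory=dict)   # overrides for SimConfig

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("response_window",):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["response_window"] = list(d["response_window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
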