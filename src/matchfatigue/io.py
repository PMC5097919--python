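"""CSV schemas and round-trip readers/writers for every pipeline table.

All tables are UTF-8 CSV with a header row and "." as the decimal
separator.  Each file written here starts with a schema comment line
(``#schema=<name> v1``) which readers tolerate and verify when present.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["SCHEMAS", "read_table", "write_table", "SchemaError",
           "load_config", "save_truth"]

SCHEMA_VERSION = "v1"

#: table name -> ordered column list
SCHEMAS: dict[str, list[str]] = {
    "track": ["player_id", "t", "x", "y", "period"],
    "running_summary": ["player_id", "scope", "DC_m", "DCmin_m_per_min", "S_N", "S_T_s"],
    "ball": ["kick_id", "t", "x", "y", "z", "is_contact"],
    "crossings": ["kick_id", "x", "z"],
    "kicks": ["kick_id", "set", "speed_kmh", "vx", "vy", "vz",
              "cross_x", "cross_z", "accuracy_m", "flags"],
    "force": ["t", "force_N", "stim"],
    "emg": ["t", "mv", "stim"],
    "neuro": ["trial_id", "F_PEAK_N", "TC_N", "TS_N", "force_at_stim_N",
              "VA_pct", "corrected", "RMS_mV", "MWave_mV", "RMS_MW"],
    "breaths": ["t", "vo2", "vco2", "hr", "stage_kmh"],
    "lactate": ["period", "mmol"],
    "hr": ["t", "bpm", "period"],
    "paired": ["subject", "variable", "before", "after"],
    "effects": ["variable", "n", "before_mean", "before_sd", "after_mean",
                "after_sd", "delta_mean", "delta_sd", "t", "p", "es",
                "es_label", "swc", "pos_pct", "trivial_pct", "neg_pct",
                "inference"],
}

_NON_NUMERIC = {"player_id", "period", "kick_id", "set", "flags", "trial_id",
                "corrected", "subject", "variable", "scope", "es_label",
                "inference"}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    cols = SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema}: missing columns {missing}")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"#schema={schema} {SCHEMA_VERSION}\n")
        df[cols].to_csv(fh, index=False)


def read_table(path, schema: str) -> pd.DataFrame:
    cols = SCHEMAS[schema]
    path = Path(path)
    df = pd.read_csv(path, comment="#", encoding="utf-8")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    for c in cols:
        if c in _NON_NUMERIC:
            continue
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = converted.isna() & df[c].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise SchemaError(
                f"{path.name}: non-numeric value in column {c!r} at line {row}"
            )
        df[c] = converted
    return df[cols]


def load_config(path) -> dict:
    """Load a JSON study/simulation configuration."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def save_truth(truth, path) -> None:
    """Write a TruthRecord dataclass (or dict) as a JSON sidecar."""
    import dataclasses

    import numpy as np

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    if dataclasses.is_dataclass(truth):
        truth = dataclasses.asdict(truth)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, default=default)
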