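"""Delimited-text exchange schemas and result records.

All data cross the package boundary as comma-separated text with a header
row; units are encoded in the column names (time_min vs time_s, conc_uM)
so that kinetics (minutes) and FRAP (seconds) grids cannot be confused.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .frap import FrapTrace
from .kinetics import GelTimecourse, KineticTrace
from .partition import PartitionMeasurement

__all__ = [
    "SchemaError",
    "TableParseError",
    "SCHEMAS",
    "read_table",
    "write_table",
    "kinetic_trace_to_frame",
    "frame_to_kinetic_trace",
    "gel_to_frame",
    "frame_to_gel",
    "frap_trace_to_frame",
    "frame_to_frap_trace",
    "partition_to_frame",
    "frame_to_partition",
    "ResultRecord",
]


class SchemaError(ValueError):
    """Header does not match the declared schema."""


class TableParseError(ValueError):
    """A cell could not be parsed as the declared type."""


#: schema name -> {column: "num" | "str"}
SCHEMAS = {
    "kinetics": {"time_min": "num", "intensity": "num", "condition": "str"},
    "gel": {"time_min": "num", "I_cleaved": "num", "I_uncleaved": "num"},
    "frap": {"time_s": "num", "intensity": "num", "mode": "str",
             "radius_um": "num"},
    "partition": {"I_coac": "num", "I_sup": "num", "V_coac_ul": "num",
                  "V_ini_ul": "num", "c_ini_uM": "num"},
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a delimited-text table against a named schema.

    Missing files, empty files, missing columns and non-numeric cells each
    raise a distinct, named error; the parse error cites the offending row.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; available: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise TableParseError(f"{path}: file is empty") from None
    if df.empty:
        raise TableParseError(f"{path}: table has a header but no rows")
    spec = SCHEMAS[schema]
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing} required by schema {schema!r}"
        )
    out = pd.DataFrame(index=df.index)
    for col, kind in spec.items():
        if kind == "num":
            values = pd.to_numeric(df[col], errors="coerce")
            # empty cells are permitted (optional fields like radius_um)
            bad = values.isna() & df[col].notna() & (df[col].str.strip() != "")
            if bad.any():
                row = int(bad.idxmax())
                raise TableParseError(
                    f"{path}: non-numeric value {df[col][row]!r} in column "
                    f"{col!r} at data row {row}"
                )
            out[col] = values.astype(float)
        else:
            out[col] = df[col]
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# object <-> frame converters

def kinetic_trace_to_frame(trace: KineticTrace) -> pd.DataFrame:
    return pd.DataFrame({
        "time_min": trace.times,
        "intensity": trace.intensities,
        "condition": trace.condition,
    })


def frame_to_kinetic_trace(df: pd.DataFrame, t0: float = 0.0) -> KineticTrace:
    condition = str(df["condition"].iloc[0]) if "condition" in df else "buffer"
    return KineticTrace(df["time_min"].to_numpy(), df["intensity"].to_numpy(),
                        condition=condition, t0=t0)


def gel_to_frame(gel: GelTimecourse) -> pd.DataFrame:
    return pd.DataFrame({
        "time_min": gel.times,
        "I_cleaved": gel.I_cleaved,
        "I_uncleaved": gel.I_uncleaved,
    })


def frame_to_gel(df: pd.DataFrame) -> GelTimecourse:
    return GelTimecourse(df["time_min"].to_numpy(),
                         df["I_cleaved"].to_numpy(),
                         df["I_uncleaved"].to_numpy())


def frap_trace_to_frame(trace: FrapTrace) -> pd.DataFrame:
    return pd.DataFrame({
        "time_s": trace.times,
        "intensity": trace.intensities,
        "mode": trace.mode,
        "radius_um": np.nan if trace.r is None else trace.r,
    })


def frame_to_frap_trace(df: pd.DataFrame, t_bleach: float = 0.0) -> FrapTrace:
    mode = str(df["mode"].iloc[0])
    r = df["radius_um"].iloc[0] if "radius_um" in df else np.nan
    return FrapTrace(df["time_s"].to_numpy(), df["intensity"].to_numpy(),
                     t_bleach=t_bleach, mode=mode,
                     r=None if pd.isna(r) else float(r))


def partition_to_frame(m: PartitionMeasurement) -> pd.DataFrame:
    return pd.DataFrame({
        "I_coac": [m.I_coac], "I_sup": [m.I_sup],
        "V_coac_ul": [m.V_coac], "V_ini_ul": [m.V_ini],
        "c_ini_uM": [m.c_ini],
    })


def frame_to_partition(df: pd.DataFrame) -> list[PartitionMeasurement]:
    return [
        PartitionMeasurement(
            I_coac=row.I_coac, I_sup=row.I_sup, c_ini=row.c_ini_uM,
            V_ini=row.V_ini_ul, V_coac=row.V_coac_ul,
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# result records

@dataclass
class ResultRecord:
    """One pipeline stage's estimates with units, diagnostics and provenance."""

    stage: str
    parameters: list = field(default_factory=list)   # dicts: name/value/unit/stderr
    diagnostics: dict = field(default_factory=dict)  # sse, n, converged ...
    provenance: dict = field(default_factory=dict)   # input, preset, seed, version

    def add(self, name: str, value: float, unit: str,
            stderr: float | None = None) -> None:
        self.parameters.append(
            {"name": name, "value": float(value), "unit": unit,
             "stderr": None if stderr is None else float(stderr)}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"stage": self.stage, **p} for p in self.parameters
        ])

    def write(self, directory: str | Path) -> Path:
        """Write the record as JSON (machine readable) and CSV (flat)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        json_path = directory / f"{self.stage}.json"
        json_path.write_text(json.dumps(asdict(self), indent=2, default=str))
        self.to_frame().to_csv(directory / f"{self.stage}.csv", index=False)
        return json_path
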