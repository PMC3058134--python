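"""Measurement tables: a TSV dialect for heteroplasmy data.

One row per measurement: subject, sample, sample type, developmental stage,
mutant load in percent, optional replicate index and pool id.  Loads are
percentages (0-100) on disk — the clinical-report convention — and fractions
in memory; the table round-trips through write/read as identical text.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MeasurementTable", "ValidationError", "read_measurements", "write_measurements", "SAMPLE_TYPES"]

SAMPLE_TYPES = frozenset(
    {
        "embryo",
        "blastomere",
        "trophectoderm",
        "amniocyte",
        "trophoblast_cell",
        "lymphocyte",
        "tissue",
        "oocyte",
    }
)

REQUIRED_COLUMNS = ("subject_id", "sample_id", "sample_type", "stage", "load_percent")
OPTIONAL_COLUMNS = ("replicate_index", "pool_id")


class ValidationError(ValueError):
    """Input table failed validation; ``errors`` lists (line, message) pairs."""

    def __init__(self, errors):
        self.errors = list(errors)
        msgs = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors[:10])
        extra = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"invalid measurement table: {msgs}{extra}")


@dataclass
class MeasurementTable:
    """Validated measurements with loads available as both percent and fraction."""

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    @property
    def loads(self) -> np.ndarray:
        """Mutant loads as fractions in [0, 1]."""
        return (self.df["load_percent"].to_numpy(dtype=float)) / 100.0

    def pools(self) -> dict[str, np.ndarray]:
        """Loads (fractions) grouped by pool_id, skipping rows without one."""
        sub = self.df[self.df["pool_id"].notna() & (self.df["pool_id"] != "")]
        return {
            str(pid): grp["load_percent"].to_numpy(dtype=float) / 100.0
            for pid, grp in sub.groupby("pool_id", sort=True)
        }

    def replicate_groups(self) -> dict[str, np.ndarray]:
        """Replicate loads (fractions) grouped by (subject, sample).

        Only rows carrying a replicate index participate; whole-sample rows
        are not replicates of themselves.
        """
        sub = self.df[self.df["replicate_index"].astype(str) != ""]
        return {
            f"{s}/{sm}": grp["load_percent"].to_numpy(dtype=float) / 100.0
            for (s, sm), grp in sub.groupby(["subject_id", "sample_id"], sort=True)
        }


def _validate(df: pd.DataFrame) -> list[tuple[int, str]]:
    errors: list[tuple[int, str]] = []
    # data lines start at 2 (line 1 is the header)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            errors.append((1, f"missing required column {col!r}"))
    if errors:
        return errors
    loads = pd.to_numeric(df["load_percent"], errors="coerce")
    for pos in np.nonzero(loads.isna().to_numpy())[0]:
        errors.append((int(pos) + 2, f"load_percent {df['load_percent'].iloc[pos]!r} is not a number"))
    bad = ((loads < 0) | (loads > 100)).to_numpy(dtype=bool)
    for pos in np.nonzero(bad)[0]:
        errors.append((int(pos) + 2, f"load_percent {loads.iloc[pos]} outside [0, 100]"))
    bad_type = ~df["sample_type"].astype(str).isin(SAMPLE_TYPES).to_numpy()
    for pos in np.nonzero(bad_type)[0]:
        errors.append((int(pos) + 2, f"unknown sample_type {df['sample_type'].iloc[pos]!r}"))
    rep = df["replicate_index"] if "replicate_index" in df.columns else pd.Series("", index=df.index)
    key = df[["subject_id", "sample_id"]].astype(str).agg("/".join, axis=1) + "/" + rep.fillna("").astype(str)
    dup = key.duplicated(keep="first").to_numpy()
    for pos in np.nonzero(dup)[0]:
        errors.append((int(pos) + 2, f"duplicate (subject, sample, replicate) key {key.iloc[pos]!r}"))
    return errors


def read_measurements(path, dialect: str = "tsv") -> MeasurementTable:
    """Read and validate a measurement table (UTF-8, header row required).

    ``dialect`` is ``"tsv"`` (primary) or ``"csv"``.  All validation failures
    are collected and reported with their line numbers.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    errors = _validate(df)
    if errors:
        raise ValidationError(errors)
    df = df.copy()
    df["load_percent"] = pd.to_numeric(df["load_percent"])
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    return MeasurementTable(df=df[list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)])


def write_measurements(table: MeasurementTable, path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, sep=sep, index=False, encoding="utf-8")


def cohort_to_table(cohort, subject_id: str = "S1", sample_type: str = "embryo", stage: str = "day3") -> MeasurementTable:
    """Render a simulated cohort as a measurement table.

    Whole-sample rows carry the censored measured loads; if the cohort has
    replicate measurements they are emitted as additional blastomere rows with
    a replicate index.
    """
    rows = []
    for i, load in enumerate(cohort.measured_loads, start=1):
        rows.append(
            {
                "subject_id": subject_id,
                "sample_id": f"E{i:02d}",
                "sample_type": sample_type,
                "stage": stage,
                "load_percent": round(100.0 * load, 4),
                "replicate_index": "",
                "pool_id": "",
            }
        )
    if cohort.replicates is not None:
        for i, reps in enumerate(cohort.replicates, start=1):
            for j, load in enumerate(reps, start=1):
                rows.append(
                    {
                        "subject_id": subject_id,
                        "sample_id": f"E{i:02d}",
                        "sample_type": "blastomere",
                        "stage": stage,
                        "load_percent": round(100.0 * load, 4),
                        "replicate_index": j,
                        "pool_id": "",
                    }
                )
    return MeasurementTable(df=pd.DataFrame(rows))
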