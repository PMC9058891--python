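"""Readers and writers for the pipeline's delimited-text formats.

All files are UTF-8 comma-separated text with a mandatory header row and
period decimals; no dialect sniffing.  The long measurement format is
``patient_id,marker,day,concentration`` with integer days (visit-based
sampling) and strictly positive concentrations; duplicate
(patient, marker, day) rows are rejected with the offending line number.
Floats are written with ``repr`` precision so that write-then-read
round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .trajectories import BiomarkerSeries, Measurement

MEASUREMENT_COLUMNS = ["patient_id", "marker", "day", "concentration"]

PathLike = Union[str, Path]


class MeasurementFormatError(ValueError):
    """Malformed measurement file; the message carries 1-based line numbers."""


def _float_fmt(x: float) -> str:
    return repr(float(x))


def read_measurements(path: PathLike) -> list[BiomarkerSeries]:
    """Read a long-format measurement file into validated series.

    Rows are grouped by (patient_id, marker) and time-sorted.  Errors name
    the offending line (header = line 1): malformed numbers, fractional or
    non-finite days, non-positive concentrations, duplicate
    (patient, marker, day) keys.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementFormatError(f"{path}: missing columns {missing}")

    problems: list[str] = []
    records: list[tuple[str, str, int, float]] = []
    seen: dict[tuple[str, str, int], int] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        pid, marker = str(row["patient_id"]), str(row["marker"])
        try:
            day_f = float(row["day"])
            conc = float(row["concentration"])
        except (TypeError, ValueError):
            problems.append(f"line {line}: non-numeric day or concentration")
            continue
        if not np.isfinite(day_f) or day_f != int(day_f):
            problems.append(f"line {line}: day must be a finite integer, got {row['day']}")
            continue
        day = int(day_f)
        if not (np.isfinite(conc) and conc > 0):
            problems.append(f"line {line}: concentration must be positive, got {row['concentration']}")
            continue
        key = (pid, marker, day)
        if key in seen:
            problems.append(
                f"line {line}: duplicate (patient_id, marker, day) {key}, first at line {seen[key]}"
            )
            continue
        seen[key] = line
        records.append((pid, marker, day, conc))

    if problems:
        raise MeasurementFormatError(f"{path}: " + "; ".join(problems))

    grouped: dict[tuple[str, str], list[tuple[int, float]]] = {}
    for pid, marker, day, conc in records:
        grouped.setdefault((pid, marker), []).append((day, conc))
    series = []
    for (pid, marker), rows in grouped.items():
        rows.sort()
        series.append(BiomarkerSeries(pid, marker, tuple(Measurement(d, c) for d, c in rows)))
    return series


def write_measurements(data: Union[pd.DataFrame, Iterable[BiomarkerSeries]], path: PathLike) -> None:
    """Write series or a long-format frame as the canonical measurement CSV."""
    if isinstance(data, pd.DataFrame):
        df = data[MEASUREMENT_COLUMNS].copy()
    else:
        rows = [
            {"patient_id": s.patient_id, "marker": s.marker, "day": m.day,
             "concentration": m.concentration}
            for s in data for m in s.measurements
        ]
        df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    df["day"] = df["day"].astype(int)
    df["concentration"] = df["concentration"].map(_float_fmt)
    df.to_csv(path, index=False)


def series_from_frame(df: pd.DataFrame) -> list[BiomarkerSeries]:
    """Build validated series from an in-memory long-format frame."""
    out = []
    for (pid, marker), g in df.groupby(["patient_id", "marker"], sort=True):
        g = g.sort_values("day")
        out.append(BiomarkerSeries(
            str(pid), str(marker),
            tuple(Measurement(int(d), float(c)) for d, c in zip(g["day"], g["concentration"])),
        ))
    return out


def read_patients(path: PathLike) -> pd.DataFrame:
    """Read the per-patient table (arm, survival endpoints, rad. PD day)."""
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise MeasurementFormatError(f"{path}: missing patient_id column")
    df["patient_id"] = df["patient_id"].astype(str)
    if "rad_pd_day" in df.columns:
        df["rad_pd_day"] = pd.to_numeric(df["rad_pd_day"], errors="coerce").astype("Float64")
    return df


def write_patients(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False)


def write_key_value(values: dict, path: PathLike) -> None:
    """Flat ``key=value`` text report (one pair per line, sorted keys)."""
    lines = [f"{k}={_float_fmt(v) if isinstance(v, float) else v}" for k, v in sorted(values.items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_key_value(path: PathLike) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            k, _, v = line.partition("=")
            out[k] = v
    return out


def write_manifest(manifest: dict, path: PathLike) -> None:
    """Deterministic JSON run manifest (sorted keys, no timestamps)."""
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
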