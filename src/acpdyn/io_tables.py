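"""Tabular I/O for residue-indexed NMR and biophysics data.

Every downstream analysis consumes one of three record shapes: a per-residue
chemical-shift record (one HSQC peak), a per-residue (x, y) series (exchange
or relaxation decay, denaturation curve, thermal melt, DSC thermogram), or a
per-residue scalar score.  This module owns parsing, validation and unit
harmonisation so the analysis modules can assume canonical units throughout:
seconds, Kelvin, molar, kcal/mol.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("acpdyn")

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Canonical internal units by physical dimension.
CANONICAL_UNITS = {"time": "s", "temperature": "K", "concentration": "M"}

#: Accepted unit tags and the (dimension, scale, offset) mapping to canonical.
_UNIT_MAP = {
    "s": ("time", 1.0, 0.0),
    "min": ("time", 60.0, 0.0),
    "K": ("temperature", 1.0, 0.0),
    "C": ("temperature", 1.0, 273.15),
    "M": ("concentration", 1.0, 0.0),
    "mM": ("concentration", 1e-3, 0.0),
    "uM": ("concentration", 1e-6, 0.0),
}


@dataclass(frozen=True, order=True)
class ResidueID:
    """A residue in 1-based mature-protein numbering (e.g. Ser36, Ile72)."""

    index: int
    aa: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")
        if self.aa not in AMINO_ACIDS:
            raise ValueError(f"unknown amino-acid code {self.aa!r}")

    @property
    def label(self) -> str:
        return f"{self.aa}{self.index}"


@dataclass(frozen=True)
class ShiftRecord:
    """One assigned backbone amide peak: chemical shifts plus intensity.

    ``intensity=None`` means the peak is absent from the spectrum -- distinct
    from an intensity of zero, so that disappearance under paramagnetic
    broadening can be recognised downstream.
    """

    rid: ResidueID
    dH: float
    dN: float
    intensity: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dH) and np.isfinite(self.dN)):
            raise ValueError(f"{self.rid.label}: chemical shifts must be finite")
        if self.intensity is not None and self.intensity < 0:
            raise ValueError(f"{self.rid.label}: intensity must be >= 0")


@dataclass
class SeriesTable:
    """An (x, y) series for one residue, with x in canonical units."""

    rid: ResidueID
    x: np.ndarray
    y: np.ndarray
    y_err: np.ndarray | None = None
    x_unit: str = "s"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y_err is not None:
            self.y_err = np.asarray(self.y_err, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError(f"{self.rid.label}: len(x) != len(y)")
        if self.x.size and np.any(np.diff(self.x) < 0):
            logger.warning("%s: unsorted x axis; sorting (stable)", self.rid.label)
            order = np.argsort(self.x, kind="stable")
            self.x = self.x[order]
            self.y = self.y[order]
            if self.y_err is not None:
                self.y_err = self.y_err[order]


@dataclass(frozen=True)
class PerResidueScore:
    """A residue-indexed scalar (logP, CSP, R2, ...) plus a significance flag."""

    rid: ResidueID
    value: float
    error: float = float("nan")
    flag: bool = False


def convert_axis(values: np.ndarray, unit: str) -> tuple[np.ndarray, str]:
    """Convert an axis to the canonical unit of its dimension.

    Converting values that already carry the canonical tag is rejected, so a
    min->s conversion can never be applied twice.
    """
    if unit not in _UNIT_MAP:
        raise ValueError(f"unknown unit tag {unit!r}")
    dim, scale, offset = _UNIT_MAP[unit]
    canonical = CANONICAL_UNITS[dim]
    if unit == canonical:
        raise ValueError(f"axis already in canonical unit {canonical!r}; refusing to convert again")
    return np.asarray(values, dtype=float) * scale + offset, canonical


# -- Sparky backbone-amide assignment grammar: e.g. "I72N-H" -----------------
_SPARKY_ASSIGNMENT = re.compile(r"^([A-Z])(\d+)N-H$")


def _parse_sparky_line(line: str, lineno: int) -> ShiftRecord:
    parts = line.split()
    if len(parts) not in (3, 4):
        raise ValueError(f"line {lineno}: expected 'assignment w1 w2 [height]', got {line!r}")
    m = _SPARKY_ASSIGNMENT.match(parts[0])
    if m is None:
        raise ValueError(f"line {lineno}: unparseable assignment {parts[0]!r}")
    aa, idx = m.group(1), int(m.group(2))
    # Sparky convention: w1 is the 15N dimension, w2 the attached 1H.
    dN, dH = float(parts[1]), float(parts[2])
    intensity = float(parts[3]) if len(parts) == 4 else None
    return ShiftRecord(ResidueID(idx, aa), dH=dH, dN=dN, intensity=intensity)


def read_peaklist(path: str | Path, dialect: str | None = None) -> list[ShiftRecord]:
    """Read a peak list as CSV, TSV or a Sparky-style list.

    ``dialect=None`` auto-detects from the extension: ``.csv`` -> csv,
    ``.tsv`` -> tsv, ``.list`` -> sparky.  Delimited rows carry columns
    (residue, aa, dH, dN[, intensity]); Sparky lines follow
    ``assignment w1 w2 [height]`` with backbone-amide assignments ``XnnN-H``.
    """
    path = Path(path)
    if dialect is None:
        dialect = {".csv": "csv", ".tsv": "tsv", ".list": "sparky"}.get(path.suffix)
        if dialect is None:
            raise ValueError(f"cannot infer dialect from extension of {path.name}")

    records: list[ShiftRecord] = []
    if dialect == "sparky":
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            records.append(_parse_sparky_line(line, lineno))
    elif dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, header=None, comment="#", skipinitialspace=True)
        if df.iloc[0].astype(str).str.lower().tolist()[0] in ("residue", "index"):
            df = df.iloc[1:].reset_index(drop=True)
        for i, row in df.iterrows():
            try:
                rid = ResidueID(int(row[0]), str(row[1]).strip())
                intensity = float(row[4]) if len(row) > 4 and pd.notna(row[4]) else None
                records.append(ShiftRecord(rid, float(row[2]), float(row[3]), intensity))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"row {i + 1} of {path.name}: {exc}") from exc
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    seen: set[int] = set()
    for rec in records:
        if rec.rid.index in seen:
            raise ValueError(f"duplicate residue index {rec.rid.index} in {path.name}")
        seen.add(rec.rid.index)
    return records


def read_series(path: str | Path, x_unit: str) -> list[SeriesTable]:
    """Read a long-format (residue, aa, x, y[, y_err]) table into per-residue series.

    The x axis is converted to the canonical unit of its dimension (time in
    seconds, temperature in Kelvin, concentration in molar); the canonical
    tag is recorded on each table.
    """
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    cols = list(df.columns[:5])
    if len(cols) < 4:
        raise ValueError(f"{path.name}: expected columns (residue, aa, x, y[, y_err])")
    if df[cols[3]].isna().all():
        raise ValueError(f"{path.name}: y column is empty")

    dim, _, _ = _UNIT_MAP[x_unit] if x_unit in _UNIT_MAP else (None, None, None)
    if dim is None:
        raise ValueError(f"unknown unit tag {x_unit!r}")
    canonical = CANONICAL_UNITS[dim]

    tables: list[SeriesTable] = []
    for (idx, aa), grp in df.groupby([cols[0], cols[1]], sort=True):
        x = grp[cols[2]].to_numpy(dtype=float)
        if x_unit != canonical:
            x, _ = convert_axis(x, x_unit)
        y = grp[cols[3]].to_numpy(dtype=float)
        y_err = grp[cols[4]].to_numpy(dtype=float) if len(cols) > 4 else None
        tables.append(SeriesTable(ResidueID(int(idx), str(aa)), x, y, y_err, x_unit=canonical))
    return tables


_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def write_scores(records: Sequence[PerResidueScore], path: str | Path) -> None:
    """Write per-residue scores as CSV with a fixed column order."""
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("residue,aa,value,error,flag\n")
        for rec in records:
            fh.write(
                f"{rec.rid.index},{rec.rid.aa},"
                f"{_FLOAT_FMT % rec.value},{_FLOAT_FMT % rec.error},{int(rec.flag)}\n"
            )


def read_scores(path: str | Path) -> list[PerResidueScore]:
    df = pd.read_csv(path)
    return [
        PerResidueScore(ResidueID(int(r.residue), r.aa), float(r.value), float(r.error), bool(r.flag))
        for r in df.itertuples()
    ]


def write_manifest(path: str | Path, **entries) -> None:
    """Write a JSON run manifest (seeds, thresholds, versions) next to outputs."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True, default=str) + "\n")
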