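"""Readers/writers for Skyline-style chromatogram, boundary and annotation
tables, plus the package's own output tables.

The chromatogram export is tab-separated with one row per transition trace
per run; the retention-time and intensity vectors are comma-delimited
strings inside single fields (Skyline's "Times"/"Intensities" report
columns). Peak boundaries and annotations are plain CSV. Column names, the
in-field vector separator and the isotope-label vocabulary are all
configurable through :class:`DialectConfig` so label-flipped or renamed
exports can be read without editing code.

Readers never silently drop data: each rejected row is returned in an
issues list with a machine-readable reason.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .datamodel import Annotation, Label, TransitionKey, TransitionTrace
from .errors import (InvalidBoundary, MissingColumn, RaggedVectors,
                     UnparseableNumber)
from .features import KEY_COLUMNS, feature_names

#: significant digits used for all numeric output (bit-stable round trips)
FLOAT_FORMAT = "%.12g"


@dataclass
class DialectConfig:
    """Column-name and encoding mapping for the three input tables."""

    file_name: str = "FileName"
    peptide: str = "PeptideModifiedSequence"
    precursor_charge: str = "PrecursorCharge"
    fragment_ion: str = "FragmentIon"
    product_charge: str = "ProductCharge"
    isotope_label: str = "IsotopeLabelType"
    times: str = "Times"
    intensities: str = "Intensities"
    min_start: str = "MinStartTime"
    max_end: str = "MaxEndTime"
    status: str = "Status"
    vector_separator: str = ","
    #: isotope-label vocabulary -> domain label ("light" is the endogenous
    #: analyte, "heavy" the spiked standard, unless the experiment flips them)
    label_map: dict = field(default_factory=lambda: {
        "light": Label.ENDOGENOUS, "heavy": Label.STANDARD})


@dataclass(frozen=True)
class BoundaryTableRow:
    file_name: str
    peptide_modified_sequence: str
    min_start_time: Optional[float]  # None == missing boundary
    max_end_time: Optional[float]

    @property
    def is_missing(self) -> bool:
        return self.min_start_time is None or self.max_end_time is None


@dataclass(frozen=True)
class RowIssue:
    """A rejected input row with its position and a machine-readable reason."""

    row_index: int
    reason: str
    detail: str = ""


def _require_columns(df: pd.DataFrame, names: Iterable[str], path) -> None:
    for name in names:
        if name not in df.columns:
            raise MissingColumn(name, str(path))


def _decode_vector(text, sep: str, row_index: int, what: str) -> np.ndarray:
    if text is None or (isinstance(text, float) and math.isnan(text)):
        raise UnparseableNumber(f"row {row_index}: empty {what} vector")
    try:
        return np.array([float(x) for x in str(text).split(sep) if x.strip() != ""],
                        dtype=float)
    except ValueError as exc:
        raise UnparseableNumber(f"row {row_index}: {what}: {exc}") from exc


def read_chromatograms(path, dialect: Optional[DialectConfig] = None
                       ) -> tuple[list[TransitionTrace], list[RowIssue]]:
    """Read a tab-separated chromatogram export into traces (boundaries
    unset). Returns (traces, issues); malformed rows land in issues rather
    than vanishing. Raises on structural problems (missing columns)."""
    dialect = dialect or DialectConfig()
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [dialect.file_name, dialect.peptide, dialect.precursor_charge,
            dialect.fragment_ion, dialect.product_charge, dialect.isotope_label,
            dialect.times, dialect.intensities]
    _require_columns(df, cols, path)
    traces: list[TransitionTrace] = []
    issues: list[RowIssue] = []
    for i, row in df.iterrows():
        try:
            label_raw = str(row[dialect.isotope_label]).strip().lower()
            if label_raw not in dialect.label_map:
                issues.append(RowIssue(i, "unknown_isotope_label", label_raw))
                continue
            times = _decode_vector(row[dialect.times], dialect.vector_separator,
                                   i, "times")
            intens = _decode_vector(row[dialect.intensities],
                                    dialect.vector_separator, i, "intensities")
            if len(times) != len(intens):
                raise RaggedVectors(
                    f"row {i}: {len(times)} times vs {len(intens)} intensities")
            key = TransitionKey(
                run_id=str(row[dialect.file_name]),
                peptide_sequence=str(row[dialect.peptide]),
                precursor_charge=int(row[dialect.precursor_charge]),
                fragment_ion=str(row[dialect.fragment_ion]),
                product_charge=int(row[dialect.product_charge]),
                label=dialect.label_map[label_raw])
            traces.append(TransitionTrace(key=key, times=times, intensities=intens))
        except RaggedVectors as exc:
            issues.append(RowIssue(i, "ragged_vectors", str(exc)))
        except UnparseableNumber as exc:
            issues.append(RowIssue(i, "unparseable_number", str(exc)))
        except (ValueError, Exception) as exc:  # noqa: B014 - row-local guard
            issues.append(RowIssue(i, type(exc).__name__, str(exc)))
    return traces, issues


def read_boundaries(path, dialect: Optional[DialectConfig] = None
                    ) -> tuple[list[BoundaryTableRow], list[RowIssue]]:
    """Read the comma-separated peak-boundary table.

    Blank start/end parse as a missing-boundary marker (row retained with
    ``is_missing``), never as zero. Rows with start >= end are rejected
    with an ``invalid_boundary`` issue.
    """
    dialect = dialect or DialectConfig()
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, [dialect.file_name, dialect.peptide,
                          dialect.min_start, dialect.max_end], path)
    rows: list[BoundaryTableRow] = []
    issues: list[RowIssue] = []
    for i, row in df.iterrows():
        def parse(v):
            if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
                return None
            try:
                return float(v)
            except ValueError as exc:
                raise UnparseableNumber(f"row {i}: {exc}") from exc
        try:
            start, end = parse(row[dialect.min_start]), parse(row[dialect.max_end])
            if start is not None and end is not None and start >= end:
                raise InvalidBoundary(f"row {i}: start {start} >= end {end}")
            rows.append(BoundaryTableRow(str(row[dialect.file_name]),
                                         str(row[dialect.peptide]), start, end))
        except InvalidBoundary as exc:
            issues.append(RowIssue(i, "invalid_boundary", str(exc)))
        except UnparseableNumber as exc:
            issues.append(RowIssue(i, "unparseable_number", str(exc)))
    return rows, issues


def read_annotations(path, dialect: Optional[DialectConfig] = None
                     ) -> list[Annotation]:
    """Read the analyst annotation CSV (Status in {ok, flag}, any case)."""
    dialect = dialect or DialectConfig()
    df = pd.read_csv(path, dtype=str)
    cols = [dialect.file_name, dialect.peptide, dialect.precursor_charge,
            dialect.fragment_ion, dialect.product_charge, dialect.status]
    _require_columns(df, cols, path)
    return [Annotation(run_id=str(r[dialect.file_name]),
                       peptide_sequence=str(r[dialect.peptide]),
                       precursor_charge=int(r[dialect.precursor_charge]),
                       fragment_ion=str(r[dialect.fragment_ion]),
                       product_charge=int(r[dialect.product_charge]),
                       status=str(r[dialect.status]))
            for _, r in df.iterrows()]


def attach_boundaries(traces: list[TransitionTrace],
                      boundaries: list[BoundaryTableRow]) -> None:
    """Set per-(run, peptide) boundaries on traces in place; traces whose
    group has no (or a missing) boundary row are left without boundaries."""
    table = {(b.file_name, b.peptide_modified_sequence): b
             for b in boundaries if not b.is_missing}
    for t in traces:
        b = table.get((t.key.run_id, t.key.peptide_sequence))
        if b is not None:
            t.boundary_start = b.min_start_time
            t.boundary_end = b.max_end_time


# --- output tables ---------------------------------------------------------

def write_features(path, features: pd.DataFrame) -> None:
    """Write features.csv: 5 key columns + 52 feature columns, fixed order."""
    cols = KEY_COLUMNS + feature_names()
    features.reindex(columns=cols).to_csv(path, index=False,
                                          float_format=FLOAT_FORMAT)


def read_features(path) -> pd.DataFrame:
    """Read a features.csv written by :func:`write_features`."""
    df = pd.read_csv(path)
    _require_columns(df, KEY_COLUMNS, path)
    missing = [c for c in feature_names() if c not in df.columns]
    if missing:
        raise MissingColumn(missing[0], str(path))
    return df


def write_table(path, df: pd.DataFrame) -> None:
    """Write any output table (predictions.csv, qc_summary.csv, ...)."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_chromatograms(path, traces: list[TransitionTrace],
                        dialect: Optional[DialectConfig] = None) -> None:
    """Write traces back out in the chromatogram-table dialect (used by the
    simulator so its output is read by the same ingestion path as real
    exports)."""
    dialect = dialect or DialectConfig()
    inverse = {}
    for raw, lab in dialect.label_map.items():
        inverse.setdefault(lab, raw)
    sep = dialect.vector_separator
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow([dialect.file_name, dialect.peptide, dialect.precursor_charge,
                    dialect.fragment_ion, dialect.product_charge,
                    dialect.isotope_label, dialect.times, dialect.intensities])
        for t in traces:
            w.writerow([
                t.key.run_id, t.key.peptide_sequence, t.key.precursor_charge,
                t.key.fragment_ion, t.key.product_charge, inverse[t.key.label],
                sep.join(FLOAT_FORMAT % v for v in t.times),
                sep.join(FLOAT_FORMAT % v for v in t.intensities)])


def write_boundaries(path, rows: list[BoundaryTableRow],
                     dialect: Optional[DialectConfig] = None) -> None:
    dialect = dialect or DialectConfig()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([dialect.file_name, dialect.peptide,
                    dialect.min_start, dialect.max_end])
        for b in rows:
            w.writerow([b.file_name, b.peptide_modified_sequence,
                        "" if b.min_start_time is None else FLOAT_FORMAT % b.min_start_time,
                        "" if b.max_end_time is None else FLOAT_FORMAT % b.max_end_time])
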