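"""CSV/GeoJSON readers and writers, schema validation, provenance sidecars."""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError

CELL_TABLE_REQUIRED = ("cell_id", "x_um", "y_um")
LESION_COLUMNS = ("patient_id", "timepoint", "sum_diameters_cm")
SURVIVAL_COLUMNS = ("patient_id", "time_months", "event", "endpoint")
AE_COLUMNS = ("patient_id", "term", "grade")
PANEL_COLUMNS = ("patient_id", "timepoint", "analyte", "value")
FLAGS_COLUMNS = ("patient_id", "timepoint", "detected")
VARIANT_COLUMNS = ("patient_id", "timepoint", "gene", "nt_change", "aa_change", "vaf_percent")


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CELL_TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing cell-table columns {missing}")
    if not any(c.endswith("_intensity") for c in df.columns):
        raise FormatError(f"{path}: no <marker>_intensity columns")
    return df


def config_hash(obj) -> str:
    """Stable hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_provenance(path, *, config: dict, seed: int, stage: str, extra: dict | None = None) -> None:
    from . import __version__

    doc = {
        "config_hash": config_hash(config),
        "seed": seed,
        "stage": stage,
        "version": __version__,
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# Validation


@dataclass
class Violation:
    severity: str  # "fatal" | "warning"
    file: str
    row: int | None
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def fatal(self) -> bool:
        return any(v.severity == "fatal" for v in self.violations)

    def add(self, severity, file, row, message):
        self.violations.append(Violation(severity, str(file), row, message))

    def to_dict(self) -> dict:
        return {
            "fatal": self.fatal,
            "violations": [
                {"severity": v.severity, "file": v.file, "row": v.row, "message": v.message}
                for v in self.violations
            ],
        }


def _check_columns(report, path, df, columns):
    ok = True
    for col in columns:
        if col not in df.columns:
            report.add("fatal", path, None, f"missing column {col!r}")
            ok = False
    return ok


def validate_inputs(paths: dict[str, str | Path]) -> ValidationReport:
    """Schema + unit-sanity checks for every supplied input file.

    ``paths`` maps input kind ("cells", "mask", "lesions", "survival",
    "aes", "panel", "flags", "variants") to a file path.  Violations carry
    row numbers (0-based data rows); fatal schema problems should abort.
    """
    report = ValidationReport()
    for kind, path in paths.items():
        path = Path(path)
        if not path.exists():
            report.add("fatal", path, None, "file does not exist")
            continue
        try:
            if kind == "mask":
                from .geometry import TumorMask

                TumorMask.from_geojson(path)
                continue
            df = pd.read_csv(path)
        except Exception as exc:  # unparseable file is fatal
            report.add("fatal", path, None, f"unreadable: {exc}")
            continue
        if kind == "cells":
            if not _check_columns(report, path, df, CELL_TABLE_REQUIRED):
                continue
            for ax in ("x_um", "y_um"):
                span = df[ax].max() - df[ax].min() if len(df) else 0.0
                if len(df) > 1 and span < 100:
                    report.add("warning", path, None,
                               f"{ax} span {span:.1f} um < 100 um; wrong units?")
        elif kind == "lesions":
            if not _check_columns(report, path, df, LESION_COLUMNS):
                continue
            big = df.index[df["sum_diameters_cm"] >= 50]
            for row in big:
                report.add("warning", path, int(row),
                           "diameter >= 50 cm; cm-for-mm confusion?")
            neg = df.index[df["sum_diameters_cm"] < 0]
            for row in neg:
                report.add("fatal", path, int(row), "negative diameter")
        elif kind == "survival":
            if not _check_columns(report, path, df, SURVIVAL_COLUMNS):
                continue
            for row in df.index[df["time_months"] < 0]:
                report.add("fatal", path, int(row), "negative survival time")
        elif kind == "aes":
            if not _check_columns(report, path, df, AE_COLUMNS):
                continue
            grades = pd.to_numeric(df["grade"], errors="coerce")
            for row in df.index[grades.isna() | ~grades.isin([1, 2, 3, 4, 5])]:
                report.add("fatal", path, int(row), "unknown adverse-event grade")
        elif kind == "panel":
            if not _check_columns(report, path, df, PANEL_COLUMNS):
                continue
            for row in df.index[pd.to_numeric(df["value"], errors="coerce").isna()]:
                report.add("fatal", path, int(row), "non-numeric analyte value")
        elif kind == "flags":
            _check_columns(report, path, df, FLAGS_COLUMNS)
        elif kind == "variants":
            if not _check_columns(report, path, df, VARIANT_COLUMNS):
                continue
            vaf = pd.to_numeric(df["vaf_percent"], errors="coerce")
            for row in df.index[vaf.isna() | (vaf < 0) | (vaf > 100)]:
                report.add("fatal", path, int(row), "malformed VAF")
        else:
            report.add("warning", path, None, f"unknown input kind {kind!r}")
    return report
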