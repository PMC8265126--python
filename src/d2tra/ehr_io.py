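"""Readers, writers and schema validation for routine-care cohort bundles.

A :class:`CohortBundle` holds the structured tables of one routine-care
extract (patients, prescriptions, laboratory results, clinical measurements,
hospital visits) together with free-text clinical letters.  On disk a bundle
is a directory of UTF-8 CSV files (one per table, ISO-8601 dates, rows sorted
by patient and date so output is diffable), a JSON-Lines file of letters and
a JSON manifest recording provenance and row counts.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalLetter",
    "CohortBundle",
    "SchemaReport",
    "BundleValidationError",
    "read_bundle",
    "write_bundle",
    "validate_schema",
]

# canonical column order per table; dates are parsed on read
TABLE_SCHEMAS: dict[str, list[str]] = {
    "patients": [
        "patient_id",
        "sex",
        "birth_year",
        "ra_diagnosis_date",
        "clinical_label",
        "planted_truth",
    ],
    "prescriptions": ["patient_id", "atc_code", "drug_name", "start_date"],
    "labs": ["patient_id", "test_code", "value", "unit", "datetime"],
    "clinical_measurements": [
        "patient_id",
        "date",
        "sjc28",
        "tjc28",
        "vas_gh",
        "systolic_bp",
        "height",
        "weight",
    ],
    "visits": ["patient_id", "date", "visit_type"],
}

DATE_COLUMNS: dict[str, list[str]] = {
    "patients": ["ra_diagnosis_date"],
    "prescriptions": ["start_date"],
    "labs": ["datetime"],
    "clinical_measurements": ["date"],
    "visits": ["date"],
}

SORT_COLUMNS: dict[str, list[str]] = {
    "patients": ["patient_id"],
    "prescriptions": ["patient_id", "start_date", "atc_code"],
    "labs": ["patient_id", "datetime", "test_code"],
    "clinical_measurements": ["patient_id", "date"],
    "visits": ["patient_id", "date", "visit_type"],
}

CLINICAL_LABELS = ("D2T", "nonD2T", "unlabeled")


class BundleValidationError(ValueError):
    """Raised when a bundle directory or table fails structural validation."""


def _norm_heading(heading: str) -> str:
    return " ".join(heading.strip().lower().split())


@dataclass
class ClinicalLetter:
    """One clinical letter: dated free text organised into headed sections."""

    patient_id: str
    date: dt.date
    sections: dict[str, str]

    def text(self) -> str:
        """Render the letter as plain text with ``Heading:`` section markers."""
        parts = []
        for heading, body in self.sections.items():
            parts.append(f"{heading}:")
            parts.append(body.rstrip("\n"))
        return "\n".join(parts) + "\n"

    def section(self, heading: str) -> str | None:
        """Case/whitespace-insensitive section lookup."""
        want = _norm_heading(heading)
        for key, body in self.sections.items():
            if _norm_heading(key) == want:
                return body
        return None


@dataclass
class CohortBundle:
    """All structured tables, letters and ground-truth labels of one cohort."""

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    labs: pd.DataFrame
    clinical_measurements: pd.DataFrame
    visits: pd.DataFrame
    letters: list[ClinicalLetter] = field(default_factory=list)
    #: per-letter planted truth (synthetic cohorts only): patient_id, date,
    #: active_disease — what a perfect letter reader should recover
    letter_truth: pd.DataFrame | None = None
    config: dict | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "patients": self.patients,
            "prescriptions": self.prescriptions,
            "labs": self.labs,
            "clinical_measurements": self.clinical_measurements,
            "visits": self.visits,
        }

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def patient_ids(self) -> list[str]:
        return self.patients["patient_id"].tolist()

    def copy(self) -> "CohortBundle":
        return CohortBundle(
            patients=self.patients.copy(),
            prescriptions=self.prescriptions.copy(),
            labs=self.labs.copy(),
            clinical_measurements=self.clinical_measurements.copy(),
            visits=self.visits.copy(),
            letters=[
                ClinicalLetter(l.patient_id, l.date, dict(l.sections))
                for l in self.letters
            ],
            letter_truth=None if self.letter_truth is None else self.letter_truth.copy(),
            config=None if self.config is None else dict(self.config),
        )

    def equals(self, other: "CohortBundle") -> bool:
        if sorted(self.tables()) != sorted(other.tables()):
            return False
        for name, tab in self.tables().items():
            if not tab.reset_index(drop=True).equals(
                other.tables()[name].reset_index(drop=True)
            ):
                return False
        if len(self.letters) != len(other.letters):
            return False
        for a, b in zip(self.letters, other.letters):
            if (a.patient_id, a.date, a.sections) != (b.patient_id, b.date, b.sections):
                return False
        return True


@dataclass
class SchemaReport:
    """Validation result for one table: missing columns, bad rows, warnings."""

    table_name: str
    missing_columns: list[str] = field(default_factory=list)
    bad_rows: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.missing_columns and self.bad_rows == 0


def _sorted_table(name: str, table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in TABLE_SCHEMAS[name] if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    out = table[cols + extra]
    sort_by = [c for c in SORT_COLUMNS[name] if c in out.columns]
    if sort_by and len(out):
        out = out.sort_values(sort_by, kind="mergesort")
    return out.reset_index(drop=True)


def _date_str(value) -> str:
    if isinstance(value, (pd.Timestamp, dt.datetime)):
        ts = pd.Timestamp(value)
        if ts == ts.normalize():
            return ts.date().isoformat()
        return ts.isoformat(sep="T")
    return str(value)


def write_bundle(bundle: CohortBundle, directory: str | Path) -> dict:
    """Write a bundle to ``directory``; returns the manifest.

    Output is deterministic: fixed column order, stable sort by patient and
    date, ISO dates, sorted JSON keys — writing the same bundle twice yields
    byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    row_counts: dict[str, int] = {}
    for name, table in bundle.tables().items():
        out = _sorted_table(name, table).copy()
        for col in DATE_COLUMNS[name]:
            if col in out.columns and len(out):
                out[col] = out[col].map(_date_str)
        out.to_csv(directory / f"{name}.csv", index=False, lineterminator="\n")
        row_counts[name] = len(out)

    letters = sorted(bundle.letters, key=lambda l: (l.patient_id, str(l.date)))
    with open(directory / "letters.jsonl", "w", encoding="utf-8") as fh:
        for letter in letters:
            fh.write(
                json.dumps(
                    {
                        "patient_id": letter.patient_id,
                        "date": _date_str(pd.Timestamp(letter.date)),
                        "sections": letter.sections,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    row_counts["letters"] = len(letters)

    if bundle.letter_truth is not None:
        truth = bundle.letter_truth.sort_values(
            ["patient_id", "date"], kind="mergesort"
        ).reset_index(drop=True)
        truth = truth.copy()
        truth["date"] = truth["date"].map(_date_str)
        truth.to_csv(directory / "letter_truth.csv", index=False, lineterminator="\n")
        row_counts["letter_truth"] = len(truth)

    manifest = {
        "format": "d2tra-cohort-v1",
        "row_counts": row_counts,
        "config": bundle.config,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(bundle.config, sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


def read_letters(path: str | Path) -> list[ClinicalLetter]:
    letters = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                letters.append(
                    ClinicalLetter(
                        patient_id=str(obj["patient_id"]),
                        date=dt.date.fromisoformat(obj["date"][:10]),
                        sections=dict(obj["sections"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise BundleValidationError(
                    f"letters.jsonl line {i + 1}: {exc}"
                ) from exc
    return letters


def read_bundle(directory: str | Path) -> CohortBundle:
    """Read a bundle directory written by :func:`write_bundle`."""
    directory = Path(directory)
    if not directory.is_dir():
        raise BundleValidationError(f"not a directory: {directory}")
    tables: dict[str, pd.DataFrame] = {}
    for name in TABLE_SCHEMAS:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise BundleValidationError(f"missing file: {path.name}")
        table = pd.read_csv(path, dtype={"patient_id": str})
        for col in DATE_COLUMNS[name]:
            if col in table.columns:
                try:
                    table[col] = pd.to_datetime(table[col], format="ISO8601")
                except ValueError as exc:
                    bad = pd.to_datetime(table[col], format="ISO8601", errors="coerce")
                    rows = table.index[bad.isna() & table[col].notna()].tolist()
                    raise BundleValidationError(
                        f"{name}.csv: unparseable {col} at rows {rows[:10]}"
                    ) from exc
        tables[name] = table

    letters_path = directory / "letters.jsonl"
    letters = read_letters(letters_path) if letters_path.exists() else []

    truth_path = directory / "letter_truth.csv"
    letter_truth = None
    if truth_path.exists():
        letter_truth = pd.read_csv(truth_path, dtype={"patient_id": str})
        letter_truth["date"] = pd.to_datetime(letter_truth["date"])
        if "active_disease" in letter_truth.columns:
            letter_truth["active_disease"] = letter_truth["active_disease"].astype(bool)

    config = None
    manifest_path = directory / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path, encoding="utf-8") as fh:
            config = json.load(fh).get("config")

    return CohortBundle(
        patients=tables["patients"],
        prescriptions=tables["prescriptions"],
        labs=tables["labs"],
        clinical_measurements=tables["clinical_measurements"],
        visits=tables["visits"],
        letters=letters,
        letter_truth=letter_truth,
        config=config,
    )


def _count_bad(mask: pd.Series, report: SchemaReport, message: str) -> None:
    n = int(mask.sum())
    if n:
        report.bad_rows += n
        report.warnings.append(f"{message} ({n} rows)")


def validate_schema(bundle: CohortBundle, strict: bool = False) -> list[SchemaReport]:
    """Validate tables against the bundle schema; never mutates data.

    Checks per table: required columns, referential integrity of patient_id,
    plausible value ranges (joint counts 0–28, VAS 0–100, non-negative labs).
    With ``strict=True`` any violation raises :class:`BundleValidationError`.
    """
    reports: list[SchemaReport] = []
    known_ids = set(bundle.patients.get("patient_id", pd.Series(dtype=str)))
    for name, table in bundle.tables().items():
        report = SchemaReport(table_name=name)
        missing = [c for c in TABLE_SCHEMAS[name] if c not in table.columns]
        report.missing_columns = missing
        if missing:
            reports.append(report)
            continue
        if name != "patients" and len(table):
            _count_bad(
                ~table["patient_id"].isin(known_ids),
                report,
                "patient_id not in patients table",
            )
        if name == "patients" and len(table):
            _count_bad(
                table["patient_id"].duplicated(),
                report,
                "duplicate patient_id",
            )
            _count_bad(
                ~table["clinical_label"].isin(CLINICAL_LABELS),
                report,
                "clinical_label outside {D2T, nonD2T, unlabeled}",
            )
        if name == "clinical_measurements" and len(table):
            for col in ("sjc28", "tjc28"):
                vals = pd.to_numeric(table[col], errors="coerce")
                _count_bad(
                    vals.notna() & ((vals < 0) | (vals > 28)),
                    report,
                    f"{col} outside 0–28",
                )
            vas = pd.to_numeric(table["vas_gh"], errors="coerce")
            _count_bad(
                vas.notna() & ((vas < 0) | (vas > 100)),
                report,
                "vas_gh outside 0–100",
            )
        if name == "labs" and len(table):
            vals = pd.to_numeric(table["value"], errors="coerce")
            _count_bad(~np.isfinite(vals), report, "non-finite lab value")
        reports.append(report)

    letter_report = SchemaReport(table_name="letters")
    for letter in bundle.letters:
        if letter.patient_id not in known_ids:
            letter_report.bad_rows += 1
    if letter_report.bad_rows:
        letter_report.warnings.append("letters with unknown patient_id")
    reports.append(letter_report)

    if strict:
        bad = [r for r in reports if not r.ok]
        if bad:
            raise BundleValidationError(
                "; ".join(
                    f"{r.table_name}: missing={r.missing_columns} bad_rows={r.bad_rows}"
                    for r in bad
                )
            )
    return reports
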