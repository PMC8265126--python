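"""Rule-based D2T RA classification from structured data.

Implements the first two criteria of the EULAR difficult-to-treat RA
definition as they can be evaluated on prescription and disease-activity
data alone:

1. a history of at least two b/tsDMARDs with different mechanism-of-action
   (MoA) classes, inferred from prescription start dates (stop dates are
   unreliable in routine care and are never used); and
2. signs of active disease after failing the second MoA, operationalised as
   (a) a mean DAS28-ESR >= 3.2 in the window 3–12 months after starting the
   b/tsDMARD of a second MoA, or (b) the start of a third distinct MoA class
   (switching again is itself taken as treatment failure).

The procedure is deliberately conservative: patients with insufficient data
to evaluate criterion 2 are classified non-D2T, which depresses sensitivity
but protects specificity.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .das28 import (
    ACTIVITY_THRESHOLD,
    Das28Record,
    Das28ModelResults,
    approximate_das28,
    mean_das28_in_window,
    measured_das28_records,
)
from .ehr_io import CohortBundle

__all__ = [
    "MoaTaxonomy",
    "ClassificationResult",
    "map_atc_to_moa",
    "moa_start_sequence",
    "criterion1",
    "criterion2",
    "classify_structured",
    "results_to_frame",
]

BTSDMARD_CLASSES = (
    "TNFi",
    "IL6i",
    "CTLA4Ig",
    "antiCD20",
    "JAKi",
    "IL1i",
    "other_btsDMARD",
)
NOT_BTSDMARD = "not_btsDMARD"


@dataclass(frozen=True)
class MoaTaxonomy:
    """Mapping ATC code -> b/tsDMARD mechanism-of-action class."""

    atc_to_moa: dict[str, str]
    atc_to_drug: dict[str, str]
    class_order: tuple[str, ...] = BTSDMARD_CLASSES

    def __post_init__(self):
        for code, moa in self.atc_to_moa.items():
            if moa not in self.class_order:
                raise ValueError(f"{code}: unknown MoA class {moa!r}")

    @classmethod
    def default(cls) -> "MoaTaxonomy":
        path = resources.files("d2tra") / "data" / "moa_taxonomy.yaml"
        return cls.from_yaml(path)

    @classmethod
    def from_yaml(cls, path) -> "MoaTaxonomy":
        text = (
            path.read_text(encoding="utf-8")
            if hasattr(path, "read_text")
            else Path(path).read_text(encoding="utf-8")
        )
        data = yaml.safe_load(text)
        return cls(
            atc_to_moa={c: v["moa"] for c, v in data["codes"].items()},
            atc_to_drug={c: v["drug"] for c, v in data["codes"].items()},
            class_order=tuple(data.get("class_order", BTSDMARD_CLASSES)),
        )

    def drug_to_moa(self) -> dict[str, str]:
        """Lower-cased drug name -> MoA class (for the letter miner)."""
        return {d.lower(): self.atc_to_moa[c] for c, d in self.atc_to_drug.items()}

    def class_rank(self, moa: str) -> int:
        return self.class_order.index(moa)


def map_atc_to_moa(atc_code: str, taxonomy: MoaTaxonomy | None = None) -> str:
    """MoA class for an ATC code; codes outside the taxonomy -> not_btsDMARD."""
    taxonomy = taxonomy or MoaTaxonomy.default()
    if not atc_code:
        raise ValueError("empty ATC code")
    return taxonomy.atc_to_moa.get(str(atc_code).strip().upper(), NOT_BTSDMARD)


def moa_start_sequence(
    prescriptions: pd.DataFrame, taxonomy: MoaTaxonomy | None = None
) -> list[tuple[str, pd.Timestamp]]:
    """Distinct b/tsDMARD MoA classes ordered by first start date.

    Repeat prescriptions within one class collapse to the earliest date.
    Classes first started on the same day are ordered by the taxonomy's
    fixed class enumeration (a deterministic tie-break; see
    :func:`criterion2` evidence for the tie flag).
    """
    taxonomy = taxonomy or MoaTaxonomy.default()
    if prescriptions.empty:
        return []
    firsts: dict[str, pd.Timestamp] = {}
    for row in prescriptions.itertuples():
        moa = map_atc_to_moa(row.atc_code, taxonomy)
        if moa == NOT_BTSDMARD:
            continue
        start = pd.Timestamp(row.start_date)
        if moa not in firsts or start < firsts[moa]:
            firsts[moa] = start
    return sorted(firsts.items(), key=lambda kv: (kv[1], taxonomy.class_rank(kv[0])))


def criterion1(sequence: list[tuple[str, pd.Timestamp]]) -> bool:
    """True iff at least two distinct b/tsDMARD MoA classes were started."""
    return len(sequence) >= 2


def criterion2(
    sequence: list[tuple[str, pd.Timestamp]],
    das28_records: list[Das28Record],
    threshold: float = ACTIVITY_THRESHOLD,
    anchor: str = "second_moa",
) -> tuple[bool | None, list[tuple[str, str, str]]]:
    """Active-disease criterion after failing the second MoA.

    Returns ``(met, evidence)``; ``met`` is ``None`` when criterion 1 holds
    but no DAS28 record falls in the evaluation window and no third MoA was
    started — the insufficient-data case.

    Branch (a): mean DAS28-ESR >= ``threshold`` in [anchor+3mo, anchor+12mo],
    anchored by default at the second MoA start.  Branch (b): a third
    distinct MoA class was started.
    """
    evidence: list[tuple[str, str, str]] = []
    if not criterion1(sequence):
        return False, evidence
    if anchor not in ("second_moa", "each_from_second"):
        raise ValueError(f"unknown anchor policy {anchor!r}")

    dates = [d for _, d in sequence]
    if len(set(dates)) != len(dates):
        evidence.append(("tie_same_day_starts", "", "MoA starts share a date; taxonomy order applied"))

    if len(sequence) >= 3:
        moa, date = sequence[2]
        evidence.append(("criterion2b_third_moa", str(pd.Timestamp(date).date()), f"third MoA class started: {moa}"))
        return True, evidence

    anchors = [sequence[1]] if anchor == "second_moa" else sequence[1:]
    any_window = False
    for moa, anchor_date in anchors:
        mean = mean_das28_in_window(das28_records, anchor_date)
        if mean is None:
            continue
        any_window = True
        if mean >= threshold:
            evidence.append(
                (
                    "criterion2a_active_window",
                    str(pd.Timestamp(anchor_date).date()),
                    f"mean DAS28-ESR {mean:.2f} >= {threshold} in 3–12mo window after {moa} start",
                )
            )
            return True, evidence
        evidence.append(
            (
                "criterion2a_inactive_window",
                str(pd.Timestamp(anchor_date).date()),
                f"mean DAS28-ESR {mean:.2f} < {threshold} in 3–12mo window after {moa} start",
            )
        )
    if not any_window:
        evidence.append(("criterion2_insufficient", "", "no DAS28 record in evaluation window and no third MoA"))
        return None, evidence
    return False, evidence


@dataclass
class ClassificationResult:
    """Per-patient rule-engine outcome with its evidence trail."""

    patient_id: str
    criterion1_met: bool
    criterion2_met: bool
    label: str  # "D2T" | "nonD2T"
    evidence: list[tuple[str, str, str]] = field(default_factory=list)
    data_sufficiency: str = "sufficient"  # "sufficient" | "insufficient"

    def __post_init__(self):
        expected = "D2T" if (self.criterion1_met and self.criterion2_met) else "nonD2T"
        if self.label != expected:
            raise ValueError("label must equal criterion1 AND criterion2")
        if self.data_sufficiency == "insufficient" and self.label == "D2T":
            raise ValueError("insufficient data cannot yield a D2T label")


def classify_structured(
    bundle: CohortBundle,
    taxonomy: MoaTaxonomy | None = None,
    approximator: Das28ModelResults | None = None,
    das28_source: str = "all",
    threshold: float = ACTIVITY_THRESHOLD,
    anchor: str = "second_moa",
) -> list[ClassificationResult]:
    """Apply criteria 1–2 to every patient in the bundle.

    ``das28_source`` selects the disease-activity records criterion 2 sees:
    ``"all"`` (default) uses exactly-computed scores where the four
    components were recorded and model approximations for visit dates that
    lack them; ``"measured_only"`` / ``"approximated_only"`` restrict to one
    provenance.  Patients whose criterion-2 window holds no record and who
    never started a third MoA are conservatively labeled nonD2T with
    ``data_sufficiency="insufficient"``.
    """
    if das28_source not in ("all", "measured_only", "approximated_only"):
        raise ValueError(f"unknown das28_source {das28_source!r}")
    taxonomy = taxonomy or MoaTaxonomy.default()

    records: list[Das28Record] = []
    if das28_source in ("all", "measured_only"):
        records.extend(measured_das28_records(bundle))
    if das28_source in ("all", "approximated_only") and approximator is not None:
        records.extend(approximate_das28(approximator, bundle))
    by_patient: dict[str, list[Das28Record]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec)

    rx_by_patient = dict(tuple(bundle.prescriptions.groupby("patient_id"))) if not bundle.prescriptions.empty else {}

    results = []
    for pid in bundle.patients["patient_id"]:
        rx = rx_by_patient.get(pid)
        seq = moa_start_sequence(rx, taxonomy) if rx is not None else []
        c1 = criterion1(seq)
        sufficiency = "sufficient"
        if not c1:
            c2 = False
            evidence = [("criterion1_not_met", "", f"{len(seq)} distinct b/tsDMARD MoA class(es)")]
        else:
            evidence = [
                ("criterion1_met", str(pd.Timestamp(seq[1][1]).date()),
                 "MoA sequence: " + " -> ".join(m for m, _ in seq))
            ]
            met, ev2 = criterion2(seq, by_patient.get(pid, []), threshold, anchor)
            evidence.extend(ev2)
            if met is None:
                c2 = False
                sufficiency = "insufficient"
            else:
                c2 = bool(met)
        label = "D2T" if (c1 and c2) else "nonD2T"
        results.append(
            ClassificationResult(
                patient_id=pid,
                criterion1_met=c1,
                criterion2_met=c2,
                label=label,
                evidence=evidence,
                data_sufficiency=sufficiency,
            )
        )
    return results


def results_to_frame(results: list[ClassificationResult]) -> pd.DataFrame:
    """Tabulate classification results (evidence serialised as JSON strings)."""
    import json

    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "criterion1": [r.criterion1_met for r in results],
            "criterion2": [r.criterion2_met for r in results],
            "label": [r.label for r in results],
            "sufficiency": [r.data_sufficiency for r in results],
            "evidence": [json.dumps(r.evidence) for r in results],
        }
    )
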