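"""Synthetic routine-care cohorts with planted D2T RA ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes, not clinical reality: per-patient treatment histories cycling
through b/tsDMARD mechanism-of-action (MoA) classes, piecewise-constant
latent DAS28-ESR trajectories per treatment episode (plus Gaussian
measurement noise), a hematology panel with configurable standardized group
shifts between D2T and non-D2T patients, chemistry labs, hospital visits,
and templated English clinic letters whose medication sections exactly
mirror the structured prescription table.

Planted D2T patients receive >= 2 MoA classes and persistently active
post-switch trajectories (latent level >= 3.8, so the 3–12-month window
mean after the second MoA start clears the 3.2 activity threshold by
construction); planted non-D2T patients receive 0–1 MoA classes or a
responding trajectory after the second MoA (level <= 2.4).  This makes
recovery by the rule engine a testable contract.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .ehr_io import ClinicalLetter, CohortBundle

__all__ = [
    "GeneratorConfig",
    "PatientHistory",
    "generate_cohort",
    "render_letters",
    "inject_missingness",
    "HEMATOLOGY_PANEL",
    "DEFAULT_EFFECT_SIZES",
]

DAYS_PER_MONTH = 30.44

#: hematology parameters: name -> (population mean, population SD).
#: CBC + differential + reticulocytes + a platelet intermediate-angle-scatter
#: proxy, mirroring the panel breadth of a routine hematology analyzer.
HEMATOLOGY_PANEL: dict[str, tuple[float, float]] = {
    "hemoglobin": (8.6, 0.8),           # mmol/L
    "hematocrit": (0.42, 0.035),
    "rbc": (4.7, 0.4),                  # 10^12/L
    "mcv": (90.0, 5.0),                 # fL
    "rdw": (13.5, 1.2),                 # %
    "wbc": (7.5, 1.8),                  # 10^9/L
    "neutrophils_pct": (60.0, 8.0),
    "segmented_neutrophils": (4.2, 1.2),
    "banded_neutrophils": (0.15, 0.08),
    "lymphocytes": (2.0, 0.5),
    "monocytes": (0.5, 0.15),
    "eosinophils": (0.2, 0.1),
    "basophils": (0.05, 0.02),
    "platelets": (280.0, 60.0),
    "mpv": (10.5, 0.9),
    "reticulocytes_pct": (1.2, 0.4),
    "immature_granulocytes_pct": (0.3, 0.15),
    "plt_ias": (50.0, 8.0),
}

CHEMISTRY_PANEL: dict[str, tuple[float, float]] = {
    "creatinine": (75.0, 12.0),         # umol/L
    "potassium": (4.2, 0.3),            # mmol/L
}

#: default standardized mean shifts (D2T minus non-D2T, in SD units)
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "wbc": 0.6,
    "neutrophils_pct": 0.6,
    "banded_neutrophils": 0.5,
    "platelets": 0.5,
    "hemoglobin": -0.5,
    "lymphocytes": -0.4,
    "reticulocytes_pct": 0.4,
    "immature_granulocytes_pct": 0.4,
    "plt_ias": -0.4,
}

# variance split of hematology values: between-patient vs within-patient,
# scaled so the total SD equals the panel SD
_BETWEEN_SD = np.sqrt(0.85)
_WITHIN_SD = np.sqrt(0.15)

CS_DMARDS = [("L04AX03", "methotrexate"), ("H02AB06", "prednisolone"), ("M01AE01", "ibuprofen")]

ACTIVE_TEMPLATES = [
    "Patient reports a flare of the arthritis.",
    "Examination shows active arthritis of the hands.",
    "There is an exacerbation of disease symptoms.",
    "Clinically active disease with several swollen joints.",
]
NEGATED_TEMPLATES = [
    "No flare of the arthritis.",
    "Currently no flare was reported.",
    "There is no active disease at present.",
    "Patient is without active arthritis.",
]
NEUTRAL_TEMPLATES = [
    "Disease activity is low.",
    "Stable course, continue current therapy.",
]
DISTRACTOR_TEMPLATES = [
    "No signs of infection.",
    "No new complaints today.",
]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    The defaults define the package's reference study conditions; identical
    config + seed yields byte-identical bundles.
    """

    n_patients: int = 500
    d2t_prevalence: float = 0.2
    missingness_rates: dict[str, float] = field(default_factory=dict)
    negation_rate: float = 0.3
    effect_sizes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    noise_sd: float = 0.3
    seed: int = 0
    clinical_label_fraction: float = 0.3

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, frac in {
            "d2t_prevalence": self.d2t_prevalence,
            "negation_rate": self.negation_rate,
            "clinical_label_fraction": self.clinical_label_fraction,
            **{f"missingness_rates[{k}]": v for k, v in self.missingness_rates.items()},
        }.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.effect_sizes) - set(HEMATOLOGY_PANEL) - set(CHEMISTRY_PANEL)
        if unknown:
            raise ValueError(f"effect_sizes for unknown labs: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return asdict(self)

    def with_effect_scale(self, scale: float) -> "GeneratorConfig":
        """Copy of the config with every effect size rescaled to |scale| SD."""
        d = self.to_dict()
        d["effect_sizes"] = {k: float(np.sign(v)) * scale for k, v in self.effect_sizes.items()}
        return GeneratorConfig(**d)


@dataclass
class PatientHistory:
    """Latent per-patient truth driving every rendered record."""

    patient_id: str
    sex: str
    birth_year: int
    diagnosis_date: pd.Timestamp
    end_date: pd.Timestamp
    d2t: bool
    cs_drugs: list[tuple[str, str, pd.Timestamp]]          # (atc, drug, start)
    bts_drugs: list[tuple[str, str, str, pd.Timestamp]]    # (atc, drug, moa, start)
    episodes: list[tuple[pd.Timestamp, pd.Timestamp, float]]  # (start, end, latent DAS28)

    def level_at(self, date: pd.Timestamp) -> float:
        for start, end, level in self.episodes:
            if start <= date < end:
                return level
        return self.episodes[-1][2]


def _moa_catalogue():
    from .d2t_rules import MoaTaxonomy

    tax = MoaTaxonomy.default()
    by_class: dict[str, list[tuple[str, str]]] = {}
    for atc, moa in tax.atc_to_moa.items():
        by_class.setdefault(moa, []).append((atc, tax.atc_to_drug[atc]))
    for drugs in by_class.values():
        drugs.sort()
    return by_class


def _plan_patient(pid: str, d2t: bool, rng: np.random.Generator, moa_catalogue) -> PatientHistory:
    sex = "F" if rng.random() < 0.7 else "M"
    birth_year = int(rng.integers(1940, 1986))
    diagnosis = pd.Timestamp("2005-01-01") + pd.Timedelta(days=int(rng.integers(0, 3653)))

    if d2t:
        n_moa = int(rng.choice([2, 3, 4], p=[0.45, 0.35, 0.2]))
    else:
        n_moa = int(rng.choice([0, 1, 2], p=[0.35, 0.40, 0.25]))

    classes = list(moa_catalogue)
    rng.shuffle(classes)
    # TNF inhibitors are the usual first biologic
    if n_moa and "TNFi" in classes and rng.random() < 0.8:
        classes.remove("TNFi")
        classes.insert(0, "TNFi")
    chosen = classes[:n_moa]

    bts = []
    t = diagnosis + pd.Timedelta(days=int(rng.integers(180, 900)))
    for moa in chosen:
        atc, drug = moa_catalogue[moa][int(rng.integers(len(moa_catalogue[moa])))]
        bts.append((atc, drug, moa, t))
        t = t + pd.Timedelta(days=int(rng.integers(400, 900)))

    end = diagnosis + pd.Timedelta(days=int(rng.integers(6 * 365, 9 * 365)))
    if bts:
        end = max(end, bts[-1][3] + pd.Timedelta(days=450))

    cs = [(CS_DMARDS[0][0], CS_DMARDS[0][1], diagnosis)]
    if rng.random() < 0.4:
        cs.append((CS_DMARDS[1][0], CS_DMARDS[1][1], diagnosis + pd.Timedelta(days=int(rng.integers(0, 365)))))
    if rng.random() < 0.3:
        cs.append((CS_DMARDS[2][0], CS_DMARDS[2][1], diagnosis + pd.Timedelta(days=int(rng.integers(0, 730)))))

    # piecewise-constant latent DAS28 per treatment episode
    episodes: list[tuple[pd.Timestamp, pd.Timestamp, float]] = []
    boundaries = [diagnosis] + [b[3] for b in bts] + [end]
    if not bts:
        mid = min(diagnosis + pd.Timedelta(days=180), end)
        episodes.append((diagnosis, mid, float(rng.uniform(3.5, 5.5))))
        episodes.append((mid, end, float(rng.uniform(1.5, 2.8))))
    else:
        episodes.append((boundaries[0], boundaries[1], float(rng.uniform(4.0, 6.0))))
        for k in range(len(bts)):
            seg = (boundaries[k + 1], boundaries[k + 2])
            if d2t:
                level = float(rng.uniform(3.8, 5.5))
            elif k == len(bts) - 1:
                level = float(rng.uniform(1.2, 2.4))   # responder on final drug
            else:
                level = float(rng.uniform(3.6, 5.2))   # failing an earlier drug
            episodes.append((seg[0], seg[1], level))

    return PatientHistory(
        patient_id=pid,
        sex=sex,
        birth_year=birth_year,
        diagnosis_date=diagnosis,
        end_date=end,
        d2t=d2t,
        cs_drugs=cs,
        bts_drugs=bts,
        episodes=episodes,
    )


def _visit_dates(history: PatientHistory, rng: np.random.Generator) -> list[pd.Timestamp]:
    dates = []
    t = history.diagnosis_date
    while t < history.end_date:
        dates.append(t)
        t = t + pd.Timedelta(days=int(rng.integers(25, 46)))
    return dates


def _render_visit_tables(history, visit_dates, noise_sd, effect_sizes, rng):
    """Clinical measurements + chemistry/ESR/CRP labs at each visit."""
    n = len(visit_dates)
    levels = np.array([history.level_at(d) for d in visit_dates])
    das = np.clip(levels + noise_sd * rng.standard_normal(n), 0.5, 9.0)
    tjc = np.clip(np.round(1.6 * das - 2.0 + 2.0 * noise_sd * rng.standard_normal(n)), 0, 28)
    sjc = np.clip(np.round(1.3 * das - 2.0 + 2.0 * noise_sd * rng.standard_normal(n)), 0, 28)
    vas = np.clip(9.5 * das + 10.0 * noise_sd * rng.standard_normal(n), 0.0, 100.0)
    # solve the ESR so the four components reproduce the intended score
    residual = das - 0.56 * np.sqrt(tjc) - 0.28 * np.sqrt(sjc) - 0.014 * vas
    esr = np.clip(np.exp(residual / 0.70), 1.0, 150.0)
    crp = 1.5 * np.exp(0.45 * das) * np.exp(0.15 * noise_sd * rng.standard_normal(n))

    height = float(rng.normal(170, 9))
    weight0 = float(rng.normal(75, 12))
    bp_base = float(rng.normal(130, 12))
    cm = pd.DataFrame(
        {
            "patient_id": history.patient_id,
            "date": visit_dates,
            "sjc28": sjc,
            "tjc28": tjc,
            "vas_gh": np.round(vas, 1),
            "systolic_bp": np.round(bp_base + 8 * rng.standard_normal(n), 0),
            "height": round(height, 1),
            "weight": np.round(weight0 + np.cumsum(0.2 * rng.standard_normal(n)), 1),
        }
    )

    codes: list[str] = []
    values: list[np.ndarray] = []
    units: list[str] = []
    dates: list[np.ndarray] = []
    visit_arr = np.array(visit_dates, dtype="datetime64[ns]")
    for code, vals, unit in (
        ("esr", np.round(esr, 1), "mm/h"),
        ("crp", np.round(crp, 1), "mg/L"),
    ):
        codes.append(code)
        values.append(vals)
        units.append(unit)
        dates.append(visit_arr)
    chem_idx = np.arange(0, n, 3)  # chemistry drawn every third visit
    for code, (base, sd) in CHEMISTRY_PANEL.items():
        shift = effect_sizes.get(code, 0.0) * sd if history.d2t else 0.0
        patient_base = base + shift + sd * _BETWEEN_SD * rng.standard_normal()
        vals = patient_base + sd * _WITHIN_SD * rng.standard_normal(len(chem_idx))
        codes.append(code)
        values.append(np.round(np.maximum(vals, 0.01), 2))
        units.append("umol/L" if code == "creatinine" else "mmol/L")
        dates.append(visit_arr[chem_idx])
    labs = pd.DataFrame(
        {
            "patient_id": history.patient_id,
            "test_code": np.repeat(codes, [len(v) for v in values]),
            "value": np.concatenate(values),
            "unit": np.repeat(units, [len(v) for v in values]),
            "datetime": np.concatenate(dates),
        }
    )
    return cm, labs


def _render_hematology(history, rng, effect_sizes):
    dates = []
    t = history.diagnosis_date
    while t < history.end_date:
        dates.append(t)
        t = t + pd.Timedelta(days=int(rng.integers(90, 150)))
    m = len(dates)
    if m == 0:
        return pd.DataFrame(columns=["patient_id", "test_code", "value", "unit", "datetime"])
    date_arr = np.array(dates, dtype="datetime64[ns]")
    codes = list(HEMATOLOGY_PANEL)
    blocks = []
    for code in codes:
        base, sd = HEMATOLOGY_PANEL[code]
        shift = effect_sizes.get(code, 0.0) * sd if history.d2t else 0.0
        patient_base = base + shift + sd * _BETWEEN_SD * rng.standard_normal()
        vals = patient_base + sd * _WITHIN_SD * rng.standard_normal(m)
        blocks.append(np.round(np.maximum(vals, 0.001), 3))
    return pd.DataFrame(
        {
            "patient_id": history.patient_id,
            "test_code": np.repeat(codes, m),
            "value": np.concatenate(blocks),
            "unit": "au",
            "datetime": np.tile(date_arr, len(codes)),
        }
    )


def render_letters(
    history: PatientHistory,
    negation_rate: float,
    seed: int | np.random.Generator = 0,
) -> tuple[list[ClinicalLetter], pd.DataFrame]:
    """Templated clinic letters for one patient, plus per-letter truth.

    One letter roughly per year.  The "Medication" and "DMARD history"
    sections list exactly the structured prescriptions started by the letter
    date.  The "Conclusion" carries an activity phrase when the latent
    trajectory is active at the letter date; with probability
    ``negation_rate`` that phrase is rendered negated ("no flare" style) and
    the letter-level truth records the letter as inactive.  Quiescent
    periods yield either an explicitly negated phrase or a neutral sentence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    letters: list[ClinicalLetter] = []
    truth_rows = []
    t = history.diagnosis_date + pd.Timedelta(days=int(rng.integers(200, 420)))
    while t < history.end_date:
        meds = [f"{drug} (since {start.date().isoformat()})" for _, drug, start in history.cs_drugs if start <= t]
        bts = [
            f"{drug} (start {start.date().isoformat()})"
            for _, drug, _, start in history.bts_drugs
            if start <= t
        ]
        active_latent = history.level_at(t) >= 3.2
        sentences = []
        if rng.random() < 0.3:
            sentences.append(DISTRACTOR_TEMPLATES[int(rng.integers(len(DISTRACTOR_TEMPLATES)))])
        if active_latent:
            if rng.random() < negation_rate:
                sentences.append(NEGATED_TEMPLATES[int(rng.integers(len(NEGATED_TEMPLATES)))])
                truth_active = False
            else:
                sentences.append(ACTIVE_TEMPLATES[int(rng.integers(len(ACTIVE_TEMPLATES)))])
                truth_active = True
        else:
            if rng.random() < 0.5:
                sentences.append(NEGATED_TEMPLATES[int(rng.integers(len(NEGATED_TEMPLATES)))])
            else:
                sentences.append(NEUTRAL_TEMPLATES[int(rng.integers(len(NEUTRAL_TEMPLATES)))])
            truth_active = False
        letter = ClinicalLetter(
            patient_id=history.patient_id,
            date=t.date(),
            sections={
                "Medication": "\n".join(meds) if meds else "none",
                "DMARD history": "\n".join(bts) if bts else "none",
                "Conclusion": " ".join(sentences),
            },
        )
        letters.append(letter)
        truth_rows.append(
            {"patient_id": history.patient_id, "date": t, "active_disease": truth_active}
        )
        t = t + pd.Timedelta(days=int(rng.integers(300, 430)))
    truth = pd.DataFrame(truth_rows, columns=["patient_id", "date", "active_disease"])
    return letters, truth


def letter_level_label(history: PatientHistory, letters: list[ClinicalLetter], truth: pd.DataFrame) -> str:
    """What a perfect reader of these letters should conclude (D2T/nonD2T)."""
    if not letters:
        return "nonD2T"
    last = max(pd.Timestamp(l.date) for l in letters)
    n_classes = len({moa for _, _, moa, start in history.bts_drugs if start <= last})
    c1 = n_classes >= 2
    c2 = bool(truth["active_disease"].any()) if len(truth) else False
    return "D2T" if (c1 and c2) else "nonD2T"


def generate_cohort(config: GeneratorConfig) -> CohortBundle:
    """Generate one synthetic cohort; deterministic in config + seed."""
    rng = np.random.default_rng(config.seed)
    moa_catalogue = _moa_catalogue()

    patients_rows = []
    rx_frames = []
    cm_frames = []
    lab_frames = []
    visit_frames = []
    letters: list[ClinicalLetter] = []
    truth_frames = []

    d2t_flags = rng.random(config.n_patients) < config.d2t_prevalence
    labeled_flags = rng.random(config.n_patients) < config.clinical_label_fraction

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        history = _plan_patient(pid, bool(d2t_flags[i]), rng, moa_catalogue)
        visit_dates = _visit_dates(history, rng)
        cm, labs = _render_visit_tables(
            history, visit_dates, config.noise_sd, config.effect_sizes, rng
        )
        hema = _render_hematology(history, rng, config.effect_sizes)
        pletters, ptruth = render_letters(history, config.negation_rate, rng)

        ward = rng.random(len(visit_dates)) < (0.10 if history.d2t else 0.04)
        visit_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "date": visit_dates,
                    "visit_type": np.where(ward, "ward", "outpatient"),
                }
            )
        )
        rx_rows = [
            {"patient_id": pid, "atc_code": atc, "drug_name": drug, "start_date": start}
            for atc, drug, start in history.cs_drugs
        ] + [
            {"patient_id": pid, "atc_code": atc, "drug_name": drug, "start_date": start}
            for atc, drug, _, start in history.bts_drugs
        ]
        rx_frames.append(pd.DataFrame(rx_rows))
        cm_frames.append(cm)
        lab_frames.append(labs)
        lab_frames.append(hema)
        letters.extend(pletters)
        truth_frames.append(ptruth)

        patients_rows.append(
            {
                "patient_id": pid,
                "sex": history.sex,
                "birth_year": history.birth_year,
                "ra_diagnosis_date": history.diagnosis_date,
                "clinical_label": (
                    ("D2T" if history.d2t else "nonD2T") if labeled_flags[i] else "unlabeled"
                ),
                "planted_truth": "D2T" if history.d2t else "nonD2T",
                "letter_label": letter_level_label(history, pletters, ptruth),
            }
        )

    bundle = CohortBundle(
        patients=pd.DataFrame(patients_rows),
        prescriptions=pd.concat(rx_frames, ignore_index=True),
        labs=pd.concat(lab_frames, ignore_index=True),
        clinical_measurements=pd.concat(cm_frames, ignore_index=True),
        visits=pd.concat(visit_frames, ignore_index=True),
        letters=letters,
        letter_truth=pd.concat(truth_frames, ignore_index=True),
        config=config.to_dict(),
    )
    if config.missingness_rates:
        bundle = inject_missingness(bundle, config.missingness_rates, seed=config.seed + 1)
    return bundle


def inject_missingness(
    bundle: CohortBundle, rates: dict[str, float], seed: int = 0
) -> CohortBundle:
    """Delete rows completely at random, per-table, at the stated rates.

    ``rates`` keys: prescriptions, labs, clinical_measurements, visits,
    letters.  The patients table (and its planted truth) is never touched;
    missingness here is MCAR by design.
    """
    allowed = {"prescriptions", "labs", "clinical_measurements", "visits", "letters"}
    for name, rate in rates.items():
        if name not in allowed:
            raise ValueError(f"cannot inject missingness into table {name!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {name} must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    out = bundle.copy()
    for name in ("prescriptions", "labs", "clinical_measurements", "visits"):
        rate = rates.get(name, 0.0)
        table = getattr(out, name)
        if rate > 0.0 and len(table):
            keep = rng.random(len(table)) >= rate
            setattr(out, name, table[keep].reset_index(drop=True))
    rate = rates.get("letters", 0.0)
    if rate > 0.0 and out.letters:
        keep = rng.random(len(out.letters)) >= rate
        out.letters = [l for l, k in zip(out.letters, keep) if k]
        if out.letter_truth is not None and len(out.letter_truth) == len(keep):
            out.letter_truth = out.letter_truth[keep].reset_index(drop=True)
    return out
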