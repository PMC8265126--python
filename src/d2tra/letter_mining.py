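"""D2T classification from clinical letters.

Two extraction steps feed the same two-criterion decision as the structured
rule engine: (1) medication mentions, restricted to the "Medication" and
"DMARD history" headings, establish the b/tsDMARD MoA history; (2) activity
phrases ("flare", "active arthritis", ...) in narrative headings establish
signs of active disease.  Negated mentions — a negation cue within a few
tokens before the phrase, inside the same sentence (a NegEx-style bounded
window) — are excluded, so "no flare" never counts as activity.

Matching is exact-token after lowercasing and punctuation stripping; there
is no stemming, fuzzy matching or learned NER.  The shipped lexicon is a
synthetic stand-in for locally curated term lists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .d2t_rules import ClassificationResult
from .ehr_io import ClinicalLetter

__all__ = [
    "Lexicon",
    "LetterFindings",
    "segment_sections",
    "extract_medications",
    "detect_active_disease",
    "classify_unstructured",
]

_HEADING_RE = re.compile(r"^\s*([A-Za-z][A-Za-z0-9 /\-]{0,60}):\s*$|^\s*([A-Z][A-Z /\-]{2,60})\s*$")
_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+|\n+")
_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _norm(text: str) -> str:
    return " ".join(text.strip().lower().split())


@dataclass
class Lexicon:
    """Term lists driving medication extraction and activity detection."""

    medication_terms: dict[str, tuple[str, str]]  # surface -> (drug, moa)
    activity_terms: list[str]
    negation_cues: list[str]
    target_headings: list[str] = field(default_factory=lambda: ["medication", "dmard history"])
    activity_headings: list[str] = field(default_factory=lambda: ["conclusion"])
    negation_window: int = 3

    def __post_init__(self):
        if any(not s.strip() for s in self.medication_terms):
            raise ValueError("empty medication surface form")
        self.medication_terms = {
            _norm(k): (v[0], v[1]) for k, v in self.medication_terms.items()
        }
        self.activity_terms = [_norm(t) for t in self.activity_terms]
        self.negation_cues = [_norm(c) for c in self.negation_cues]
        self.target_headings = [_norm(h) for h in self.target_headings]
        self.activity_headings = [_norm(h) for h in self.activity_headings]

    @classmethod
    def default(cls) -> "Lexicon":
        return cls.from_yaml(resources.files("d2tra") / "data" / "letter_lexicon.yaml")

    @classmethod
    def from_yaml(cls, path) -> "Lexicon":
        text = (
            path.read_text(encoding="utf-8")
            if hasattr(path, "read_text")
            else Path(path).read_text(encoding="utf-8")
        )
        data = yaml.safe_load(text)
        return cls(
            medication_terms={
                k: (v["drug"], v["moa"]) for k, v in data["medication_terms"].items()
            },
            activity_terms=list(data["activity_terms"]),
            negation_cues=list(data["negation_cues"]),
            target_headings=list(data.get("target_headings", ["medication", "dmard history"])),
            activity_headings=list(data.get("activity_headings", ["conclusion"])),
            negation_window=int(data.get("negation_window", 3)),
        )


@dataclass
class LetterFindings:
    """What the miner extracted from one letter."""

    patient_id: str
    letter_date: object
    medications_found: list[tuple[str, str]]
    active_disease: bool
    matched_spans: list[tuple[str, int, bool]]  # (phrase, char offset, negated)


def segment_sections(raw_text: str) -> dict[str, str]:
    """Split free text into heading -> body, preserving order.

    A heading is a line that either ends in a colon or is entirely
    upper-case.  Text before the first heading lands under ``"preamble"``.
    """
    if not raw_text.strip():
        raise ValueError("empty letter text")
    sections: dict[str, str] = {}
    current = "preamble"
    buffer: list[str] = []

    def flush():
        body = "\n".join(buffer).strip("\n")
        if current in sections and sections[current]:
            sections[current] += "\n" + body
        elif body or current != "preamble":
            sections[current] = body

    for line in raw_text.splitlines():
        m = _HEADING_RE.match(line)
        if m:
            flush()
            current = (m.group(1) or m.group(2)).strip()
            buffer = []
        else:
            buffer.append(line)
    flush()
    return sections


def _tokens_with_offsets(sentence: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(sentence.lower())]


def _find_phrase_matches(sentence: str, phrase: str) -> list[int]:
    """Token index of each occurrence of a (possibly multi-word) phrase."""
    toks = _tokens_with_offsets(sentence)
    words = phrase.split()
    hits = []
    for i in range(len(toks) - len(words) + 1):
        if all(toks[i + j][0] == words[j] for j in range(len(words))):
            hits.append(i)
    return hits


def extract_medications(
    sections: dict[str, str], lexicon: Lexicon | None = None
) -> list[tuple[str, str]]:
    """Drug mentions within the medication/DMARD-history headings only.

    Returns deduplicated ``(drug_name, moa_class)`` pairs in first-mention
    order; mentions under other headings (e.g. a drug merely *considered*
    in the conclusion) are ignored.
    """
    lexicon = lexicon or Lexicon.default()
    first_pos: dict[tuple[str, str], int] = {}
    # longest surface forms first so "certolizumab pegol" wins over "certolizumab"
    surfaces = sorted(lexicon.medication_terms, key=lambda s: -len(s.split()))
    offset = 0
    for heading, body in sections.items():
        if _norm(heading) not in lexicon.target_headings:
            offset += 1
            continue
        toks = [t for t, _ in _tokens_with_offsets(body)]
        consumed = [False] * len(toks)
        for surface in surfaces:
            words = surface.split()
            for i in range(len(toks) - len(words) + 1):
                if any(consumed[i + j] for j in range(len(words))):
                    continue
                if all(toks[i + j] == words[j] for j in range(len(words))):
                    key = lexicon.medication_terms[surface]
                    pos = offset * 10_000 + i
                    first_pos[key] = min(first_pos.get(key, pos), pos)
                    for j in range(len(words)):
                        consumed[i + j] = True
        offset += 1
    return sorted(first_pos, key=first_pos.get)


def detect_active_disease(
    sections: dict[str, str], lexicon: Lexicon | None = None
) -> tuple[bool, list[tuple[str, int, bool]]]:
    """Negation-aware activity detection within narrative headings.

    A phrase match is negated when a negation cue occurs within
    ``lexicon.negation_window`` tokens before it in the same sentence;
    negation never crosses a sentence boundary.  Returns ``(active, spans)``
    with ``active`` true iff at least one non-negated match exists.
    """
    lexicon = lexicon or Lexicon.default()
    spans: list[tuple[str, int, bool]] = []
    active = False
    for heading, body in sections.items():
        if _norm(heading) not in lexicon.activity_headings:
            continue
        pos = 0
        for sentence in _SENTENCE_SPLIT.split(body):
            sent_offset = body.find(sentence, pos)
            if sent_offset < 0:
                sent_offset = pos
            pos = sent_offset + len(sentence)
            if not sentence.strip():
                continue
            toks = _tokens_with_offsets(sentence)
            for phrase in lexicon.activity_terms:
                for tok_idx in _find_phrase_matches(sentence, phrase):
                    window = [
                        toks[j][0]
                        for j in range(max(0, tok_idx - lexicon.negation_window), tok_idx)
                    ]
                    negated = any(cue in window for cue in lexicon.negation_cues)
                    offset = sent_offset + toks[tok_idx][1]
                    spans.append((phrase, offset, negated))
                    if not negated:
                        active = True
    return active, spans


def mine_letter(letter: ClinicalLetter, lexicon: Lexicon | None = None) -> LetterFindings:
    """Run both extraction steps over one letter's sections."""
    lexicon = lexicon or Lexicon.default()
    meds = extract_medications(letter.sections, lexicon)
    active, spans = detect_active_disease(letter.sections, lexicon)
    return LetterFindings(
        patient_id=letter.patient_id,
        letter_date=letter.date,
        medications_found=meds,
        active_disease=active,
        matched_spans=spans,
    )


def classify_unstructured(
    letters: list[ClinicalLetter], lexicon: Lexicon | None = None,
    patient_id: str | None = None,
) -> ClassificationResult:
    """Two-criterion D2T decision from one patient's letters.

    Criterion 1: the union of drugs mentioned under the medication headings
    across all letters spans >= 2 MoA classes.  Criterion 2: any letter
    carries a non-negated activity phrase.  Evidence is cumulative — adding
    a letter can only move a patient toward D2T, never away from it.  With
    zero letters the patient is nonD2T with insufficient data.
    """
    lexicon = lexicon or Lexicon.default()
    if patient_id is None:
        patient_id = letters[0].patient_id if letters else "unknown"
    if not letters:
        return ClassificationResult(
            patient_id=patient_id,
            criterion1_met=False,
            criterion2_met=False,
            label="nonD2T",
            evidence=[("no_letters", "", "no letters available")],
            data_sufficiency="insufficient",
        )
    moa_classes: dict[str, str] = {}
    evidence: list[tuple[str, str, str]] = []
    c2 = False
    for letter in sorted(letters, key=lambda l: str(l.date)):
        findings = mine_letter(letter, lexicon)
        for drug, moa in findings.medications_found:
            if moa not in moa_classes:
                moa_classes[moa] = drug
                evidence.append(("medication_mention", str(letter.date), f"{drug} ({moa})"))
        if findings.active_disease and not c2:
            phrase = next(p for p, _, neg in findings.matched_spans if not neg)
            evidence.append(("activity_mention", str(letter.date), phrase))
            c2 = True
    c1 = len(moa_classes) >= 2
    return ClassificationResult(
        patient_id=patient_id,
        criterion1_met=c1,
        criterion2_met=c2,
        label="D2T" if (c1 and c2) else "nonD2T",
        evidence=evidence,
        data_sufficiency="sufficient",
    )
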