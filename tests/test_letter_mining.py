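"""Letter segmentation, medication extraction, negation-aware activity mining."""

import numpy as np
import pandas as pd
import pytest

from d2tra.ehr_io import ClinicalLetter
from d2tra.letter_mining import (
    Lexicon,
    classify_unstructured,
    detect_active_disease,
    extract_medications,
    mine_letter,
    segment_sections,
)

LEX = Lexicon.default()


class TestSegmentation:
    def test_two_section_split(self):
        text = "Medication:\nadalimumab 40mg\nConclusion:\nflare"
        sections = segment_sections(text)
        assert sections == {"Medication": "adalimumab 40mg", "Conclusion": "flare"}

    def test_no_headings_lands_in_preamble(self):
        sections = segment_sections("just narrative text\nover two lines")
        assert list(sections) == ["preamble"]

    def test_all_caps_line_is_a_heading(self):
        sections = segment_sections("CONCLUSION\nactive arthritis")
        assert sections == {"CONCLUSION": "active arthritis"}

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            segment_sections("   ")

    def test_content_is_conserved(self):
        text = "intro line\nMedication:\netanercept\nConclusion:\nno flare today"
        sections = segment_sections(text)
        rebuilt = " ".join(
            (h + " " + b) if h != "preamble" else b for h, b in sections.items()
        )
        for token in ["intro", "line", "Medication", "etanercept", "Conclusion", "no", "flare", "today"]:
            assert token in rebuilt


class TestMedicationExtraction:
    def test_dmard_history_lookup(self):
        sections = {"DMARD history": "etanercept, tocilizumab"}
        assert extract_medications(sections, LEX) == [
            ("etanercept", "TNFi"),
            ("tocilizumab", "IL6i"),
        ]

    def test_wrong_section_is_ignored(self):
        sections = {"Conclusion": "consider rituximab"}
        assert extract_medications(sections, LEX) == []

    def test_unknown_spelling_is_not_matched(self):
        sections = {"Medication": "adalimumabb 40mg"}
        assert extract_medications(sections, LEX) == []

    def test_heading_match_is_case_insensitive(self):
        sections = {"MEDICATION": "baricitinib 4mg"}
        assert extract_medications(sections, LEX) == [("baricitinib", "JAKi")]

    def test_duplicates_collapse(self):
        sections = {"Medication": "adalimumab; adalimumab 40mg; etanercept"}
        assert extract_medications(sections, LEX) == [
            ("adalimumab", "TNFi"),
            ("etanercept", "TNFi"),
        ]


class TestActivityDetection:
    def test_plain_flare_is_active(self):
        active, spans = detect_active_disease({"Conclusion": "flare of arthritis"}, LEX)
        assert active is True
        assert spans == [("flare", 0, False)]

    def test_no_flare_is_negated(self):
        active, spans = detect_active_disease({"Conclusion": "no flare"}, LEX)
        assert active is False
        assert spans[0][2] is True

    def test_negation_does_not_cross_sentence_boundary(self):
        active, spans = detect_active_disease(
            {"Conclusion": "No signs of infection. Flare of RA."}, LEX
        )
        assert active is True
        assert [s[2] for s in spans] == [False]

    def test_negation_window_is_bounded(self):
        # cue more than 3 tokens before the phrase no longer negates it
        active, _ = detect_active_disease(
            {"Conclusion": "no change in the persistent flare"}, LEX
        )
        assert active is True

    def test_matches_only_in_activity_headings(self):
        active, spans = detect_active_disease({"Medication": "flare"}, LEX)
        assert active is False and spans == []

    def test_span_offsets_lie_in_body(self):
        body = "Stable. There is active arthritis of the wrist."
        _, spans = detect_active_disease({"Conclusion": body}, LEX)
        for phrase, offset, _ in spans:
            assert body.lower()[offset : offset + len(phrase)] == phrase


def letter(pid, date, **sections):
    return ClinicalLetter(pid, date, dict(sections))


class TestClassifyUnstructured:
    def test_two_moa_plus_flare_is_d2t(self):
        letters = [
            letter("P1", "2015-01-01", **{"DMARD history": "etanercept, tocilizumab"}),
            letter("P1", "2016-01-01", Conclusion="flare of arthritis"),
        ]
        result = classify_unstructured(letters, LEX)
        assert (result.criterion1_met, result.criterion2_met, result.label) == (True, True, "D2T")

    def test_all_negated_activity_is_non_d2t(self):
        letters = [
            letter(
                "P1",
                "2015-01-01",
                **{"DMARD history": "etanercept, tocilizumab", "Conclusion": "no flare"},
            )
        ]
        result = classify_unstructured(letters, LEX)
        assert result.label == "nonD2T"
        assert result.criterion1_met is True

    def test_zero_letters_is_insufficient_non_d2t(self):
        result = classify_unstructured([], LEX, patient_id="P9")
        assert result.label == "nonD2T"
        assert result.data_sufficiency == "insufficient"

    def test_single_moa_never_d2t(self):
        letters = [
            letter("P1", "2015-01-01", **{"DMARD history": "etanercept, adalimumab"}),
            letter("P1", "2016-01-01", Conclusion="flare"),
        ]
        assert classify_unstructured(letters, LEX).label == "nonD2T"

    def test_adding_letters_is_monotone_toward_d2t(self, clean_cohort_500):
        by_patient = {}
        for l in clean_cohort_500.letters:
            by_patient.setdefault(l.patient_id, []).append(l)
        rng = np.random.default_rng(0)
        pids = rng.choice(sorted(by_patient), size=30, replace=False)
        for pid in pids:
            letters = sorted(by_patient[pid], key=lambda l: l.date)
            seen_d2t = False
            for k in range(1, len(letters) + 1):
                label = classify_unstructured(letters[:k], LEX).label
                if seen_d2t:
                    assert label == "D2T"
                seen_d2t = seen_d2t or label == "D2T"


class TestMinerRecoversGeneratorTruth:
    def test_per_letter_activity_matches_planted_truth(self, clean_cohort_500):
        truth = clean_cohort_500.letter_truth.set_index(["patient_id", "date"])
        for l in clean_cohort_500.letters:
            findings = mine_letter(l, LEX)
            expected = bool(
                truth.loc[(l.patient_id, pd.Timestamp(l.date)), "active_disease"]
            )
            assert findings.active_disease == expected
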