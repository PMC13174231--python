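"""Synthetic corpus generator and the exposure time-window filter."""

from datetime import date

import numpy as np
import pytest

from iraescan import SimConfig, add_months, filter_notes_by_window, generate_corpus
from iraescan.backend import mock_annotate
from iraescan.simulate import ClinicalNote, PatientRecord


def _mixture(pos=0.55, neg=0.2, hyp=0.15, alt=0.1):
    return {
        "positive_causal": pos,
        "negated": neg,
        "hypothetical": hyp,
        "alt_cause": alt,
    }


class TestConfigValidation:
    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(regime_mixture=_mixture(pos=0.9))

    def test_prevalence_must_be_probability(self):
        with pytest.raises(ValueError):
            SimConfig(prevalence=1.5)

    def test_zero_notes_with_positive_prevalence_rejected(self, demo_profile):
        cfg = SimConfig(notes_per_patient=(0, 2), prevalence=0.3, n_patients=5)
        with pytest.raises(ValueError):
            generate_corpus(cfg, demo_profile)


class TestGeneration:
    def test_same_seed_gives_byte_identical_corpora(self, demo_profile):
        cfg = SimConfig(n_patients=20, seed=42)
        a = generate_corpus(cfg, demo_profile)
        b = generate_corpus(cfg, demo_profile)
        assert a == b

    def test_different_seeds_differ(self, demo_profile):
        a = generate_corpus(SimConfig(n_patients=20, seed=1), demo_profile)
        b = generate_corpus(SimConfig(n_patients=20, seed=2), demo_profile)
        assert a != b

    def test_zero_prevalence_gives_all_none_patients(self, demo_profile):
        cfg = SimConfig(n_patients=15, prevalence=0.0, seed=5)
        records = generate_corpus(cfg, demo_profile)
        assert all(not r.gold_patient for r in records)
        assert all(not r.gold_notes for r in records)

    def test_union_of_note_gold_equals_patient_gold(self, demo_profile):
        records = generate_corpus(SimConfig(n_patients=40, seed=9), demo_profile)
        for rec in records:
            union = frozenset().union(*rec.gold_notes.values()) if rec.gold_notes else frozenset()
            assert union == rec.gold_patient

    def test_every_gold_label_realized_as_positive_mention(self, demo_profile):
        records = generate_corpus(SimConfig(n_patients=40, seed=10), demo_profile)
        for rec in records:
            for lid in rec.gold_patient:
                carrying = [nid for nid, labs in rec.gold_notes.items() if lid in labs]
                assert carrying, f"gold label {lid} has no positive-causal mention"

    def test_empirical_prevalence_converges_to_configured(self, demo_profile):
        prev = 0.2
        cfg = SimConfig(n_patients=1000, prevalence=prev, seed=77, distractor_rate=0.5)
        records = generate_corpus(cfg, demo_profile)
        for lid in demo_profile.label_ids:
            frac = np.mean([lid in r.gold_patient for r in records])
            # binomial 4-sigma band at n=1000
            assert abs(frac - prev) < 4 * np.sqrt(prev * (1 - prev) / 1000)

    def test_alt_cause_sentences_name_non_ici_agents_and_stay_non_gold(self, demo_profile):
        cfg = SimConfig(
            n_patients=60,
            seed=21,
            prevalence=0.0,
            regime_mixture=_mixture(pos=0.0, neg=0.0, hyp=0.0, alt=1.0),
            distractor_rate=0.0,
        )
        records = generate_corpus(cfg, demo_profile)
        drugs = {d.lower() for d in demo_profile.ici_drugs}
        saw_alt_sentence = False
        for rec in records:
            assert not rec.gold_patient
            for note in rec.notes:
                for sent in note.text.split(". ")[1:]:  # skip the opening line
                    low = sent.lower()
                    if "secondary to" in low or "due to" in low:
                        saw_alt_sentence = True
                        assert not any(d in low for d in drugs)
        assert saw_alt_sentence

    def test_confounders_never_trip_the_rule_backend(self, demo_profile):
        # mock calls on a gold-empty, confounder-rich corpus are all-No
        cfg = SimConfig(
            n_patients=30,
            seed=33,
            prevalence=0.0,
            regime_mixture=_mixture(pos=0.0, neg=0.4, hyp=0.3, alt=0.3),
        )
        for rec in generate_corpus(cfg, demo_profile):
            for note in rec.notes:
                calls = mock_annotate(note.text, demo_profile)
                assert set(calls.values()) == {"No"}, note.text

    def test_raising_alt_weight_does_not_create_false_negatives(self, demo_profile):
        # gold labels stay recoverable whatever the confounder mix
        for alt in (0.0, 0.5, 1.0):
            cfg = SimConfig(
                n_patients=30,
                seed=8,
                prevalence=0.25,
                regime_mixture=_mixture(pos=1 - alt, neg=0.0, hyp=0.0, alt=alt),
            )
            for rec in generate_corpus(cfg, demo_profile):
                found = set()
                for note in rec.notes:
                    calls = mock_annotate(note.text, demo_profile)
                    found |= {l for l, v in calls.items() if v == "Yes"}
                assert rec.gold_patient <= found


class TestWindowFilter:
    @staticmethod
    def _record(note_dates, first=date(2021, 1, 15), last=date(2021, 3, 10)):
        notes = tuple(
            ClinicalNote(
                note_id=f"n{i}",
                patient_id="p1",
                timestamp=d,
                note_type="progress",
                text="Stable.",
            )
            for i, d in enumerate(note_dates)
        )
        return PatientRecord(
            patient_id="p1",
            ici_exposures=(("nivolumab", first, last),),
            notes=notes,
            gold_patient=frozenset(),
        )

    def test_note_on_first_ici_day_included(self):
        rec = self._record([date(2021, 1, 15)])
        assert len(filter_notes_by_window(rec, 6).notes) == 1

    def test_note_exactly_six_months_after_last_dose_included(self):
        rec = self._record([date(2021, 9, 10)])  # 2021-03-10 + 6 months
        assert len(filter_notes_by_window(rec, 6).notes) == 1

    def test_note_one_day_beyond_window_excluded(self):
        rec = self._record([date(2021, 9, 11)])
        assert len(filter_notes_by_window(rec, 6).notes) == 0

    def test_note_seven_months_after_last_dose_excluded(self):
        rec = self._record([date(2021, 10, 10)])
        assert len(filter_notes_by_window(rec, 6).notes) == 0

    def test_note_before_first_exposure_excluded(self):
        rec = self._record([date(2021, 1, 14)])
        assert len(filter_notes_by_window(rec, 6).notes) == 0

    def test_empty_note_list_stays_empty(self):
        rec = self._record([])
        assert filter_notes_by_window(rec, 6).notes == ()

    def test_no_exposures_rejected(self):
        rec = PatientRecord(
            patient_id="p1",
            ici_exposures=(),
            notes=(),
            gold_patient=frozenset(),
        )
        with pytest.raises(ValueError):
            filter_notes_by_window(rec)

    @pytest.mark.parametrize(
        "start,months,expected",
        [
            (date(2021, 8, 31), 1, date(2021, 9, 30)),  # clamped to month end
            (date(2020, 12, 31), 2, date(2021, 2, 28)),
            (date(2021, 3, 10), 6, date(2021, 9, 10)),
        ],
    )
    def test_calendar_month_arithmetic_with_clamping(self, start, months, expected):
        assert add_months(start, months) == expected
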