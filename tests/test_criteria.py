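import numpy as np
import pandas as pd
import pytest

from pipscreen.cohort import build_cohort, filter_events
from pipscreen.criteria import (
    EngineOptions,
    eval_coprescription_rule,
    eval_dose_duration_rule,
    eval_duplication_rule,
    eval_duration_rule,
    eval_first_line_rule,
    evaluate_cohort,
    evaluate_patient,
    pip_category,
)
from pipscreen.exposure import build_episodes, classify_events, month_occupancy
from pipscreen.vocabulary import CodingSystem

from conftest import make_events, random_micro_cohort
from reference import ref_evaluate_patient

ATC = CodingSystem.ATC


def episodes_of(vocab, rows, **kw):
    return build_episodes(classify_events(make_events(rows, **kw), vocab, ATC), 63, 28)


def occupancy_of(vocab, rows, **kw):
    return month_occupancy(make_events(rows, **kw), vocab, ATC)


class TestDurationRule:
    def test_29_day_episode_triggers(self, vocab):
        rule = vocab.rule("benzo_gt_4w")
        eps = episodes_of(vocab, [("2012-01-01", "N05BA01"), ("2012-01-02", "N05BA01")])
        assert eps.loc[0, "duration_days"] == 29  # strict-inequality boundary oracle
        assert eval_duration_rule(rule, eps)

    def test_28_day_boundary_does_not(self, vocab):
        rule = vocab.rule("benzo_gt_4w")
        eps = episodes_of(vocab, [("2012-01-01", "N05BA01")])
        assert eps.loc[0, "duration_days"] == 28
        assert not eval_duration_rule(rule, eps)

    def test_no_target_episodes(self, vocab):
        rule = vocab.rule("benzo_gt_4w")
        eps = episodes_of(vocab, [("2012-01-01", "A02BC01")])
        assert not eval_duration_rule(rule, eps)


class TestDoseDurationRule:
    def test_supra_dose_57_days_triggers(self, vocab):
        rule = vocab.rule("ppi_high_dose_gt8w")
        eps = episodes_of(
            vocab,
            [("2012-01-01", "A02BC01", 80.0, 20.0), ("2012-01-30", "A02BC01", 80.0, 20.0)],
        )
        assert eps.loc[0, "duration_days"] == 57
        assert eps.loc[0, "mean_daily_dose_mg"] > 20
        assert eval_dose_duration_rule(rule, eps, vocab.dose_table, ATC)

    def test_56_day_boundary_does_not(self, vocab):
        rule = vocab.rule("ppi_high_dose_gt8w")
        eps = episodes_of(
            vocab,
            [("2012-01-01", "A02BC01", 80.0, 20.0), ("2012-01-29", "A02BC01", 80.0, 20.0)],
        )
        assert eps.loc[0, "duration_days"] == 56
        assert not eval_dose_duration_rule(rule, eps, vocab.dose_table, ATC)

    def test_maintenance_dose_never_triggers(self, vocab):
        rows = [
            (pd.Timestamp("2012-01-01") + pd.Timedelta(days=28 * k), "A02BC01", 28.0, 20.0)
            for k in range(13)
        ]
        eps = episodes_of(vocab, rows)
        assert eps.loc[0, "duration_days"] > 300
        assert not eval_dose_duration_rule(
            vocab.rule("ppi_high_dose_gt8w"), eps, vocab.dose_table, ATC
        )

    def test_unknown_dose_skipped(self, vocab):
        eps = episodes_of(
            vocab,
            [("2012-01-01", "A02BC01", 80.0, np.nan), ("2012-02-28", "A02BC01", 80.0, np.nan)],
        )
        assert not eval_dose_duration_rule(
            vocab.rule("ppi_high_dose_gt8w"), eps, vocab.dose_table, ATC
        )


class TestCoPrescriptionRule:
    def test_opioid_without_laxative(self, vocab):
        rule = vocab.rule("opioid_no_laxative")
        occ = occupancy_of(vocab, [("2012-04-10", "N02AA01")])
        assert eval_coprescription_rule(rule, occ)

    def test_same_month_laxative_covers(self, vocab):
        rule = vocab.rule("opioid_no_laxative")
        occ = occupancy_of(vocab, [("2012-04-10", "N02AA01"), ("2012-04-20", "A06AB02")])
        assert not eval_coprescription_rule(rule, occ)

    def test_any_uncovered_month_violates(self, vocab):
        # per-month exhaustive oracle: month 5 has opioid, no laxative
        rule = vocab.rule("opioid_no_laxative")
        occ = occupancy_of(
            vocab,
            [
                ("2012-03-10", "N02AA01"),
                ("2012-03-12", "A06AD11"),
                ("2012-05-10", "N02AA01"),
            ],
        )
        assert eval_coprescription_rule(rule, occ)


class TestFirstLineRule:
    def test_new_user_antihistamine_triggers(self, vocab):
        rule = vocab.rule("first_gen_antihistamine_first_line_gt7d")
        ev = make_events([("2012-02-01", "R06AB04")])
        eps = build_episodes(classify_events(ev, vocab, ATC), 63, 28)
        assert eval_first_line_rule(rule, eps, classify_events(ev, vocab, ATC))

    def test_second_gen_in_leadin_blocks(self, vocab):
        rule = vocab.rule("first_gen_antihistamine_first_line_gt7d")
        ev = make_events(
            [
                ("2011-11-01", "R06AE07", 28.0, 10.0, "leadin"),
                ("2012-02-01", "R06AB04"),
            ]
        )
        cls = classify_events(ev, vocab, ATC)
        eps = build_episodes(cls, 63, 28)
        assert not eval_first_line_rule(rule, eps, cls)

    def test_short_use_below_threshold_does_not_trigger(self, vocab):
        rule = vocab.rule("first_gen_antihistamine_first_line_gt7d")
        ev = make_events([("2012-02-01", "R06AB04")])
        cls = classify_events(ev, vocab, ATC)
        eps = build_episodes(cls, 63, 7)  # 7-day coverage -> boundary episode
        assert not eval_first_line_rule(rule, eps, cls)

    def test_tca_with_ssri_history_blocked(self, vocab):
        rule = vocab.rule("tca_first_line")
        ev = make_events(
            [("2011-10-20", "N06AB06", 28.0, 50.0, "leadin"), ("2012-03-01", "N06AA09")]
        )
        cls = classify_events(ev, vocab, ATC)
        assert not eval_first_line_rule(rule, build_episodes(cls, 63, 28), cls)

    def test_tca_any_use_new_user_triggers(self, vocab):
        rule = vocab.rule("tca_first_line")
        ev = make_events([("2012-03-01", "N06AA09")])
        cls = classify_events(ev, vocab, ATC)
        assert eval_first_line_rule(rule, build_episodes(cls, 63, 28), cls)

    def test_episode_starting_in_leadin_does_not_trigger(self, vocab):
        rule = vocab.rule("tca_first_line")
        ev = make_events([("2011-12-01", "N06AA09", 28.0, 25.0, "leadin")])
        cls = classify_events(ev, vocab, ATC)
        assert not eval_first_line_rule(rule, build_episodes(cls, 63, 28), cls)


class TestDuplicationRule:
    def test_two_chemicals_one_month(self, vocab):
        occ = occupancy_of(vocab, [("2012-03-05", "N02AA01"), ("2012-03-15", "N02AA05")])
        assert eval_duplication_rule(vocab.rule("duplicate_opioids"), occ)

    def test_one_chemical_many_times(self, vocab):
        occ = occupancy_of(vocab, [("2012-03-%02d" % d, "N02AA01") for d in (1, 5, 9, 13, 17)])
        assert not eval_duplication_rule(vocab.rule("duplicate_opioids"), occ)

    def test_adjacent_months_do_not_count(self, vocab):
        # month-partition oracle: chemicals split across 2012-03 / 2012-04
        occ = occupancy_of(vocab, [("2012-03-31", "N02AA01"), ("2012-04-01", "N02AA05")])
        assert not eval_duplication_rule(vocab.rule("duplicate_opioids"), occ)


class TestEvaluatePatient:
    def test_zero_events_all_false(self, vocab):
        prof = evaluate_patient(vocab, make_events([]), ATC)
        assert not prof["any_pip"]
        assert prof["n_pip"] == 0
        assert prof["pip_category"] == "0"
        assert not any(prof[r] for r in vocab.rule_ids)

    def test_leadin_only_events_all_false(self, vocab):
        ev = make_events(
            [("2011-11-01", "N05BA01", 28.0, 5.0, "leadin"),
             ("2011-11-02", "N05BA01", 28.0, 5.0, "leadin")]
        )
        prof = evaluate_patient(vocab, ev, ATC)
        assert not any(prof[r] for r in vocab.rule_ids)

    def test_triple_positive(self, vocab):
        ev = make_events(
            [
                ("2012-01-01", "N05BA01"),  # benzo > 28 d (chained below)
                ("2012-01-05", "N05BA01"),
                ("2012-05-01", "N02AA01"),  # opioid, no laxative
                ("2012-08-01", "N06AA09"),  # TCA first-line
            ]
        )
        prof = evaluate_patient(vocab, ev, ATC)
        assert prof["n_pip"] == 3
        assert prof["pip_category"] == "3+"

    def test_duplication_separate_by_default(self, vocab):
        # same-day duplicate codes: 28-day episode, so no duration trigger
        ev = make_events(
            [("2012-03-05", "N05BA01"), ("2012-03-05", "N05BA04"),
             ("2012-06-20", "A06AB02")]
        )
        prof = evaluate_patient(vocab, ev, ATC)
        assert prof["duplicate_benzodiazepines"]
        assert prof["any_duplication"]
        assert not prof["any_pip"]
        assert prof["n_pip"] == 0

    def test_duplication_counted_when_configured(self, vocab):
        ev = make_events([("2012-03-05", "N05BA01"), ("2012-03-05", "N05BA04")])
        opts = EngineOptions(duplication_in_any_pip=True)
        prof = evaluate_patient(vocab, ev, ATC, opts)
        assert prof["any_pip"]
        assert prof["n_pip"] == 1

    def test_any_pip_iff_n_pip_positive(self, vocab):
        rng = np.random.default_rng(11)
        for _ in range(20):
            _, events = random_micro_cohort(rng, vocab, ATC)
            events["phase"] = "observation"
            for pid, pev in events.groupby("patient_id"):
                prof = evaluate_patient(vocab, pev, ATC)
                assert prof["any_pip"] == (prof["n_pip"] >= 1)
                assert prof["pip_category"] == pip_category(prof["n_pip"])


class TestEvaluateCohort:
    def test_empty_cohort(self, vocab):
        windows = pd.DataFrame(
            columns=["patient_id", "gender", "age", "age_group",
                     "window_start", "window_end", "leadin_start"]
        )
        out = evaluate_cohort(vocab, make_events([]), windows, ATC)
        assert out.empty

    def test_require_any_dispensing_drops_event_free(self, vocab):
        reg = pd.DataFrame(
            {
                "patient_id": ["P0", "P1"],
                "date_of_birth": [pd.Timestamp("1950-01-01")] * 2,
                "gender": ["male", "female"],
            }
        )
        windows = build_cohort(reg)
        ev = filter_events(make_events([("2012-03-01", "N05BA01")]).drop(columns="phase"), windows)
        assert list(evaluate_cohort(vocab, ev, windows, ATC)["patient_id"]) == ["P0"]
        opts = EngineOptions(require_any_dispensing=False)
        assert list(evaluate_cohort(vocab, ev, windows, ATC, opts)["patient_id"]) == ["P0", "P1"]

    def test_matches_per_patient_evaluation(self, vocab):
        rng = np.random.default_rng(42)
        for _ in range(25):
            patients, events = random_micro_cohort(rng, vocab, ATC)
            windows = build_cohort(patients)
            phased = filter_events(events, windows)
            cohort_prof = evaluate_cohort(vocab, phased, windows, ATC)
            for row in cohort_prof.itertuples(index=False):
                pev = phased[phased["patient_id"] == row.patient_id]
                single = evaluate_patient(vocab, pev, ATC)
                for rid in vocab.rule_ids:
                    assert getattr(row, rid) == single[rid], rid

    def test_matches_bruteforce_reference(self, vocab):
        rng = np.random.default_rng(7)
        for _ in range(40):
            patients, events = random_micro_cohort(rng, vocab, ATC)
            windows = build_cohort(patients)
            phased = filter_events(events, windows)
            prof = evaluate_cohort(vocab, phased, windows, ATC)
            for row in prof.itertuples(index=False):
                pev = phased[phased["patient_id"] == row.patient_id]
                ref_events = [
                    {
                        "dispense_date": e.dispense_date,
                        "drug_code": e.drug_code,
                        "phase": e.phase,
                        "mg": None
                        if (pd.isna(e.quantity) or pd.isna(e.strength_mg))
                        else e.quantity * e.strength_mg,
                    }
                    for e in pev.itertuples(index=False)
                ]
                ref = ref_evaluate_patient(vocab, ref_events, ATC)
                for rid in vocab.rule_ids:
                    assert getattr(row, rid) == ref[rid], (rid, ref_events)
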