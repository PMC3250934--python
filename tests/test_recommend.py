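"""Status classification, summary page, detailed messages, translation."""

import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from precare.patient import DECLINED, Event
from precare.recommend import (
    MESSAGE_DOMAINS,
    SUMMARY_SECTIONS,
    StatusState,
    actionability_audit,
    build_message,
    build_summary,
    classify_status,
    select_resources,
    trend_series,
)
from precare.rules import Verdict, evaluate_eligibility
from precare.synthetic import PopulationSpec, generate_patient
from precare.patient import merge
from precare.translate import LAY_DICTIONARY, translate_term

from helpers import AS_OF, make_profile, obs


def _status(ruleset, service_id, profile, as_of=AS_OF):
    rule = ruleset.get(service_id)
    elig = evaluate_eligibility(rule, profile, as_of)
    return classify_status(elig, rule, profile, as_of)


def _up_to_date_profile():
    recent = dt.date(2010, 6, 15)
    return make_profile(
        sex="female",
        age=55,
        vitals=[
            obs("systolic_bp", 118), obs("diastolic_bp", 72),
            obs("height", 165), obs("weight", 60),
        ],
        labs=[
            obs("total_cholesterol", 180), obs("hdl", 55), obs("ldl", 95),
            obs("fasting_glucose", 90),
        ],
        screening_events=[
            Event(code="mammogram", date=recent),
            Event(code="pap_smear", date=recent),
            Event(code="colonoscopy", date=dt.date(2005, 6, 15)),
            Event(code="bp_check", date=recent),
            Event(code="lipid_panel", date=recent),
            Event(code="aspirin_counseling", date=dt.date(2010, 7, 1)),
            Event(code="bmi_assessment", date=recent),
            Event(code="alcohol_screening", date=recent),
        ],
        immunizations=[
            Event(code="influenza_vaccine", date=dt.date(2010, 10, 1)),
            Event(code="td_booster", date=dt.date(2005, 6, 15)),
        ],
    )


class TestClassifyStatus:
    def test_never_screened_is_due_now(self, ruleset):
        status = _status(ruleset, "colorectal_cancer_screening", make_profile(age=60))
        assert status.state == StatusState.due_now
        assert status.next_due == AS_OF and status.last_received is None

    def test_recent_screen_is_up_to_date(self, ruleset):
        profile = make_profile(
            age=60, screening_events=[Event(code="mammogram", date=dt.date(2010, 6, 1))]
        )
        status = _status(ruleset, "breast_cancer_screening", profile)
        assert status.state == StatusState.up_to_date
        assert status.next_due == dt.date(2012, 6, 1)

    def test_eligible_man_prostate_is_discussion(self, ruleset):
        status = _status(ruleset, "prostate_cancer_screening", make_profile(sex="male", age=60))
        assert status.state == StatusState.discussion
        assert status.cue == "info"

    def test_declined_field_is_missing_info(self, ruleset):
        profile = make_profile(
            sex="male", age=45, hra_overrides={"family_colorectal_cancer": DECLINED}
        )
        status = _status(ruleset, "colorectal_cancer_screening", profile)
        assert status.state == StatusState.missing_info
        assert status.reasons  # names the absent field

    def test_cue_mapping_is_one_to_one(self, ruleset):
        seen = {}
        for profile, sid in [
            (make_profile(age=60), "colorectal_cancer_screening"),
            (_up_to_date_profile(), "breast_cancer_screening"),
            (make_profile(sex="male", age=60), "prostate_cancer_screening"),
            (make_profile(sex="male", age=60), "cervical_cancer_screening"),
            (
                make_profile(sex="male", age=45,
                             hra_overrides={"family_colorectal_cancer": DECLINED}),
                "colorectal_cancer_screening",
            ),
        ]:
            status = _status(ruleset, sid, profile)
            seen[status.state] = status.cue
        assert len(seen) == 5 and len(set(seen.values())) == 5

    @given(
        age=st.integers(18, 75),
        sex=st.sampled_from(["female", "male"]),
        months_ago=st.none() | st.integers(0, 200),
    )
    def test_total_over_verdict_due_combinations(self, ruleset, age, sex, months_ago):
        events = []
        if months_ago is not None:
            when = AS_OF - dt.timedelta(days=int(months_ago * 30.44) + 40)
            if when <= dt.date(2011, 5, 1):
                events = [Event(code="mammogram", date=when)]
        profile = make_profile(sex=sex, age=age, screening_events=events)
        status = _status(ruleset, "breast_cancer_screening", profile)
        assert status.state in set(StatusState)
        if status.state == StatusState.up_to_date:
            assert status.next_due is None or status.next_due > AS_OF


class TestSummaryPage:
    def test_five_sections_present(self, ruleset):
        summary = build_summary(make_profile(), ruleset, AS_OF)
        assert summary.sections == SUMMARY_SECTIONS
        for section in SUMMARY_SECTIONS:
            assert hasattr(summary, section)

    def test_fully_up_to_date_patient_needs_nothing(self, ruleset):
        summary = build_summary(_up_to_date_profile(), ruleset, AS_OF)
        assert summary.needs_now == []
        assert summary.missing_information == []

    def test_every_service_listed_exactly_once(self, ruleset):
        summary = build_summary(make_profile(age=30), ruleset, AS_OF)
        assert sorted(summary.statuses) == sorted(r.service_id for r in ruleset.services)

    def test_declined_item_listed_as_missing(self, ruleset):
        profile = make_profile(hra_overrides={"diet_quality": DECLINED})
        summary = build_summary(profile, ruleset, AS_OF)
        assert "diet_quality" in summary.missing_information

    def test_uncontrolled_condition_in_needs_now(self, ruleset):
        profile = _up_to_date_profile()
        hot = profile.extract.model_copy(
            update={"vitals": [obs("systolic_bp", 162), obs("diastolic_bp", 96)]}
        )
        profile = profile.model_copy(update={"extract": hot})
        summary = build_summary(profile, ruleset, AS_OF)
        kinds = {(item.kind, item.ref) for item in summary.needs_now}
        assert ("condition", "systolic_bp") in kinds

    def test_entries_carry_links(self, ruleset):
        summary = build_summary(make_profile(age=60), ruleset, AS_OF)
        assert all(item.link for item in summary.needs_now)


class TestDetailedMessage:
    def test_five_mandatory_domains(self, ruleset):
        message = build_message(make_profile(age=60), ruleset.get("colorectal_cancer_screening"), AS_OF)
        assert tuple(message.domains) == MESSAGE_DOMAINS
        assert all(message.domains.values())

    def test_cholesterol_message_cites_values_and_trend(self, ruleset):
        profile = make_profile(
            sex="male",
            age=56,
            labs=[
                obs("ldl", 220, dt.date(2009, 1, 1)),
                obs("ldl", 200, dt.date(2010, 1, 1)),
                obs("total_cholesterol", 240), obs("hdl", 45),
            ],
            vitals=[obs("systolic_bp", 130)],
        )
        message = build_message(profile, ruleset.get("cholesterol_screening"), AS_OF)
        assert "mg/dL" in message.domains["patient_summary"]
        assert "goal" in message.domains["patient_summary"].lower()
        assert message.trend is not None
        assert "heart attack in the next 10 years" in message.domains["patient_summary"]

    def test_prostate_message_has_decision_support(self, ruleset):
        message = build_message(
            make_profile(sex="male", age=60), ruleset.get("prostate_cancer_screening"), AS_OF
        )
        assert message.risk_block and message.decision_block

    def test_routine_service_has_no_decision_block(self, ruleset):
        message = build_message(
            make_profile(age=60), ruleset.get("cervical_cancer_screening"), AS_OF
        )
        assert message.risk_block is None and message.decision_block is None

    def test_no_history_means_no_trend_and_due_now_steps(self, ruleset):
        message = build_message(make_profile(age=60), ruleset.get("colorectal_cancer_screening"), AS_OF)
        assert message.trend is None
        assert "due now" in message.domains["next_steps"]

    def test_actionability_audit_passes_on_generated_panel(self, ruleset):
        spec = PopulationSpec(n_patients=6, seed=7)
        for i in range(spec.n_patients):
            extract, hra = generate_patient(spec, i, ruleset=ruleset)
            profile = merge(extract, hra)
            for rule in ruleset.services:
                message = build_message(profile, rule, AS_OF)
                audit = actionability_audit(message, profile, rule)
                assert all(audit.values()), (rule.service_id, audit)


class TestTranslate:
    @pytest.mark.parametrize(
        "clinical, lay",
        [
            ("2 PO BID", "take 2 pills twice daily by mouth"),
            ("fecal occult blood test", "stool test for colon cancer screening"),
            ("1 PO QD", "take 1 pill once daily by mouth"),
        ],
    )
    def test_worked_examples(self, clinical, lay):
        result = translate_term(clinical)
        assert result.text == lay and result.translated

    def test_unknown_term_passes_through(self):
        result = translate_term("gabapentin")
        assert result.text == "gabapentin" and not result.translated

    @given(
        text=st.one_of(
            st.sampled_from(sorted(LAY_DICTIONARY)),
            st.sampled_from(sorted(LAY_DICTIONARY.values())),
            st.from_regex(r"[0-9]{1,2} PO (QD|BID|TID|QID)", fullmatch=True),
            st.text(max_size=30),
        )
    )
    def test_idempotent(self, text):
        once = translate_term(text).text
        assert translate_term(once).text == once


class TestTrendSeries:
    def test_falling_ldl(self):
        series = trend_series(
            [obs("ldl", 220, dt.date(2009, 1, 1)), obs("ldl", 200, dt.date(2010, 1, 1))],
            "ldl",
        )
        assert series.deltas == [-20.0]
        assert series.direction == "falling"

    def test_single_observation(self):
        series = trend_series([obs("ldl", 150)], "ldl")
        assert series.direction == "single_point" and series.deltas == []

    def test_unsorted_input_sorted_ascending(self):
        series = trend_series(
            [
                obs("ldl", 180, dt.date(2011, 1, 1)),
                obs("ldl", 220, dt.date(2009, 1, 1)),
                obs("ldl", 200, dt.date(2010, 1, 1)),
            ],
            "ldl",
        )
        assert [d for d, _ in series.points] == sorted(d for d, _ in series.points)
        assert series.deltas == [-20.0, -20.0]
        assert series.direction == "falling"

    def test_other_analytes_filtered_out(self):
        series = trend_series([obs("ldl", 180), obs("hdl", 50)], "ldl")
        assert len(series.points) == 1


class TestSelectResources:
    def test_uncertainty_service_offers_decision_aid(self, ruleset):
        resources = select_resources(make_profile(age=44), ruleset.get("breast_cancer_screening"))
        assert resources[0].category.value == "decision_aid"

    def test_no_matching_predicate_yields_empty(self, ruleset):
        profile = make_profile(age=40, vitals=[obs("height", 165), obs("weight", 60)])
        assert select_resources(profile, ruleset.get("obesity_screening")) == []

    def test_matching_predicate_selects(self, ruleset):
        profile = make_profile(age=40, vitals=[obs("height", 165), obs("weight", 95)])
        resources = select_resources(profile, ruleset.get("obesity_screening"))
        assert [r.category.value for r in resources] == ["community_resource"]

    def test_category_order_stable(self, ruleset):
        profile = make_profile(
            sex="male", age=56, labs=[obs("ldl", 150)], vitals=[obs("systolic_bp", 130)]
        )
        resources = select_resources(profile, ruleset.get("cholesterol_screening"))
        assert [r.category.value for r in resources] == ["risk_calculator", "self_management"]
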