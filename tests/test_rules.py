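"""Rule registry content, eligibility logic, due dates, discrepancies."""

import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from precare.errors import ConfigError, ContractError
from precare.patient import DECLINED, Event
from precare.rules import (
    Category,
    Verdict,
    detect_discrepancies,
    dump_ruleset,
    evaluate_eligibility,
    load_ruleset,
    next_due,
)

from helpers import AS_OF, make_profile, obs


class TestRegistry:
    def test_eighteen_unique_services(self, ruleset):
        ids = [r.service_id for r in ruleset.services]
        assert len(ids) == 18 and len(set(ids)) == 18

    def test_five_categories_exactly(self, ruleset):
        cats = {r.category for r in ruleset.services}
        assert cats == set(Category)

    def test_prostate_screening_is_shared_decision(self, ruleset):
        assert ruleset.get("prostate_cancer_screening").uncertainty

    def test_every_rule_names_a_source(self, ruleset):
        assert all(r.sources for r in ruleset.services)

    def test_dump_load_round_trip_is_exact(self, ruleset):
        text = dump_ruleset(ruleset)
        reloaded = load_ruleset(text)
        assert reloaded == ruleset
        assert dump_ruleset(reloaded) == text

    def test_corrupted_file_is_config_error(self, tmp_path):
        bad = tmp_path / "rules.yaml"
        bad.write_text("version: x\neffective_date: 2011-01-01\nservices: [{}]\n")
        with pytest.raises(ConfigError):
            load_ruleset(bad)


class TestEligibility:
    def test_average_risk_woman_55_colorectal_indicated(self, ruleset):
        rule = ruleset.get("colorectal_cancer_screening")
        result = evaluate_eligibility(rule, make_profile(sex="female", age=55), AS_OF)
        assert result.verdict == Verdict.indicated

    def test_family_history_lowers_colorectal_start_age(self, ruleset):
        rule = ruleset.get("colorectal_cancer_screening")
        average = make_profile(sex="male", age=45)
        elevated = make_profile(
            sex="male",
            age=45,
            hra_overrides={
                "family_colorectal_cancer": True,
                "family_colorectal_cancer_age_band": "before_60",
            },
        )
        assert evaluate_eligibility(rule, average, AS_OF).verdict == Verdict.not_indicated
        assert evaluate_eligibility(rule, elevated, AS_OF).verdict == Verdict.indicated

    def test_male_not_eligible_for_cervical_screening(self, ruleset):
        rule = ruleset.get("cervical_cancer_screening")
        result = evaluate_eligibility(rule, make_profile(sex="male", age=40), AS_OF)
        assert result.verdict == Verdict.not_indicated
        assert any("sex" in reason for reason in result.reasons)

    def test_declined_decisive_answer_gives_insufficient_info(self, ruleset):
        rule = ruleset.get("colorectal_cancer_screening")
        profile = make_profile(
            sex="male", age=45, hra_overrides={"family_colorectal_cancer": DECLINED}
        )
        result = evaluate_eligibility(rule, profile, AS_OF)
        assert result.verdict == Verdict.insufficient_info
        assert any("family_colorectal_cancer" in r for r in result.reasons)

    def test_mammography_start_age_stratum_is_uncertain(self, ruleset):
        rule = ruleset.get("breast_cancer_screening")
        assert evaluate_eligibility(rule, make_profile(age=44), AS_OF).verdict == Verdict.uncertain
        assert evaluate_eligibility(rule, make_profile(age=60), AS_OF).verdict == Verdict.indicated

    @given(
        age=st.integers(18, 75),
        sex=st.sampled_from(["female", "male"]),
        tobacco=st.sampled_from(["never", "former", "current", DECLINED]),
    )
    def test_exhaustive_single_verdict(self, ruleset, age, sex, tobacco):
        profile = make_profile(sex=sex, age=age, hra_overrides={"tobacco_use": tobacco})
        for rule in ruleset.services:
            result = evaluate_eligibility(rule, profile, AS_OF)
            assert result.verdict in set(Verdict)


class TestNextDue:
    def test_colonoscopy_interval_arithmetic(self, ruleset):
        rule = ruleset.get("colorectal_cancer_screening")
        profile = make_profile(
            sex="female",
            age=60,
            screening_events=[Event(code="colonoscopy", date=dt.date(2005, 3, 1))],
        )
        assert next_due(rule, profile, AS_OF) == dt.date(2015, 3, 1)

    def test_never_screened_due_immediately(self, ruleset):
        rule = ruleset.get("colorectal_cancer_screening")
        assert next_due(rule, make_profile(age=60), AS_OF) == AS_OF

    def test_one_time_vaccine_received_never_due_again(self, ruleset):
        rule = ruleset.get("pneumococcal_vaccine")
        profile = make_profile(
            age=70, immunizations=[Event(code="pneumococcal_vaccine", date=dt.date(2009, 1, 1))]
        )
        assert next_due(rule, profile, AS_OF) is None

    def test_most_recent_event_governs(self, ruleset):
        rule = ruleset.get("breast_cancer_screening")
        profile = make_profile(
            age=60,
            screening_events=[
                Event(code="mammogram", date=dt.date(2007, 1, 1)),
                Event(code="mammogram", date=dt.date(2010, 6, 1)),
            ],
        )
        assert next_due(rule, profile, AS_OF) == dt.date(2012, 6, 1)

    def test_contract_error_on_not_indicated(self, ruleset):
        rule = ruleset.get("cervical_cancer_screening")
        with pytest.raises(ContractError):
            next_due(rule, make_profile(sex="male", age=40), AS_OF)

    @given(shift=st.integers(-60, 60), day=st.integers(1, 28))
    def test_translation_covariance_in_months(self, ruleset, shift, day):
        """Shifting the event and as_of by k months shifts the due date by k.

        Due dates are calendar-month arithmetic, so the covariance unit is
        the month (day-level shifts can land on months of different length).
        """
        from precare._dates import add_months

        rule = ruleset.get("breast_cancer_screening")
        base_event = dt.date(2010, 3, day)
        profile = make_profile(
            age=60, screening_events=[Event(code="mammogram", date=base_event)]
        )
        shifted_date = add_months(base_event, shift)
        shifted_extract = profile.extract.model_copy(
            update={
                "screening_events": [Event(code="mammogram", date=shifted_date)],
                "extract_date": add_months(profile.extract.extract_date, shift),
            }
        )
        shifted = profile.model_copy(update={"extract": shifted_extract})
        base_due = next_due(rule, profile, AS_OF)
        shifted_due = next_due(rule, shifted, add_months(AS_OF, shift))
        assert shifted_due == add_months(base_due, shift)


class TestDiscrepancies:
    def test_ada_yes_uspstf_no_flags_diabetes(self, ruleset):
        # 50-year-old, normal blood pressure, no hypertension: ADA screens by
        # age >= 45, USPSTF requires elevated pressure.
        profile = make_profile(
            sex="male", age=50, vitals=[obs("systolic_bp", 118), obs("diastolic_bp", 76)]
        )
        flags = detect_discrepancies(profile, ruleset, AS_OF)
        assert len(flags) == 1
        flag = flags[0]
        assert flag.service_id == "diabetes_screening"
        assert set(flag.organizations) == {"USPSTF", "ADA"}
        assert set(flag.verdicts) == {Verdict.indicated, Verdict.not_indicated}

    def test_agreement_produces_no_flag(self, ruleset):
        profile = make_profile(
            sex="male",
            age=50,
            conditions=["hypertension"],
            vitals=[obs("systolic_bp", 150), obs("diastolic_bp", 92)],
        )
        assert detect_discrepancies(profile, ruleset, AS_OF) == []

    def test_undecidable_variant_produces_no_flag(self, ruleset):
        # No blood pressure on file: the USPSTF branch cannot be decided.
        profile = make_profile(sex="male", age=40)
        assert detect_discrepancies(profile, ruleset, AS_OF) == []
        rule = ruleset.get("diabetes_screening")
        assert (
            evaluate_eligibility(rule, profile, AS_OF).verdict == Verdict.insufficient_info
        )

    def test_single_organization_rules_never_flag(self, ruleset):
        profile = make_profile(sex="female", age=55)
        flags = detect_discrepancies(profile, ruleset, AS_OF)
        assert all(f.service_id == "diabetes_screening" for f in flags)
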