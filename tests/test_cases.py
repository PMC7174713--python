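"""Naranjo scoring, risk-factor screening, time to onset."""

import datetime as dt

import pytest
from hypothesis import given, strategies as st

from quinpv.cases import (
    Causality,
    NARANJO_WEIGHTS,
    NegativeLatencyError,
    RiskFactor,
    flag_risk_factors,
    load_non_approved_indications,
    naranjo_score,
    risk_factor_crosstab,
    time_to_event,
)
from quinpv.icsr import Gender

from conftest import make_icsr

answers_strategy = st.lists(
    st.sampled_from(["yes", "no", "unknown"]), min_size=10, max_size=10
)


class TestNaranjo:
    def test_all_unknown_is_doubtful_zero(self):
        a = naranjo_score(["unknown"] * 10)
        assert a.score == 0
        assert a.category is Causality.DOUBTFUL

    def test_single_positive_answer(self):
        answers = ["unknown"] * 10
        answers[1] = "yes"  # drug-then-event question, weight +2
        a = naranjo_score(answers)
        assert a.score == 2
        assert a.category is Causality.POSSIBLE

    def test_probable_composite(self):
        answers = ["unknown"] * 10
        answers[0] = answers[1] = answers[2] = "yes"
        answers[4] = "no"  # no alternative cause: +2
        a = naranjo_score(answers)
        assert a.score == 6
        assert a.category is Causality.PROBABLE

    @pytest.mark.parametrize(
        "score,category",
        [(-4, Causality.DOUBTFUL), (0, Causality.DOUBTFUL),
         (1, Causality.POSSIBLE), (4, Causality.POSSIBLE),
         (5, Causality.PROBABLE), (8, Causality.PROBABLE),
         (9, Causality.DEFINITE), (13, Causality.DEFINITE)],
    )
    def test_category_boundaries_exact(self, score, category):
        """Construct an answer vector achieving each boundary score."""
        vector = _vector_with_score(score)
        a = naranjo_score(vector)
        assert a.score == score
        assert a.category is category

    @given(answers_strategy)
    def test_score_is_sum_of_weights(self, answers):
        index = {"yes": 0, "no": 1, "unknown": 2}
        expected = sum(
            NARANJO_WEIGHTS[q][index[a]] for q, a in enumerate(answers)
        )
        assert naranjo_score(answers).score == expected

    @given(answers_strategy)
    def test_score_within_scale_range(self, answers):
        assert -4 <= naranjo_score(answers).score <= 13

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="10"):
            naranjo_score(["yes"] * 9)

    def test_bad_token_rejected(self):
        with pytest.raises(ValueError, match="maybe"):
            naranjo_score(["maybe"] + ["unknown"] * 9)


def _vector_with_score(target: int) -> list:
    """Greedy exact construction over per-question (yes, no) weight options."""
    answers = ["unknown"] * 10
    remaining = target
    if remaining < 0:
        for q in (1, 3, 4, 5):  # negative options: -1 each on q2/q4; q5 yes; q6 yes
            choice = {1: "no", 3: "no", 4: "yes", 5: "yes"}[q]
            if remaining < 0:
                answers[q] = choice
                remaining += 1
        assert remaining == 0
        return answers
    gains = [(4, "no", 2), (1, "yes", 2), (3, "yes", 2), (0, "yes", 1),
             (2, "yes", 1), (6, "yes", 1), (7, "yes", 1), (8, "yes", 1),
             (9, "yes", 1), (5, "no", 1)]
    for q, token, w in gains:
        if remaining >= w and answers[q] == "unknown":
            answers[q] = token
            remaining -= w
        if remaining == 0:
            break
    assert remaining == 0
    return answers


class TestRiskFactors:
    def test_age_over_threshold(self, pt_dict):
        icsr = make_icsr("R-1", ["ciprofloxacin"], ["tremor"], pt_dict, age_years=74)
        profile = flag_risk_factors(icsr)
        assert profile.flags == {RiskFactor.AGE_OVER_60}

    def test_age_exactly_sixty_not_flagged(self, pt_dict):
        icsr = make_icsr("R-2", ["ciprofloxacin"], ["tremor"], pt_dict, age_years=60)
        assert RiskFactor.AGE_OVER_60 not in flag_risk_factors(icsr).flags

    def test_missing_age_not_flagged(self, pt_dict):
        icsr = make_icsr("R-3", ["ciprofloxacin"], ["tremor"], pt_dict)
        assert RiskFactor.AGE_OVER_60 not in flag_risk_factors(icsr).flags

    def test_comorbidity_triple(self, pt_dict):
        icsr = make_icsr(
            "R-4", ["ciprofloxacin"], ["tremor"], pt_dict,
            age_years=65,
            comorbidities={"renal_failure", "organ_transplantation"},
        )
        profile = flag_risk_factors(icsr)
        assert profile.n_flags == 3
        assert {RiskFactor.RENAL_FAILURE, RiskFactor.ORGAN_TRANSPLANTATION} <= profile.flags

    def test_corticosteroid_and_history(self, pt_dict):
        icsr = make_icsr(
            "R-5", ["ciprofloxacin"], ["tremor"], pt_dict,
            concomitant_corticosteroid=True, prior_quinolone_reaction=True,
        )
        assert {RiskFactor.CORTICOSTEROID_USE,
                RiskFactor.HISTORY_OF_SIDE_EFFECTS} == flag_risk_factors(icsr).flags

    def test_indication_screen(self, pt_dict):
        icsr = make_icsr("R-6", ["ciprofloxacin"], ["tremor"], pt_dict)
        icsr.suspects[0].indication = "Tonsillitis"
        approved = {"urinary tract infection"}
        assert RiskFactor.THERAPEUTIC_INDICATION in flag_risk_factors(icsr, approved).flags
        icsr.suspects[0].indication = "urinary  tract INFECTION"
        assert RiskFactor.THERAPEUTIC_INDICATION not in flag_risk_factors(icsr, approved).flags
        icsr.suspects[0].indication = None  # missing: never flagged
        assert RiskFactor.THERAPEUTIC_INDICATION not in flag_risk_factors(icsr, approved).flags

    def test_packaged_non_approved_list(self):
        listed = load_non_approved_indications()
        assert "tonsillitis" in listed and "renal colic" in listed
        assert len(listed) == 10


class TestTimeToEvent:
    def test_same_day(self):
        assert time_to_event(dt.date(2018, 5, 3), dt.date(2018, 5, 3)) == 0

    def test_three_days(self):
        assert time_to_event(dt.date(2018, 5, 3), dt.date(2018, 5, 6)) == 3

    def test_negative_latency_rejected(self):
        with pytest.raises(NegativeLatencyError):
            time_to_event(dt.date(2018, 5, 3), dt.date(2018, 5, 1))

    @given(st.integers(0, 3650))
    def test_shift_identity(self, k):
        start = dt.date(2010, 1, 1)
        assert time_to_event(start, start + dt.timedelta(days=k)) == k


class TestCrosstab:
    def test_single_flagged_icsr(self, pt_dict):
        icsr = make_icsr("X-1", ["ciprofloxacin"], ["tremor"], pt_dict, age_years=70)
        icsr.suspects[0].indication = "flu"
        table = risk_factor_crosstab([icsr]).set_index("soc_group")
        row = table.loc["nervous"]
        assert row["total_flags"] == 2
        assert row["flagged_icsrs"] == 1
        assert table.loc["total", "total_flags"] == 2

    def test_hand_fixture_totals(self, pt_dict):
        icsrs = [
            make_icsr("X-1", ["levofloxacin"], ["myalgia"], pt_dict, age_years=75),
            make_icsr("X-2", ["levofloxacin"], ["insomnia"], pt_dict, age_years=30,
                      comorbidities={"renal_failure"}),
            make_icsr("X-3", ["ciprofloxacin"], ["tremor", "myalgia"], pt_dict,
                      age_years=66, concomitant_corticosteroid=True),
            make_icsr("X-4", ["ciprofloxacin"], ["nausea"], pt_dict, age_years=80),
            make_icsr("X-5", ["ciprofloxacin"], ["headache"], pt_dict, age_years=50),
        ]
        table = risk_factor_crosstab(icsrs).set_index("soc_group")
        assert table.loc["musculoskeletal", "age_over_60"] == 1
        assert table.loc["psychiatric", "renal_failure"] == 1
        assert table.loc["multiple", "total_flags"] == 2
        # X-4 (no target-SOC event) and X-5 (no flags) contribute nothing
        assert table.loc["total", "total_flags"] == 4
        assert table.loc["total", "flagged_icsrs"] == 3

    def test_conservation_against_per_icsr_flags(self, pt_dict):
        import numpy as np
        from conftest import random_listing

        icsrs = random_listing(np.random.default_rng(7), 40, pt_dict)
        for i, icsr in enumerate(icsrs):
            icsr.age_years = 40 + i
        from quinpv.icsr import classify_icsr_soc_group, SocGroup

        table = risk_factor_crosstab(icsrs).set_index("soc_group")
        expected = sum(
            flag_risk_factors(r).n_flags
            for r in icsrs
            if classify_icsr_soc_group(r) is not SocGroup.NONE
        )
        assert table.loc["total", "total_flags"] == expected

    def test_no_flags_all_zero(self, pt_dict):
        icsr = make_icsr("X-9", ["ciprofloxacin"], ["tremor"], pt_dict)
        table = risk_factor_crosstab([icsr])
        assert (table.drop(columns="soc_group").to_numpy() == 0).all()
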