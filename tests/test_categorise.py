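"""Risk categorisation: bands, overrides, actions, VFA, end-to-end assess."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from noggrisk import (
    Action,
    Category,
    FraxProbabilities,
    PatientProfile,
    apply_clinical_overrides,
    assess,
    classify_outcome,
    combine_categories,
    recommend_action,
    thresholds_at,
    vfa_indicated,
)

from .conftest import PUBLISHED_ANCHORS, make_probs


def oracle_classify(prob, lat, it, uat, vhrt, bmd_included):
    """Brute-force comparator written independently of the engine."""
    if bmd_included:
        if prob < it:
            return "low"
        elif prob < vhrt:
            return "high"
        else:
            return "very_high"
    else:
        if prob < lat:
            return "low"
        elif prob < uat:
            return "intermediate"
        elif prob < vhrt:
            return "high"
        else:
            return "very_high"


class TestClassifyOutcome:
    def test_high_with_bmd(self):
        assert classify_outcome(25, thresholds_at(70, "mof"), True) is Category.HIGH

    def test_very_high_with_bmd(self):
        assert classify_outcome(33, thresholds_at(70, "mof"), True) is Category.VERY_HIGH

    def test_low_without_bmd(self):
        assert classify_outcome(10, thresholds_at(70, "mof"), False) is Category.LOW

    def test_boundary_goes_to_higher_category(self):
        t = thresholds_at(70, "mof")
        assert classify_outcome(t.it, t, True) is Category.HIGH
        assert classify_outcome(t.vhrt, t, True) is Category.VERY_HIGH
        assert classify_outcome(t.lat, t, False) is Category.INTERMEDIATE
        assert classify_outcome(t.uat, t, False) is Category.HIGH

    def test_no_intermediate_with_bmd(self):
        t = thresholds_at(60, "mof")
        for prob in np.arange(0, 50, 0.5):
            assert classify_outcome(float(prob), t, True) is not Category.INTERMEDIATE

    def test_unordered_thresholds_rejected(self):
        from noggrisk.thresholds import Thresholds

        with pytest.raises(ValueError):
            classify_outcome(10, Thresholds(5, 4, 6, 8), True)

    @pytest.mark.parametrize("outcome", list(PUBLISHED_ANCHORS))
    @pytest.mark.parametrize("bmd", [True, False])
    def test_grid_agrees_with_oracle(self, outcome, bmd):
        """Exhaustive 0-50% grid (0.1 steps) at every anchor age matches the
        independently written comparator."""
        for age in PUBLISHED_ANCHORS[outcome]:
            t = thresholds_at(age, outcome)
            for prob in np.round(np.arange(0, 50.0001, 0.1), 1):
                got = classify_outcome(float(prob), t, bmd).token
                want = oracle_classify(float(prob), *t, bmd)
                assert got == want, (outcome, age, prob, bmd)


class TestCombine:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (Category.HIGH, Category.VERY_HIGH, Category.VERY_HIGH),
            (Category.LOW, Category.LOW, Category.LOW),
            (Category.INTERMEDIATE, Category.LOW, Category.INTERMEDIATE),
        ],
    )
    def test_maximum(self, a, b, expected):
        assert combine_categories(a, b) is expected
        assert combine_categories(b, a) is expected


class TestOverrides:
    def test_tscore_override(self):
        prof = PatientProfile(age=70, min_tscore_override=-3.7)
        cat, reasons = apply_clinical_overrides(Category.HIGH, prof)
        assert cat is Category.VERY_HIGH
        assert any("-3.5" in r for r in reasons)

    def test_no_flags_no_change(self, neutral_profile):
        cat, reasons = apply_clinical_overrides(Category.LOW, neutral_profile)
        assert cat is Category.LOW and reasons == []

    def test_recent_vertebral_fracture(self):
        prof = PatientProfile(
            age=70, recent_vertebral_fracture=True, vertebral_fracture_count=1
        )
        cat, _ = apply_clinical_overrides(Category.HIGH, prof)
        assert cat is Category.VERY_HIGH

    def test_two_vertebral_fractures(self):
        prof = PatientProfile(age=70, vertebral_fracture_count=2)
        cat, _ = apply_clinical_overrides(Category.LOW, prof)
        assert cat is Category.VERY_HIGH

    def test_high_dose_glucocorticoids(self):
        prof = PatientProfile(age=70, gc_dose_tier="high")
        cat, reasons = apply_clinical_overrides(Category.LOW, prof)
        assert cat is Category.VERY_HIGH
        assert any("glucocorticoid" in r for r in reasons)

    def test_multiple_crfs_with_recent_fracture_only_from_high(self):
        prof = PatientProfile(
            age=75, recurrent_falls=True, kyphosis=True, parkinsons=True,
            prior_fragility_fracture=True, recent_mof_months=6,
        )
        from_high, _ = apply_clinical_overrides(Category.HIGH, prof)
        assert from_high is Category.VERY_HIGH
        from_low, _ = apply_clinical_overrides(Category.LOW, prof)
        assert from_low is Category.LOW

    def test_never_lowers(self, neutral_profile):
        for cat in Category:
            out, _ = apply_clinical_overrides(cat, neutral_profile)
            assert out >= cat

    def test_recent_vf_requires_count(self):
        with pytest.raises(ValueError):
            PatientProfile(age=70, recent_vertebral_fracture=True)


class TestRecommendAction:
    def test_very_high(self, neutral_profile):
        assert (
            recommend_action(Category.VERY_HIGH, neutral_profile)
            is Action.OFFER_TREATMENT_CONSIDER_REFERRAL
        )

    def test_low(self, neutral_profile):
        assert recommend_action(Category.LOW, neutral_profile) is Action.LIFESTYLE_ADVICE

    def test_high(self, neutral_profile):
        assert recommend_action(Category.HIGH, neutral_profile) is Action.OFFER_TREATMENT

    def test_intermediate_bmd_practical(self, neutral_profile):
        assert (
            recommend_action(Category.INTERMEDIATE, neutral_profile)
            is Action.MEASURE_BMD_THEN_REASSESS
        )

    def test_intermediate_bmd_impractical_prior_fracture(self):
        prof = PatientProfile(age=82, bmd_practical=False, prior_fragility_fracture=True)
        assert recommend_action(Category.INTERMEDIATE, prof) is Action.OFFER_TREATMENT

    def test_intermediate_bmd_impractical_no_trigger(self):
        prof = PatientProfile(age=82, bmd_practical=False)
        assert recommend_action(Category.INTERMEDIATE, prof) is Action.LIFESTYLE_ADVICE


class TestVfa:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"height_loss_cm": 5},
            {"height_loss_cm": 4},
            {"kyphosis": True},
            {"gc_dose_tier": "medium"},
            {"min_tscore_override": -2.6},
            {"fn_tscore": -2.5},
            {"acute_back_pain": True, "recurrent_falls": True},
        ],
    )
    def test_indicated(self, kwargs):
        assert vfa_indicated(PatientProfile(age=70, **kwargs))

    def test_not_indicated_empty_profile(self, neutral_profile):
        assert not vfa_indicated(neutral_profile)

    def test_back_pain_alone_insufficient(self):
        assert not vfa_indicated(PatientProfile(age=70, acute_back_pain=True))


class TestAssess:
    def test_neutral_low(self, neutral_profile):
        a = assess(neutral_profile, make_probs(5, 0.5))
        assert a.overall_category is Category.LOW
        assert a.action is Action.LIFESTYLE_ADVICE
        assert a.dual_points is None

    def test_gc_dual_points(self):
        prof = PatientProfile(age=70, gc_dose_tier="high")
        a = assess(prof, make_probs(18, 4, bmd=True))
        assert a.dual_points is not None
        medium, high = a.dual_points
        assert medium.ledger.final.mof_pct == pytest.approx(18)
        assert high.ledger.final.mof_pct == pytest.approx(18 * 1.15)

    def test_vertebral_fractures_force_very_high(self):
        prof = PatientProfile(age=60, vertebral_fracture_count=2)
        a = assess(prof, make_probs(2, 0.2, age=60))
        assert a.overall_category is Category.VERY_HIGH
        assert a.action is Action.OFFER_TREATMENT_CONSIDER_REFERRAL

    def test_hip_outcome_can_drive_overall(self):
        a = assess(PatientProfile(age=70), make_probs(5, 9, bmd=True))
        assert a.hip_category is Category.VERY_HIGH  # 9 >= 8.6
        assert a.overall_category is Category.VERY_HIGH

    def test_deterministic(self):
        prof = PatientProfile(age=70, recurrent_falls=True, gc_dose_tier="low")
        p = make_probs(15, 3)
        assert assess(prof, p).to_dict() == assess(prof, p).to_dict()

    @given(
        p1=st.floats(0.1, 45), p2=st.floats(0.1, 45),
        hip=st.floats(0.05, 5), bmd=st.booleans(),
        age=st.floats(50, 95),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_in_mof_probability(self, p1, p2, hip, bmd, age):
        """Raising the MOF probability never lowers the overall category."""
        lo, hi = sorted((p1, p2))
        prof = PatientProfile(age=age)
        a_lo = assess(prof, make_probs(lo, hip, age=age, bmd=bmd))
        a_hi = assess(prof, make_probs(hi, hip, age=age, bmd=bmd))
        assert a_lo.overall_category <= a_hi.overall_category
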