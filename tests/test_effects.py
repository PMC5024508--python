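"""Per-domain incremental effects: golden values and invariant properties."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simsmoke import (
    Domain,
    MarketingTier,
    MediaTier,
    PolicyStatus,
    all_policy_effects,
    cessation_effect,
    compute_price_increase,
    long_term_effect,
    marketing_effect,
    media_effect,
    smokefree_effect,
    tax_effect,
    warnings_effect,
)
from simsmoke.profile import WarningTier
from simsmoke.synthetic import generate_profile

# Published Israel values: short-term and long-term fractional reductions.
ISRAEL_GOLDEN = {
    Domain.TAX: (0.059, 0.117, 0.001),
    Domain.SMOKEFREE: (0.046, 0.058, 0.005),
    Domain.CESSATION: (0.026, 0.065, 0.001),
    Domain.MEDIA: (0.055, 0.066, 0.001),
    Domain.MARKETING: (0.044, 0.057, 0.001),
    Domain.WARNINGS: (0.020, 0.040, 0.001),
}


@pytest.mark.parametrize("domain", list(ISRAEL_GOLDEN))
def test_israel_effects_match_published(israel_profile, israel_status, params, domain):
    """Each MPOWER domain reproduces the published Israel effect sizes."""
    effect = all_policy_effects(israel_profile, israel_status, params)[domain]
    short, long, tol = ISRAEL_GOLDEN[domain]
    assert effect.short_term == pytest.approx(short, abs=tol)
    # Long-term tolerance is looser only via the multiplier on the same slack.
    mult = params.long_term_multipliers[domain]
    assert effect.long_term == pytest.approx(long, abs=max(tol * mult, 0.0011))


class TestTax:
    def test_short_term_is_elasticity_times_price_increase(self, israel, params):
        profile, status = israel
        e = tax_effect(profile, status, params, price_increase_override=0.39)
        assert e.short_term == pytest.approx(0.15 * 0.39)
        assert e.long_term == pytest.approx(0.117)

    def test_fixture_override_used(self, israel, params):
        profile, status = israel
        assert status.price_increase_override == pytest.approx(0.39)
        assert tax_effect(profile, status, params).short_term == pytest.approx(0.0585)

    def test_at_target_share_zero_effect(self, israel, params, caplog):
        profile, status = israel
        status = status.replace(excise_share=0.75, price_increase_override=None)
        with caplog.at_level("WARNING"):
            e = tax_effect(profile, status, params)
        assert e.short_term == 0.0
        assert any("zero tax effect" in r.message for r in caplog.records)

    def test_price_increase_net_component_fixed(self, israel, params):
        # hand algebra: (1-0.50)/(1-0.60) - 1 = 0.25, VAT-free
        _, status = israel
        status = status.replace(excise_share=0.50, vat_rate=0.0,
                                price_increase_override=None)
        pc = compute_price_increase(status, params.with_overrides(tax_target_share=0.60))
        assert pc.relative_price_increase == pytest.approx(0.25)

    def test_no_share_change_no_price_change(self, israel, params):
        _, status = israel
        status = status.replace(excise_share=0.75, vat_rate=0.17,
                                price_increase_override=None)
        pc = compute_price_increase(status, params)
        assert pc.relative_price_increase == 0.0

    def test_target_plus_vat_share_at_unity_rejected(self, israel, params):
        _, status = israel
        status = status.replace(vat_rate=0.30, price_increase_override=None)
        bad = params.with_overrides(tax_target_share=0.80)
        with pytest.raises(ValueError, match="price undefined"):
            compute_price_increase(status, bad)


class TestSmokefree:
    def test_zero_when_already_at_target(self, israel_profile, params):
        status = PolicyStatus.mpower_target(vat_rate=0.17)
        assert smokefree_effect(israel_profile, status, params).short_term == 0.0

    def test_adjustors_annihilate_worksite_term(self, israel, params):
        # No labor force and no venue change: only worksite term remains and
        # it is wiped out by the labor adjustor.
        profile, _ = israel
        profile = profile.replace(
            labor_participation_by_gender={g: 0.0 for g in profile.genders},
            pct_agriculture=0.0,
        )
        status = PolicyStatus.mpower_target(vat_rate=0.17)
        e = smokefree_effect(profile, status, params)
        assert e.short_term == 0.0

    def test_gender_symmetric_profile_gives_identical_effects(self, israel, params):
        profile, status = israel
        profile = profile.replace(
            population_by_gender={"male": 1_000_000, "female": 1_000_000},
            prevalence_by_gender={"male": 0.2, "female": 0.2},
            labor_participation_by_gender={"male": 0.65, "female": 0.65},
        )
        e = smokefree_effect(profile, status, params)
        assert e.short_by_gender["male"] == pytest.approx(e.short_by_gender["female"])

    def test_pooled_effect_weighted_by_smokers(self, israel, params):
        profile, status = israel
        e = smokefree_effect(profile, status, params)
        smokers = {
            g: profile.population_by_gender[g] * profile.prevalence_by_gender[g]
            for g in profile.genders
        }
        expected = sum(e.short_by_gender[g] * smokers[g] for g in smokers) / sum(
            smokers.values()
        )
        assert e.short_term == pytest.approx(expected)


class TestCessation:
    def test_israel_current_is_sum_of_present_subpolicies(self, israel, params):
        profile, status = israel
        e = cessation_effect(profile, status, params)
        current = 0.00667 + 0.00334 + 0.01125  # NRT-OTC, Rx meds, provision-some
        assert e.short_term == pytest.approx(0.0475 - current)

    def test_all_subpolicies_present_zero_effect(self, israel_profile, params):
        status = PolicyStatus.mpower_target(vat_rate=0.17)
        assert cessation_effect(israel_profile, status, params).short_term == 0.0

    def test_publicity_scaling_symmetric(self, israel, params):
        profile, status = israel
        plain = cessation_effect(profile, status, params)
        scaled = cessation_effect(profile, status, params, apply_publicity=True)
        factor = 0.75 + 0.25 * status.publicity_level
        assert scaled.short_term == pytest.approx(plain.short_term * factor)


class TestTierPolicies:
    def test_media_low_to_high(self, israel_status, params):
        e = media_effect(israel_status, params)
        assert e.short_term == pytest.approx(0.065 - 0.01)
        assert e.long_term == pytest.approx(0.066)

    def test_media_already_high(self, israel_status, params):
        status = israel_status.replace(media_tier=MediaTier.HIGH)
        assert media_effect(status, params).short_term == 0.0

    def test_marketing_partial_enforcement_two(self, israel_status, params):
        e = marketing_effect(israel_status, params)
        assert e.short_term == pytest.approx(0.05 - 0.01 * 0.6)
        assert e.long_term == pytest.approx(0.044 * 1.3)

    def test_marketing_comprehensive_fully_enforced(self, israel_status, params):
        status = israel_status.replace(
            marketing_tier=MarketingTier.COMPREHENSIVE, marketing_enforcement=10
        )
        assert marketing_effect(status, params).short_term == 0.0

    def test_warnings_default_full_credit(self, israel_status, params):
        e = warnings_effect(israel_status, params)
        assert e.short_term == pytest.approx(0.02)
        assert e.long_term == pytest.approx(0.04)

    def test_warnings_baseline_credit_subtracts_current_tier(self, israel_status, params):
        e = warnings_effect(israel_status, params, baseline_credit=True)
        assert e.short_term == pytest.approx(0.02 - 0.01)

    def test_warnings_complete_always_zero(self, israel_status, params):
        status = israel_status.replace(warning_tier=WarningTier.COMPLETE)
        assert warnings_effect(status, params).short_term == 0.0
        assert warnings_effect(status, params, baseline_credit=True).short_term == 0.0


@pytest.mark.parametrize(
    "short, domain, expected",
    [(0.026, Domain.CESSATION, 0.065), (0.0, Domain.TAX, 0.0), (0.02, Domain.WARNINGS, 0.04)],
)
def test_long_term_effect(params, short, domain, expected):
    assert long_term_effect(short, domain, params) == pytest.approx(expected)


def test_long_term_effect_capped(params):
    assert long_term_effect(0.9, Domain.CESSATION, params) == params.long_term_cap


# ---------------------------------------------------------------------------
# Properties over synthetic statuses


@settings(max_examples=150, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_all_effects_bounded_and_ordered(seed, params):
    """Every effect lies in [0, 1) with short <= long, for any admissible status."""
    profile, status = generate_profile(seed)
    for e in all_policy_effects(profile, status, params).values():
        assert 0.0 <= e.short_term <= e.long_term < 1.0


@settings(max_examples=100, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_weaker_baseline_never_decreases_effect(seed, params):
    """Weakening any current-policy field cannot shrink the incremental effect."""
    profile, status = generate_profile(seed)
    base = all_policy_effects(profile, status, params)
    weaker = status.replace(
        smokefree_coverage=status.smokefree_coverage / 2,
        smokefree_enforcement=max(0, status.smokefree_enforcement - 1),
        marketing_enforcement=max(0, status.marketing_enforcement - 1),
        media_tier=MediaTier.NONE,
        cessation_quitline=False,
        excise_share=min(status.excise_share, 0.40),
        price_increase_override=None,
    )
    low = all_policy_effects(profile, weaker, params)
    for d in base:
        assert low[d].short_term >= base[d].short_term - 1e-12


def test_zero_effect_when_current_equals_target(params):
    profile, _ = generate_profile(7)
    status = PolicyStatus.mpower_target()
    effects = all_policy_effects(profile, status, params)
    assert all(e.short_term == 0.0 for e in effects.values())
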