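"""Counts and report assembly: golden Israel cells and structural invariants."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simsmoke import (
    Domain,
    PolicyEffect,
    attributable_deaths,
    build_report,
    combine_effects,
    reduction_in_smokers,
    smokers_from_profile,
)
from simsmoke.projection import percent, round_half_away
from simsmoke.synthetic import generate_profile


def _eff(value, domain=Domain.MEDIA, long=None):
    return PolicyEffect(domain=domain, short_term=value,
                        long_term=value if long is None else long)


def inclusion_exclusion(effects):
    """Brute-force oracle: union of overlapping policy effects.

    Treating each effect as the measure of an independent event, the joint
    effect is the measure of the union, expanded by inclusion-exclusion.
    """
    total = 0.0
    for k in range(1, len(effects) + 1):
        for subset in itertools.combinations(effects, k):
            term = 1.0
            for e in subset:
                term *= e
            total += (-1) ** (k + 1) * term
    return total


class TestSmokersAndDeaths:
    def test_israel_baseline_counts(self, israel_profile):
        smokers = smokers_from_profile(israel_profile)
        assert smokers == {"male": 698_936, "female": 394_152, "total": 1_093_088}

    def test_direct_product(self, israel_profile):
        profile = israel_profile.replace(
            population_by_gender={"male": 1_000_000, "female": 1_000_000},
            prevalence_by_gender={"male": 0.25, "female": 0.0},
            labor_participation_by_gender={"male": 0.7, "female": 0.6},
        )
        assert smokers_from_profile(profile) == {
            "male": 250_000, "female": 0, "total": 250_000
        }

    def test_israel_attributable_deaths(self, israel_profile):
        assert attributable_deaths(1_093_088, israel_profile) == (546_544, 710_507)

    def test_zero_smokers_zero_deaths(self, israel_profile):
        assert attributable_deaths(0, israel_profile) == (0, 0)


class TestCombine:
    def test_single_effect_identity(self):
        e = _eff(0.3)
        assert combine_effects([e]) is e

    def test_two_halves(self):
        c = combine_effects([_eff(0.5), _eff(0.5)])
        assert c.short_term == pytest.approx(0.75)

    def test_israel_published_short_effects(self):
        effects = [_eff(v) for v in (0.059, 0.046, 0.026, 0.055, 0.020, 0.044)]
        assert combine_effects(effects).short_term == pytest.approx(0.226, abs=5e-4)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0.0, 0.95), min_size=1, max_size=4))
    def test_matches_inclusion_exclusion_oracle(self, values):
        c = combine_effects([_eff(v) for v in values])
        assert c.short_term == pytest.approx(inclusion_exclusion(values), abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.0, 0.95), min_size=2, max_size=6))
    def test_commutative_bounded_dominating(self, values):
        effects = [_eff(v) for v in values]
        c = combine_effects(effects)
        c_rev = combine_effects(effects[::-1])
        assert c.short_term == pytest.approx(c_rev.short_term)
        assert 0.0 <= c.short_term < 1.0
        assert c.short_term >= max(values) - 1e-12


class TestReductions:
    def test_tax_long_term_reduction(self):
        assert reduction_in_smokers(0.117, 1_093_088) == pytest.approx(127_969, rel=1e-3)

    def test_combined_long_term_reduction(self):
        assert reduction_in_smokers(0.3425, 1_093_088) == pytest.approx(374_408, rel=5e-3)

    def test_zero_effect(self):
        assert reduction_in_smokers(0.0, 10_000) == 0

    def test_rounding_half_away(self):
        assert round_half_away(2.5) == 3
        assert round_half_away(-2.5) == -3
        assert round_half_away(2.4999) == 2


class TestReport:
    def test_israel_tax_row_deaths_lower(self, israel, params):
        profile, status = israel
        report = build_report(profile, status, params)
        row = report.row(Domain.TAX)
        assert row.deaths_lower_total == pytest.approx(63_984, rel=1e-3)

    def test_israel_combined_deaths_upper(self, israel, params):
        profile, status = israel
        report = build_report(profile, status, params)
        assert report.combined.deaths_upper_total == pytest.approx(243_365, rel=5e-3)

    def test_all_policies_at_target_all_zero(self, israel_profile, params):
        from simsmoke import PolicyStatus

        report = build_report(israel_profile, PolicyStatus.mpower_target(), params)
        assert all(r.reduction_total == 0 for r in report.rows)
        assert all(r.deaths_upper_total == 0 for r in report.rows)

    @settings(max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 5_000))
    def test_structural_invariants(self, seed, params):
        """Gender cells sum to totals; death bounds keep their exact ratio;
        the combined row dominates every single-policy row."""
        profile, status = generate_profile(seed)
        report = build_report(profile, status, params)
        for row in report.rows:
            assert abs(sum(row.reduction_by_gender.values()) - row.reduction_total) <= 1
            assert abs(sum(row.deaths_lower_by_gender.values()) - row.deaths_lower_total) <= 1
            assert abs(sum(row.deaths_upper_by_gender.values()) - row.deaths_upper_total) <= 1
            # pre-rounding ratio identity: reconstruct from the row's effect
            if row.reduction_total > 100:
                ratio = row.deaths_lower_total / row.deaths_upper_total
                expected = profile.death_fraction_lower / profile.death_fraction_upper
                assert ratio == pytest.approx(expected, rel=0.02)
        combined = report.combined
        for row in report.rows[:-1]:
            assert combined.reduction_total >= row.reduction_total
            assert combined.deaths_lower_total >= row.deaths_lower_total
            assert combined.deaths_upper_total >= row.deaths_upper_total

    def test_to_frame_columns(self, israel, params):
        profile, status = israel
        frame = build_report(profile, status, params).to_frame()
        assert list(frame["scenario"])[-1] == "Combined policies"
        assert {"short_term_effect", "long_term_effect",
                "reduction_smokers_total"} <= set(frame.columns)


def test_percent_half_up_presentation():
    assert percent(0.15 * 0.39) == 5.9
    assert percent(0.0585 * 2) == 11.7
    assert percent(0.044) == 4.4
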