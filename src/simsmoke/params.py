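"""Effect-size constants for the abridged SimSmoke policy model.

Every policy domain carries a maximal short-term effect (the relative
reduction in smoking prevalence achieved over five years by moving from no
policy to the full MPOWER target), a long-term multiplier converting the
five-year effect into the forty-year effect, and an interval half-width used
for sensitivity analysis.  Parts of the smoke-free, marketing and cessation
effects are contingent on enforcement scores or on the publicity generated
by tobacco-control funding.

All quantities are fractions; percentages appear only at I/O boundaries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping


class Domain(str, enum.Enum):
    """The six MPOWER policy domains."""

    TAX = "tax"
    SMOKEFREE = "smokefree"
    CESSATION = "cessation"
    MEDIA = "media"
    MARKETING = "marketing"
    WARNINGS = "warnings"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _frozen(d: dict) -> Mapping:
    return MappingProxyType(dict(d))


@dataclass(frozen=True)
class EffectSizeTable:
    """Maximal policy effects, multipliers and adjustor shares.

    Defaults are the abridged SimSmoke constants.  An instance is immutable;
    derive variants with :meth:`with_overrides`.
    """

    # Smoke-free air: venue-specific components of the full-target effect.
    # Worksite tiers are mutually exclusive; restaurants and pubs/bars add on.
    smokefree_worksite: Mapping[str, float] = field(
        default_factory=lambda: _frozen(
            {
                "workplace_full": 0.06,
                "offices_only": 0.04,
                "partial_facilities": 0.02,
            }
        )
    )
    smokefree_restaurants: float = 0.02
    smokefree_pubs_bars: float = 0.01

    # Mass-media campaign tiers (mutually exclusive).
    media_tiers: Mapping[str, float] = field(
        default_factory=lambda: _frozen(
            {"none": 0.0, "low": 0.01, "moderate": 0.035, "high": 0.065}
        )
    )

    # Marketing-restriction tiers (mutually exclusive).
    marketing_tiers: Mapping[str, float] = field(
        default_factory=lambda: _frozen(
            {"none": 0.0, "partial": 0.01, "direct_ban": 0.03, "comprehensive": 0.05}
        )
    )

    # Health-warning tiers (mutually exclusive).
    warning_tiers: Mapping[str, float] = field(
        default_factory=lambda: _frozen(
            {"none": 0.0, "weak": 0.005, "moderate": 0.01, "complete": 0.02}
        )
    )

    # Cessation-treatment sub-policies (additive), and the overall effect of
    # the complete, well-publicised package.  The package total exceeds the
    # sum of the listed sub-policies: it includes financial coverage and
    # publicity components not separately itemised.
    cessation_subpolicies: Mapping[str, float] = field(
        default_factory=lambda: _frozen(
            {
                "nrt_otc": 0.00667,
                "nrt_rx": 0.00334,
                "rx_meds": 0.00334,
                "provision_most": 0.0225,
                "provision_some": 0.01125,
                "quitline": 0.005,
            }
        )
    )
    cessation_full: float = 0.0475

    long_term_multipliers: Mapping[Domain, float] = field(
        default_factory=lambda: _frozen(
            {
                Domain.TAX: 2.0,
                Domain.SMOKEFREE: 1.25,
                Domain.MEDIA: 1.2,
                Domain.MARKETING: 1.3,
                Domain.WARNINGS: 2.0,
                Domain.CESSATION: 2.5,
            }
        )
    )

    # Fraction of a domain's effect contingent on the 0-10 enforcement score.
    enforcement_share: Mapping[Domain, float] = field(
        default_factory=lambda: _frozen(
            {Domain.SMOKEFREE: 0.25, Domain.MARKETING: 0.50}
        )
    )

    # Fraction contingent on tobacco-control publicity (funding level).
    publicity_share: Mapping[Domain, float] = field(
        default_factory=lambda: _frozen(
            {Domain.SMOKEFREE: 0.25, Domain.CESSATION: 0.25}
        )
    )

    # Whether the urban/labor adjustor applies to the domain's worksite reach.
    urban_adjusted: Mapping[Domain, bool] = field(
        default_factory=lambda: _frozen(
            {
                Domain.TAX: False,
                Domain.SMOKEFREE: True,
                Domain.CESSATION: True,
                Domain.MEDIA: False,
                Domain.MARKETING: False,
                Domain.WARNINGS: False,
            }
        )
    )

    # Sensitivity half-widths: effects scale by (1 - r) and (1 + r).
    sensitivity_ranges: Mapping[Domain, float] = field(
        default_factory=lambda: _frozen(
            {
                Domain.TAX: 0.25,
                Domain.SMOKEFREE: 0.50,
                Domain.MEDIA: 0.50,
                Domain.MARKETING: 0.50,
                Domain.WARNINGS: 0.50,
                Domain.CESSATION: 0.75,
            }
        )
    )

    prevalence_elasticity: float = -0.15
    tax_target_share: float = 0.75
    long_term_cap: float = 0.999

    def __post_init__(self) -> None:
        for name, tiers in [
            ("media_tiers", self.media_tiers),
            ("marketing_tiers", self.marketing_tiers),
            ("warning_tiers", self.warning_tiers),
        ]:
            vals = list(tiers.values())
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must strictly increase with tier strength")
        ws = self.smokefree_worksite
        if not ws["partial_facilities"] < ws["offices_only"] < ws["workplace_full"]:
            raise ValueError("smokefree worksite tiers must strictly increase")
        for dom, m in self.long_term_multipliers.items():
            if m < 1:
                raise ValueError(f"long-term multiplier for {dom} must be >= 1")
        all_effects = (
            list(ws.values())
            + [self.smokefree_restaurants, self.smokefree_pubs_bars]
            + [v for v in self.media_tiers.values() if v > 0]
            + [v for v in self.marketing_tiers.values() if v > 0]
            + [v for v in self.warning_tiers.values() if v > 0]
            + list(self.cessation_subpolicies.values())
            + [self.cessation_full]
        )
        if not all(0 < e < 1 for e in all_effects):
            raise ValueError("all maximal effects must lie in (0, 1)")
        if not 0 < self.tax_target_share < 1:
            raise ValueError("tax_target_share must lie in (0, 1)")

    def with_overrides(self, **changes) -> "EffectSizeTable":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def sensitivity_scale(self, domain: Domain, direction: str) -> float:
        """Multiplier (1 ± r) for the domain's sensitivity bound."""
        r = self.sensitivity_ranges[domain]
        if direction == "lower":
            return 1.0 - r
        if direction == "upper":
            return 1.0 + r
        raise ValueError(f"direction must be 'lower' or 'upper', got {direction!r}")


def default_effect_sizes() -> EffectSizeTable:
    """The standard abridged SimSmoke effect-size constants."""
    return EffectSizeTable()
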