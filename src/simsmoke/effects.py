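"""Per-domain incremental policy effects.

Each function returns a :class:`PolicyEffect`: the fractional reduction in
smoking prevalence expected over five years (short term) and forty years
(long term) from moving one MPOWER domain from its current status to its
full target.  Incremental effects are absolute differences, target effect
minus current effect; the long-term effect is the short-term effect times
the domain's long-term multiplier, capped just below one.

Conventions
-----------
* Enforcement and publicity scale only their contingent share of an effect:
  a share ``s`` and a level ``x`` in [0, 1] give the factor
  ``(1 - s) + s * x``, so the non-contingent part survives zero enforcement.
* The smoke-free worksite component is reduced by the urban adjustor
  ``1 - pct_agriculture`` and by labor-force participation, per gender;
  per-gender effects are pooled weighting by smoker counts.
* A domain already at target yields a zero effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional

from .params import Domain, EffectSizeTable
from .profile import (
    CountryProfile,
    MarketingTier,
    MediaTier,
    NRTAvailability,
    PolicyStatus,
    RxMedsAvailability,
    TreatmentProvision,
    WarningTier,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PolicyEffect",
    "PriceChange",
    "compute_price_increase",
    "tax_effect",
    "smokefree_effect",
    "cessation_effect",
    "media_effect",
    "marketing_effect",
    "warnings_effect",
    "long_term_effect",
    "all_policy_effects",
]


@dataclass(frozen=True)
class PolicyEffect:
    """Computed (short-term, long-term) prevalence reduction for one domain.

    ``short_by_gender`` is populated only where the domain's effect is
    gender-specific (smoke-free, via labor participation); ``short_term``
    is then the smoker-weighted pooled value used for count projections.
    """

    domain: Domain
    short_term: float
    long_term: float
    short_by_gender: Optional[Mapping[str, float]] = None
    adjustors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.short_by_gender is not None:
            object.__setattr__(
                self, "short_by_gender", MappingProxyType(dict(self.short_by_gender))
            )
        object.__setattr__(self, "adjustors", MappingProxyType(dict(self.adjustors)))
        if not (0.0 <= self.short_term <= self.long_term < 1.0):
            raise ValueError(
                f"{self.domain}: need 0 <= short ({self.short_term}) <= "
                f"long ({self.long_term}) < 1"
            )


@dataclass(frozen=True)
class PriceChange:
    """Relative cigarette price change implied by an excise-share move."""

    current_excise_share: float
    target_excise_share: float
    vat_rate: float
    relative_price_increase: float


def long_term_effect(short: float, domain: Domain, params: EffectSizeTable) -> float:
    """Forty-year effect: short-term effect times the domain multiplier.

    Capped at ``params.long_term_cap`` to keep effects strictly below one
    for extreme inputs.
    """
    if not 0.0 <= short < 1.0:
        raise ValueError(f"short-term effect must lie in [0, 1), got {short}")
    return min(short * params.long_term_multipliers[domain], params.long_term_cap)


def _contingency_factor(share: float, level: float) -> float:
    # (1 - share) of the effect is unconditional; the rest scales with level.
    return (1.0 - share) + share * level


def _effect(
    domain: Domain,
    short: float,
    params: EffectSizeTable,
    *,
    short_by_gender: Optional[Mapping[str, float]] = None,
    adjustors: Optional[Mapping[str, float]] = None,
) -> PolicyEffect:
    short = max(0.0, short)
    return PolicyEffect(
        domain=domain,
        short_term=short,
        long_term=long_term_effect(short, domain, params),
        short_by_gender=short_by_gender,
        adjustors=adjustors or {},
    )


# ---------------------------------------------------------------------------
# Taxation


def compute_price_increase(status: PolicyStatus, params: EffectSizeTable) -> PriceChange:
    """Relative price increase from raising the excise share to target.

    Convention: the net-of-tax price component is held fixed, so the pre-VAT
    retail price scales as ``(1 - s) / (1 - s')`` when the excise share moves
    from ``s`` to ``s'``.  VAT multiplies the excise-inclusive price both
    before and after the change and therefore cancels from the ratio.  When
    a country's published price response differs from this algebra (tax
    structures are rarely this clean), pin it with
    ``PolicyStatus.price_increase_override``.
    """
    s, t = status.excise_share, params.tax_target_share
    vat_share = status.vat_rate / (1.0 + status.vat_rate)
    if t + vat_share >= 1.0:
        raise ValueError(
            "target excise share plus implied VAT share >= 1: price undefined"
        )
    if s >= t:
        rel = 0.0
    else:
        rel = (1.0 - s) / (1.0 - t) - 1.0
    return PriceChange(
        current_excise_share=s,
        target_excise_share=t,
        vat_rate=status.vat_rate,
        relative_price_increase=rel,
    )


def tax_effect(
    profile: CountryProfile,
    status: PolicyStatus,
    params: EffectSizeTable,
    price_increase_override: Optional[float] = None,
) -> PolicyEffect:
    """Prevalence reduction from raising the excise tax share to target.

    The prevalence elasticity is applied to the relative price increase:
    ``short = |elasticity| * dP/P``.  An explicit ``price_increase_override``
    (argument or ``status.price_increase_override``) replaces the internally
    computed price change.
    """
    if status.excise_share >= params.tax_target_share:
        logger.warning(
            "excise share %.4f already at or above target %.4f: zero tax effect",
            status.excise_share,
            params.tax_target_share,
        )
        return _effect(Domain.TAX, 0.0, params, adjustors={"price_increase": 0.0})
    if price_increase_override is None:
        price_increase_override = status.price_increase_override
    if price_increase_override is not None:
        rel = price_increase_override
    else:
        rel = compute_price_increase(status, params).relative_price_increase
    short = abs(params.prevalence_elasticity) * rel
    return _effect(Domain.TAX, short, params, adjustors={"price_increase": rel})


# ---------------------------------------------------------------------------
# Smoke-free air laws


def _smokefree_gross(
    profile: CountryProfile,
    params: EffectSizeTable,
    gender: str,
    coverage: float,
    enforcement: int,
    publicity: float,
) -> float:
    """Smoke-free effect at a given coverage/enforcement/publicity level.

    The worksite component reaches only indoor workers: it is scaled by the
    urban adjustor (1 - share employed in agriculture) and by labor-force
    participation for the gender.  Restaurant and pubs/bars components apply
    to everyone.  Coverage scales the full-regime effect; the enforcement
    and publicity factors scale their contingent shares.
    """
    urban = 1.0 - profile.pct_agriculture
    labor = profile.labor_participation_by_gender[gender]
    full = (
        params.smokefree_worksite["workplace_full"] * urban * labor
        + params.smokefree_restaurants
        + params.smokefree_pubs_bars
    )
    enf = _contingency_factor(
        params.enforcement_share[Domain.SMOKEFREE], enforcement / 10.0
    )
    pub = _contingency_factor(params.publicity_share[Domain.SMOKEFREE], publicity)
    return coverage * full * enf * pub


def smokefree_effect(
    profile: CountryProfile, status: PolicyStatus, params: EffectSizeTable
) -> PolicyEffect:
    """Incremental effect of complete, fully enforced smoke-free air laws.

    Target: full coverage, enforcement 10/10, full publicity.  Current:
    the same expression at the status quo coverage, enforcement and
    publicity.  Per-gender effects (labor participation differs) are pooled
    weighting by smoker counts.
    """
    by_gender: dict[str, float] = {}
    for g in profile.genders:
        target = _smokefree_gross(profile, params, g, 1.0, 10, 1.0)
        current = _smokefree_gross(
            profile,
            params,
            g,
            status.smokefree_coverage,
            status.smokefree_enforcement,
            status.publicity_level,
        )
        by_gender[g] = max(0.0, target - current)
    smokers = {
        g: profile.population_by_gender[g] * profile.prevalence_by_gender[g]
        for g in profile.genders
    }
    total_smokers = sum(smokers.values())
    if total_smokers > 0:
        pooled = sum(by_gender[g] * smokers[g] for g in profile.genders) / total_smokers
    else:
        pooled = sum(by_gender.values()) / len(by_gender)
    return _effect(
        Domain.SMOKEFREE,
        pooled,
        params,
        short_by_gender=by_gender,
        adjustors={
            "urban": 1.0 - profile.pct_agriculture,
            "enforcement": _contingency_factor(
                params.enforcement_share[Domain.SMOKEFREE],
                status.smokefree_enforcement / 10.0,
            ),
            "publicity": _contingency_factor(
                params.publicity_share[Domain.SMOKEFREE], status.publicity_level
            ),
        },
    )


# ---------------------------------------------------------------------------
# Cessation treatment


def _cessation_current(status: PolicyStatus, params: EffectSizeTable) -> float:
    sub = params.cessation_subpolicies
    at_max = (
        status.cessation_nrt is NRTAvailability.OTC
        and status.cessation_rx_meds is RxMedsAvailability.WITH_PRESCRIPTION
        and status.cessation_provision is TreatmentProvision.MOST
        and status.cessation_quitline
    )
    if at_max:
        # The complete package is worth the overall effect, which exceeds
        # the sum of its itemised parts (coverage/publicity components).
        return params.cessation_full
    total = 0.0
    if status.cessation_nrt is NRTAvailability.OTC:
        total += sub["nrt_otc"]
    elif status.cessation_nrt is NRTAvailability.WITH_PRESCRIPTION:
        total += sub["nrt_rx"]
    if status.cessation_rx_meds is RxMedsAvailability.WITH_PRESCRIPTION:
        total += sub["rx_meds"]
    if status.cessation_provision is TreatmentProvision.MOST:
        total += sub["provision_most"]
    elif status.cessation_provision is TreatmentProvision.SOME:
        total += sub["provision_some"]
    if status.cessation_quitline:
        total += sub["quitline"]
    return total


def cessation_effect(
    profile: CountryProfile,
    status: PolicyStatus,
    params: EffectSizeTable,
    *,
    apply_publicity: bool = False,
    apply_urban: bool = False,
) -> PolicyEffect:
    """Incremental effect of the complete cessation-treatment package.

    Current effect is the sum of sub-policy effects in place (NRT, bupropion
    and varenicline, provision of treatments, quitline); the target is the
    complete package.  Publicity and urban scaling are off by default: the
    headline package effect already embeds typical publicity, and turning
    them on scales current and target symmetrically.
    """
    current = _cessation_current(status, params)
    target = params.cessation_full
    scale = 1.0
    adjustors: dict[str, float] = {}
    if apply_publicity:
        pub = _contingency_factor(
            params.publicity_share[Domain.CESSATION], status.publicity_level
        )
        scale *= pub
        adjustors["publicity"] = pub
    if apply_urban:
        urban = 1.0 - profile.pct_agriculture
        scale *= urban
        adjustors["urban"] = urban
    short = max(0.0, (target - current) * scale)
    return _effect(Domain.CESSATION, short, params, adjustors=adjustors)


# ---------------------------------------------------------------------------
# Media, marketing, warnings


def media_effect(status: PolicyStatus, params: EffectSizeTable) -> PolicyEffect:
    """Incremental effect of a highly publicised media campaign."""
    short = params.media_tiers[MediaTier.HIGH.value] - params.media_tiers[
        status.media_tier.value
    ]
    return _effect(Domain.MEDIA, short, params)


def marketing_effect(status: PolicyStatus, params: EffectSizeTable) -> PolicyEffect:
    """Incremental effect of a fully enforced comprehensive marketing ban.

    Half of a marketing ban's effect is enforcement-contingent, so the
    current effect is the tier effect times ``0.5 + 0.5 * enforcement/10``;
    the target assumes complete enforcement.
    """
    enf = _contingency_factor(
        params.enforcement_share[Domain.MARKETING], status.marketing_enforcement / 10.0
    )
    current = params.marketing_tiers[status.marketing_tier.value] * enf
    target = params.marketing_tiers[MarketingTier.COMPREHENSIVE.value]
    return _effect(
        Domain.MARKETING, target - current, params, adjustors={"enforcement": enf}
    )


def warnings_effect(
    status: PolicyStatus, params: EffectSizeTable, *, baseline_credit: bool = False
) -> PolicyEffect:
    """Incremental effect of complete (bold, graphic) pack warnings.

    By default the existing sub-complete warning is credited at zero — the
    full complete-tier effect applies unless warnings are already complete.
    ``baseline_credit=True`` subtracts the current tier's effect instead.
    """
    target = params.warning_tiers[WarningTier.COMPLETE.value]
    if status.warning_tier is WarningTier.COMPLETE:
        short = 0.0
    elif baseline_credit:
        short = target - params.warning_tiers[status.warning_tier.value]
    else:
        short = target
    return _effect(Domain.WARNINGS, short, params)


def all_policy_effects(
    profile: CountryProfile, status: PolicyStatus, params: EffectSizeTable
) -> dict[Domain, PolicyEffect]:
    """All six per-domain incremental effects, keyed by domain."""
    return {
        Domain.SMOKEFREE: smokefree_effect(profile, status, params),
        Domain.CESSATION: cessation_effect(profile, status, params),
        Domain.MEDIA: media_effect(status, params),
        Domain.WARNINGS: warnings_effect(status, params),
        Domain.MARKETING: marketing_effect(status, params),
        Domain.TAX: tax_effect(profile, status, params),
    }
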