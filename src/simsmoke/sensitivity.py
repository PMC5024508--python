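"""Interval sensitivity analysis on the effect sizes.

Each policy domain carries an uncertainty half-width r; the lower and upper
bound scenarios scale that domain's computed incremental effect by (1 - r)
and (1 + r) respectively.  The ranges scale the incremental effect (after
baseline subtraction), and compound multiplicatively with any enforcement
or publicity factors already folded into it.  Bounds are intervals, not
probabilistic uncertainty.
"""

from __future__ import annotations

from typing import Mapping, Optional

from .effects import PolicyEffect, all_policy_effects, long_term_effect
from .params import Domain, EffectSizeTable
from .profile import CountryProfile, PolicyStatus
from .projection import ProjectionReport, build_report

__all__ = ["apply_range", "bounds_report", "scale_effects"]


def apply_range(
    effect: PolicyEffect, params: EffectSizeTable, direction: str
) -> PolicyEffect:
    """Scale one domain's effect to its lower or upper sensitivity bound.

    The short-term effect is multiplied by ``(1 ± r)`` and clamped to
    [0, 1); the long-term effect is rebuilt from the scaled short-term
    effect so the domain's multiplier relation is preserved.
    """
    scale = params.sensitivity_scale(effect.domain, direction)
    short = min(max(effect.short_term * scale, 0.0), 0.999999)
    by_gender = None
    if effect.short_by_gender is not None:
        by_gender = {
            g: min(max(v * scale, 0.0), 0.999999)
            for g, v in effect.short_by_gender.items()
        }
    return PolicyEffect(
        domain=effect.domain,
        short_term=short,
        long_term=long_term_effect(short, effect.domain, params),
        short_by_gender=by_gender,
        adjustors=dict(effect.adjustors) | {"sensitivity_scale": scale},
    )


def scale_effects(
    effects: Mapping[Domain, PolicyEffect], params: EffectSizeTable, direction: str
) -> dict[Domain, PolicyEffect]:
    """Apply every domain's sensitivity range simultaneously."""
    return {d: apply_range(e, params, direction) for d, e in effects.items()}


def bounds_report(
    profile: CountryProfile,
    status: PolicyStatus,
    params: EffectSizeTable,
    effects: Optional[Mapping[Domain, PolicyEffect]] = None,
) -> tuple[ProjectionReport, ProjectionReport]:
    """(lower, upper) projection reports with all ranges at their limits."""
    if effects is None:
        effects = all_policy_effects(profile, status, params)
    lower = build_report(profile, status, params, scale_effects(effects, params, "lower"))
    upper = build_report(profile, status, params, scale_effects(effects, params, "upper"))
    return lower, upper
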