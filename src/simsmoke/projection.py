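"""From prevalence effects to counts: smokers, reductions, deaths averted.

All arithmetic is carried in full precision; counts are rounded
half-away-from-zero only at presentation, so ratio identities (e.g. lower
and upper deaths averted differ exactly by the ratio of the death
fractions) hold pre-rounding in every row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import reduce
from types import MappingProxyType
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .effects import PolicyEffect, all_policy_effects
from .params import Domain, EffectSizeTable
from .profile import CountryProfile, PolicyStatus

__all__ = [
    "percent",
    "round_half_away",
    "smokers_from_profile",
    "attributable_deaths",
    "combine_effects",
    "reduction_in_smokers",
    "ScenarioRow",
    "ProjectionReport",
    "build_report",
]

#: Presentation order of the per-policy rows, mirroring the usual report.
ROW_ORDER: tuple[Domain, ...] = (
    Domain.SMOKEFREE,
    Domain.CESSATION,
    Domain.MEDIA,
    Domain.WARNINGS,
    Domain.MARKETING,
    Domain.TAX,
)

ROW_LABELS: Mapping[Domain, str] = MappingProxyType(
    {
        Domain.SMOKEFREE: "Smoke-free air laws",
        Domain.CESSATION: "Cessation treatments",
        Domain.MEDIA: "Mass media campaigns",
        Domain.WARNINGS: "Health warnings",
        Domain.MARKETING: "Marketing restrictions",
        Domain.TAX: "Cigarette taxes",
    }
)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent(fraction: float, ndigits: int = 1) -> float:
    """A fraction on the percent scale, rounded half-up at ``ndigits``.

    Uses decimal arithmetic on the shortest repr so presentation matches
    hand arithmetic (0.0585 -> 5.9) instead of binary-float banker's
    rounding (which would print 5.8).
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(fraction * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def smokers_from_profile(profile: CountryProfile) -> dict[str, int]:
    """Current smokers per gender plus ``"total"``: prevalence x population."""
    exact = {
        g: profile.population_by_gender[g] * profile.prevalence_by_gender[g]
        for g in profile.genders
    }
    counts = {g: round_half_away(v) for g, v in exact.items()}
    counts["total"] = round_half_away(sum(exact.values()))
    return counts


def attributable_deaths(smokers: float, profile: CountryProfile) -> tuple[int, int]:
    """(lower, upper) premature deaths expected among ``smokers`` smokers."""
    if smokers < 0:
        raise ValueError("smokers must be >= 0")
    return (
        round_half_away(profile.death_fraction_lower * smokers),
        round_half_away(profile.death_fraction_upper * smokers),
    )


def combine_effects(effects: Sequence[PolicyEffect]) -> PolicyEffect:
    """Joint effect of simultaneous policies: ``1 - prod(1 - e_i)``.

    Each additional policy acts on the prevalence remaining after the
    others, so overlapping effects are discounted and the result stays in
    [0, 1) and is order-invariant.  Short- and long-term components combine
    separately; per-gender components combine where present.
    """
    effects = list(effects)
    if not effects:
        raise ValueError("combine_effects requires at least one effect")
    short = 1.0 - reduce(lambda acc, e: acc * (1.0 - e.short_term), effects, 1.0)
    long = 1.0 - reduce(lambda acc, e: acc * (1.0 - e.long_term), effects, 1.0)
    genders: set[str] = set()
    for e in effects:
        if e.short_by_gender:
            genders.update(e.short_by_gender)
    by_gender = None
    if genders:
        by_gender = {
            g: 1.0
            - reduce(
                lambda acc, e: acc
                * (1.0 - (e.short_by_gender or {}).get(g, e.short_term)),
                effects,
                1.0,
            )
            for g in sorted(genders)
        }
    if len(effects) == 1:
        return effects[0]
    # The combined row is labelled at report level; the domain slot just
    # carries the first constituent.
    return PolicyEffect(
        domain=effects[0].domain,
        short_term=short,
        long_term=min(long, 0.999999),
        short_by_gender=by_gender,
    )


def reduction_in_smokers(effect: float, smokers: float) -> int:
    """Smokers removed by a fractional prevalence reduction."""
    if not 0.0 <= effect < 1.0:
        raise ValueError(f"effect must lie in [0, 1), got {effect}")
    return round_half_away(effect * smokers)


@dataclass(frozen=True)
class ScenarioRow:
    """One report row: a single policy (or the combined package)."""

    label: str
    domain: Optional[Domain]  # None for the combined row
    short_term: float
    long_term: float
    reduction_by_gender: Mapping[str, int]
    reduction_total: int
    deaths_lower_by_gender: Mapping[str, int]
    deaths_lower_total: int
    deaths_upper_by_gender: Mapping[str, int]
    deaths_upper_total: int

    def __post_init__(self) -> None:
        for f in ("reduction_by_gender", "deaths_lower_by_gender", "deaths_upper_by_gender"):
            object.__setattr__(self, f, MappingProxyType(dict(getattr(self, f))))


@dataclass(frozen=True)
class ProjectionReport:
    """Baseline block plus one row per policy and a combined row."""

    profile_name: str
    year: int
    prevalence_by_gender: Mapping[str, float]
    smokers_by_gender: Mapping[str, int]
    smokers_total: int
    baseline_deaths_lower_by_gender: Mapping[str, int]
    baseline_deaths_lower_total: int
    baseline_deaths_upper_by_gender: Mapping[str, int]
    baseline_deaths_upper_total: int
    rows: tuple[ScenarioRow, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for f in (
            "prevalence_by_gender",
            "smokers_by_gender",
            "baseline_deaths_lower_by_gender",
            "baseline_deaths_upper_by_gender",
        ):
            object.__setattr__(self, f, MappingProxyType(dict(getattr(self, f))))
        object.__setattr__(self, "rows", tuple(self.rows))

    @property
    def combined(self) -> ScenarioRow:
        return self.rows[-1]

    def row(self, domain: Domain) -> ScenarioRow:
        for r in self.rows:
            if r.domain is domain:
                return r
        raise KeyError(domain)

    def to_frame(self) -> pd.DataFrame:
        """Report rows as a DataFrame (fractions, unrounded effects)."""
        genders = list(self.smokers_by_gender)
        records = []
        for r in self.rows:
            rec = {
                "scenario": r.label,
                "short_term_effect": r.short_term,
                "long_term_effect": r.long_term,
            }
            for g in genders:
                rec[f"reduction_smokers_{g}"] = r.reduction_by_gender[g]
            rec["reduction_smokers_total"] = r.reduction_total
            for g in genders:
                rec[f"deaths_averted_lower_{g}"] = r.deaths_lower_by_gender[g]
            rec["deaths_averted_lower_total"] = r.deaths_lower_total
            for g in genders:
                rec[f"deaths_averted_upper_{g}"] = r.deaths_upper_by_gender[g]
            rec["deaths_averted_upper_total"] = r.deaths_upper_total
            records.append(rec)
        return pd.DataFrame.from_records(records)


def _make_row(
    label: str,
    domain: Optional[Domain],
    effect: PolicyEffect,
    profile: CountryProfile,
    smokers_exact: Mapping[str, float],
) -> ScenarioRow:
    # Pooled long-term effect drives all count columns; gendered diagnostics
    # stay on the PolicyEffect.  Totals are rounded from the unrounded sum so
    # per-gender cells and totals agree to within one count.
    genders = [g for g in smokers_exact if g != "total"]
    red_exact = {g: effect.long_term * smokers_exact[g] for g in genders}
    red_total_exact = sum(red_exact.values())
    lo, up = profile.death_fraction_lower, profile.death_fraction_upper
    return ScenarioRow(
        label=label,
        domain=domain,
        short_term=effect.short_term,
        long_term=effect.long_term,
        reduction_by_gender={g: round_half_away(v) for g, v in red_exact.items()},
        reduction_total=round_half_away(red_total_exact),
        deaths_lower_by_gender={g: round_half_away(lo * v) for g, v in red_exact.items()},
        deaths_lower_total=round_half_away(lo * red_total_exact),
        deaths_upper_by_gender={g: round_half_away(up * v) for g, v in red_exact.items()},
        deaths_upper_total=round_half_away(up * red_total_exact),
    )


def build_report(
    profile: CountryProfile,
    status: PolicyStatus,
    params: EffectSizeTable,
    effects: Optional[Mapping[Domain, PolicyEffect]] = None,
) -> ProjectionReport:
    """Full projection: baseline, per-policy rows, combined row.

    ``effects`` may supply precomputed (e.g. sensitivity-scaled) per-domain
    effects; otherwise they are computed from the status quo.
    """
    if effects is None:
        effects = all_policy_effects(profile, status, params)
    smokers_exact = {
        g: profile.population_by_gender[g] * profile.prevalence_by_gender[g]
        for g in profile.genders
    }
    smokers_exact["total"] = sum(smokers_exact.values())
    smokers = smokers_from_profile(profile)
    base_lo = {
        g: round_half_away(profile.death_fraction_lower * smokers_exact[g])
        for g in profile.genders
    }
    base_up = {
        g: round_half_away(profile.death_fraction_upper * smokers_exact[g])
        for g in profile.genders
    }
    rows = [
        _make_row(ROW_LABELS[d], d, effects[d], profile, smokers_exact)
        for d in ROW_ORDER
        if d in effects
    ]
    combined = combine_effects([effects[d] for d in ROW_ORDER if d in effects])
    rows.append(_make_row("Combined policies", None, combined, profile, smokers_exact))
    return ProjectionReport(
        profile_name=profile.name,
        year=profile.year,
        prevalence_by_gender=dict(profile.prevalence_by_gender),
        smokers_by_gender={g: smokers[g] for g in profile.genders},
        smokers_total=smokers["total"],
        baseline_deaths_lower_by_gender=base_lo,
        baseline_deaths_lower_total=round_half_away(
            profile.death_fraction_lower * smokers_exact["total"]
        ),
        baseline_deaths_upper_by_gender=base_up,
        baseline_deaths_upper_total=round_half_away(
            profile.death_fraction_upper * smokers_exact["total"]
        ),
        rows=rows,
    )
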