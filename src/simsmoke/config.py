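"""YAML country-configuration parsing and report serialization.

The config schema mirrors the model inputs: a demographic block, a labor
block, death-fraction bounds and one sub-block per MPOWER policy domain.
Fractions may be written either as plain numbers (0.245) or with an
explicit percent suffix ("24.5%").  Unknown keys are rejected with their
location, so typos fail loudly rather than silently using a default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .params import EffectSizeTable, default_effect_sizes
from .profile import (
    PUBLICITY_PRESETS,
    CountryProfile,
    PolicyStatus,
)
from .projection import ProjectionReport

__all__ = ["ConfigError", "read_config", "write_config", "write_report", "report_to_dict"]


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the field."""


def parse_fraction(value: Any, where: str) -> float:
    """Accept 0.245, "0.245" or "24.5%" (percent only with explicit suffix)."""
    if isinstance(value, str):
        s = value.strip()
        if s.endswith("%"):
            try:
                return float(s[:-1]) / 100.0
            except ValueError:
                raise ConfigError(f"{where}: cannot parse percentage {value!r}") from None
        value = s
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"{where}: expected a number or percentage, got {value!r}") from None


def _require_mapping(node: Any, where: str) -> dict:
    if not isinstance(node, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(node).__name__}")
    return node


def _take(node: dict, key: str, where: str, default: Any = ...) -> Any:
    if key not in node:
        if default is not ...:
            return default
        raise ConfigError(f"{where}: missing required key {key!r}")
    return node.pop(key)

def _reject_unknown(node: dict, where: str) -> None:
    if node:
        raise ConfigError(f"{where}: unknown key(s) {sorted(node)!r}")


def _parse_publicity(value: Any, where: str) -> float:
    if isinstance(value, str) and value.strip().lower() in PUBLICITY_PRESETS:
        return PUBLICITY_PRESETS[value.strip().lower()]
    return parse_fraction(value, where)


def read_config(
    path: Union[str, Path],
) -> tuple[CountryProfile, PolicyStatus, EffectSizeTable]:
    """Parse and validate a country configuration file.

    Returns the profile, the policy status and the effect-size table (the
    defaults, unless the optional ``effect_size_overrides`` block replaces
    named constants).
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    doc = _require_mapping(raw, str(path))
    try:
        return _parse_document(doc, str(path))
    except ConfigError:
        raise
    except ValueError as exc:  # invariant violations from the dataclasses
        raise ConfigError(f"{path}: {exc}") from exc


def _parse_document(
    doc: dict, where: str
) -> tuple[CountryProfile, PolicyStatus, EffectSizeTable]:
    name = _take(doc, "country", where)
    year = _take(doc, "year", where)
    pop = _require_mapping(_take(doc, "population", where), f"{where}:population")
    prev = _require_mapping(_take(doc, "prevalence", where), f"{where}:prevalence")
    labor = _require_mapping(_take(doc, "labor", where), f"{where}:labor")
    agri = parse_fraction(
        _take(labor, "agriculture_share", f"{where}:labor"), f"{where}:labor.agriculture_share"
    )
    part = _require_mapping(
        _take(labor, "participation", f"{where}:labor"), f"{where}:labor.participation"
    )
    _reject_unknown(labor, f"{where}:labor")
    deaths = _require_mapping(
        _take(doc, "deaths", where, {}), f"{where}:deaths"
    )
    lower = parse_fraction(_take(deaths, "lower_fraction", f"{where}:deaths", 0.50),
                           f"{where}:deaths.lower_fraction")
    upper = parse_fraction(_take(deaths, "upper_fraction", f"{where}:deaths", 0.65),
                           f"{where}:deaths.upper_fraction")
    _reject_unknown(deaths, f"{where}:deaths")

    profile = CountryProfile(
        name=str(name),
        year=int(year),
        population_by_gender={g: int(v) for g, v in pop.items()},
        prevalence_by_gender={
            g: parse_fraction(v, f"{where}:prevalence.{g}") for g, v in prev.items()
        },
        pct_agriculture=agri,
        labor_participation_by_gender={
            g: parse_fraction(v, f"{where}:labor.participation.{g}") for g, v in part.items()
        },
        death_fraction_lower=lower,
        death_fraction_upper=upper,
    )

    pol = _require_mapping(_take(doc, "policies", where), f"{where}:policies")
    sf = _require_mapping(_take(pol, "smokefree", f"{where}:policies"),
                          f"{where}:policies.smokefree")
    cess = _require_mapping(_take(pol, "cessation", f"{where}:policies"),
                            f"{where}:policies.cessation")
    mkt = _require_mapping(_take(pol, "marketing", f"{where}:policies"),
                           f"{where}:policies.marketing")
    tax = _require_mapping(_take(pol, "tax", f"{where}:policies"),
                           f"{where}:policies.tax")
    media = _take(pol, "media", f"{where}:policies")
    warn = _take(pol, "warnings", f"{where}:policies")
    publicity = _parse_publicity(
        _take(pol, "publicity", f"{where}:policies"), f"{where}:policies.publicity"
    )
    _reject_unknown(pol, f"{where}:policies")

    override = _take(tax, "price_increase_override", f"{where}:policies.tax", None)
    status = PolicyStatus(
        smokefree_coverage=parse_fraction(
            _take(sf, "coverage", f"{where}:policies.smokefree"),
            f"{where}:policies.smokefree.coverage",
        ),
        smokefree_enforcement=_int_field(
            _take(sf, "enforcement", f"{where}:policies.smokefree"),
            f"{where}:policies.smokefree.enforcement",
        ),
        cessation_nrt=_take(cess, "nrt", f"{where}:policies.cessation", "none"),
        cessation_rx_meds=_take(cess, "rx_meds", f"{where}:policies.cessation", "none"),
        cessation_provision=_take(cess, "provision", f"{where}:policies.cessation", "none"),
        cessation_quitline=bool(
            _take(cess, "quitline", f"{where}:policies.cessation", False)
        ),
        media_tier=media,
        marketing_tier=_take(mkt, "tier", f"{where}:policies.marketing"),
        marketing_enforcement=_int_field(
            _take(mkt, "enforcement", f"{where}:policies.marketing"),
            f"{where}:policies.marketing.enforcement",
        ),
        warning_tier=warn,
        excise_share=parse_fraction(
            _take(tax, "excise_share", f"{where}:policies.tax"),
            f"{where}:policies.tax.excise_share",
        ),
        vat_rate=parse_fraction(
            _take(tax, "vat_rate", f"{where}:policies.tax", 0.0),
            f"{where}:policies.tax.vat_rate",
        ),
        publicity_level=publicity,
        price_increase_override=(
            None if override is None
            else parse_fraction(override, f"{where}:policies.tax.price_increase_override")
        ),
    )
    _reject_unknown(sf, f"{where}:policies.smokefree")
    _reject_unknown(cess, f"{where}:policies.cessation")
    _reject_unknown(mkt, f"{where}:policies.marketing")
    _reject_unknown(tax, f"{where}:policies.tax")

    overrides = _take(doc, "effect_size_overrides", where, {})
    params = default_effect_sizes()
    if overrides:
        params = params.with_overrides(
            **_require_mapping(overrides, f"{where}:effect_size_overrides")
        )
    _reject_unknown(doc, where)
    return profile, status, params


def _int_field(value: Any, where: str) -> int:
    if isinstance(value, bool) or not isinstance(value, int):
        raise ConfigError(f"{where}: expected an integer, got {value!r}")
    return value


def write_config(
    profile: CountryProfile, status: PolicyStatus, path: Union[str, Path]
) -> None:
    """Serialize a profile/status pair to the YAML config schema.

    A round trip through :func:`read_config` is value-identical.
    """
    doc = {
        "country": profile.name,
        "year": profile.year,
        "population": dict(profile.population_by_gender),
        "prevalence": {g: float(v) for g, v in profile.prevalence_by_gender.items()},
        "labor": {
            "agriculture_share": float(profile.pct_agriculture),
            "participation": {
                g: float(v) for g, v in profile.labor_participation_by_gender.items()
            },
        },
        "deaths": {
            "lower_fraction": float(profile.death_fraction_lower),
            "upper_fraction": float(profile.death_fraction_upper),
        },
        "policies": {
            "smokefree": {
                "coverage": float(status.smokefree_coverage),
                "enforcement": status.smokefree_enforcement,
            },
            "cessation": {
                "nrt": status.cessation_nrt.value,
                "rx_meds": status.cessation_rx_meds.value,
                "provision": status.cessation_provision.value,
                "quitline": status.cessation_quitline,
            },
            "media": status.media_tier.value,
            "marketing": {
                "tier": status.marketing_tier.value,
                "enforcement": status.marketing_enforcement,
            },
            "warnings": status.warning_tier.value,
            "tax": {
                "excise_share": float(status.excise_share),
                "vat_rate": float(status.vat_rate),
                **(
                    {"price_increase_override": float(status.price_increase_override)}
                    if status.price_increase_override is not None
                    else {}
                ),
            },
            "publicity": float(status.publicity_level),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def report_to_dict(report: ProjectionReport) -> dict:
    """JSON-ready dict mirroring the report layout."""
    return {
        "country": report.profile_name,
        "year": report.year,
        "baseline": {
            "prevalence": dict(report.prevalence_by_gender),
            "smokers": {**dict(report.smokers_by_gender), "total": report.smokers_total},
            "deaths_lower": {
                **dict(report.baseline_deaths_lower_by_gender),
                "total": report.baseline_deaths_lower_total,
            },
            "deaths_upper": {
                **dict(report.baseline_deaths_upper_by_gender),
                "total": report.baseline_deaths_upper_total,
            },
        },
        "scenarios": [
            {
                "scenario": r.label,
                "domain": r.domain.value if r.domain else "combined",
                "short_term_effect": r.short_term,
                "long_term_effect": r.long_term,
                "reduction_smokers": {
                    **dict(r.reduction_by_gender),
                    "total": r.reduction_total,
                },
                "deaths_averted_lower": {
                    **dict(r.deaths_lower_by_gender),
                    "total": r.deaths_lower_total,
                },
                "deaths_averted_upper": {
                    **dict(r.deaths_upper_by_gender),
                    "total": r.deaths_upper_total,
                },
            }
            for r in report.rows
        ],
    }


def write_report(
    report: ProjectionReport, path: Union[str, Path], format: str = "csv"
) -> None:
    """Write a projection report as CSV (one row per scenario) or JSON."""
    path = Path(path)
    if format == "csv":
        report.to_frame().to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(report_to_dict(report), fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")
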