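"""Randomized but admissible country profiles for testing and simulation.

The generator draws every input from ranges bracketing plausible national
values (including the packaged Israel baseline): per-gender adult
populations of 1e5-1e7, smoking prevalences of 5-50%, agriculture shares up
to 40%, labor participation 40-90%, enforcement scores over the full 0-10
scale, policy tiers uniform over their enumerations, excise shares of
30-74% of price and VAT rates up to 25%.  A single integer seed governs all
draws; no global random state is touched.
"""

from __future__ import annotations

from importlib import resources
from typing import Any, Mapping, Optional

import numpy as np

from . import config as _config
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

__all__ = ["generate_profile", "israel_fixture"]

_PROFILE_FIELDS = frozenset(CountryProfile.__dataclass_fields__)
_STATUS_FIELDS = frozenset(PolicyStatus.__dataclass_fields__)


def generate_profile(
    seed: int, overrides: Optional[Mapping[str, Any]] = None
) -> tuple[CountryProfile, PolicyStatus]:
    """Draw a random admissible (profile, status) pair, deterministically.

    ``overrides`` maps field names of either output type to pinned values;
    they are applied after drawing and re-validated, so an override that
    violates a type invariant raises ``ValueError`` naming the field.
    """
    rng = np.random.default_rng(seed)
    genders = ("male", "female")
    profile_kwargs: dict[str, Any] = {
        "name": f"synthetic-{seed}",
        "year": 2014,
        "population_by_gender": {
            g: int(rng.integers(100_000, 10_000_001)) for g in genders
        },
        "prevalence_by_gender": {g: float(rng.uniform(0.05, 0.50)) for g in genders},
        "pct_agriculture": float(rng.uniform(0.0, 0.4)),
        "labor_participation_by_gender": {
            g: float(rng.uniform(0.4, 0.9)) for g in genders
        },
        "death_fraction_lower": 0.50,
        "death_fraction_upper": 0.65,
    }
    status_kwargs: dict[str, Any] = {
        "smokefree_coverage": float(rng.uniform(0.0, 1.0)),
        "smokefree_enforcement": int(rng.integers(0, 11)),
        "cessation_nrt": rng.choice([e.value for e in NRTAvailability]),
        "cessation_rx_meds": rng.choice([e.value for e in RxMedsAvailability]),
        "cessation_provision": rng.choice([e.value for e in TreatmentProvision]),
        "cessation_quitline": bool(rng.integers(0, 2)),
        "media_tier": rng.choice([e.value for e in MediaTier]),
        "marketing_tier": rng.choice([e.value for e in MarketingTier]),
        "marketing_enforcement": int(rng.integers(0, 11)),
        "warning_tier": rng.choice([e.value for e in WarningTier]),
        "excise_share": float(rng.uniform(0.30, 0.74)),
        "vat_rate": float(rng.uniform(0.0, 0.25)),
        "publicity_level": float(rng.uniform(0.0, 1.0)),
    }
    for key, value in (overrides or {}).items():
        if key in _PROFILE_FIELDS:
            profile_kwargs[key] = value
        elif key in _STATUS_FIELDS:
            status_kwargs[key] = value
        else:
            raise ValueError(f"unknown override field {key!r}")
    return CountryProfile(**profile_kwargs), PolicyStatus(**status_kwargs)


def israel_fixture() -> tuple[CountryProfile, PolicyStatus]:
    """The packaged Israel 2014 baseline profile and policy status."""
    ref = resources.files("simsmoke.data").joinpath("israel.yaml")
    with resources.as_file(ref) as path:
        profile, status, _ = _config.read_config(path)
    return profile, status
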