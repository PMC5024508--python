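"""Country demographic profiles and MPOWER policy status.

A :class:`CountryProfile` holds the single baseline year of data the model
needs: adult (20+) population and current-smoking prevalence by gender, the
labor statistics feeding the worksite urban adjustor, and the bounds on the
fraction of smokers expected to die prematurely of smoking.

A :class:`PolicyStatus` records where each of the six MPOWER policy domains
currently stands; the model computes effects of moving every domain from
this status to its full MPOWER target.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping, Optional


class NRTAvailability(str, enum.Enum):
    NONE = "none"
    WITH_PRESCRIPTION = "with_prescription"
    OTC = "otc"


class RxMedsAvailability(str, enum.Enum):
    NONE = "none"
    WITH_PRESCRIPTION = "with_prescription"


class TreatmentProvision(str, enum.Enum):
    NONE = "none"
    SOME = "some"
    MOST = "most"


class MediaTier(str, enum.Enum):
    NONE = "none"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


class MarketingTier(str, enum.Enum):
    NONE = "none"
    PARTIAL = "partial"
    DIRECT_BAN = "direct_ban"
    COMPREHENSIVE = "comprehensive"


class WarningTier(str, enum.Enum):
    NONE = "none"
    WEAK = "weak"
    MODERATE = "moderate"
    COMPLETE = "complete"


#: Named presets mapping qualitative tobacco-control funding levels to the
#: continuous publicity fraction used in the enforcement/publicity scaling.
PUBLICITY_PRESETS: Mapping[str, float] = MappingProxyType(
    {"none": 0.0, "low": 0.25, "moderate": 0.5, "high": 1.0}
)


def _check_fraction(name: str, value: float, *, upper_open: bool = False) -> None:
    hi_ok = value < 1.0 if upper_open else value <= 1.0
    if not (0.0 <= value and hi_ok):
        bound = "[0, 1)" if upper_open else "[0, 1]"
        raise ValueError(f"{name} must lie in {bound}, got {value}")


def _check_enforcement(name: str, value: int) -> None:
    if not (isinstance(value, int) and not isinstance(value, bool) and 0 <= value <= 10):
        raise ValueError(f"{name} must be an integer in [0, 10], got {value!r}")


@dataclass(frozen=True)
class CountryProfile:
    """Baseline-year demographic and labor inputs for one country.

    Parameters
    ----------
    name, year
        Label and baseline year of the profile.
    population_by_gender
        Adult (ages 20+) population counts keyed by gender label.
    prevalence_by_gender
        Current-smoking prevalence per gender, as fractions.
    pct_agriculture
        Fraction of workers employed in agriculture; ``1 - pct_agriculture``
        is the urban adjustor limiting worksite smoke-free reach.
    labor_participation_by_gender
        Labor-force participation per gender, as fractions.
    death_fraction_lower, death_fraction_upper
        Bounds on the fraction of current smokers who will die prematurely
        of smoking (defaults 0.50 and 0.65).
    """

    name: str
    year: int
    population_by_gender: Mapping[str, int]
    prevalence_by_gender: Mapping[str, float]
    pct_agriculture: float
    labor_participation_by_gender: Mapping[str, float]
    death_fraction_lower: float = 0.50
    death_fraction_upper: float = 0.65

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "population_by_gender", MappingProxyType(dict(self.population_by_gender))
        )
        object.__setattr__(
            self, "prevalence_by_gender", MappingProxyType(dict(self.prevalence_by_gender))
        )
        object.__setattr__(
            self,
            "labor_participation_by_gender",
            MappingProxyType(dict(self.labor_participation_by_gender)),
        )
        genders = set(self.population_by_gender)
        if not genders:
            raise ValueError("population_by_gender must name at least one gender")
        if set(self.prevalence_by_gender) != genders or set(
            self.labor_participation_by_gender
        ) != genders:
            raise ValueError("per-gender fields must share identical gender keys")
        for g, n in self.population_by_gender.items():
            if not (isinstance(n, int) and not isinstance(n, bool) and n > 0):
                raise ValueError(
                    f"population_by_gender[{g!r}] must be a positive integer, got {n!r}"
                )
        for g, p in self.prevalence_by_gender.items():
            _check_fraction(f"prevalence_by_gender[{g!r}]", p)
        for g, p in self.labor_participation_by_gender.items():
            _check_fraction(f"labor_participation_by_gender[{g!r}]", p)
        _check_fraction("pct_agriculture", self.pct_agriculture)
        _check_fraction("death_fraction_lower", self.death_fraction_lower)
        _check_fraction("death_fraction_upper", self.death_fraction_upper)
        if self.death_fraction_lower > self.death_fraction_upper:
            raise ValueError("death_fraction_lower must be <= death_fraction_upper")

    @property
    def genders(self) -> tuple[str, ...]:
        return tuple(self.population_by_gender)

    def replace(self, **changes) -> "CountryProfile":
        return replace(self, **changes)


@dataclass(frozen=True)
class PolicyStatus:
    """Current standing of each MPOWER policy domain.

    ``publicity_level`` is a continuous fraction in [0, 1] proxying
    tobacco-control campaign funding; the named presets in
    :data:`PUBLICITY_PRESETS` (none=0, low=0.25, moderate=0.5, high=1.0) are
    accepted at the config boundary.
    """

    smokefree_coverage: float
    smokefree_enforcement: int
    cessation_nrt: NRTAvailability
    cessation_rx_meds: RxMedsAvailability
    cessation_provision: TreatmentProvision
    cessation_quitline: bool
    media_tier: MediaTier
    marketing_tier: MarketingTier
    marketing_enforcement: int
    warning_tier: WarningTier
    excise_share: float
    vat_rate: float
    publicity_level: float
    #: Pins the relative cigarette price increase implied by raising the
    #: excise share to target, when the published figure cannot be
    #: reproduced from the share algebra alone.
    price_increase_override: Optional[float] = None

    def __post_init__(self) -> None:
        _check_fraction("smokefree_coverage", self.smokefree_coverage)
        _check_enforcement("smokefree_enforcement", self.smokefree_enforcement)
        _check_enforcement("marketing_enforcement", self.marketing_enforcement)
        _check_fraction("excise_share", self.excise_share, upper_open=True)
        _check_fraction("vat_rate", self.vat_rate, upper_open=True)
        _check_fraction("publicity_level", self.publicity_level)
        # VAT claims v/(1+v) of the retail price on top of the excise share.
        if self.excise_share + self.vat_rate / (1.0 + self.vat_rate) >= 1.0:
            raise ValueError("excise share plus implied VAT share must be < 1")
        if self.price_increase_override is not None and self.price_increase_override < 0:
            raise ValueError("price_increase_override must be >= 0")
        for fname, etype in [
            ("cessation_nrt", NRTAvailability),
            ("cessation_rx_meds", RxMedsAvailability),
            ("cessation_provision", TreatmentProvision),
            ("media_tier", MediaTier),
            ("marketing_tier", MarketingTier),
            ("warning_tier", WarningTier),
        ]:
            object.__setattr__(self, fname, etype(getattr(self, fname)))
        if not isinstance(self.cessation_quitline, bool):
            raise ValueError("cessation_quitline must be a boolean")

    def replace(self, **changes) -> "PolicyStatus":
        return replace(self, **changes)

    @classmethod
    def mpower_target(
        cls, *, vat_rate: float = 0.0, tax_target_share: float = 0.75
    ) -> "PolicyStatus":
        """A status with every domain already at its full MPOWER target.

        Running the model against this status yields a zero incremental
        effect in every domain, hence a zero combined effect.
        """
        return cls(
            smokefree_coverage=1.0,
            smokefree_enforcement=10,
            cessation_nrt=NRTAvailability.OTC,
            cessation_rx_meds=RxMedsAvailability.WITH_PRESCRIPTION,
            cessation_provision=TreatmentProvision.MOST,
            cessation_quitline=True,
            media_tier=MediaTier.HIGH,
            marketing_tier=MarketingTier.COMPREHENSIVE,
            marketing_enforcement=10,
            warning_tier=WarningTier.COMPLETE,
            excise_share=tax_target_share,
            vat_rate=vat_rate,
            publicity_level=1.0,
        )
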