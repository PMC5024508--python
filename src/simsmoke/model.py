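"""Model/Results facade over the policy-simulation pipeline.

``AbridgedSimSmoke`` bundles a country profile, its current MPOWER policy
status and the effect-size constants; ``fit()`` evaluates every policy
scenario and returns an ``AbridgedSimSmokeResults`` carrying the central
projection, interval sensitivity bounds and a printable summary table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .config import read_config, report_to_dict, write_report
from .effects import PolicyEffect, all_policy_effects
from .params import Domain, EffectSizeTable, default_effect_sizes
from .profile import CountryProfile, PolicyStatus
from .projection import ProjectionReport, build_report, percent
from .sensitivity import bounds_report

__all__ = ["AbridgedSimSmoke", "AbridgedSimSmokeResults"]


class AbridgedSimSmoke:
    """Single-baseline-year MPOWER policy simulation for one country.

    Parameters
    ----------
    profile
        Demographic and labor inputs for the baseline year.
    status
        Current standing of the six MPOWER policy domains.
    params
        Effect-size constants; defaults to the standard table.

    Examples
    --------
    >>> from simsmoke import AbridgedSimSmoke, israel_fixture
    >>> model = AbridgedSimSmoke(*israel_fixture())
    >>> res = model.fit()
    >>> round(res.combined_short_term, 3)
    0.226
    """

    def __init__(
        self,
        profile: CountryProfile,
        status: PolicyStatus,
        params: Optional[EffectSizeTable] = None,
    ) -> None:
        self.profile = profile
        self.status = status
        self.params = params or default_effect_sizes()

    @classmethod
    def from_config(cls, path: Union[str, Path]) -> "AbridgedSimSmoke":
        """Build a model from a YAML country-configuration file."""
        profile, status, params = read_config(path)
        return cls(profile, status, params)

    def fit(self, bounds: bool = True) -> "AbridgedSimSmokeResults":
        """Evaluate all policy scenarios.

        ``bounds=False`` skips the sensitivity-bound reports.
        """
        effects = all_policy_effects(self.profile, self.status, self.params)
        central = build_report(self.profile, self.status, self.params, effects)
        lower = upper = None
        if bounds:
            lower, upper = bounds_report(self.profile, self.status, self.params, effects)
        return AbridgedSimSmokeResults(self, effects, central, lower, upper)


class AbridgedSimSmokeResults:
    """Fitted policy projections with sensitivity bounds.

    Attributes
    ----------
    effects
        Per-domain incremental :class:`PolicyEffect` objects.
    report
        Central :class:`ProjectionReport` (per-policy and combined rows).
    report_lower, report_upper
        Reports with every effect at its sensitivity bound, or ``None``
        when the model was fitted with ``bounds=False``.
    """

    def __init__(
        self,
        model: AbridgedSimSmoke,
        effects: Mapping[Domain, PolicyEffect],
        report: ProjectionReport,
        report_lower: Optional[ProjectionReport],
        report_upper: Optional[ProjectionReport],
    ) -> None:
        self.model = model
        self.effects = dict(effects)
        self.report = report
        self.report_lower = report_lower
        self.report_upper = report_upper

    # -- convenience accessors -------------------------------------------
    @property
    def combined_short_term(self) -> float:
        return self.report.combined.short_term

    @property
    def combined_long_term(self) -> float:
        return self.report.combined.long_term

    def short_term(self, domain: Domain) -> float:
        return self.effects[domain].short_term

    def long_term(self, domain: Domain) -> float:
        return self.effects[domain].long_term

    # -- tabular output ---------------------------------------------------
    def summary_frame(self) -> pd.DataFrame:
        """Central report as a DataFrame (fractions, unrounded effects)."""
        return self.report.to_frame()

    def summary(self) -> str:
        """Human-readable scenario table, percentages to one decimal."""
        p = self.model.profile
        rep = self.report
        lines = [
            f"Abridged SimSmoke projection: {rep.profile_name}, {rep.year}",
            "=" * 72,
            "Baseline"
        ]
        for g in p.genders:
            lines.append(
                f"  {g:<8} prevalence {100 * rep.prevalence_by_gender[g]:5.1f}%   "
                f"smokers {rep.smokers_by_gender[g]:>11,}"
            )
        lines.append(f"  {'total':<8} smokers {rep.smokers_total:>24,}")
        lines.append(
            f"  projected smoker deaths: {rep.baseline_deaths_lower_total:,} (lower) - "
            f"{rep.baseline_deaths_upper_total:,} (upper)"
        )
        lines.append("-" * 72)
        lines.append(
            f"{'Scenario':<26}{'5-yr':>7}{'40-yr':>7}{'Fewer smokers':>15}"
            f"{'Deaths averted':>17}"
        )
        for row in rep.rows:
            lines.append(
                f"{row.label:<26}"
                f"{percent(row.short_term):>6.1f}%"
                f"{percent(row.long_term):>6.1f}%"
                f"{row.reduction_total:>15,}"
                f"{row.deaths_lower_total:>9,}-{row.deaths_upper_total:<,}"
            )
        lines.append("-" * 72)
        lines.append(
            "Effects are relative reductions in smoking prevalence at 5 and 40"
        )
        lines.append(
            "years; deaths averted span the 50%-65% premature-death fractions."
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return report_to_dict(self.report)

    def save(self, path: Union[str, Path], format: str = "csv", which: str = "central") -> None:
        """Write the central or a bound report as CSV or JSON."""
        rep = {
            "central": self.report,
            "lower": self.report_lower,
            "upper": self.report_upper,
        }[which]
        if rep is None:
            raise ValueError(f"no {which!r} report: model fitted with bounds=False")
        write_report(rep, path, format=format)

    def plot_effects(self, ax=None):
        """Horizontal bar chart of per-policy short- and long-term effects."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        frame = self.summary_frame()
        y = range(len(frame))
        ax.barh(
            [i + 0.2 for i in y], 100 * frame["long_term_effect"], height=0.4,
            label="40-year",
        )
        ax.barh(
            [i - 0.2 for i in y], 100 * frame["short_term_effect"], height=0.4,
            label="5-year",
        )
        ax.set_yticks(list(y), frame["scenario"])
        ax.invert_yaxis()
        ax.set_xlabel("Reduction in smoking prevalence (%)")
        ax.legend()
        return ax
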