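# Methods

## Scope and assumptions

The model is the *abridged* form of the SimSmoke tobacco-control policy
simulation: it works from a single baseline year and projects the effects
of policy change on **current smokers only**. It deliberately omits cohort
dynamics — births, deaths, initiation and background cessation — as well as
future initiation among youth, subpopulation stratification, morbidity and
cost outcomes, and non-cigarette tobacco products. Its outputs are the
relative reduction in smoking prevalence at two fixed horizons (5 and 40
years), and the implied reductions in smoker counts and premature deaths
among smokers alive in the baseline year. There is no time path between
the two horizons.

All fractions are carried as fractions internally; percentages appear only
at I/O boundaries (configs accept an explicit `%` suffix; summaries print
percent to one decimal, rounded half-up on the decimal representation so
presentation matches hand arithmetic).

## Effect computation

**Incremental effects are absolute differences.** Each domain's short-term
effect is (target effect − current effect), not the relative complement
(target − current)/(1 − current). The absolute difference is the variant
consistent with the published per-domain numbers this implementation was
validated against; the relative form shifts the media effect by about
0.1 percentage points.

**Contingency scaling.** Where a share *s* of an effect depends on
enforcement (0–10 score) or publicity (fraction in [0, 1]), the effect is
scaled by (1 − s) + s·x — the non-contingent part survives zero
enforcement. Shares: smoke-free 25% enforcement + 25% publicity; marketing
50% enforcement; cessation 25% publicity (see below).

**Smoke-free air laws.** The full-target effect per gender is
`0.06·(1 − agri)·LFP + 0.02 (restaurants) + 0.01 (pubs/bars)`, where
`agri` is the agriculture employment share (urban adjustor) and `LFP` the
gender's labor-force participation — worksite bans only reach indoor
workers. The current effect evaluates the same expression at the current
coverage fraction (partial smoke-free regimes are modelled as a
proportional fraction of the full-regime effect — the simplest reading of
a "50% of full restrictions" status), enforcement score and publicity
level; the target assumes full coverage, enforcement 10 and full
publicity. Per-gender effects are pooled weighting by smoker counts
(effects act on smokers, keeping gender cells and totals consistent).

**Cessation treatment.** The current effect is the sum of the sub-policy
effects in place (NRT over-the-counter 0.667% / prescription 0.334%;
bupropion+varenicline 0.334%; provision in most facilities 2.25% / some
1.125%; quitline 0.5%); the target is the complete package at 4.75%. The
package total exceeds the itemised sum (it includes financial-coverage and
publicity components that are not separately listed), so a status with
every sub-policy at maximum is credited the full 4.75%, making the
incremental effect vanish at target. Publicity and urban scaling are **off
by default**: the published per-country validation values equal the bare
difference, and when enabled (keyword flags) the factors apply
symmetrically to current and target and therefore scale the difference.

**Media, marketing, warnings.** Tier effects are mutually exclusive
(media: 1.0/3.5/6.5%; marketing: 1/3/5%; warnings: 0.5/1/2%). The media
and marketing targets are the top tier (marketing additionally at full
enforcement). Health warnings default to *zero baseline credit*: moving to
complete warnings is worth the full 2% regardless of the current
sub-complete tier (the published numbers credit nothing for an existing
moderate warning); a `baseline_credit=True` switch restores subtraction.
A baseline already at the complete tier yields zero either way — no policy
change, no effect — which also keeps the all-policies-at-target combined
effect exactly zero.

**Taxation.** The short-term effect is |elasticity| × relative price
increase, elasticity −0.15. `compute_price_increase` holds the net-of-tax
price component fixed, so the pre-VAT price scales as (1 − s)/(1 − s′)
when the excise share of retail price moves from s to s′; VAT multiplies
the price both before and after the change and cancels from the ratio.
Real tax structures are rarely this clean: when a published price response
differs from the algebra (the packaged Israel baseline's 39% does), the
config pins it via `price_increase_override`. An excise share already at
or above the 75% target yields a zero effect with a logged warning rather
than an error.

**Long term and combination.** Long-term effect = short-term ×
per-domain multiplier (tax 2, smoke-free 1.25, media 1.2, marketing 1.3,
warnings 2, cessation 2.5), capped at 0.999 so effects stay below one for
extreme synthetic inputs. Policies combine as 1 − ∏(1 − eᵢ), separately
for the two horizons — each policy acts on the prevalence the others
leave — which is order-invariant, bounded in [0, 1), and equal to the
inclusion–exclusion expansion of overlapping effects.

## Counts and rounding

Smokers = prevalence × adult population per gender; reductions = pooled
effect × smokers; deaths averted = death fractions (defaults 0.50 and
0.65) × reductions. All arithmetic is full precision; counts are rounded
half-away-from-zero only at presentation, so the lower/upper deaths ratio
equals the ratio of the death fractions exactly pre-rounding, and gender
cells match totals within one count. Count columns use the pooled effect
for every row, including smoke-free (per-gender smoke-free effects remain
on the `PolicyEffect` for diagnostics): at printed precision, pooled and
gendered projections are indistinguishable, and pooled keeps rows
internally consistent.

## Sensitivity analysis

Each domain carries an interval half-width r (tax 0.25; smoke-free,
media, marketing, warnings 0.50; cessation 0.75). Bound scenarios scale
the domain's **incremental** effect (after baseline subtraction, hence
compounding multiplicatively with any enforcement/publicity factors
already folded in) by (1 − r) or (1 + r), clamped to [0, 1); long-term
effects are rebuilt from the scaled short-term effect so the multiplier
relation is preserved. The bounds are intervals, not probabilistic
uncertainty: all domains sit at their limits simultaneously, and the
central report lies cell-wise between the two bound reports.

## Synthetic data

`generate_profile(seed)` draws an admissible country at random: per-gender
adult populations uniform on [10⁵, 10⁷], prevalences on [0.05, 0.50],
agriculture share on [0, 0.4], labor participation on [0.4, 0.9],
enforcement integers on 0–10, tiers uniform over their enumerations,
excise share on [0.30, 0.74] (always below the 75% target) and VAT on
[0, 0.25] — ranges chosen to bracket plausible national values including
the packaged Israel baseline. One integer seed drives all draws through a
local generator; no global random state. The generator emulates the
*structure* of real inputs, not their correlations: prevalences, policy
tiers and tax levels are drawn independently, and survey sampling error in
prevalence is not modelled (the model consumes point prevalences). A green
property test therefore establishes that the pipeline's invariants hold on
admissible inputs, not that the effect sizes are right for any real
country — the latter rests on the packaged baseline reproducing its
published projection.

## The packaged Israel baseline

`israel_fixture()` ships the 2014 Israel inputs: prevalence 24.5% (male) /
13.2% (female), 2% agriculture employment, labor participation 70%/60%,
smoke-free coverage 50% with enforcement 3/10, NRT over the counter,
subsidised prescription cessation medication, provision in some
facilities, no national quitline, low media tier, partial marketing ban
with enforcement 2/10, moderate warnings, excise share 69.03% with 17%
VAT, low publicity (0.25), and a pinned 39% price response for the tax
move. Adult population counts (2,852,800 male; 2,986,000 female) are
back-derived from the published smoker and death counts, since no explicit
20+ population is published with them; they are marked `[DERIVED]` in the
fixture file.

## Numerical and design notes

- Publicity is a continuous fraction with named presets none=0, low=0.25,
  moderate=0.5, high=1.0, overridable in config — sources typically state
  only a qualitative funding level.
- Effect-size constants are immutable at load time (tier monotonicity and
  range checks are asserted); variants go through
  `EffectSizeTable.with_overrides`, which re-validates.
- Unknown config keys are rejected with their location; enum fields reject
  values outside their enumerations; validation errors name the field.
- Known limitations: no cohort dynamics or initiation effects (projections
  are conservative for long horizons), no interpolation between the 5- and
  40-year horizons, interval-only uncertainty, and a price-change
  convention that cannot capture specific-vs-ad-valorem tax structure —
  use the override when a country's price response is known.
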