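# simsmoke-abridged

Abridged SimSmoke: a single-baseline-year tobacco-control policy simulation.
Given one year of country data — adult population and current-smoking
prevalence by gender, and the current standing of the six WHO MPOWER policy
domains (smoke-free air laws, cessation treatment, media campaigns, health
warnings, marketing restrictions, cigarette taxation) — it projects, for
each policy individually and for all of them together, the relative
reduction in smoking prevalence at 5 years (short term) and 40 years (long
term) from full MPOWER implementation, and converts those reductions into
numbers of smokers and smoking-attributable deaths averted among current
smokers. It is written for tobacco-control researchers and health-policy
analysts who need MPOWER scenario numbers without the data demands of a
full cohort simulation.

## Model

For each policy domain the incremental short-term effect is the difference
between the effect of the full MPOWER target and the effect of the current
policy level, using tiered maximal effect sizes (e.g. a complete workplace
smoking ban is worth a 6% prevalence reduction, a comprehensive marketing
ban 5%, the complete cessation package 4.75%). Parts of an effect are
contingent on implementation quality: a contingent share *s* and a level
*x* ∈ [0, 1] scale the effect by (1 − s) + s·x. For smoke-free laws, 25% of
the effect depends on the 0–10 enforcement score and 25% on tobacco-control
publicity; for marketing bans, 50% depends on enforcement. The worksite
component of smoke-free laws reaches only indoor workers: it is scaled by
the urban adjustor (1 − fraction employed in agriculture) and by per-gender
labor-force participation. The tax effect applies a prevalence elasticity
of −0.15 to the relative cigarette-price increase implied by raising the
excise share of retail price to 75%.

The long-term (40-year) effect is the short-term effect times a per-domain
multiplier (tax 2, smoke-free 1.25, media 1.2, marketing 1.3, warnings 2,
cessation 2.5). Simultaneous policies combine as the complement product

    E = 1 − ∏ᵢ (1 − eᵢ),

so overlapping effects are discounted and E stays in [0, 1). Counts follow
as smokers = prevalence × population, reduction = E × smokers, and deaths
averted = 0.50 (lower) or 0.65 (upper) × reduction, the bounds on the
fraction of current smokers expected to die prematurely of smoking.
Per-domain uncertainty ranges (±25% tax, ±50% smoke-free/media/marketing/
warnings, ±75% cessation) scale the incremental effects to give interval
bounds on every report cell. See `docs/methods.md` for conventions and
limitations.

## Worked example

```python
from simsmoke import AbridgedSimSmoke, israel_fixture

model = AbridgedSimSmoke(*israel_fixture())   # packaged Israel 2014 baseline
res = model.fit()
print(res.summary())
```

```
Abridged SimSmoke projection: Israel, 2014
========================================================================
Baseline
  male     prevalence  24.5%   smokers     698,936
  female   prevalence  13.2%   smokers     394,152
  total    smokers                1,093,088
  projected smoker deaths: 546,544 (lower) - 710,507 (upper)
------------------------------------------------------------------------
Scenario                     5-yr  40-yr  Fewer smokers   Deaths averted
Smoke-free air laws          4.6%   5.7%         62,717   31,358-40,766
Cessation treatments         2.6%   6.6%         71,707   35,853-46,609
Mass media campaigns         5.5%   6.6%         72,144   36,072-46,893
Health warnings              2.0%   4.0%         43,724   21,862-28,420
Marketing restrictions       4.4%   5.7%         62,525   31,262-40,641
Cigarette taxes              5.9%  11.7%        127,891   63,946-83,129
Combined policies           22.6%  34.3%        374,426  187,213-243,377
------------------------------------------------------------------------
```

Reading the table: of Israel's 1.09 million adult smokers in 2014, between
547 and 711 thousand are expected to die prematurely of smoking if nothing
changes. Raising the excise tax share from 69% to 75% of price alone cuts
prevalence 5.9% within five years and 11.7% within forty; implementing the
whole MPOWER package cuts it 22.6% and 34.3%, averting 187–243 thousand of
those deaths. `res.report_lower` / `res.report_upper` hold the same table
with every effect size at its sensitivity bound, and
`res.summary_frame()` returns the rows as a pandas DataFrame.

The same run is available from the shell:

```bash
simsmoke simulate --config my_country.yaml            # summary to stdout
simsmoke simulate --config my_country.yaml --scenario combined --format json --out report.json
simsmoke sensitivity --config my_country.yaml --out bounds.csv   # central/lower/upper
simsmoke synth --seed 5 --out synthetic.yaml          # random admissible profile
simsmoke validate --config my_country.yaml
```

Config files are YAML with one block per input group; fractions may be
written as `0.245` or `"24.5%"`. `src/simsmoke/data/israel.yaml` is a
complete, commented example.

## Acceptance script

`scripts/acceptance.py` rebuilds the headline effect sizes from scratch —
it loads the packaged Israel baseline, runs the policy engine, and writes
the short- and long-term tax effects and the short-term marketing effect
(percent scale, printed precision) to JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
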