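# Methods

## Scope and structure

The package quantifies the all-cause mortality benefits of a national
active-travel trajectory relative to a frozen base-year counterfactual. The
computation proceeds in five stages, each an importable module:

1. **Inputs** (`synthetic`, `io`) — demography (population, annual death
   probability, residual life expectancy per 1-year age and calendar year),
   the national mileage trajectory, the age distribution of mileage, and a
   VSLY series, either read from CSV or generated synthetically.
2. **Allocation** (`allocation`) — national per-capita mileage distributed
   over ages and split between classical bike and e-bike.
3. **Dose-response** (`dose_response`) — mileage to minutes to capped linear
   relative risks per mode, combined multiplicatively.
4. **Impacts** (`engine`) — deaths and YLL averted, scenario deltas, period
   life-expectancy gain.
5. **Economics and uncertainty** (`economics`) — VSLY monetization, interval
   propagation, sensitivity variants.

## The exposure model

The scenario signal is weekly per-capita kilometres walked and cycled plus
an e-bike share of cycled kilometres, one value per calendar year. The
reference counterfactual reuses the base year's values for every year and
passes through the identical allocation and split machinery, so deltas
isolate the mileage change itself.

**Age allocation.** National kilometres in year *y* (per-capita value times
total population) are distributed by a fixed age distribution *d(a)*; the
overall relative growth therefore affects all ages homogeneously, and the
population-weighted mean per-capita mileage reproduces the national value to
machine precision (asserted at 1e−9 relative in tests).

**E-bike split.** The e-bike fraction of cycled km at age *a* is a
two-parameter logistic s(a) = expit(α + βa). Each year, (α, β) solve two
constraints: the km-weighted national share equals the scenario's share for
that year, and the km-weighted mean age of e-bike minus classical km equals
a fixed gap target (default 6.7 years, reflecting the older profile of
e-bike users in multi-country survey evidence). The logistic is the minimal
monotone two-parameter family satisfying both constraints; with a positive
gap target the solved β is non-negative, so the e-bike share rises with age.
Numerically, the share constraint is strictly monotone in α and solved by
bracketed Brent iteration (xtol 1e−13) nested inside a Brent solve on β for
the gap (xtol 1e−9, residual checked against 1e−3 years; bracket expanded
geometrically up to |β| = 50 before declaring the gap infeasible). Years
with share targets of exactly 0 or 1, or with no cycling at all, have an
undefined mean-age gap; they fall back to a constant share with a logged
warning. A config switch (`enforce_gap_each_year=False`) instead calibrates
β once, in the largest-volume year, and lets the achieved gap drift.

## Dose-response

Exposure time is mileage divided by mode speed (walking 4.8, classical bike
14.9, e-bike 18.1 km h⁻¹). E-bike minutes are multiplied by a MET ratio
(default 0.90) to express them in classical-cycling-equivalent effort; the
reference volumes of both dose-response functions correspond to 11.25
MET·h week⁻¹, which makes the minutes and MET·h parameterizations
proportional, so the package accounts in minutes only.

The relative risk is linear in effective exposure down from 1, anchored at a
10% [6–13%] reduction for 100 min week⁻¹ of cycling and 11% [4–17%] for
168 min week⁻¹ of walking, and capped at a maximum reduction of 45%
(cycling) and 30% (walking). The cap applies per mode, after the MET-ratio
multiplier; exposures above the cap threshold are capped silently with a
per-run INFO diagnostic of capped person-minutes. Effects apply to ages in a
closed window, default 20–84; outside it RR = 1.

**Mode combination.** The combined RR per (year, age) is the product over
modes. The multiplicative rule treats proportional reductions as
independent; per-mode impact surfaces are additionally computed with each
mode's own (1 − RR), so per-mode results sum to at least the combined
impact (1 − ΠRR ≤ Σ(1 − RR)). The combined surface feeds total deaths, YLL
and life-expectancy outputs; the per-mode surfaces feed the mode-contribution
shares.

## Impacts

Deaths averted at (year, age) are N·q·(1 − RR) on the projected mortality,
the standard HEAT-style attribution; baseline rates are not renormalized for
activity already embedded in observed mortality. YLL weight deaths by
residual life expectancy from the demography table — by default the same
(baseline) expectancy in both scenarios, keeping the delta attributable to
the mortality-risk change only; `yll_residual_le="scenario"` switches to
expectancies recomputed under each scenario's RR. Life-expectancy gain per
year compares period life tables built from q·RR_all (clamped to ≤ 1);
period rather than cohort tables match the convention of reporting a gain
"in year Y". Life tables use Chiang's construction with a_fraction = 0.5 and
closure at age 110 (q = 1), both configurable. Negative deltas (possible
for classical bike late in the horizon, when its mileage falls below the
base year's) are reported, not clipped.

## Economics and uncertainty

YLL deltas are valued at the calendar year's VSLY with no additional
discounting; amounts are labelled 2020 euros. Uncertainty intervals re-run
the entire pipeline three times with all modes simultaneously at the lower,
central and upper CI reductions — a joint, not per-mode-Cartesian,
propagation — so interval ordering is inherited from the monotonicity of
the pipeline in the reduction parameters. Four sensitivity variants are
bundled: zero mean-age gap; MET ratio 0.78; effect window capped at 74; and
the alternative cycling dose-response of 19% [9–29%] at the reference
volume, which also rescales the e-bike effect through the same MET-ratio
mechanism. Variants are pure config overrides, audited by configuration
hashing.

## The synthetic generators

The generators emulate the statistical structure of the real inputs, not
their values:

* **Demography.** Mortality hazard m(a,y) = (c + b·e^{θa})·(1−ρ)^{y−y₀} with
  defaults c = 2·10⁻⁴, b = 2.7·10⁻⁵, θ = 0.095, ρ = 1%/year — a
  Gompertz–Makeham schedule giving life expectancy at birth near 80 years
  with a plausible secular improvement — converted to annual probability
  q = 1 − e^{−m}. The base pyramid is the stationary population of the
  base-year rates times a smooth mid-age bulge and a small seeded lognormal
  jitter (σ = 1%), scaled to 65 M; it evolves by ageing and survival with a
  constant birth cohort. This is a plausible, internally consistent pyramid,
  not a demographic forecast (no migration, no cohort-component detail).
* **Mileage.** Monotone piecewise-cubic (PCHIP) interpolation through anchor
  points, constant beyond the outermost anchors; anchors are reproduced
  exactly and interpolants never overshoot neighbouring anchors, which
  preserves the scenario's inverse-U shapes. Default anchors: cycling
  2.4 → 17.1 (2040) → 17.5 (2045) → 17.1 (2050) km/inh/week; e-bike share
  3.3% → 70% (2040), constant after; walking +11% over the horizon from a
  6.0 km/week base. The walking base is a package choice (≈75 min week⁻¹,
  about 1 km/day of travel walking — a mid-range value for a European
  country) since only the relative growth is anchored.
* **Age distribution.** A Gaussian hump on a uniform floor, normalized to
  sum to one over ages 0–110: cycling peaks at 25 with spread 16 and floor
  0.35 (young-adult-dominated but present at all ages); walking uses peak
  45, spread 35, floor 0.8 (nearly flat). Grouped-to-single-age bridging of
  survey data is sidestepped: shares are generated directly at 1-year ages.
* **VSLY.** 139 k€ in 2020 growing geometrically at 1.2%/year, a mid-range
  per-capita growth assumption matching public-investment evaluation
  practice of indexing the VSLY to economic growth.

Passing tests on these inputs demonstrates the machinery — conservation,
solver recovery, dose-response and life-table correctness, orderings and
peak timing — not calibration to any country's observed travel or mortality
data; headline magnitudes shift with the demographic and distributional
defaults.

## Numerical choices and edge cases

* Age intervals are integer years; windows are closed ([20, 84] includes
  both endpoints).
* The default run covers 2021–2050 × ages 0–110 (3,330 cells per table);
  a full three-bound uncertainty run completes in a few seconds.
* Degenerate single-year horizons run end-to-end (the demography generator
  internally extends one year and trims).
* A zero-mileage scenario propagates to identically zero impacts at every
  bound (asserted in tests).
* Allocation rejects ages with zero population but positive mileage share;
  the split solver raises with diagnostics when it cannot bracket, rather
  than returning a best effort.
* CSV readers use round-trip float parsing so write→read→write is
  byte-identical; all written inputs carry seed and parameter-hash header
  comments, and every run serializes its effective configuration.

## Known limitations

* The dose-response internalizes road-injury and air-pollution effects on
  the active travellers themselves (it is fitted to all-cause mortality);
  population-wide ("altruistic") air-quality or noise pathways are out of
  scope, as are morbidity outcomes and non-linear dose-response shapes.
* The logistic e-bike split is a reconstruction of a constrained allocation,
  not a transcription of any particular survey model; alternative monotone
  forms would satisfy the same two constraints.
* The reference scenario freezes mileage at the base year; it does not model
  autonomous growth in cycling absent the transition policies.
* Whether caps should bind before or after summing cycling sub-modes at one
  age is unresolved in the underlying evidence; the package caps per mode
  after the MET multiplier.
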