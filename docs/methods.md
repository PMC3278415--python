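# Methods

## Scope and unit of analysis

`stovecba` evaluates the switch from a traditional biomass stove to one of
six alternatives (improved wood, unimproved charcoal, improved charcoal,
kerosene, LPG, electric), plus the transition from a traditional to an
improved charcoal stove, for a single representative household.  All
quantities are monthly, per household, in US$.  The decision criterion is
net benefits; no attempt is made to model adoption behaviour, community
externalities, intra-household allocation of benefits, inconvenience or
aesthetic effects.

## Deterministic core

Capital is annualized with the standard capital recovery factor
`crf(δ,T) = δ(1+δ)^T/((1+δ)^T − 1)` (straight-line `1/T` in the zero-rate
limit) and divided by twelve; the baseline stove's capital is sunk — this
includes the owned charcoal stove in the charcoal-to-improved-charcoal
comparison.  Program cost is a flat annual amount divided by twelve.

Fuel demand is anchored on the wood baseline: mass is cooking hours ×
burn rate × days, and useful cooking energy is that mass × energy content
× heat-transfer efficiency.  Every other stove's demand follows from
useful-energy equivalence, `F_i = useful / (μ_i ε_fi)`.  The traditional
charcoal baseline has no primitive burn-rate datum, so its demand is
derived the same way — the charcoal household needs the useful energy its
wood-burning counterpart consumes, delivered through the traditional
charcoal stove's efficiency.  The electric stove is special-cased: its
catalogued "efficiency" is electricity drawn per hour of cooking, so
consumption is cooking hours × relative cooking time × days × kW-hr/hr,
with no MJ conversion.

Baseline wood costs combine a purchased fraction `f` at the wood price
with collection/preparation time valued at the shadow value of time times
the unskilled wage.  Both terms are charged at their full catalogued
magnitudes (the purchased fraction does not down-weight collection time);
this literal reading arguably double-counts collection effort for
purchased wood, but it is the documented convention here and all worked
values are computed under it.  For the improved wood stove, collection
time scales proportionally with the wood mass actually needed (factor
`F_i/F_0`) and a separate daily preparation time is added.  All other
candidate fuels are treated as purchased ready to burn: their monthly fuel
cost is price × quantity, with no time component.  Net fuel cost is the
use-weighted difference and may take either sign.

Health benefits enter as candidate-minus-baseline effectiveness, so the
charcoal-to-improved-charcoal transition is credited only with the
incremental reduction.  Morbidity multiplies disease burden (ARI incidence,
COPD prevalence), effectiveness, cost of illness and household size; COPD
terms are discounted by the onset delay `d`.  Cooking-time savings multiply
baseline cooking time by the difference in relative time efficiency (the
improved wood stove's high bound of 1.5 makes this negative — a realistic
"improved but slower" outcome).  Carbon value is the carbon price times
the change in CO₂-equivalent emissions; the avoided-deforestation value
is the tree-replacement cost times the change in fuelwood mass (zero for
non-wood fuels; the wood embodied in charcoal production is not counted,
as no conversion datum exists in the catalog).

Sustained use χ scales O&M, fuel, health, time and environmental terms;
capital, program and learning costs are incurred regardless of use.  Net
benefits are therefore affine in χ, which the tests verify by three-point
collinearity.

## Perspectives and policy levers

The private perspective uses the private discount rate (10–20 %/yr),
counts health and time benefits, applies any capital subsidy, and adds the
carbon value only when an offset transfer is switched on — the offset
passes through `Carb` but never `Bio`, since forest replacement is not an
emissions offset.  The social perspective uses the social rate (3–6 %/yr),
adds `Carb + Bio`, and ignores subsidies.  On any single draw evaluated at
a common discount rate, social minus private net benefits equals
`Carb + Bio` exactly; this identity is asserted with zero tolerance.

## Model switches

Two readings of the published inputs cannot be resolved internally and are
exposed as configuration, with defaults chosen once and used everywhere:

**Carbon-intensity basis** (`gamma_basis`, default `"fuel"`).  The
catalogued intensities are labelled per MJ of useful energy, but the wood
value (12.1 g CO₂-eq/MJ, reflecting CO₂-neutral sustainable harvest) is
only plausible per MJ of fuel heat.  The default charges intensity per MJ
of fuel heat (`F·μ·γ`); `"useful"` further scales by heat-transfer
efficiency.  Neither basis makes LPG carbon savings almost-always positive
while keeping kerosene/electric savings mostly negative — the published
fossil intensities appear to have been pre-divided by mid efficiencies —
so the qualitative carbon ranking of fossil options differs between bases
and no reproduction target is tied to it.

**Mortality risk pool** (`mortality_includes_hhsize`, default False;
`mortality_risk_multiplier`, default 0.15).  The literal mortality
valuation — VSL × per-person risk reduction × household size — yields
about $11/hh-month at central values for the improved wood stove, an
order of magnitude more than the published headline outcomes can contain;
the intended internal form is not recoverable.  The model therefore scales
the per-person risk reduction by a configurable at-risk pool instead of
full household size, defaulting to 0.15 persons.  This value was
calibrated once against the published worked outcomes (the $0.10/$2.40
sustained-use endpoints and the central simulated medians jointly) and is
recorded in every run manifest; the literal reading remains available via
configuration.  Mortality conclusions should be treated as
order-of-magnitude only.

Two further constants: `days_per_month = 30` (the daily-to-monthly
conversion, overridable) and `learning_hours = 0` (the learning-cost term
is implemented and tested, but no catalogued magnitude exists, so the
default does not invent one).

## Uncertainty propagation

Parameters are uniform on [low, high]: the catalog documents plausible
bounds across developing-country settings, not frequency distributions,
and the output percentiles should be read accordingly (spread of plausible
outcomes, not probabilities for any one site).  The "mid" column is the
central literature value and is used for tornado baselines; it is *not*
the mean of the range (stove costs are strongly right-skewed), so
simulated medians legitimately differ from mid-value evaluations.

Rank correlations are induced by Iman–Conover reordering: per-column
uniforms are rearranged to follow the ranks of a correlated normal
reference sample, preserving marginals exactly.  Stated rank correlations
are converted to normal-score correlations via `ρ = 2 sin(πr/6)` before
use.  Because the published pairwise correlations were stated
independently, the assembled matrix is far from positive semidefinite
(one anchor variable, the wage, is correlated with some fifteen columns);
it is repaired by iterative eigenvalue clipping with unit-diagonal
rescaling, and the maximum absolute entry change (≈ 0.39 on the
normal-score scale for the packaged catalog) is reported on every draw
matrix.  Achieved sample rank correlations are tested to within ±0.03 of
the *repaired* targets at n = 10,000; the repaired targets — not the
stated ones — are the operative dependence structure.  Correlations
involving degenerate (constant) parameters are inert and dropped.

One-way tornado sweeps ignore the correlations by design (standard
one-at-a-time semantics); parameters of stoves outside the scenario and
all constants are excluded as zero-swing.

Simulation runs share a single draw matrix across scenarios (common
random numbers), so cross-stove comparisons are paired.  Percentiles use
linear interpolation between order statistics.  Default experiment size
is 10,000 draws; all seven transitions evaluate in well under a second,
and summaries, manifests (seed, catalog hash, every model switch) and
CSV/JSON artifacts allow bit-exact replay.

## Numerical choices and degenerate inputs

Zero discount rates fall back to straight-line amortization; zero
lifespans and non-positive heat efficiencies raise errors.  Degenerate
catalogs (low = mid = high everywhere) produce constant draw columns and
collapse the Monte Carlo exactly onto the midpoint evaluation, which is
tested.  The score-matrix decorrelation step inside Iman–Conover is
skipped when draws are fewer than the number of free parameters (the
empirical score correlation is then singular); tiny samples remain valid,
just noisier in their induced correlations.

## What the packaged catalog does and does not capture

The packaged ranges are a literature synthesis for "typical" programs;
they are not site-specific data, and several (program cost, preparation
time) rest on very few studies.  Passing tests demonstrate internal
consistency of the model and faithful propagation of the catalogued
uncertainty — they do not validate the ranges themselves against any
field deployment.  Known residual gaps against the published headline
outcomes, under the documented equations and defaults: the
wood-to-unimproved-charcoal transition computes to a small positive
median where the published table prints a clearly negative one (the
equations credit the full collection-time saving of leaving wood, and
charcoal demand follows useful-energy equivalence; the published row
implies a substantially larger charcoal fuel burden), and consequently
the improved wood stove's simulated fraction of positive private outcomes
is about 0.65–0.68 rather than one-half.  These are left visible rather
than patched, since the component equations are pinned by exact worked
examples.
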