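# stovecba

Probabilistic cost–benefit analysis of improved-cookstove (ICS) adoption at
the household level.

Nearly three billion people cook on traditional solid-fuel stoves, with
well-documented consequences for respiratory health (acute respiratory
infection, ARI/ALRI, and chronic obstructive pulmonary disease, COPD), for
the time of those who cook and collect fuelwood, for forests, and for the
climate.  Improved or alternative-fuel stoves are widely promoted on the
claim that their benefits clearly exceed their costs — yet adoption has been
slow.  `stovecba` simulates the monthly economics of the switch for a
representative developing-country household, propagating the published
uncertainty in roughly thirty parameters, so that the *distribution* of
net benefits across plausible settings — not a single average — drives the
conclusions.  It is aimed at health economists, energy-access researchers
and program designers who want to stress-test stove interventions or carbon
-finance proposals before fielding them.

## Model

For a switch from a baseline stove (traditional wood- or charcoal-burning)
to candidate stove *i*, monthly household net benefits are

```
net = Morb + Mort + Timesav [+ Carb + Bio]  −  (Cap + Prog + O&M + Fuel + Learn)
```

with (all per household per month, US$):

| term | content |
|---|---|
| `Cap`  | capital cost `cc_i`, annualized by the capital recovery factor `crf(δ, T_i) = δ(1+δ)^T / ((1+δ)^T − 1)`, ÷ 12; baseline capital is sunk |
| `Prog` | program/promotion cost `cp` ÷ 12 |
| `O&M`  | χ · (cm_i − cm_0) ÷ 12 |
| `Fuel` | χ · (C_i − C_0), where baseline wood use is `F_0 = cookt_0 · fuelt_0 · days`, candidate use scales by relative energy content and heat-transfer efficiency `F_i = F_0 · μ_0 ε_f0 / (μ_i ε_fi)`, and costs combine purchased fuel (`f · p · F`) with collection/preparation time valued at `v^t · w` |
| `Learn`| one-off learning time, annualized like capital (0 by default) |
| `Morb` | χ · hhsize · [ I^ARI · η_i^ARI · COI^ARI + P^COPD · η_i^COPD · COI^COPD / (1+δ)^d ] ÷ 12 |
| `Mort` | χ · pool · VSL · [ I^ARI · f^ALRI · CFR^ALRI · η_i^ARI + drate^COPD · η_i^COPD / (1+δ)^d ] ÷ 12 |
| `Timesav` | χ · cookt_0 · (ε_t0 − ε_ti) · days · v^t · w (negative if the new stove cooks slower) |
| `Carb` | carbon price × χ × avoided g CO₂-eq ÷ 10⁶, under basic (CO₂/CH₄/N₂O) or extended (+CO, NMHC, black carbon) accounting |
| `Bio`  | tree-replacement cost × χ × avoided fuelwood mass |

χ is sustained use — the fraction of cooking actually moved to the new
stove — and scales every use-dependent term.  The private perspective
discounts at δ_p (10–20 %/yr), counts health and time benefits, and adds
`Carb` only when a carbon-offset payment is passed through to the
household; the social perspective discounts at δ_s (3–6 %/yr), adds
`Carb + Bio`, and ignores capital subsidies (a transfer).

Uncertainty: every parameter is uniform on its catalogued [low, high]
range, with the catalogued pairwise rank correlations induced by
Iman–Conover reordering against a multivariate-normal reference (the
assembled correlation matrix is repaired to the nearest positive
semidefinite correlation matrix first).  One-way tornado sweeps move each
parameter alone between its bounds with everything else at its central
value.  See `docs/methods.md` for assumptions, switches and limitations.

## Worked example

Simulate the wood→improved-wood and wood→kerosene transitions (10,000
correlated draws, private perspective, no subsidy):

```
$ stovecba --draws 10000 --seed 1 --out demo run --stove wood_ics --stove kerosene
wood_ics_private_basic: median +0.69 US$/hh-month, P(net>0)=0.68
kerosene_private_basic: median +3.33 US$/hh-month, P(net>0)=0.91
```

The improved wood stove is marginal for a typical household — the median
gain is under a dollar a month and roughly a third of parameter
combinations lose money — while kerosene is robustly attractive on private
grounds.  The full policy table (10th/50th/90th percentiles across the
seven transitions and four policy blocks, negatives in parentheses):

```
$ stovecba --draws 10000 --seed 1 --out demo table4 --block private --block social_basic
                           private:Low private:Median private:High social_basic:Low social_basic:Median social_basic:High
stove_option
charcoal_traditional            ($3.0)           $0.4         $4.6           ($2.5)                $0.8              $5.0
wood_ics                        ($1.0)           $0.7         $4.2           ($0.7)                $1.1              $4.8
charcoal_ics                    ($2.2)           $1.0         $5.8           ($1.6)                $1.5              $6.5
charcoal_ics_from_charcoal      ($1.4)           $0.1         $2.8           ($1.2)                $0.3              $3.0
kerosene                          $0.1           $3.3         $9.7             $0.4                $3.6             $10.1
lpg                             ($0.4)           $2.9         $9.4             $0.3                $3.7             $10.3
electric                        ($5.1)         ($1.0)         $5.5           ($2.6)                $1.2              $8.0
```

`stovecba tornado --stove wood_ics --perspective social` writes the
one-way sensitivity CSV; for the improved wood stove the dominant drivers
are the ARI cost-of-illness, relative time efficiency and sustained use —
moving use alone from 20 % to 80 % swings social net benefits from about
$0.09 to $2.21 per household-month.

Everything is also available as a library:

```python
from stovecba import load_catalog, run, Scenario

catalog = load_catalog()                      # packaged parameter ranges
sim = run(catalog, [Scenario("wood_traditional", "lpg")], n_draws=10_000, seed=1)
sim.summary("lpg_private_basic").percentiles  # {0.1: ..., 0.5: ..., 0.9: ...}
```

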