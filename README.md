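# osmofreeze

Process optimisation and shelf-life kinetics for **osmodehydrofreezing** —
partial osmotic dehydration of a plant food (here parameterised for cherry
tomato immersed in a glycerol/NaCl/CaCl₂ solution) followed by freezing and
frozen storage. The package is aimed at food process engineers who want to
(a) choose osmotic-dehydration (OD) conditions by response-surface
methodology and multi-response desirability, and (b) predict frozen shelf
life from accelerated-storage kinetics, including under fluctuating
(temperature-abuse) profiles.

## What it computes

**OD process design.** The three OD factors — temperature *T* (25–45 °C),
immersion time *t* (30–90 min) and glycerol concentration *C* (50–70 % w/w)
— are screened with a 15-run, three-level Box–Behnken design (12 edge
midpoints + 3 centre replicates), and each response *y* (water loss WL,
solid gain SG, water activity a_w, colour change ΔE, firmness) is fitted by
the full second-order polynomial in coded units *x*ᵢ ∈ [−1, 1]:

    y = a₀ + Σ aᵢxᵢ + Σ aᵢᵢxᵢ² + Σ aᵢⱼxᵢxⱼ

with ANOVA diagnostics (R², adjusted R², model F-test, lack-of-fit from the
centre-point pure error) and an exact algebraic conversion between coded and
actual-unit coefficients. Mass-transfer indices use the initial-dry-mass
convention: WL = ((M₀−m₀)−(M−m))/m₀ and SG = (m−m₀)/m₀, in g per g initial
dry mass.

**Multi-response optimisation.** Each fitted response is scored by a
Derringer-type desirability d ∈ [0, 1] (linear ramps; an `upper_bound` goal
is fully desirable at or below its cap) and settings are ranked by the
weighted geometric mean D. The optimiser is a deterministic grid search over
the factor cube plus simplex refinement — no randomness, no extrapolation.

**Frozen-storage kinetics.** Vitamin C and lycopene decay first-order,
C(t) = C₀·e^(−kt); sensory score decays zero-order, S(t) = S₀ − kt. Rates
follow the reference-temperature Arrhenius form

    k(T) = k_ref · exp[ −(E_a/R)(1/T − 1/T_ref) ],   T_ref = −18 °C

fitted as ln k vs (1/T − 1/T_ref) across storage temperatures. Shelf life is
ln(C₀/C_limit)/k(T) (first order, 50 % retention by default) or
(S₀−S_limit)/k(T) (zero order). Fluctuating piecewise-constant profiles are
summarised by the **effective temperature** — the constant temperature giving
the same quality loss over the same time, obtained by time-averaging k and
inverting the Arrhenius relation — and quality trajectories are integrated
segment-by-segment in closed form.

A `presets` module ships the study's published factor space, the five uncoded
regression surfaces, the validation pairs at the optimum, and the Arrhenius
parameters per quality index and treatment, so every published-figure
computation is a one-liner. A synthetic-data module simulates both the OD
experiment and the storage study for testing and power analysis.

## Worked example

Optimal OD conditions under the study's criteria (minimise a_w subject to
WL ≤ 5 g/g i.d.m. and ΔE ≤ 8):

```bash
$ python examples/03_desirability_optimum.py
optimum: 36.0 °C, 64.1 min, 61.0 % w/w glycerol
(reported optimum for comparison: 36 °C, 72 min, 61.5 % w/w)
  d(water_activity) = 1.000  ->  predicted 0.9107
  d(water_loss) = 1.000  ->  predicted 5
  d(delta_e) = 1.000  ->  predicted 7.575
composite desirability D = 1.000
```

The optimum sits on the WL = 5 constraint surface at the water-activity
minimum: 36 °C with moderate time and ~61 % glycerol drives a_w down to
0.911 while keeping dehydration and colour change inside their caps. (The
time axis is nearly flat there, which is why 64 min and the reported 72 min
score the same.)

Shelf lives from the kinetic presets:

```bash
$ python examples/04_shelf_life.py
...
sensory SL at  -5.0 °C: untreated     50 d, OD    151 d (rates 0.0619 vs 0.0332 /d)
sensory SL at -18.0 °C: untreated    182 d, OD    556 d (rates 0.0170 vs 0.0090 /d)
```

Sensory rejection (score reaching 4 on the 9-point scale) is the
shelf-life-limiting index for both treatments; OD pretreatment roughly
halves the sensory loss rate and raises the initial score, a ~3× extension.

The other examples cover the raw quality indices (`01`), design generation
and surface fitting with ANOVA (`02`), and non-isothermal prediction with
effective temperature (`05`). The same operations are exposed as a thin CLI
(`osmofreeze design|fit-rsm|optimize|simulate|fit-kinetics|shelf-life|teff|reproduce-study`).

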