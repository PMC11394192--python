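# Methods

This note records the models implemented, the conventions and defaults
chosen where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Quality indices

Water loss and solid gain are normalised by **initial dry mass**
(g/g i.d.m.): WL = ((M₀−m₀)−(M−m))/m₀, SG = (m−m₀)/m₀. Much of the
osmotic-dehydration literature normalises by initial *total* mass; values on
that convention are ~10× smaller and not comparable. Negative WL (net water
uptake) and negative SG (solute leaching) are physically meaningful and are
returned unclipped — the response-surface optimiser needs the raw surface.
ΔE is the CIELab Euclidean distance; the conventional visibility threshold
(ΔE > 2) is a named constant (`DELTA_E_VISIBLE`), never folded into the
numeric return. Drip loss is computed as 100·(1 − w_after/w_before) so the
w_after = 0 bound is exact in floating point.

## Design and response-surface fitting

The three-factor Box–Behnken design enumerates, for each factor pair, the
four (±1, ±1) combinations with the third factor at its centre, plus
replicated centre points (default 3 → 15 runs). Coding is affine,
xᵢ = (Xᵢ − centre)/half-range, with the **larger actual level mapping to
+1** — coding is defined by magnitude, not by row labels in any particular
levels table.

Fitting is ordinary least squares on the ten-term quadratic basis in coded
units; uncoded coefficients come from exact algebraic expansion of the
coding map (and vice versa for models constructed from published uncoded
equations), so the two prediction paths agree to machine precision. On the
15-run design this leaves 5 residual df. Diagnostics:

- per-coefficient t-tests, starred at the 0.05 level with no
  multiple-testing correction (matching standard RSM software output);
- overall model F-test against the intercept-only model;
- lack-of-fit F-test with pure error pooled from replicated design points —
  in this design only the 3 centre replicates (2 pure-error df, 3
  lack-of-fit df). With fewer than two replicates the lack-of-fit p-value is
  reported as missing (`None`), never as zero. With only 2 pure-error df
  this test is low-powered and erratic: at realistic noise roughly one seed
  in eight flags spurious lack of fit, which is a property of the design,
  not of the fit.

Surface evaluation accumulates the polynomial elementwise rather than via a
matrix product, so equal inputs give bitwise-equal outputs irrespective of
their position in an array (this keeps noiseless centre replicates exactly
identical in simulation).

## Desirability optimisation

Individual desirabilities are linear Derringer ramps raised to a positive
weight and clamped to [0, 1]. Goal semantics:

- `minimize` / `maximize`: d runs 0↔1 between `bound_low` and `bound_high`;
  unspecified bounds default to the surface's min/max over the factor cube.
- `upper_bound`: d = 1 for y at or below the cap (`bound_low`), falling
  linearly to 0 at `bound_high` (default: surface maximum). A value under
  the cap is *fully* desirable — the cap is a constraint, not a target to
  undershoot. This is the semantics under which the study's reported
  optimum (36 °C, 72 min, 61.5 % w/w, with WL = 4.96 just under its cap of
  5 and d ≈ 0.99) is reproducible; a ramp with d = 0 *at* the cap would
  instead push the optimum to the cold/long/concentrated corner of the
  cube.
- `target`: triangular ramp peaking at `target`.

Unspecified bounds are resolved from surface extrema refined by a clamped
Nelder–Mead from the best grid cell — grid-only extrema would create a d = 1
plateau around the true optimum and blur the argmax.

The composite score D is the weighted geometric mean (zero if any d is
zero). The optimiser grid-searches the closed cube (default 51³), breaks
exact ties toward lower temperature, then shorter time, then lower
concentration (cheapest process first), and refines by Nelder–Mead with
evaluations clamped to the cube. It is deterministic and idempotent;
repeated calls return identical results. If D is zero over the whole grid
the error names the criterion with the largest zero-desirability fraction.

Validation percent error is signed, 100·(experimental − predicted)/
experimental, with |error| ≤ 20 % as the conventional acceptance band. Note
one boundary case in the shipped validation pairs: the colour-change pair
(6.24, 7.49) recomputes to 20.03 %, which this package reports honestly as
just outside the band even though the source's rounded table quotes 18 %.

## Storage kinetics

First-order rates are fitted by least squares of ln(value) on time — the
reference behaviour, appropriate under multiplicative (lognormal)
measurement error; a nonlinear least-squares option (`method="nls"`) exists
for additive-error data. Zero-order rates are fitted on the raw scale.
k is the negative slope; a non-negative slope raises a "no degradation
detected" warning and flags the estimate rather than hiding it. Series may
contain replicate measurements as repeated time points; fitting requires at
least three distinct times.

The Arrhenius fit regresses ln k on (1/T − 1/T_ref) in kelvin
(T(K) = T(°C) + 273.15, R = 8.314 J mol⁻¹ K⁻¹, default T_ref = −18 °C, a
typical frozen-chain reference). Slope = −E_a/R, intercept = ln k_ref; two
temperatures give the exact two-point solution. The sign convention is
k increasing with temperature for E_a > 0.

Shelf life uses the closed forms ln(C₀/C_limit)/k(T) and (S₀−S_limit)/k(T).
The concentration limit defaults to 50 % retention. The sensory limit is
always an explicit input; both common rejection scores (4 and 5 on the
9-point hedonic scale) ship as named presets because sources differ, with
the parameter-table value (4) as the `"table"` preset.

**Effective temperature.** For a piecewise-constant profile,
k_eff = Σ k(Tᵢ)tᵢ / t_tot and 1/T_eff = 1/T_ref − (R/E_a)·ln(k_eff/k_ref).
T_eff always lies within the profile's temperature range and — because k is
convex in T — at or above the arithmetic time-weighted mean; it increases
with E_a. At E_a = 0 the inversion is degenerate and the harmonic
time-weighted mean (the E_a → 0 limit) is returned with a warning. Profile
durations are stored in hours (the natural unit for abuse cycles) and
converted to days internally. Non-isothermal trajectories are integrated
segment-by-segment in closed form; by construction the end value equals the
constant-T_eff prediction to machine precision, which the tests assert.
Zero-order predictions are not floored at the scale minimum — crossing the
acceptance limit is flagged, not masked.

## Synthetic data

`simulate_od_experiment` samples each response from its quadratic surface
plus additive Gaussian noise (defaults per response: a_w 0.005, WL 0.2
g/g i.d.m., SG 0.02, ΔE 0.4, firmness 0.15 N — chosen so refitted
diagnostics land in the R² ≈ 0.92–0.96 range typical of careful OD
experiments). `simulate_degradation` uses multiplicative lognormal noise
(σ = 5 %) for concentrations — keeping simulated values strictly positive,
consistent with the log-scale fit — and additive Gaussian noise (σ = 0.3
score units) for sensory scores, truncated at the scale floor of 1 with a
warning; default sampling spans roughly one shelf life per temperature
(8 times × 2 replicates at −5, −8, −14, −23 °C). All generators are
bit-reproducible given a seed.

What the generators do *not* emulate: sample-to-sample biological
variability and batch effects, drift or serial correlation within a storage
run, deviations from the assumed kinetic forms (e.g. biphasic loss,
glass-transition effects near the matrix Tg), and panel effects in sensory
scoring. Passing recovery tests therefore demonstrates correctness of the
estimation pipeline under the stated error model, not robustness to
model misspecification.

## Numerical choices and problem sizes

- Default optimiser grid 51³ (101³ in the oracle cross-check test);
  Nelder–Mead tolerances xatol 1e-6, fatol 1e-12.
- Noisy kinetic-recovery checks use 500 simulated studies of 7 time points
  × 3 replicates at 4 temperatures; the type-I-error check uses 400
  null-response design fits.
- Kelvin conversion constant 273.15 exactly; all user-facing temperatures
  are °C.

## Known limitations

- The lack-of-fit test is nearly uninformative with only 2 pure-error df
  (see above).
- Response surfaces are local: the optimiser deliberately refuses to search
  outside the design cube, and predictions outside it are extrapolations
  (coding beyond ±1 is only logged).
- Arrhenius extrapolation below the coldest studied temperature is
  unreliable if the matrix passes its glass transition; no WLF correction
  is implemented.
- The desirability bounds behind a published composite score are rarely
  printed; reproducing a reported optimum therefore depends on the goal
  semantics documented above.
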