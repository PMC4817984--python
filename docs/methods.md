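# Methods

## Model and assumptions

The package models a stand's size hierarchy with the Y–N curve
`Y(N) = N/(AN + B)` (Y: cumulative aboveground biomass in kg of the N
largest trees; N: rank from the largest). `A = 1/Ymax` and
`B = 1/Mmax` are census-specific. The rank-N individual biomass is
the derivative `M(N) = B/(AN + B)²`, invertible as
`N = (√(B/M) − B)/A` for `0 < M < 1/B`.

Growth is modelled as *rank-preserving re-indexing*: a tree keeps its
rank while `(A, B)` evolve, giving the closed form
`M_T = B_T[(A_T/A_0)(√(B_0/M_0) − B_0) + B_T]⁻²`. Two scalings close
the system: `B = K₃Aᶜ` (equivalent, through `Ymax = K₁Hmax^(a+1)` and
`M = K₂Hᵇ`, to `c = b/(a+1)`) and the diameter allometry
`M = K₄D^(8/3)`. The resulting curves map `D₀` to `D_T^(2/3)` and to
the annual rate `(D_T − D₀)/Δt`. They are always evaluated as
**plug-in** curves: all five parameters `(A₀, A_T, K₃, c, K₄)` are
estimated upstream (Y–N fits of the first and last census, B–A
log-log regression, fixed-8/3 allometric fit), never refit to the
growth pairs — the curves are flexible enough that direct fitting
would be uninformative. Their goodness of fit is reported as
`r² = 1 − SSres/SStot` with zero fitted parameters, and "adjusted" r²
for a plug-in curve uses p = 0, which reduces to plain r²; this
convention is recorded here because no standard exists for
zero-parameter curves.

The comparison model is metabolic-scaling growth `dD/dt = βD^(1/3)`,
whose integral is the slope-one line `D_T^(2/3) = D₀^(2/3) + k`. Its
internal constants (assimilation and tissue-density factors) are
deliberately lumped into the single rate constant β, fitted by the
closed-form least squares `β = Σ(g·D₀^(1/3))/Σ(D₀^(2/3))`; `k` is
taken as the mean residual of the slope-one line (its least-squares
intercept).

## Statistical conventions

- **OLS**: scipy `linregress`; slope CI from the t quantile with
  n − 2 df.
- **RMA** (model II): slope `sign(r)·sd(y)/sd(x)`; 95% CI via
  `B = F₀.₉₅(1, n−2)(1 − r²)/(n − 2)`, bounds
  `slope·(√(B+1) ± √B)` — the standard model-II interval. RMA is used
  wherever neither axis is controlled (`D_T` on `D₀`, `M` on `D`).
- **Spearman ρ** with midrank ties (the tie convention is a choice;
  biomass ties are rare but possible after rounding).
- **NLS**: scipy `least_squares` (Levenberg–Marquardt, i.e. damped
  Gauss–Newton; trust-region-reflective when bounds are present),
  finite-difference Jacobian, tolerances 1e-10, 200-evaluation cap.
  Non-convergence is flagged on the result, never raised, so one bad
  census cannot abort a plot. Y–N fits are unweighted on Y and start
  from the natural values `A = 1/Y(n)`, `B = 1/Y(1)`.
- Assumption verdicts are explicit, configurable heuristics (the
  underlying field analyses report outcomes, not criteria):
  assumption 1 requires convergence and r² ≥ 0.95 in every census;
  assumption 2 requires ρ ≥ 0.9; assumptions 3–5 require the 95% CI
  of the exponent to exclude the null value (≤ 1 for a+1, 0 for b and
  c); assumption 6 reports whether the CI contains 8/3 and returns
  "partial" when a power law holds with a different exponent. CI
  containment uses a 1e-9 relative pad so exact-data degenerate
  intervals are not missed by floating-point rounding.

## Data conventions

Diameters in cm (DBH, 1.3 m), heights in m, biomass in kg summed per
plot (not per hectare) — A and B magnitudes depend on this. Wide
input files use 2-digit year suffixes mapped to the 1900s
(configurable). Trees without a final-census diameter are excluded
(death or measurement loss), as are explicitly listed trees (e.g. a
largest tree judged to belong to an older cohort); shrinking trees
get rate 0 with the raw pair preserved. Recorded biomass columns take
precedence over recomputation; otherwise biomass comes from the
generic multi-species equation
`M = exp(−1.196 + 1.622 lnD + 0.338 (lnD)² − 0.044 (lnD)³ + 0.708 lnδ)·1.029`
with wood density δ from a lookup table (default 0.5 g/cm³ with a
warning when a species is missing — reconstruction without known
densities is approximate). Plots with ranged or bounded stand ages in
the descriptor table enter correlation analyses as midpoints ("7–10"
→ 8.5) or bounds ("<90" → 90).

## Synthetic stands

The generator realises the model's statistical structure exactly so
every stage is testable without field data. Census t has
`(A_t, B_t = K₃A_tᶜ)` with A declining geometrically; the rank-N tree
receives the *integer increment* `M(N) = Y(N) − Y(N−1)` of the
cumulative curve, not the continuous density `B/(AN+B)²`. This makes
the generated cumulative curve satisfy the Y–N equation exactly at
integer ranks, conserves total biomass as `Y(n)`, and is what makes
noise-free parameter recovery exact to machine precision. The cost is
that integer-rank increments do not transform *exactly* under the
continuous rank-preserving projection (deviation O(A/(AN+B)), about
1e-3 relative at the default sizes), so closed-loop projection checks
on generated stands use that tolerance while the projection algebra
itself is verified to 1e-9 against the rank-inversion oracle.

Noise is measurement noise on diameters only (lognormal,
σ_lnD = 0.02 by default — tape-measurement scale); recorded biomass
is recomputed from the noisy diameter, mirroring field tables whose
biomass column is itself diameter-derived. Heights are noise-free
transforms of true biomass. Rank swaps are adjacent-pair exchanges
(keeping ρ high, as observed in closed stands); mortality removes all
subsequent measurements of a tree (default 0).

Default conditions emulate a young, yearly-censused stand: 250 trees,
10 censuses, `A₀ = 0.02 kg⁻¹` (initial asymptotic biomass 50 kg,
a 25 m² regeneration plot), A falling 15% per census (biomass ×4.3
over the decade), `K₃ = 33`, `c = 1.2`, `K₄ = 0.06 kg·cm^(−8/3)`
(consistent with the generic equation at δ ≈ 0.5), `K₂ = 0.1`,
`b = 2.5`. These sizes keep the full test suite and the acceptance
run in seconds. Identifiability note: K₃ is the intercept of the B–A
log-log line at `ln A = 0`; when A is far from unity scale (large
mature stands) this is a long extrapolation and K₃ is poorly
identified under noise, which is a property of the model, not of the
fitter — the young-stand defaults keep the extrapolation short.

Presets: `young` (120 trees, 8 yearly censuses, A ratio 0.75/census,
c = 1.2) and `mature` (300 trees, 6 biennial censuses, 2% total A
decline, c = 1.05, trees up to ~45 cm DBH). With `c = 1` the
projection curve is exactly linear through the origin with slope
`(A₀/A_T)^(1/4)`, so a strongly super-unity RMA slope requires a
substantial A decline; the young preset's overall ratio (~0.13)
yields slope ≈ 1.8, the mature preset ≈ 1.005.

## What passing tests do and do not show

The generator produces data *from* the model; recovery and
maturity-gradient results demonstrate the correctness and internal
consistency of the estimators and closed forms, not the model's
empirical adequacy for real forests. Real censuses add species
mixtures with differing allometries, recruitment, non-geometric A
trajectories, crown damage, and biomass that is not an exact function
of diameter. One behaviour of the emulator worth knowing: with noise,
the mature preset's assumption-3 test is usually *unsupported* — its
stand biomass changes only ~2% across censuses, so the height-scaling
exponent is unidentifiable there. That mirrors field practice, where
the height scaling is tested in young plots (mature-stand heights are
not measurable accurately anyway).

## Known limitations

- No per-species analysis: all trees in a plot are pooled.
- No recruitment; mortality in the generator frees no rank slot.
- The B–A fit treats per-census (Â, B̂) estimates as error-free
  predictors (errors-in-variables are ignored, as in the standard
  analysis chain).
- Spearman significance is not computed (ρ only).
- Per-interval growth rates are available (`--per-interval`), but the
  default and all reported results use first-to-last census pairs.
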