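# ynstand — size-structure model of tree diameter growth

`ynstand` is an analysis package for forest ecologists working with
repeated-census permanent-plot data. It implements a tree growth model
built on the stand's size hierarchy rather than on individual
physiology, and compares it against the metabolic-scaling growth
model, which ignores competition.

## The model

In a closed stand, competition for light is asymmetric: large trees
shade small ones, not vice versa. This produces an inverse-J size
distribution that is well summarised by the **Y–N curve**

```
Y(N) = N / (A·N + B)
```

where `Y` is the cumulative aboveground biomass (kg) of the `N`
largest trees and `N` is a tree's rank from the largest. The
parameters have direct meaning: `1/A` is the asymptotic stand biomass
`Ymax`, `1/B` the maximum individual biomass `Mmax`.
Differentiating gives the biomass of the rank-`N` tree,
`M(N) = B/(A·N + B)²`.

Because asymmetric competition keeps size ranks nearly frozen, a
tree's future biomass can be obtained by holding its rank fixed while
`(A, B)` evolve:

```
M_T = B_T · [ (A_T/A_0)(√(B_0/M_0) − B_0) + B_T ]⁻²
```

With two further empirical scalings — `B = K₃·Aᶜ` between the curve
parameters, and the diameter allometry `M = K₄·D^(8/3)` — the
projection becomes a closed-form map from initial diameter `D₀` to
final diameter `D_T` and growth rate `(D_T − D₀)/Δt`, fully
determined by five plug-in parameters `(A₀, A_T, K₃, c, K₄)` that are
all estimated *upstream*, never fitted to the growth data themselves.

The comparison model (metabolic scaling) predicts
`dD/dt = β·D^(1/3)`, i.e. `D_T^(2/3) = D₀^(2/3) + k`: a straight
slope-one line on two-thirds-power axes. The size-structure model
predicts that line only in mature, slowly changing stands; in young
stands it predicts a steeper, curvilinear relation. The RMA
(reduced-major-axis) slope of `D_T^(2/3)` on `D₀^(2/3)` is therefore
a maturity diagnostic.

The model's six assumptions are each testable on census data:
Y–N fit per census; rank persistence (Spearman ρ); stand biomass vs
top height `Ymax = K₁·Hmax^(a+1)`; tree biomass vs height
`M = K₂·Hᵇ`; `B = K₃·Aᶜ`; and `M = K₄·D^(8/3)`.

## Worked example

Simulate a young stand, test the assumptions, and compare the two
growth models:

```
$ ynstand simulate --preset young --seed 3 --out yy.csv
wrote yy.csv (120 trees x 8 censuses), yy.truth.json, yy_wood_density.csv

$ ynstand assumptions --input yy.csv
1: Y-N curve fits each census: supported
2: ranks persist over time: supported
3: stand biomass scales with top height: supported
4: tree biomass allometric in height: supported
5: B scales with A: supported
6: biomass scales as D^(8/3): supported
```

Running the model comparison (`ynstand compare --input yy.csv`)
prints an RMA slope of **1.82** — far above the slope of 1 demanded
by metabolic scaling, as expected for a rapidly thinning young stand —
and a plug-in projection `r² = 0.997` against `0.80` for the best
slope-one line (`delta_r2 ≈ 0.20`): the size-structure curve explains
about 20% more variance in `D_T^(2/3)` here. On the `mature` preset
the same commands give an RMA slope of 1.01 and a delta near zero:
both models coincide where stand structure barely changes.

The numbered scripts under `analysis/` run the same study as a batch:
`01_simulate_stands.py` → `05_stand_maturity.py` write their tables
to `results/`.

Field data are read from wide CSVs with year-suffixed columns
(`D85` = DBH in cm in 1985, `H85` = height in m, `WA85` = biomass in
kg, one row per tree). When biomass columns are absent it is computed
from DBH by the generic multi-species allometric equation for Japanese
natural forests (cubic in `ln D`, wood-density term, correction factor
1.029); supply `--wood-density species.csv` for species-specific
densities.

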