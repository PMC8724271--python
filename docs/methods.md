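# Methods

## The model chain

The package implements a three-stage quantitative argument about
paracrine-mediated (non-cell-autonomous) AAV therapy in myocardium:

1. **Distance–area regression.** For untransduced (GFP−) cardiomyocytes in
   treated hearts, cross-sectional area *Y* (μm²) is regressed on distance
   *X* (μm) to the nearest transduced cell by ordinary least squares,
   pooling cells across animals. Significance of the slope is the exact
   two-sided *t* test with *n* − 2 degrees of freedom; no mixed-effects or
   robust alternatives are offered (the pooled-cell OLS is the modelled
   analysis).
2. **Hypertrophic threshold.** The mean area of an untreated hypertrophic
   population carries a symmetric *t* confidence interval,
   mean ± *t*₍(1+γ)/2, n−1₎ · sd/√n, γ = 0.95 by default. The *lower* bound
   *L* is the reference level: a treated cell whose expected area reaches
   *L* is no longer distinguishable from hypertrophic. The interval is on
   the mean (not the population distribution), matching the "confidence
   interval" reading of the quantity; a *t* rather than *z* quantile
   matters at the n ≈ 100 sample sizes involved.
3. **Effective range and coverage.** *X\** = (*L* − *b₀*)/*b₁* is the
   paracrine action radius. One infected 120 × 20 × 20 μm cuboid
   (myofiber long axis along x) in a 3-D lattice reaches *N* neighbours
   within *X\** of its margins under a coverage criterion; the minimum
   infection rate is the exact rational *f* = 1/(*N* + 1) — tile the
   tissue into (*N* + 1)-cell neighbourhoods, one infected cell each.

With the generator's exact parameters (below), *X\** =
(304.7 − 202.723)/1.193 = **85.48 μm**. A published analysis of this
geometry reports 84.5 μm from its own (unprinted) full-precision fit; the
package always reports the value computed from its inputs and never
substitutes a rounded literature value.

## Synthetic data generator

No animal data ship with the package; the generator emulates the study
conditions the chain assumes:

| parameter | default | meaning |
|---|---|---|
| treated line | 202.723 + 1.193·X μm² | GFP− area vs distance, treated arm |
| treated correlation | R = 0.265 | sets noise SD via calibration |
| control line | 326.868 + 0.077·X μm² | pressure-overload (AAC) arm |
| control correlation | R = 0.022 | essentially flat |
| X distribution | Uniform(0, 110) μm | the line reaches the hypertrophic mean near X ≈ 109, so the linear regime plausibly spans this range |
| regression n | 105 per replicate | back-solved from (R = 0.265, p = 0.006) via the t statistic; the exact scan (`infer_sample_size`) gives 107, and 105 is kept as the round design value |
| hypertrophic areas | Normal(332.2, 138.6²) μm² | SD back-solved from lower 95% bound 304.7 at n = 100 |
| infection rates | 0.388 treated / 0.363 control | per-cell Bernoulli within each animal |
| animals × cells | 5 × 200 | the infection-rate study condition |

**Noise calibration.** For *Y* = *b₀* + *b₁X* + ε with ε ~ N(0, σ²)
independent of X, R² = *b₁*²Var(X)/(*b₁*²Var(X) + σ²), so
σ = |*b₁*|·sd(X)·√(1/R² − 1). At the defaults σ ≈ 137.8 μm² (treated) and
≈ 111 μm² (control). σ is undefined at R = 0 (raises) and exactly 0 at
R = 1.

**Positivity vs calibration.** Cell tables from `simulate_cells` floor
areas at 1 μm² (areas are physical; flooring events are logged). At the
calibrated noise the floor truncates ~4–7% of treated-arm draws, which
measurably attenuates a recovered slope (to ≈ 1.12 at the defaults). The
replicate generator `simulate_distance_area` therefore draws the pure
linear-Gaussian model by default (flooring available via `floor=`): the
calibration identities, and the parameter-recovery checks built on them,
hold exactly only without truncation. Full-pipeline fits on floored tables
consequently run slightly shallow — a property of clamped Gaussian
morphometry worth remembering when comparing the two paths.

**What the generator does not emulate:** spatial correlation between
neighbouring cells, per-animal random effects (all animals share one
line), measurement error in distance, non-Gaussian area distributions,
and any image-level structure. Passing tests therefore demonstrate the
correctness of the estimators and geometry under the stated model, not
robustness to those real-data features. GFP+ cells are given areas at the
arm's distance-zero line value and a lognormal reporter intensity; only
the GFP boolean is consumed downstream.

## Lattice coverage: criteria and conventions

Distance is measured to the infected cell's *margins*; for exterior points
this equals the distance to the solid box, via the per-axis clamp
d_a = max(|p_a − c_a| − h_a, 0). The whole-cell criterion uses the exact
farthest-point distance (per-axis max clamped offset, attained at a
neighbour corner); centre-in uses the centre's clamped distance;
half-volume counts voxel centres (default 1 μm, convergence-checked at
0.5 μm). All criteria are evaluated over an enumeration extent derived
from the radius and re-checked at doubled extent, so no affected cell can
be clipped. Rates are kept as `fractions.Fraction` — f·(N+1) = 1 holds
exactly — and formatted to two decimals only for display.

Published counts for this geometry (radius 84.5 μm) are 60 cells
(whole-cell, rate printed 1.67% = 1/60) and 156 (half-a-cell, 0.64% =
1/156), from an unpublished script whose packing and discretisation
conventions are unknown. The package therefore runs an explicit
**convention sweep** (`pararange sweep`) over packing ∈ {axis_aligned,
brick_staggered_x} × criterion ∈ {whole_cell, whole_cell_voxel, center_in,
half_volume}, with every convention validated against an independent
brute-force offset enumeration:

| packing | criterion | N affected | 1/(N+1) |
|---|---|---:|---:|
| axis_aligned | whole_cell | 56 | 1.75% |
| axis_aligned | whole_cell_voxel | 60 | 1.64% |
| axis_aligned | center_in | 158 | 0.63% |
| axis_aligned | half_volume | 158 | 0.63% |
| brick_staggered_x | whole_cell | 48 | 2.04% |
| brick_staggered_x | whole_cell_voxel | 52 | 1.89% |
| brick_staggered_x | center_in | 142 | 0.70% |
| brick_staggered_x | half_volume | 142 | 0.70% |

The **documented published-matching convention** is axis-aligned packing with
the voxel-assessed whole-cell criterion and the half-volume criterion: its
whole-cell affected count (60) reproduces the published count exactly, and
no convention in the sweep comes closer on the half-cell count (158 vs
156). Two residual discrepancies are documented rather than forced:

* The published percentages equal 1/N (reciprocal of the affected count),
  whereas this package's rate is 1/(N+1), counting the infected cell
  itself in the covered neighbourhood. `CoverageResult.reciprocal_affected`
  exposes the per-affected-cell reading (1/60 = 1.67% under the documented
  convention).
* The 1 μm voxel whole-cell reading includes four corner cells at offsets
  (0, ±3, ±3) whose farthest corner lies 84.85 μm away — 0.35 μm outside
  the radius — because voxel centres sit half a voxel inside the surface;
  the exact criterion gives 56. Both are reported; the discretised reading
  is what a voxel script of this kind produces at 1 μm (it is stable at
  0.5 μm and flips to the exact count at 0.25 μm).

The lattice is a deliberate idealisation: identical axis-aligned cuboids,
no interstitium, no curvature, and a single infected cell (the rate is the
single-cell reciprocal, not a covering-design optimum over multiple
infected cells).

## Cohort statistics

Per-animal summaries take the animal as the replication unit for infection
rates (group mean ± SD of per-animal GFP+ fractions). Area comparisons use
Welch's unequal-variance *t* (two-sided, Welch–Satterthwaite df) with
Cohen's d on the pooled SD; cell-level pooling is the default unit of
analysis, matching the >20-cells-per-animal pooling the chain models. No
multiple-testing correction is applied by default. The scalar
non-cell-autonomy index is 1 − mean(treated GFP−)/mean(control GFP−);
positive values mean untransduced cells in treated animals are smaller
than pressure-overload controls.

## Numerical choices and degenerate inputs

* OLS: closed-form normal equations; all-identical X raises a
  degenerate-design error; all-identical Y is legal (slope 0, R set to 0,
  p = 1, and the range stage reports no crossing instead of raising).
* Zero slope in `effective_range` yields a flagged no-crossing result,
  never an exception; negative *X\** (e.g. the control line, which starts
  above the bound) is reported with `crossing=False`.
* `infer_sample_size` scans n upward in vectorised chunks against the
  exact t tail (monotone in n), capped at 10⁶.
* Voxel resolutions that do not evenly divide the cell dimensions warn and
  round the voxel count.
* Bootstrap CI on *X\** exists (`bootstrap_range_ci`) but is off the
  default path: the headline range deliberately carries no uncertainty
  band.
* Reports serialise with sorted keys; serialise → parse → serialise is
  byte-stable.

## Problem sizes

The statistical checks use 1000 replicates for regression and threshold
recovery (Monte-Carlo SE of the mean slope ≈ 0.013 at n = 105 per
replicate, so the 3-SE acceptance band is ±0.04) and 200 replicates of
5 × 200-cell studies for infection-rate recovery (SE ≈ 0.001). The
geometric checks are exact and deterministic; the voxel oracle runs at
0.5 μm over all candidate offsets and at 0.25 μm on the borderline corner
cells.

## Known limitations

* The regression pools cells across animals; with per-animal random
  intercepts the effective n would be smaller and the slope CI wider.
* The threshold is a confidence bound on the *mean* hypertrophic area; a
  population-quantile reading would push *X\** further out.
* The coverage model's minimum rate assumes perfectly regular tiling of
  infected cells; random AAV mosaicism needs a higher rate for the same
  coverage probability.
* Generator realism limits listed above apply to every downstream
  statistical statement.
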