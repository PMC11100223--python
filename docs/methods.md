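# Methods

## Trait derivation

All raw measurements enter in the units they are recorded in (lengths in
µm, counts per area in mm⁻²); conversions to SI happen inside the
conductivity formula only. The hydraulic diameter `D_h = Σd⁵/Σd⁴` is
computed per individual from that individual's own list of measured
tracheid diameters, and `K_s = (πρ_w/128η)·CD·D_h⁴` from that individual's
`D_h` and tracheid density. Species-level `K_s` is the mean of individual
values, never `K_s` of the species-mean `D_h`: the quartic makes the two
differ (Jensen's inequality), and averaging individuals is the convention
that keeps every derived trait on the same footing.

Two wall-mechanics formulas are not uniquely fixed by common usage, so both
are explicit package choices, selectable via keyword:

- `TSR = 2·DWT / mean(LD_r, LD_c)` (default) — double wall thickness over
  mean lumen span. With wall ≈ 4.5 µm and lumen ≈ 15 µm this lands at
  ≈ 0.6, the magnitude conifer earlywood studies report. The squared
  variant `(DWT/lumen)²` is available but produces values an order of
  magnitude smaller.
- `CWR = 100·(1 − (LD_r·LD_c)/(D_r·D_c))` (default) — percent wall area in
  a rectangular cross-section approximation, ≈ 37–46% at realistic
  geometries; a linear-span variant is available.

Pit metrics are returned even when the geometry is inconsistent
(DPA ≥ DT or DT ≥ DPM); such rows are flagged (`pit_in_range=False`) and
warned about rather than dropped, since no exclusion rule is part of the
measurement definitions. `VE` is stored as the exact product `TO·MF`.

## Variation statistics

The log transform is the natural log with no offset; non-positive values
are an error naming the cell, because silently offsetting would change the
meaning of ratios downstream. ANOVA is the classical one-way decomposition
(scipy), Tukey HSD uses the studentized-range distribution
(`scipy.stats.tukey_hsd`), and the compact letter display is an
insert-and-absorb construction with alphabetical tie-breaking, so two
groups share a letter exactly when their HSD p ≥ α. Interspecific CV is
100·SD/mean over species means (sample SD); within-species CVs are emitted
per species. Pearson p-values use the t transform with n − 2 df;
correlations are complete-case by default with a pairwise-complete option.
Trait clustering is average-linkage on distance 1 − |r| with columns sorted
alphabetically first, which makes leaf order deterministic under column
permutations.

## Ordination

PCA is performed on species means (the species, not individuals, are the
unit of comparison in a common garden), z-scored per trait, via
eigendecomposition of the correlation matrix. Signs are fixed so each
component's largest-magnitude loading is positive. With 17 species and 19
traits the matrix is rank-deficient; trailing components have (numerically)
zero eigenvalues and are reported, not errored — their loadings span a null
space and are not interpretable.

## Piecewise path model

Estimation is local, one OLS per endogenous variable on its parents, on
z-scored data, so slopes are standardized path coefficients — the piecewise
approach, not global covariance fitting. The default DAG encodes the
hydraulic cascade DWT→TSR, D_r→TSR, D_r→D_h, TSR→D_h, D_h→K_s; the direct
D_r→D_h edge is included by default and any structure can be supplied as
JSON. Non-significant edges stay in the effect computation.

Total effects are computed from the coefficient matrix B as the finite
series Σ_{k≥1} Bᵏ (nilpotent for a DAG); the k = 1 term is the direct
effect and the remainder the indirect, so total = direct + indirect holds
identically. Tests check this algebra against exhaustive path enumeration.

Goodness of fit is the d-separation test: one claim per non-adjacent pair,
conditioned on the union of both nodes' parents, tested as the partial
t-test of the omitted edge in a regression of the (topologically later)
node; Fisher's C = −2Σln pᵢ against χ² with 2·(claims) df, acceptance at
p > 0.05. Claims are ordered deterministically (lexicographic topological
order). Collinear parents trigger a warning, not an error.

## Phylogenetic signal

The BM covariance V is built by node-depth accumulation over the tree;
tips without trait data are pruned with a log message. Blomberg's K follows
the ratio-of-MSE definition with the phylogenetic GLS mean; its permutation
test shuffles trait values across tips and counts permutations whose
phylogenetic MSE is at most the observed one, with the add-one rule
p = (1 + #{≤})/(n_perm + 1). The default permutation count is 999 and a
seed is mandatory; each trait derives its own sub-seed so results are
independent of trait order.

Pagel's λ multiplies V's off-diagonals; the likelihood is profiled
analytically over the mean and rate and maximized over λ by bounded 1-D
search on [0, λ_max], with both interval endpoints also evaluated so
boundary optima are exact. λ_max is the pairwise bound
min V_ii·V_jj/V_ij², capped at 1.5, backed off slightly if the Cholesky
factorization fails; for an ultrametric unit-depth tree this sits just
above 1. The LRT against λ = 0 uses χ²₁; because λ̂ is boundary-constrained
this p-value is conservative at the ends, a known property accepted here.

Both statistics are affine-invariant in the trait, which the tests assert
numerically.

## Climate screen

Species-mean traits plus the first two PCA scores (as pseudo-traits) are
Pearson-correlated with ten climate-of-origin covariates. Significance is
annotated in raw-p tiers (* p < 0.1, ** p < 0.05, *** p < 0.001) with an
optional Benjamini–Hochberg adjustment flag; no correction is applied by
default because the screen is exploratory.

## Synthetic data

The generator emulates a 17-species × 10-individual common-garden design:

- **Tree**: pure-birth (Yule) with the requested tip count, extended past
  the final speciation by one exponential waiting time (otherwise the
  simulator leaves a zero-length cherry and a singular V), rescaled to unit
  depth.
- **Species means**: log-scale BM deviations (tunable λ) around
  field-realistic magnitudes — torus ≈ 6 µm inside a ≈ 12 µm membrane with
  a ≈ 3.5 µm aperture, radial tracheid ≈ 20.5 µm with wall ≈ 4.55 µm,
  density ≈ 1600 mm⁻², fiber ≈ 1.3 mm. Structural couplings keep the data
  physically coherent: lumen = diameter − wall, torus and aperture nested
  fractions of the membrane, and density trading off against diameter
  (log-coupling −1.5), which makes K_s the trait with the widest
  interspecific CV, as in real conifer datasets.
- **Individuals**: multiplicative Gaussian replicates (within-species CV
  5–9% per trait) with the measurement invariants enforced by redrawing the
  row; 50 tracheid diameters per individual at 15% spread.
- **Path data**: a standardized linear SEM with unit-variance construction;
  default coefficients (−0.4, −0.5, −0.5, +0.5, +0.8) chosen feasible and
  strong enough for recovery tests.
- **Climate**: each targeted covariate is r·z(trait) + √(1−r²)·noise, then
  shifted to montane-conifer scales; r = ±1 yields an exact copy.

What the generator does **not** emulate: non-Gaussian trait distributions,
measurement error structure specific to microscopy, earlywood/latewood
heterogeneity, spatially coherent climate geography, or a causal link from
anatomy to climate. Passing tests on synthetic data therefore demonstrate
correctness of the estimators and plumbing under known truth — not that any
particular biological conclusion transfers to real measurements.

A deliberate property of the synthetic anatomy is that K_s is constructed
from both diameter and density, so the default five-edge DAG (which omits a
density→K_s link) is *correctly rejected* by the d-separation test on
generated anatomy tables, while it is accepted on data simulated from the
DAG itself. Both behaviours are tested.

## Numerical choices and problem sizes

Cholesky factorizations back all GLS algebra; the λ optimizer tolerance is
1e-8; permutation p-values use the add-one estimator; PCA reproducibility
is enforced by the loading sign convention; CSV intermediates carry units
in `#` header comments and diameter lists semicolon-joined at 3 decimals.
Calibration checks use 50-tip trees with 500 Brownian replicates for K and
the permutation type-I error, 100-tip trees with 200 replicates per end for
λ recovery, and n = 10⁴ draws for path-coefficient recovery — sizes at
which Monte-Carlo error is comfortably inside the asserted bands while the
whole suite stays quick on a laptop.

## Known limitations

- Within-species variance is ignored in the signal tests (one value per
  tip); measurement-error-aware extensions of K and λ are out of scope.
- The d-sep test assumes Gaussian residuals and linear links; only OLS
  local models are implemented.
- The compact letter display is greedy insert-and-absorb; it is correct
  (letters respect pairwise significance exactly) but not guaranteed to use
  the minimum possible number of letters.
- The χ²₁ LRT for λ is conservative at the parameter boundary.
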