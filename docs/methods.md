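# Methods

## Model and assumptions

`nmadiag` implements a *fixed-effects* network meta-analysis of
contrast-level data with known sampling (co)variances. Study s of design
d (treatment set of size N_d) contributes a vector Y_s of N_s−1 contrasts
against a design reference and a covariance block V_s. The consistency
model is the general linear model Y = Xθ + ε with block-diagonal V; the
basic parameters θ are the T contrasts of each non-reference treatment
against the network reference A₀, and every other contrast is a linear
combination of them.

Fixed effects are a deliberate modelling stance, not a simplification:
with variances treated as known, the residual sum of squares is a
generalized Cochran statistic with an exact chi-squared reference
distribution under the null, and a deviating design inflates Q the same
way whether it is the sole representative of its design or one of many.
Random-effects pooling, node splitting and the full design-by-treatment
interaction model (all designs freed simultaneously) are intentionally
out of scope.

Estimation is two-stage — per-design inverse-variance pooling followed by
GLS on the pooled estimates — which is algebraically identical to the
one-stage study-level fit; the test suite verifies the equivalence to
1e-8 on random networks.

## Canonical conventions

* Treatments are ordered lexicographically. The network reference A₀ is
  the smallest label; each design's reference is its smallest treatment;
  design ids are the sorted treatment lists joined by ":". All Q
  statistics are invariant to these choices (tested by relabeling), so a
  deterministic canonical form costs nothing and makes runs reproducible.
* Input rows `study,treat1,treat2,effect,se` are interpreted as the
  effect of `treat2` relative to `treat1` and re-oriented to the design
  reference by sign flips.
* Multi-arm covariance blocks are built from arm-level variances as
  Var(Y₀ᵢ) = v₀ + vᵢ, Cov(Y₀ᵢ, Y₀ⱼ) = v₀. If instead all n(n−1)/2
  pairwise standard errors are given, arm variances are recovered by
  least squares from vᵢ + vⱼ = se²ᵢⱼ (exact for three arms); non-positive
  solutions are rejected. A multi-arm study with neither is an error —
  pairwise SEs alone under-determine the block.

## Diagnostics

**Hat matrix.** H is computed densely (networks of interest have D ≲ 50
designs) at the design-contrast level. Its diagonal equals the weight of
the direct estimate against the combined indirect evidence; for networks
of two-arm designs this weight has an electrical analogue — the
conductance 1/V_d against the effective conductance of the remaining
graph — which the tests use as an independent oracle over all connected
graphs with up to five edges. For multi-arm designs the rows of H depend
on the (canonical) design reference; output labels carry a `*` on
multi-arm contrasts to flag this. Study-level splitting of a design's
self-weight (proportional to study inverse variances) is provided for
two-arm designs only; no analogous decomposition is defined for
correlated multi-arm blocks.

**Q decomposition.** Q_net (study level) splits exactly into Q_het (sum
of per-design pooled-fit statistics) and Q_inc (aggregate-level residual
quadratic form); additivity to 1e-8 is asserted on random networks with
injected heterogeneity. Degrees of freedom follow the design-size
inventory only. df_inc = 0 (no loops) triggers a warning that
inconsistency is unassessable, and p-values at df = 0 are reported as 1.

**Detaching.** Detaching design d appends N_d−1 indicator columns and
refits. The extended normal equations are solved with a pseudo-inverse:
when a detachment saturates the model (e.g. any detachment in a
single-loop network) or leaves a parameter unidentifiable, the residuals
— which depend only on the column space — remain well defined, and the
residual block of d is zero by construction. Its df is
df_inc − (N_d−1), floored at zero. A design is detachable only if at
least two of its treatments appear elsewhere and removing its studies
leaves those treatments connected; bridge and pendant designs carry no
assessable inconsistency and are excluded from the Q-difference matrix
and the plot (their aggregate residuals are identically zero, so the
column-sum identity Σ_{d′} Qᵈⁱᶠᶠ_{d′,d} = Q_inc − Q₍d₎ⁱⁿᶜ survives the
restriction).

**Q-difference rows for multi-arm designs.** The per-design summand
Qⁱⁿᶜ_{d′} is a quadratic form r′V⁻¹r over d′'s contrast block. For
display at contrast resolution each row i carries rᵢ·(V⁻¹r)ᵢ, which sums
exactly to the design summand and reduces to the squared Pearson
residual for two-arm designs. Other splits of a quadratic form are
possible; this one is symmetric, exact in aggregate, and needs no extra
convention. Whole designs are always detached together — freeing single
contrasts of a multi-arm design separately is not defined here.

**Clustering and rendering.** Rows/columns of the design-level
Q-difference matrix are ordered by complete-linkage clustering of the
city-block distance on rows plus columns
(Σ_k |Q_{i,k}−Q_{j,k}| + Σ_k |Q_{k,i}−Q_{k,j}|); labels are pre-sorted so
ties break deterministically, and an all-zero matrix keeps label order.
Colors use a symmetric diverging ramp (blue → white → yellow/orange/red)
in 13 discrete bins over [−cap, +cap], saturating at the configurable cap
(default 8). The exact palette is a presentation choice; any symmetric
warm/blue ramp with that saturation behaviour is equivalent. Gray squares
are drawn with side √|H_{d′,d}| per cell so their *area* is proportional
to the hat-matrix contribution; multi-arm hat columns of one design are
summed into the design's column. Rendering is a pure function of the
layout (SVG output is byte-identical across runs; the SVG hash salt and
date metadata are pinned).

## Numerical choices

Matrix inverses go through linear solves; accumulated precision matrices
and covariances are re-symmetrized by averaging with their transpose.
Covariance blocks must be symmetric positive definite (checked at
construction, tolerance 1e-10 on symmetry). Residual magnitudes below
1e-10 are snapped to zero in detachment output so saturated fits report
exact zeros. p-values are displayed to three decimals in text output and
kept at full precision in the JSON export.

## Synthetic data

`scenarios.make_scenario` builds the illustrative six-treatment networks
used throughout the tests: one single-study design per edge, unit
variances, all effects zero except a perturbation δ (default 5, i.e.
five standard errors of a direct estimate — large enough to give the
diagnostics visible power at desk scale) on one design. Three topologies
are provided: the 8-edge two-triangle network, the 6-cycle, and the
complete graph K₆. `simulate_network` draws study effects
Yₛ ~ N(true contrast + uₛ, V) with an optional between-study shift
uₛ ~ N(0, het_sd²), for null-distribution and recovery testing.
`diabetes_structure` reproduces only the design-size inventory
(26 studies, 15 designs, one three-arm design, ten treatments) of a
published glucose-lowering network for degrees-of-freedom bookkeeping;
it contains no outcome data.

These generators emulate the *structure* of real networks — connectivity,
multi-arm correlation, heterogeneity — but not small-study effects,
effect-measure asymmetries, missing-variance reporting or correlated
biases. Passing tests therefore certify the algebra and the diagnostics'
null behaviour, not robustness to real-data pathologies.

Problem sizes used in the test suite (chosen as representative desk
scale): networks of up to 15 designs, up to 20 studies per design,
10,000 replicates for the null-distribution check of Q_inc (vectorized
through the fitted projection matrix) and a few hundred full-pipeline
simulation replicates.

## Known limitations

* Inputs are contrast-level; computing effects from raw 2×2 tables or
  means is out of scope.
* Only one design is detached at a time; masking by several jointly
  deviating designs can hide sources (the plot may still show two
  blocks, but identification is not guaranteed).
* In single-loop networks inconsistency is detectable but not locatable
  (every detachment saturates the model).
* The chi-squared reference distributions treat variances as known; with
  small studies the "known variance" assumption is itself an
  approximation.
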