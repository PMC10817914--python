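# Methods

This note documents the statistical models, the synthetic-study generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Study design emulated by the generator

The generator reproduces the statistical skeleton of a longitudinal
developmental imaging study: `N` cortical parcels (default 100 at desk
scale; the emulated design uses 1000) on two mirror-symmetric hemispheres, a
binary WM connectome, and a mixed scan roster in which some subjects are
scanned once, some twice and some three times at ~1-year intervals (defaults
158/105/51, giving 521 scans and 207 consecutive scan pairs). Group
membership follows the scan age at a 10.0-year cut-off.

**Parcellation.** Parcels sit on a per-hemisphere Fibonacci lattice
(deterministic quasi-uniform coverage); spatial adjacency is the Delaunay
triangulation of each hemisphere's (y, z) projection — a computational proxy
for shared parcel borders, which atlas files do not encode. System labels
(default 7) are nearest-seed partitions from farthest-point-sampled seeds,
mirrored across hemispheres, with a repair pass that reassigns fragmented
minority components so every label is spatially connected. Laminar labels
(4 classes) are built the same way.

**Connectome.** Edge weight ∝ exp(−d/ℓ)·(1 + b·1[same system]) with
ℓ = 1.0 (unit-sphere units) and b = 8 by default; a Euclidean minimum
spanning tree guarantees connectivity and the remaining edge quota is drawn
by weighted sampling without replacement, so realized density equals the
target up to rounding. The community bonus is calibrated once so that ≈60%
of a node's first-scale diffusion mass stays within its own system — the
strong community segregation observed in real structural connectomes
(within-system first-scale diffusion probability above 0.5, decaying with
scale). This matters: a purely distance-dependent graph carries no topology
beyond geometry, and geometry-preserving rewired surrogates would then match
it exactly, leaving the constraint analysis nothing to detect.

**Planted effect maps.** A maturation map led by chosen "dominant" nodes is
the weighted sum of those nodes' symmetrized diffusion-profile rows, either
at one scale (`scale_m=k`, exact row semantics) or averaged across scales
1…M (`scale_m=None`, default) — the across-scale mean is smooth along the
network's own wiring, the regime the dominance analysis targets. Recovery
experiments plant the two highest-degree hubs, mirroring the observation
that dominant regions are high-degree association cortex. Spatial noise is
one adjacency-averaging pass over i.i.d. Gaussians (raw sd 0.01 by default
against a planted-map sd of ≈0.027, i.e. ≈15% noise-to-signal after
smoothing).

**CT roster.** CT_ij = node baseline (3.0 mm + smooth spatial variation) +
β·1[adolescent] + sex effect + subject random intercept (sd 0.10 mm) +
i.i.d. noise (sd 0.05 mm). With all noise terms zero the adolescent-minus-
child group difference reproduces β exactly (tested to 1e-10).

**Gene panels.** One sample per (region, age); genes inside a target set
share a latent age trajectory whose level differs between dominant and
non-dominant regions by a planted divergence; background genes are noise.

**Isotropic maps.** `gen_autocorrelated_map` samples a Gaussian process with
squared-exponential covariance over centroids (default length scale 0.6).
Its distribution is rotation-invariant — exactly the exchangeability class
of the spin test — which is why the calibration studies use it as the
network-independent autocorrelated map family.

## Maturation models

*Model I* fits, per node, CT ~ group + sex (+ site as a fixed covariate when
present) with a per-subject random intercept by REML (statsmodels MixedLM);
the group term is coded child = 1 so the t statistic is positive for
cortical thinning. A per-subject random group slope can be requested
(`random_slope="auto"`); it is not the default because the slope is
unidentifiable for subjects observed in only one group and the attempted fit
mostly exercises the fallback. When every subject has a single scan the
random intercept is unidentifiable and the model drops to OLS, whose t then
matches the closed-form OLS oracle to 1e-6. Significance is Bonferroni
(α/N): at the emulated 1000-node resolution the per-node threshold is
5×10⁻⁵. P-values use the normal approximation for mixed fits (hundreds of
scans; exact t for the OLS path); the family-wise error under the null is
verified ≤ 0.05 by simulation.

*Model II* represents the age smooth with a cubic B-spline basis (default
dimension 5, boundary knots at the observed age range, interior knots at age
quantiles) plus sex, with a subject random intercept fit by REML. Smoothness
is controlled by the modest basis dimension rather than an explicit
wiggliness penalty — a deliberate simplification: no installed Python
library fits penalized smooths jointly with random effects, and at ≈500
scans a df-5 spline is already in the REML-chosen smoothness regime of the
penalized alternative. Maturation rate at age a is the central finite
difference of the fitted smooth with step 0.01 y; evaluation ages must lie
inside the observed range by at least that step.

*Model III* is ΔCT/Δage per consecutive same-subject scan pair (negative =
thinning), exactly antisymmetric under swapping the two scans.

## Surrogate nulls

**Spin test.** Each surrogate applies one uniform random 3-D rotation to the
left-hemisphere centroids and its x-mirrored twin to the right; every parcel
takes the value of its nearest rotated same-hemisphere parcel (duplicates
permitted). Identity rotations reproduce the input exactly and Moran's I is
preserved within ±50% on smooth maps. Two desk-scale caveats are documented
by the calibration studies: duplicated assignments (~30% of parcels at
N=100–250) mildly over-smooth surrogates, making the test conservative for
maps rougher than the rotation scale; and "observed exceeds *all* n spins"
is unattainable at any effect size because a near-identity rotation arises
with probability ≈1/3 per 99-spin ensemble.

**Rewired test.** Edges are split into 10 equal-frequency Euclidean-length
bins; within each bin degree-preserving double-edge swaps run for
`n_swap_factor × bin-size` attempts, rejecting self-loops, multi-edges and
swaps whose new edge lengths leave the bin. Degree sequences and per-bin
edge counts are preserved exactly. The spec-stated default factor of 10 is
kept for exploratory use, but at desk scale it leaves surrogates sharing
most of the source's wiring (the swap chain has not mixed), which biases
null correlations toward the observed value. Inference-grade experiments —
the calibration and recovery studies — therefore run the chain to
approximate mixing (factor 120, chosen where surrogate-vs-source divergence
saturates). Connectivity is not enforced unless requested
(`ensure_connected=True`, used when surrogates feed the diffusion model;
disconnected draws are redrawn and logged).

**Empirical p.** (k+1)/(n+1) with k the number of nulls at or beyond the
observed value — the guard avoids p = 0; `literal_fraction=True` restores
the plain fraction.

**Calibration.** Under the tests' joint H0 — isotropic GP maps on a
geometry-only connectome (community bonus 0), mixed rewired chain — both
tests reject at the nominal 5% within the binomial band (measured 0.04–0.06
at N=250 over 100–200 simulations, 99 nulls). With community structure in
the network the rewired test becomes conservative for network-independent
maps (destroying communities while keeping geometry slightly *improves*
neighbor prediction of smooth maps); this direction is safe.

## Diffusion model and prediction

Dense matrix powers compute Pᵐ for m = 1…M (M = diameter; ≤ ~1000 nodes
this is exact and fast); rows are verified stochastic to 1e-12. The SVR
uses nodes as samples and scale-m rows of S_m as features (self-entry
included; `drop_self` available). Features *and target* are z-scored with
training-fold statistics only — target scaling makes the ε-insensitive tube
(default 0.1) scale-free, without which mm-scale maps train to a constant.
C is selected per outer fold by inner 5-fold CV over the 16-value grid
2⁻⁵…2¹⁰; accuracy is the Pearson r between the map and assembled
out-of-fold predictions; contributions are mean absolute linear weights on
the standardized scale. Significance re-runs the identical CV on spun
targets (spin) or on profiles recomputed from rewired networks (rewired).

## Dominance and genes

Cosine similarity is computed on raw (uncentered) vectors (`--centered`
style flag gives the correlation variant); per node and scale the spin p is
one-sided and the conjunction map is the per-node fraction of dominant
scales, with no across-scale multiplicity correction (thresholding is per
scale by design). On planted data the source attribution is sharpest at the
first neighboring scale; at deeper scales the likelihood correctly spreads
to the planted hubs' neighborhoods. The rank-based alternative averages the
ascending ranks of the map and of its neighbor-mean estimate (average ranks
on ties; degree-0 nodes rank lowest).

Gene-set PC1 is the first principal axis of the column-standardized set
submatrix fit jointly over all samples, sign-fixed to nonnegative mean
loading; zero-variance genes are dropped with a warning. The contrast
restricts samples to an age window (default 6–14 y, the childhood-to-
adolescence span) and resamples same-size gene sets from the remaining panel
(categories fixed). Map–gene correlation uses one shared spin ensemble of
the phenotype map (two-sided p, floor 1/(n+1)) and BH-FDR across genes —
with n spins the attainable q-values are bounded below by (1/(n+1))·G/rank,
so small screens need n ≥ 999.

## Consensus backbone

Candidate edges (present in ≥1 individual) are pooled intra- vs
inter-hemispherically when hemisphere labels exist (flag to disable),
split into 10 equal-frequency length bins per pool, and each bin keeps its
quota — the mean individual edge count in the bin — of the most frequent
edges (ties: shorter first, then lexicographic). Integer quotas are
apportioned by largest remainder so the backbone's total edge count equals
the rounded mean individual count exactly. Edge length is Euclidean
centroid distance: streamline lengths do not exist outside tractography, and
this substitution is the only length available to the pipeline.

## Problem sizes

Unit and acceptance studies run at 100 nodes (calibration at 250, the
Bonferroni check at the emulated 1000), 99-surrogate ensembles, 20-seed
recovery batches, 100–200-simulation calibration batches. These sizes give
the test suite stable verdicts (binomial bands, 2% Monte-Carlo tolerances)
while each stage remains a few seconds to a few minutes.

## Known limitations

- The generator's geometry is a sphere pair, not a folded cortex; distances
  are chord lengths, not geodesics or streamlines.
- Spin and rewired tests are family-vs-observation heuristics, not exact
  permutation tests; their calibration is demonstrated in their H0 worlds
  and degrades gracefully (conservatively) outside them.
- Model II's smoothness control by basis dimension can under-smooth very
  wiggly truths at large basis dimensions; the default targets monotone or
  single-bend developmental trajectories.
- Passing tests on synthetic data show the machinery is correct and
  calibrated under the stated generative assumptions; they do not show that
  real cortical maturation obeys those assumptions.
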