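# Methods

This note documents the statistical machinery implemented in `liponet`, the
assumptions behind it, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Data model and preprocessing

The unit of analysis is a samples x fractions table of the 21 lipoprotein
main fractions (mg/dL) with per-sample sex (`M`/`W`) and age (years).
Concentrations are non-negative and right-skewed, with variance growing
with the mean; the preprocessing chain is therefore a **square-root
transform** (variance stabilization) followed by **autoscaling** (zero
mean, unit sample variance per column, n−1 denominator), in that order.
All multivariate stages (PCA, Random Forest, networks) consume the
transformed, autoscaled matrix; rank-based univariate tests run on raw
concentrations, where the monotone transform is irrelevant.

Age groups are defined within sex: *young* = strictly below the 33%
quantile of that sex's age distribution, *old* = strictly above the 67%
quantile (linear-interpolation quantiles).  The middle tertile belongs to
the sex-level group only; excluding it from the age contrast sharpens the
comparison of distributional extremes.  Strict inequalities at the
boundaries mean a subject sitting exactly on a quantile is assigned to
neither stratum.

## Univariate testing and ROC

Each fraction is compared between two groups with the two-sided
Mann-Whitney-Wilcoxon rank-sum test (scipy implementation); the U
statistic counts pairs (a, b) with a > b plus half the ties.  Bonferroni
correction multiplies p by the panel size m and caps at 1; flagging
adjusted p < 0.05 with m = 21 is equivalent to raw p < 0.05/21 ≈ 0.0024.
A stricter convention (adjusted p < 0.01) circulates for the same kind of
panel; both thresholds are exposed via `alphas.univariate`, and the
family-wise 0.05 default is used in reports.

ROC analysis uses AUC = U/(n₁·n₂).  The reported AUC is oriented to be
≥ 0.5 with the direction recorded and the raw value preserved (a variable
can genuinely discriminate "downward").  The 95% CI is the 2.5/97.5
percentile interval of 2000 stratified bootstrap replicates (resampling
within each group, sizes preserved).  The operating threshold maximizes
Youden's J = sensitivity + specificity − 1 over the observed cut-points —
the conventional default when no costs are specified — and accuracy,
sensitivity and specificity are reported at that threshold.

## Dimensionality: sequential Tracy-Widom testing

Under the null of uncorrelated variables, the largest eigenvalue ℓ of an
n x p white Wishart matrix satisfies (ℓ − μ)/σ → TW1 with the Johnstone
constants μ = (√(n−1) + √p)², σ = (√(n−1) + √p)(1/√(n−1) + 1/√p)^{1/3}.
The k-th test treats the remaining eigenvalues as such a problem of
effective dimension p = m − k + 1, rescales the leading remaining
eigenvalue by n / mean(remaining) so the null scale is restored after
earlier components are removed, and stops at the first non-significant
component (α = 0.001).  The count of passed tests is the estimated number
of signal components.

The TW1 CDF is computed from the Painlevé II representation: the
Hastings-McLeod solution q of q″ = sq + 2q³ (q ~ Ai(s) at +∞) is
integrated once, together with ∫q and ∫(x−s)q², from s = 10 down to
s = −10 (RK45, rtol 1e-11), giving
F₂ = exp(−∫(x−s)q²) and F₁ = √F₂ · exp(−½∫q).  The resulting spline is
cached per process.  A shifted-gamma moment-matching approximation was
considered and rejected: its α = 0.001 quantile is off by 0.026, while the
requirement here is agreement within 1e-2 of the published critical values
(0.9793 / 2.0234 / 3.2724 at 95/99/99.9%); the ODE route agrees to ~2e-4.

Caveats: the sequential scheme is calibrated for residuals that look like
white noise.  If the variables carry strongly heterogeneous residual
variances after autoscaling, lower-order tests become anti-conservative;
the simulation tests therefore plant signal through constant-diagonal
(circulant) correlation structures where the null behavior is exact.

## Random-Forest classification and permutation significance

Groups are compared with a Random Forest (scikit-learn, 500 trees by
default, √m feature subsampling).  Class imbalance is neutralized by the
resampling scheme: per iteration an equal-size training sample of
⌊0.85 · min(n₁, n₂)⌋ subjects per class is drawn without replacement, the
forest is scored on all remaining subjects, and accuracy, sensitivity,
specificity and AUC are averaged over 100 iterations with percentile 95%
CIs.  For the default design (661 men, 183 women) the per-class training
size is ⌊0.85 · 183⌋ = 155.

Significance uses a label-permutation null: the complete resampled fit is
re-run on K permuted label vectors and

    p = (1 + #{null ≥ observed}) / K.

This exact form is the contract: its floor is 1/K (0.001 at K = 1000) and
its ceiling (1 + K)/K, marginally above 1.  Variable importance is the
mean decrease in Gini impurity (scikit-learn's normalized impurity
importance); per-variable permutation p-values compare each variable's
importance to its own permutation null, and are reported uncorrected and
Bonferroni-adjusted side by side — importance permutation tests of this
kind are known to lose power under correction, and neither convention is
endorsed.

## Association networks: shrinkage GGM gated by PCLRC

**Edge weights.**  Partial correlations come from the analytic shrinkage
estimator: the sample correlation matrix R is replaced by
(1−λ*)R + λ*I with

    λ* = Σ_{i≠j} V̂ar(r_ij) / Σ_{i≠j} r_ij²   (clipped to [0, 1]),

inverted, and scaled to partial correlations
r̃_ij = −ω_ij/√(ω_ii ω_jj).  Shrinkage guarantees a well-conditioned
inverse for groups barely larger than the panel (smallest default stratum:
56 women vs 21 fractions).  If every off-diagonal correlation is zero the
intensity is 1 with a warning.  No Python implementation of this estimator
ships with the scientific stack, so it is implemented here and checked
against a pseudo-inverse partial-correlation oracle at λ = 0 and against
planted-precision-matrix recovery.

**Edge selection.**  PCLRC repeats, on each of Niter = 1000 subsamples of
⌊0.75 n⌋ rows: compute the absolute association matrix (shrinkage partial
correlations by default; Pearson correlations available as the alternative
reading of the algorithm's coupling with the GGM), CLR-transform it —
z_i(j) = max(0, (A_ij − mean_i)/sd_i) against each node's off-diagonal
background, combined as s_ij = √(z_i(j)² + z_j(i)²) — and mark the top
rank_thr = 0.3 fraction of the *predicted* interactions, i.e. the pairs
with strictly positive CLR score (ties at the quantile cutoff all kept).
The selection probability P_ij is the fraction of iterations in which the
pair was marked, and the final network keeps w_ij = r̃_ij where
P_ij ≥ 0.95, exactly zero elsewhere.

Two design choices deserve a note.  First, the stability score is computed
on the same quantity that becomes the edge weight (partial correlations
inside the subsamples), the most literal reading of replacing correlations
by partial correlations throughout.  Second, the per-iteration cutoff is a
quantile of the positive CLR scores, not of all pairs: thresholding all
m(m−1)/2 pairs keeps so deep a cut (63 of 210 pairs at m = 21) that pairs
elevated only by full-sample sampling noise — which recurs across
overlapping subsamples — acquire stable probabilities above 0.95, and
planted-edge precision collapses to ~0.5.  Restricting the quantile to the
above-background pairs restores precision ≥ 0.8 at perfect recall in the
recovery simulations (5 strong edges, n = 600, 5 seeds) while keeping the
advertised "fraction of predicted interactions" semantics.

Because subsampling depends on row order, network inference canonicalizes
the row order (sorted sample identifiers) so shuffled inputs give
identical networks.

## Differential connectivity and topology

Node connectivity is Χ_i = Σ_{j≠i} |w_ij| — absolute values, since a
strongly negative partial correlation contributes to a node's wiring just
as a positive one does (equivalently: the row sum of |W| with unit
diagonal, minus the self-term).  Differential connectivity
Δ_i = Χ_i^A − Χ_i^B is z-scored across the m = 21 nodes with the sample
standard deviation (m−1 denominator), and |z| > 2 flags a node (the sign
says which network is more wired).  Identical networks make σ(Δ) = 0; the
report is then all-null with a warning rather than dividing by zero.

Topology profiles are computed on the binarized masked network (the named
measures are standard unweighted ones): average shortest path length,
betweenness, closeness (component-wise), clustering coefficient, degree,
eccentricity, neighborhood connectivity, number of undirected edges,
radiality, stress, and topological coefficient are the default set; degree
centrality, harmonic closeness, local efficiency and eccentricity
centrality are available as extras through the `measures` argument.
Disconnected pairs are excluded from shortest-path averages; isolated
nodes take clustering 0, eccentricity 0, closeness 0, so profiles contain
no missing values.  Stress and the topological coefficient have no
networkx counterpart and are implemented by direct enumeration (the
networks have 21 nodes; cost is irrelevant), and are tested against
independent brute-force oracles.

Cross-condition node comparison min-max scales the two profiles jointly
per measure — without this, count-valued measures such as Stress dominate
the angle — then takes d_i = 1 − cos(v_i^A, v_i^B) per node, z-scored
across nodes, with both z > 1 and z > 2 selections reported.  A node whose
profile is all-zero in either condition gets d = 1 with a warning.  Joint
PCA of the stacked node x measure matrices (rows = node x condition,
autoscaled, constant columns dropped with a warning) gives a score space
in which paired nodes are directly comparable.

## COVSCA

The K group networks (masked signed weight matrices; possibly indefinite,
which the Frobenius loss does not mind) are decomposed as

    S_k ≈ Σ_{l=1}^{L} c_kl Z_l Z_lᵀ,   c_kl ≥ 0,

with L = 2 prototypes of rank 2 by default.  Fitting alternates (a) exact
per-k nonnegative least squares for c over the vectorized prototype outer
products, and (b) for each prototype, the best PSD rank-R_l approximation
(top clipped eigenpairs) of the coefficient-weighted residual aggregate
Σ_k c_kl (S_k − Σ_{l'≠l} c_kl' Z_l' Z_l'ᵀ) / Σ_k c_kl².  Both half-steps
solve their subproblem exactly, so the recorded loss trace is
non-increasing; 10 random starts (default) guard against local minima.
Goodness of fit is 100·(1 − Σ‖S_k − Ŝ_k‖²_F / Σ‖S_k‖²_F): 100% for a
perfect fit, and exactly attained (to tolerance) on noiseless
model-generated input.

Scale indeterminacy is fixed by reporting prototypes with unit-Frobenius
Z_l Z_lᵀ and absorbing the scale into the coefficients; the order of the
dimensions is arbitrary, so comparisons align dimensions by best
|correlation| matching first.  Reported loadings are pruned by z-score
across the m entries at |z| ≥ 1 — two-sided, because loadings are signed —
with a constant column pruning to all zeros with a warning.  L and the
ranks are user choices, not selected automatically.

## Synthetic cohorts and ground-truth generators

`generate_cohort` draws, per subject, a latent Gaussian vector on the
square-root concentration scale: mean √(median of the subject's group),
standard deviation `noise_sd`·√(men's reference median) — identical across
groups, so the square-root transform is *exactly* variance-stabilizing by
construction (verified by Levene tests across strata) — and correlation
from a class-block matrix (default 0.6 within a density class, 0.2
between; positive-definiteness checked before sampling).  Squaring gives
strictly positive, right-skewed concentrations whose group medians follow
the design's effect table.  The default design: 844 subjects, 661 men /
183 women; age strata YM = 216 (median 29), OM = 213 (median 52),
YW = 56 (median 27), OW = 60 (median 55), with stratum boundaries at
35/45 (men) and 37/48 (women) years and ages drawn from per-stratum
triangular distributions hitting the target medians.  The default group
median table is a reference set of healthy-donor values; `noise_sd` = 0.12
(sqrt-scale CV) was chosen once as a realistic biological-variation level
that keeps all draws positive by a wide margin.

What the generator does *not* emulate: measurement error structure of NMR
quantification, lipoprotein subclasses, non-Gaussian tail behavior,
covariate effects other than sex and age, and any dependence between age
and the fraction correlations within a stratum.  Tests passing on this
cohort show the machinery behaves as specified under its own assumptions;
they do not certify performance on real donor data.

`generate_from_planted_network` samples a Gaussian whose precision matrix
has unit diagonal and off-diagonal −r_ij, so the partial correlations of
the sampled law equal the planted values exactly; `generate_covsca_instances`
builds matrices exactly from the prototype model with positive
coefficients (optional symmetric noise).  Both return their ground truth
for recovery tests.

## Problem sizes and numerical conventions

Resampling counts are configurable everywhere; the published-scale
defaults (Niter = 1000, 100 resamples, K = 1000 permutations, 2000
bootstrap replicates) are expensive in combination, so the test suite and
the acceptance script run the same code at reduced counts chosen to keep
each check's Monte-Carlo error well inside its assertion margin
(networks at Niter = 200; Random-Forest fixtures at tens of resamples and
permutations; ROC bootstraps at 50–400 where only the interval's coverage
is asserted).  Quantiles are linear-interpolation throughout; standard
deviations use the n−1 denominator; all randomness flows from a single
root seed split per stage via `numpy.random.SeedSequence`, so any fixed
seed reproduces every artifact byte for byte.

## Known limitations

* The PCLRC probability mask (p_ij ≥ 0.95) is the only edge-selection rule
  implemented; the shrinkage-GGM literature's local-FDR model selection is
  not reproduced.
* The sequential Tracy-Widom count assumes white residuals after
  autoscaling (see above).
* Permutation p-values follow the printed (1 + #)/K convention rather than
  the (1 + #)/(K + 1) variant; at K = 1000 the difference is a thousandth.
* The "15 topological measures" convention in the field is larger than the
  canonical named set; the default here is the 11 standard measures, with
  4 documented extras available, rather than inventing unnamed ones.
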