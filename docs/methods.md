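# Methods

This note documents the models implemented in `cercodent`, the choices made
where the design was genuinely open, and what the synthetic-data tests do and
do not establish.

## Traits

Four maxillary dental traits are computed from mesiodistal crown length (L)
and buccolingual breadth (W), in mm, of P4, M1, M2 and M3:

| trait | definition | units |
|---|---|---|
| 2D area (per molar) | L × W | mm² |
| MMC | L(M3) / L(M1) | — |
| PMM | L(M2) / L(P4) | — |
| IC | area(M3) / area(M1) | — |

Ratios are computed **per specimen**, requiring both component teeth on one
side, and only then averaged — never as ratios of group means. Left-side
measurements are preferred; a trait falls back to the right side when any
left tooth it needs is absent, and sides are never mixed within one trait
(a property test exercises random missingness patterns). Interstitial wear
is not modelled.

Aggregation for comparative analyses is two-level and unweighted:
specimen → species mean → genus mean, so heavily sampled species do not
dominate a genus. The 2D areas are geometric-mean size-corrected at the
level entering the ANOVA: each area is divided by the geometric mean of the
observation's three molar areas, making the corrected values invariant to
overall size. Descriptive kurtosis is the Pearson moment ratio m₄/m₂²
(non-excess; a normal sample gives ≈ 3), matching the `moments` convention.

## Pedigree variance decomposition

The phenotypic covariance among pedigree members is modelled as

    Cov(y) = σ²_G A + σ²_E I,    h² = σ²_G / σ²_P,   σ²_P = σ²_G + σ²_E,

with A the additive (numerator) relationship matrix, built by the tabular
recursion with founders unrelated and non-inbred (A_ii = 1 + F_i). Fitting
is maximum likelihood, not REML, so nested models are comparable by
likelihood-ratio tests; σ²_G therefore carries the usual small-sample
downward bias (documented, accepted). The likelihood is profiled in one
dimension: a one-time eigendecomposition A = UDUᵀ diagonalises the
covariance for any h², the fixed effects are solved by weighted least
squares and the total variance analytically, leaving a bounded 1-D search
over h² ∈ [0, 1) (Brent; deterministic, no restarts). A brute-force
grid/dense-matrix oracle confirms likelihood equivalence to 1e-6 log-units.

Per-trait workflow (mirroring the heritability table machinery):

1. restrict A to phenotyped individuals;
2. screen sex and age (age as a linear term only — it proxies wear) inside
   the variance-decomposition likelihood: a joint LRT, then drop-one
   marginal LRTs at α = 0.05, all non-boundary χ²;
3. form residuals from the retained-covariate GLS mean model and record
   the covariate burden 1 − var(resid)/var(y), clamped to [0, 1];
4. rank-based inverse-normal transform with Blom offsets,
   z = Φ⁻¹((r − 3/8)/(n + 1/4)), mid-ranks for ties;
5. fit h² on the transformed scale. Because the transform fixes the scale,
   the covariate burden must be (and is) computed on the raw scale in
   step 3.

The order — screening on the raw scale, normalisation of the final
residuals — was an open point; this package fixes it as stated. Shared
environment (cage/household) components are not modelled.

Significance of h² uses the boundary LRT: Λ = 2(llₐ − ll₀) referred to a
½:½ mixture of a point mass at zero and χ²₁, i.e. the χ²₁ tail halved
(p = 0.5 exactly at Λ = 0). The standard error of h² comes from the
curvature of the profile log-likelihood at the maximum and is flagged
unreliable within 0.02 of either boundary. When A has no off-diagonal
structure (no family information) the model raises an unidentifiability
flag instead of pretending to estimate.

## Comparative methods

All tree analyses run on a rooted ultrametric chronogram with branch
lengths in Ma. Ultrametricity is checked to a relative tolerance of 1e-6 of
tree depth; failures set a warning flag rather than aborting, since
published chronograms often carry rounding jitter. Internal nodes are
addressed by the tip set whose MRCA they are — node numbers of particular
software traversals are not portable. Taxa missing from a chronogram are
grafted onto a sister's terminal branch at a stated split age (both
daughter branches get that length, preserving ultrametricity); the default
use is adding a congener at 1.3 Ma.

Under Brownian motion the tip covariance V has entries equal to shared
root-to-MRCA path lengths. Rates are estimated from Felsenstein's
standardized independent contrasts: the contrast sum of squares equals the
GLS quadratic form, so σ̂² = Σu²/n (ML, default) or Σu²/(n−1) (REML
toggle). Polytomies are resolved arbitrarily with zero-length branches,
which leaves V unchanged.

**Blomberg's K** is (MSE₀/MSE) / E[MSE₀/MSE] with MSE₀ about the
phylogenetically corrected mean, MSE the GLS mean squared error, and
expectation (tr V − n/(1ᵀV⁻¹1))/(n − 1). The randomization test shuffles
tip values; its statistic is the *sample variance* of the standardized
contrasts, not their mean square — the mean square equals the GLS quadratic
form, which is permutation-invariant on a star tree and would make the
test degenerate there. p-values use +1 smoothing, (1 + hits)/(1 + n_perm),
so 0 is never reported; permutation counts default to 999 and the
configuration refuses fewer than 99.

**Phylogenetic ANOVA**: the observed F is an ordinary one-way ANOVA of
species tip values by genus; the null F distribution comes from BM
simulations on the tree with the rate estimated from the data (F is
scale-invariant, so the rate only matters through the tree structure).
Per-genus p-values are a documented interpretation, not a printed formula:
each genus mean's absolute deviation from the grand mean is compared with
its own simulated null distribution (two-sided by construction). Genera
with no data are dropped with a warning.

**Ancestral state reconstruction**: the ML state of an internal node under
BM equals the GLS root estimate after re-rooting there,
â = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹x. Re-rooting is implicit through patristic distances
(V_r[i,j] = (d(r,i) + d(r,j) − d(i,j))/2), so no tree surgery is needed.
The estimate's variance is σ̂²(1ᵀV⁻¹1)⁻¹ and the 95% CI is ±1.96 SD.
Because the GLS weights form a convex combination of tip values, every
reconstruction lies inside the observed tip range — this is the mechanism
behind systematic under-estimation of fossil trait values and is asserted
directly in the tests. Estimates agree with `phytools::fastAnc` to 1e-5
(variances after selecting the REML rate, which is what fastAnc uses) and
with a brute-force grid maximization of the joint BM likelihood to 1e-4.
Signal tests run on species tips; ASR is run at whichever level the
supplied tip values represent (the genus level mirrors the published
node table), since both levels cannot be distinguished from the text.

## ASR–fossil gap

Pairings of nodes (or extant tips) with candidate fossil genera are data,
not inference: the pairing table carries two explicit subsets rather than
hard-coded rules, because the printed per-trait averages use the 11
internal-node pairings while the "all but two" direction counts reconcile
only when the two tip pairings are included and the deepest
(Victoriapithecus) pairing excluded. Ties (ASR = fossil) count as "not
lower". Aggregates are reported unrounded plus half-up-rounded to 3
decimals to match printed values. Fossil ages are ranges; midpoints are
used for plotting.

## Synthetic data

The generators produce inputs with the statistical structure the analyses
assume, so every stage is testable without deposited data.

* **Pedigree**: non-overlapping generations from a founder cohort
  (default 60 founders, 6 generations — the structure of a large managed
  breeding colony), random mate assignment avoiding full-sibling matings,
  ~1:2 male:female ratio, ages 8–32 with older generations older. Expected
  total size follows the branching process n₀(rᵍ − 1)/(r − 1) for
  per-capita offspring rate r.
* **Pedigree traits**: y = Xβ + g + e with g generated by the Mendelian
  sampling recursion g = (g_sire + g_dam)/2 + m,
  m ~ N(0, σ²_G/2 · (1 − (F_s + F_d)/2)); inbreeding coefficients come from
  a memoized pairwise-kinship recursion, so no O(n²) matrix or
  factorization is needed and very large pedigrees stay cheap. Equivalence
  with the covariance route is asserted on small pedigrees (full-sib
  covariance 0.5σ²_G; inbred diagonal 1 + F).
* **Crown metrics**: per specimen and side, M1 is drawn around a size
  target, M3 length = MMC × realized M1 length, M2 length = PMM × realized
  P4 length, and M3 breadth realizes the IC area ratio; every metric
  carries multiplicative lognormal noise with coefficient of variation cv
  (median on target, so cv = 0 recovers targets exactly). The default
  cv = 0.05 matches typical odontometric repeatability. Left/right
  missingness is configurable to exercise the side-fallback rule.
* **Clades**: one BM realization recorded at every node (default rates
  0.002–0.004 per Ma and roots 1.1/1.55/1.2 for MMC/PMM/IC, plausible for
  cercopithecid ratio traits), with "fossil" observations at internal
  nodes equal to the true node state plus observation noise plus an
  optional trend × node-age term. A positive trend makes older fossils
  larger — a trait that declined toward the present — which reproduces the
  systematic ASR-below-fossil pattern by construction.

What the generators do **not** emulate: real measurement protocols and wear,
taphonomy, non-Brownian evolution (no OU or rate shifts), assortative
mating or overlapping generations, and shared-environment effects. Passing
tests therefore show that the estimators recover the truth under their own
assumptions at realistic sizes, not that those assumptions hold for any
particular empirical dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale problem sizes
chosen to give tight Monte-Carlo bands: heritability recovery on a
~600-member, 3-generation pedigree (50 replicates per true h², mean bias
≤ 0.05); null calibration of the boundary test at 500 replicates
(empirical rejection in [0.02, 0.08]); K calibration at 500 BM replicates
(mean in [0.9, 1.1]) and ANOVA type-I error at 200 runs of 199 simulations
each; clade experiments over 200 seeds on a 9-tip chronogram of depth
10 Ma. Fixture arithmetic is exact.

Degenerate inputs are handled explicitly rather than numerically: constant
traits refuse signal tests; identical tip values give F = 0 and p = 1;
singular BM covariances (zero-length branches) use eigenvalue-clipped
factors and pseudo-inverses; optimisation failures (negative likelihood
ratios beyond 1e-6) raise rather than clamp silently.

## Known limitations

* ML variance components are biased downward in small samples; no REML
  option is provided on the pedigree side because the LRT framework
  requires comparable likelihoods.
* The per-genus ANOVA p-values are an interpretation of a printed table
  without a published formula (flagged above).
* Blomberg's K is computed for the tip set as given; no measurement-error
  or within-species sampling correction is applied.
* The gap analysis takes node–fossil pairings as supplied; it does not
  infer ancestor–descendant relationships.
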