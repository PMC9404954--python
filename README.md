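# cercodent

Dental-trait evolution toolkit for cercopithecid monkeys (and, with your
own inputs, other mammals): compute genotype:phenotype-mapped crown traits
from linear metrics, estimate their heritability on a pedigree, test
phylogenetic signal and genus-level differentiation on a time-calibrated
tree, reconstruct ancestral states under Brownian motion, and quantify how
far those reconstructions fall from the values actually observed in
fossils.

## The problem

Paleontologists traditionally summarise molar size as two-dimensional
occlusal area (mesiodistal length × buccolingual breadth), a trait that
mixes dental patterning genetics with body-size and sex effects.
Quantitative genetics and developmental biology suggest ratio traits that
isolate the dental genetic architecture:

* **MMC** (molar module component) = L(M3)/L(M1),
* **PMM** (premolar–molar module) = L(M2)/L(P4),
* **IC** (inhibitory cascade trait) = area(M3)/area(M1).

This package implements the full analysis chain around these traits:

* **Heritability** — maximum-likelihood variance decomposition on a
  pedigree, Cov(y) = σ²_G·A + σ²_E·I with A the additive relationship
  matrix; h² = σ²_G/σ²_P, tested with the boundary LRT (½:½ mixture of a
  point mass at 0 and χ²₁; the χ² tail p is halved). Covariates (sex, age)
  are screened by non-boundary LRTs and residuals are inverse-normal
  transformed before fitting.
* **Phylogenetic signal** — Blomberg's K with a tip-shuffling
  randomization test on the variance of standardized independent
  contrasts; K ≈ 1 under Brownian drift, K < 1 suggests departures such as
  selection.
* **Phylogenetic ANOVA** — observed one-way F of species values by genus
  against a null distribution of F from BM simulation on the chronogram.
* **Ancestral state reconstruction** — per-node ML states under BM via the
  GLS estimate â = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹x on the re-rooted covariance, with
  variances σ̂²(1ᵀV⁻¹1)⁻¹. Estimates are convex combinations of tip
  values, so they can never leave the extant range — the formal reason ASR
  alone underestimates fossil variation ("the tyranny of the present").
* **ASR–fossil gap** — pair internal nodes with candidate fossil genera
  and report per-pairing signed/absolute differences, per-trait mean
  absolute gaps and direction counts.

A synthetic-data module generates pedigrees with additive genetic
covariance (Mendelian sampling), crown metrics realizing target trait
ratios, and BM trait evolution on chronograms with optional directional
trends and noisy fossil observations — so every stage is testable without
any deposited data. The printed reference tables (sample composition,
heritability table, trait summaries, node–fossil pairings) ship as
packaged fixtures: `load_fixture("table1"|"table2"|"table3"|"table5"|"table8")`.

## Worked example

The packaged node–fossil pairing table reproduces the headline gap
analysis in one call:

```python
>>> import cercodent as cd
>>> print(cd.gap_from_fixture().summary())
ASR vs fossil gap report
  MMC: mean |ASR - fossil| = 0.066364 (~0.066) over 11 pairings; ASR >= fossil in 2/12 direction-subset pairings
  PMM: mean |ASR - fossil| = 0.161818 (~0.162) over 11 pairings; ASR >= fossil in 2/12 direction-subset pairings
```

Reading: over the eleven internal-node pairings the reconstruction misses
the fossil value by 0.066 (MMC) and 0.162 (PMM) on average — the
premolar–molar trait is underestimated more than twice as much — and in
ten of the twelve direction-subset pairings per trait the reconstruction
sits *below* the fossil.

Heritability on a simulated three-generation pedigree (true h² = 0.6 and a
1-SD male effect):

```python
>>> spec = cd.PedigreeSimSpec(n_founders=90, n_generations=3,
...                           mean_offspring=1.2, h2_true=0.6,
...                           sex_effect=1.0, seed=77)
>>> ped = cd.simulate_pedigree(spec)
>>> vals = cd.simulate_pedigree_traits(ped, spec, seed=78)
>>> covars = ped.set_index("id")[["sex", "age"]].copy()
>>> covars["sex"] = (covars["sex"] == "M").astype(float)
>>> res = cd.heritability_analysis(vals["y"], ped, covars,
...                                trait_name="MMC (simulated)")
>>> print(res.summary())
Variance decomposition: MMC (simulated)
  n = 321
  h2       = 0.5860  (se 0.1098)
  sigma_G2 = 0.5981
  sigma_E2 = 0.4225
  sigma_P2 = 1.0206
  loglik   = -432.4730  (null -453.6293)
  p(h2=0)  = 3.89e-11  [boundary LRT, halved]
  covariates = sex  (proportion of variance 0.230)
```

The estimate (0.586 ± 0.110) brackets the simulated truth, the sex
covariate is detected and its share of the raw phenotypic variance
reported, and the halved boundary-LRT p-value is decisive.

There is also a CLI (`cercodent traits|h2|phylosig|phyloanova|asr|gap|simulate|run`)
and a YAML-configured pipeline (`cercodent.run_pipeline`) that writes every
stage's output as CSV plus a run log; reruns with the same seed are
byte-identical.

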