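# Methods

`admixscan` implements admixture mapping of quantitative phenotypes
(circulating metabolites being the motivating application) in cohorts
descended from three ancestral populations — African (AFR), European
(EUR), and Native American (NAM) — together with the synthetic-data
generator needed to validate every stage without access to restricted
cohort data.

## The model

For each phenotype a null linear mixed model is fitted once by REML:

    y = X beta + u_g + u_h + u_c + e
    u_g ~ N(0, sigma_g^2 * 2K)        genetic relatedness (kinship K)
    u_h ~ N(0, sigma_h^2 * Zh Zh')    shared household
    u_c ~ N(0, sigma_c^2 * Zc Zc')    census-block neighbourhood
    e   ~ N(0, sigma_e^2 * I)

X contains an intercept, age, sex, an eGFR-like continuous covariate,
recruitment-center and sampling-group indicators, and a population
structure adjustment: either the first five genotype principal
components or two of the three genome-wide ancestry proportions
(the third is collinear).  Kinship enters as 2K (numerator-relationship
scaling); the factor is configurable.

With the variance components held fixed at their null-model estimates,
every association test is a generalized-least-squares Wald test of a
covariate block W added to X:

    gamma_hat = S^{-1} W*' V^{-1} y,   S = W*' V^{-1} W*,
    chi2 = gamma_hat' S gamma_hat on df = rank(W after projection on X),

where W* is W residualized on X in the V inner product.  Tested blocks:

* **joint admixture test** — the three local-ancestry dosages at a
  region sum to 2, so the test has 2 df; the ancestry with the largest
  mean dosage is dropped as reference.  The statistic is invariant to
  the choice of reference (unit-tested to 1e-10).
* **ancestry-specific tests** — each dosage alone (1 df, that ancestry
  against the others).  The *driving ancestry* is the smallest
  ancestry-specific p, ties broken by larger |statistic| then the fixed
  order AFR < EUR < NAM (exact ties arise only on degenerate fixtures).
  Reported effect sizes come from the driving ancestry's 1-df model.
* **SNV tests** — allele count as a single covariate.

Multiplicity is Bonferroni over metabolites × regions at family-wise
alpha 0.05; with 640 metabolites and 15,500 local-ancestry regions the
genome-wide gate is 5.04e-9.

### REML

Average-information REML with step halving, an EM fallback when the AI
update is not an ascent direction, and boundary handling: a component
proposed negative is projected to the floor, and a floor-pinned
component with a negative gradient (or one projected negative twice) is
fixed at zero.  Convergence is a REML log-likelihood change below 1e-6
(max 100 iterations); unconverged fits are flagged and downstream tests
refuse them.  Accepted iterations never decrease the objective.

### Solving with V

V = sigma_g^2·2K + sigma_h^2·ZhZh' + sigma_c^2·ZcZc' + sigma_e^2·I is
block diagonal over the connected components of the combined
relatedness graph (kinship nonzeros ∪ shared household ∪ shared block).
The solver groups components by size and batches the per-block
factorizations, so a cohort of 1,000 with sib pairs, households of 4
and 4-household blocks fits in ~10 ms.  A fully dense kinship matrix
collapses to one block and degrades gracefully to an O(n^3) dense
solve.  This is exact, not an approximation.

## Post-scan refinement

* **Conditional region analysis.**  Local ancestry tracts average
  100/g ≈ 6.7 cM after g = 15 generations, so neighbouring significant
  regions are correlated (admixture-LD).  Per metabolite, the smallest-p
  region anchors; every other surviving significant region whose
  midpoint is within 10 cM (same chromosome) is re-tested with the
  anchor's driving-ancestry dosage as a fixed covariate and kept only if
  the conditional joint p stays below 5e-5.  Survivors anchor in turn
  (descending significance) until no unresolved pair remains.  A region
  whose dosages are collinear with the conditioning dosage (perfect
  admixture-LD) is recorded as non-independent.
* **SNV selection.**  Within an independent region, mutually independent
  associated SNVs are chosen by forward stepwise conditional regression
  on individual-level data at entry threshold 5e-8, with near-collinear
  candidates (R² > 0.99 with the selected set) skipped and one backward
  pruning pass on the final joint model.  This is the
  conditional-and-joint selection target computed exactly, rather than
  the summary-statistic approximation with an external LD reference
  panel; the two have the same inferential target, and the exact version
  is testable against an all-subsets enumeration oracle (≤ 8 SNVs),
  which the test suite exercises.
* **Conditioning decision.**  Each selected SNV enters singly as a
  covariate of the joint admixture test; the region's signal is
  *explained_by_single* if any conditional joint p rises above 5e-5,
  else all selected SNVs enter jointly (*explained_by_set* on the same
  rule), else *not_explained*.  A region with no SNV passing the entry
  threshold has nothing to condition on and is classified
  *not_explained*.  The decision is monotone in the threshold: raising
  it never converts explained to not-explained.
* **Novelty.**  A region is novel when no known significant variant
  (user-supplied positions or BED intervals) falls in
  [start_bp, end_bp) — inclusive start, exclusive end.
* **Replication.**  Independent associations are re-tested in a second
  cohort with the same model; the threshold is alpha divided by the
  number of replication tests (0.05/404 = 1.24e-4 at the reference
  study size; the exact quotient is the default, and the threshold is
  configurable).  Reported concordance: sign of the discovery driving
  ancestry's effect, and identity of the driving ancestry.

## Phenotype preparation

Metabolites with ≥ 25% missing samples are excluded (strict boundary:
exactly 25% is excluded); remaining missing values are imputed with the
metabolite's observed minimum (the platform's left-censoring
convention); each metabolite is then rank-based inverse-normal
transformed, Phi^{-1}((r − c)/(n − 2c + 1)) with Blom offset c = 3/8 and
average ranks for ties.  Order is filter → impute → transform; both the
cutoff and the offset are parameters.  The transform convention and the
impute-before-transform order are package choices (several conventions
coexist in metabolomics practice); both only affect results through
monotone rank maps.

## Synthetic cohorts

The generator produces exactly the inputs the analysis consumes:

* **Structure.**  Declared relationships: sibships with pairwise kinship
  0.25 (0.5 self), sib pairs sharing a household, households of 4
  grouped 4 per census block.  Sibships larger than two spread over
  consecutive households — a sibship that coincides exactly with a
  household would make sigma_g^2 and sigma_h^2 jointly unidentifiable.
* **Tracts.**  Per haplotype, ancestry switch points form a Poisson
  process at rate g per Morgan (default g = 15) and each tract's
  ancestry is an independent draw from the individual's proportion
  vector, itself Dirichlet(30 × group mean) around group means
  mainland-like (0.10, 0.45, 0.45) and caribbean-like
  (0.35, 0.50, 0.15), 60/40 mixture.  This yields mean tract length
  L/(gL_M + 1) ≈ 100/g cM and the admixture-LD decay scale the
  conditional analysis relies on, without a pedigree-explicit
  recombination simulation.  Adjacent tracts may repeat an ancestry;
  tracts are delimited by switch points, keeping the 100/g expectation
  exact.
* **Genotypes.**  Per-ancestry allele frequencies default to
  Balding–Nichols draws around a shared ancestral frequency with
  differentiation Fst = 0.12 (continental scale), so genome-wide
  genotypes are ancestry-informative and principal components track
  admixture proportions, as with real array data.  A haplotype's allele
  is Bernoulli with the frequency of the tract ancestry covering the
  site.
* **Phenotypes.**  y = Xβ + causal ancestry/SNV effects + u_g + u_h +
  u_c + e with default components (0.30, 0.10, 0.05, 0.55) — roughly
  30% heritability, typical of serum metabolites — and
  missing-completely-at-random entries at a configurable rate.

What the generator does **not** emulate: realistic haplotype-level LD
within ancestries (SNVs are independent given local ancestry, except
constructed proxies in tests), assortative mating, X chromosome,
phasing or local-ancestry inference error, survey weighting, and
non-MCAR missingness.  Passing tests therefore validate the statistical
machinery under the model's assumptions, not robustness to these real
data features.

## Validation studies and problem sizes

`admixscan.studies` (run by `scripts/acceptance.py` and
`tests/test_acceptance.py`) regenerates each claim from scratch:

* threshold arithmetic (exact);
* mean tract length at g = 15 on 1,000 haplotypes × 35 Morgans
  (expected 6.65 cM, > 6);
* type-I error of the joint test over 2,000 null phenotypes at n = 1,000
  with full structure, each with its own REML fit (warm-started from the
  previous fit's estimates — the phenotypes are exchangeable draws from
  one model, so this accelerates convergence without changing the
  estimates);
* Wald statistics vs an explicit dense-matrix GLS oracle at n = 30;
* stepwise SNV selection vs all-subsets enumeration on 6-SNV fixtures;
* variance-component recovery over 200 replicates at
  (2, 1, 0.5, 1) with 250 sib pairs at n = 1,000, and driving-ancestry
  effect recovery (β = −0.5) over 100 replicates;
* a three-planted-signal end-to-end fixture (pure ancestry effect, its
  perfect-admixture-LD duplicate, and an AFR-enriched causal SNV) over
  10 seeds at n = 1,500 on a 10-Morgan genome — the expected outcome is
  two independent regions with decisions not_explained /
  explained_by_single; because the scan controls family-wise error at
  0.05, roughly 1 seed in 20 adds a stray α-level region, which counts
  as a failure under the strict definition used;
* rank concordance of the two covariate modes on a 35-Morgan,
  12,000-SNV fixture (both adjustments must estimate the same structure;
  a short genome or few SNVs breaks the equivalence for reasons that are
  properties of the data regime, not of the method).

## Numerical choices and edge cases

* Collinear tested covariates are dropped by a pivoted-Cholesky style
  greedy pass at relative tolerance 1e-8; df reduces accordingly and
  df = 0 flags the test untestable (e.g., a region where everyone is
  EUR/EUR).
* The conditional design (null X plus conditioning covariates) uses a
  pseudoinverse Gram so conditioning covariates collinear with X are
  tolerated.
* Monomorphic SNVs are skipped in scans and dropped before PCA; PC
  columns are returned orthonormal with the first sample's coordinate
  non-negative.
* Rank-deficient fixed-effect designs are rejected with the collinear
  column names; phenotypes with missing values are rejected (preparation
  must run first).
* Region distance is midpoint-to-midpoint in cM; region intervals are
  half-open [start, end) in both cM and bp.

## Known limitations

Score tests, survey weights, non-Gaussian outcomes, and
summary-statistic (external LD panel) SNV selection are out of scope.
The simulator's independence assumptions above mean power/calibration
numbers transfer to real cohorts only to the extent those assumptions
hold.
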