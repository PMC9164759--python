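# Methods

## Model and assumptions

`metags` implements a meta-analysis of population-level summary statistics
that reproduces joint multi-trait SNP-BLUP across populations. The working
assumptions are those of the underlying model:

* phenotypes are pre-corrected for all fixed effects except a population
  mean, and enter as sire daughter-averages whose residual variance is
  `σ²_e / n_k` with effective daughter count `n_k` (the residual precision
  matrix is diagonal);
* all populations code the same reference allele, so centred design
  matrices and effect estimates are directly combinable;
* every SNP carries the same effect variance within a population
  (`σ²·θ`, with `θ = 1/Σ 2p(1−p)` converting the DGV variance to a per-SNP
  variance), and effects of the same SNP in two populations are correlated
  with the genetic correlation of breeding values, supplied as an input —
  variance components and correlations are *not* estimated here;
* no residual polygenic effect is fitted.

## Mean handling

The single-population equations carry an explicit mean; the
across-population equations carry none. To make the two consistent, the
package absorbs `μ_i` at summary-construction time: `y_i` is centred at its
precision-weighted mean (weights `n_ik/σ²_e,i`) before `Z'R⁻¹y` is formed,
and the shared effects solve `(Z'R⁻¹Z + λI) g = Z'R⁻¹(y − ȳ_w)` with
`λ = 1/(σ²θ)`. This equals fitting the mean and then eliminating it up to
the weighted column means of `Z`, which are ~0 for frequency-centred
genotypes; the joint raw-data solver applies the identical convention, so
the equivalence between the two routes is exact rather than approximate.
The explicit-mean two-block solve is retained (`solve_single_pop`) and is
where the centring-invariance property (estimates independent of the
frequencies used to centre, given a fitted mean) is verified.
`recover_rhs` inverts the absorbed solve, `rhs = (lhs + λI)·ĝ`, so holders
may share effects instead of right-hand sides; the round-trip is exact to
solver tolerance.

## Across-population covariance and solver

The stacked effect prior is `G = Σ ⊗ I_m` with
`Σ_ik = r_ik √(σ²_iσ²_k) √(θ_iθ_k)`; only the c × c `Σ` is inverted and its
scalars are added to the assembled blocks — the dense `G` (c·m × c·m) is
never formed, which is what keeps assembly O(c²m) instead of O((cm)²) in
memory beyond the data blocks themselves. Numerical policies:

* correlation matrices must be positive semidefinite (checked by smallest
  eigenvalue, reported on failure);
* off-diagonal correlations with |r| > 0.999 raise a hard error advising a
  perturbation — silent ridging of a user-supplied correlation would change
  the model without saying so;
* supplied precision matrices are used as-is; asymmetry beyond 1e−8
  relative triggers a warning and `(A + A')/2` averaging;
* the assembled system is solved by Cholesky factorization up to 20,000
  unknowns (ample at desk scale) and by Jacobi-block-preconditioned
  conjugate gradients (relative residual 1e−8) beyond; both paths are
  cross-checked in the tests.

The verification oracle (`metags.oracle`) shares none of this code: it
materializes `G` with `np.kron`, inverts it densely and solves the pooled
system with a generic solver. Agreement between the two is therefore
evidence about correctness, not an identity by construction.

## Rescaling and summary-statistic imputation

`Z'R⁻¹Z` captures the population's (weighted) LD structure; for traits
phenotyped on subsets of the genotyped individuals it differs essentially
by scale, so one matrix built on all α genotyped individuals is rescaled by
`n/α` per trait. The validation protocol masks a fraction of individuals'
phenotypes, rebuilds the matrix from the remainder and compares it
(correlation and regression slope over lower-triangle entries) with the
rescaled full matrix; the subset matrix is unbiased for the rescaled one
under random masking, which the slope test confirms.

For mismatched SNP panels, `T = (Z_i'Z_i)⁻¹ Z_i'Z_c` is estimated per block
of (by default) 200 adjacent SNPs within a chromosome on a reference panel,
making the full `T` block-diagonal and each inverse small. Design choices
where the procedure was genuinely open:

* **Centring:** reference genotypes are column-centred (reference-panel
  frequencies) before forming the cross-products, as uncentred products
  would mix allele-frequency information into the LD regression.
* **Cross-block products:** the imputed precision matrix
  `T'·lhs_i·T` retains cross-block terms `T_a'·lhs_ab·T_b` — the observed
  matrix carries cross-block LD, and discarding it would discard real
  information; the result is symmetrized and PSD by construction.
* **Ridge policy:** with `ridge="auto"` each block uses the exact inverse
  where `Z_i'Z_i` is nonsingular and falls back to a ridge of
  1e−6 × mean diagonal (logged) when a block has at least as many observed
  SNPs as reference individuals or is otherwise rank deficient. With an
  explicit ridge the user's value is used verbatim, and 0 on a singular
  block is an error. Exactness under ridge 0 means observed SNPs'
  statistics pass through unchanged and SNPs in perfect LD with an
  observed SNP are recovered exactly.
* **Fully masked blocks** cannot be imputed (their `T` has no rows); they
  contribute zeros, are counted in the evaluation output, and are not
  fatal.
* Evaluation correlations are computed over masked entries only — masked
  positions of the vectors, masked rows/columns of the matrix — so the
  pass-through of observed entries does not inflate accuracy.

The masking protocol splits a population into thirds (reference for `T`,
training for summaries, evaluation for prediction), mirroring the
independent-reference design, and reports mean and normal-theory 95%
intervals over replicates.

## Synthetic data

The generator produces the study conditions for every test: two (or c)
populations, block-LD genotypes, correlated per-SNP effects and sire-model
phenotypes.

* **Genotypes** — per LD block, a small founder-haplotype pool is drawn
  once and shared by all populations (common ancestral LD, which is what
  makes a reference panel from one population informative about another);
  each haplotype copies a random founder and mutates each site with
  probability μ. With the default two complementary founders every site is
  polymorphic near frequency 0.5 and the dosage correlation between block
  mates is ≈ (1−2μ)², giving the closed-form calibration
  μ = (1 − √r_target)/2; a target of 0 yields μ = ½, i.e. independent
  sites. Blocks are independent, so LD is exactly block-diagonal.
* **Effects** — per SNP, the c-vector of effects is multivariate normal
  with covariance `Σ_ik = r_ik √(σ²_iσ²_k) √(θ_iθ_k)` computed from
  realized frequencies, making E[var(DGV_i)] = σ²_i exactly.
* **Phenotypes** — `y = μ_pop + DGV + e`, `var(e) = σ²_e/n_k`, with `n_k`
  uniform on the configured range: the sire model emulated directly rather
  than via individually simulated daughters (identical distribution,
  far cheaper).
* **Defaults** (chosen once as realistic dairy-evaluation conditions, in
  trait units² where applicable): two populations of 800 and 300 sires,
  2,000 SNPs in 200-SNP blocks with within-block r ≈ 0.8, effect
  correlation 0.5, `σ²_dgv = 1`, `σ²_e = 10` with `n_k ∈ {10..100}` —
  daughter-average reliabilities ≈ 0.5–0.9, typical of progeny-tested
  bulls — MAF filter 0.05 applied jointly across populations so SNP lists
  match by construction, and nonzero population means so mean absorption
  is actually exercised.

What the generator does **not** emulate: LD decaying with distance inside a
block (within-block correlation is near-uniform), admixture or
population-specific LD patterns, selection, pedigree structure, and
non-genetic covariance between relatives. Consequently, passing tests
demonstrate the algebraic and statistical machinery — equivalence of the
summary-statistic and raw-data solvers, unbiasedness of rescaling, LD-based
recoverability of summary statistics — but the *absolute* accuracy numbers
(e.g. imputation correlations near 0.99) are optimistic relative to real
SNP-chip data, where LD is weaker and less regular. The effect-vector
imputation accuracy, by contrast, is pessimistic here: under near-perfect
within-block LD individual effects are barely identified, and its observed
collapse (while right-hand sides remain recoverable) reproduces, in
exaggerated form, the known pattern that effect vectors impute poorly while
`Z'R⁻¹Z` and `Z'R⁻¹y` impute well.

## Problem sizes and determinism

The shipped benchmark scales — 1,100 individuals × 2,000 SNPs for the
equivalence runs, 1,500 × 2,000 for SNP masking (20 replicates), 1,000 ×
1,000 for phenotype masking (100 replicates) — were chosen as the smallest
sizes at which sampling noise is clearly below the effect sizes being
demonstrated; everything completes in seconds to a minute on one core. All
stochastic steps draw from `numpy.random.default_rng` seeded explicitly;
scenario seeds fully determine panels, effects and phenotypes, and the
acceptance script derives all of its seeds from the single `--seed`
argument.

## Known limitations

* Variance components and genetic correlations are inputs; no REML.
* No residual polygenic term, no pedigree, no deregression of proofs.
* The direct solver's dense assembly bounds practical problem size to a
  few tens of thousands of SNP-population unknowns; the CG path relaxes
  the factorization cost but still holds the assembled matrix densely.
* Summary-statistic imputation assumes the reference panel shares the LD
  of the target population; accuracy degrades with relatedness, as for any
  LD-based imputation.
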