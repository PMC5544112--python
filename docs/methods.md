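# Methods

## The estimation problem

A GWAS meta-analysis reports, for each SNP j in a region, the *marginal*
effect O_j — the coefficient of a single-SNP regression of the trait on that
SNP alone — together with its standard error, the effect-allele frequency and
the sample size. Fine mapping asks for the *joint* effects V_j: the
coefficients the SNPs would receive in one multiple regression, each adjusted
for its correlated neighbours. With individual-level genotypes that multiple
regression is trivial; with only summary statistics, the correlation
structure must come from an external phased reference panel.

Most summary-level conditional methods represent LD by the matrix of pairwise
genotype correlations. This package instead uses the region's haplotypes.
Pairwise r² is a two-locus summary: with three or more loci it discards
higher-order dependence, and three-locus systems constrain the attainable
pairwise values. The haplotype frequency vector carries the full joint
distribution of alleles on a chromosome, so an estimator driven by haplotypes
uses strictly more of the panel's LD information.

## Model

From the phased panel we form the K×J binary matrix M of distinct haplotypes
(rows) by SNPs (columns), m_kj = 1 when haplotype k carries the effect allele
of SNP j, and the frequency vector F (F_k > 0, ΣF = 1). Under an additive
model with joint effects V, haplotype k contributes Z_k = (M V)_k. The
marginal effect implied by haplotype effects Z is the difference of
frequency-weighted group means,

    U_j = Σ_{l∈HE_j} F_l Z_l / Σ_{l∈HE_j} F_l  −  Σ_{o∈HB_j} F_o Z_o / Σ_{o∈HB_j} F_o ,

where HE_j / HB_j are the haplotypes carrying the effect / baseline allele of
SNP j. U is linear in Z (U = W Z) and hence in V (U = A V, A = W M). A short
calculation gives A_jl = D_jl / (p_j (1 − p_j)) with D the haplotype-level
covariance D_jl = Σ_k F_k m_kj m_kl − p_j p_l and p_j the effect-allele
frequency; in particular A_jj = 1 identically. Estimation therefore amounts
to inverting the marginal map: find V such that the marginals implied under
the reference panel's haplotype distribution equal the observed ones.

## The iteration

The solver is an empirical fixed-point iteration in haplotype-effect space:

1. draw random initial joint effects V0 (seeded standard normal) and set
   Z = M V0;
2. compute the implied marginals U;
3. pick the SNP x with the largest |U_x − O_x|; shift every haplotype in
   HE_x by δ = O_x − U_x (which sets U_x = O_x exactly and perturbs other
   SNPs only through shared haplotypes);
4. repeat until max_j |U_j − O_j| < 1e-10 ("ten decimal places"), then
   recover V = pinv(M) Z by the Moore–Penrose pseudoinverse. Z provably
   stays in the column space of M (the start and every adjustment are column
   combinations), so for full-column-rank M any left inverse gives the same
   answer; for rank-deficient M the minimum-norm solution is returned with a
   warning.

This is a Gauss–Southwell (greedy coordinate) sweep on the linear system
A V = O. Because A = S D with S = diag(1/(p_j(1−p_j))) and D symmetric
positive semi-definite, A is similar to the unit-diagonal SPD matrix
S^{1/2} D S^{1/2}, and greedy coordinate descent on an SPD quadratic
converges; the convergence rate degrades with the condition number of that
standardized LD matrix, which is why collinear SNPs must be removed first
(see VIF below). Convergence cannot be guaranteed for pathological inputs,
so the iteration carries a cap (default 10^6) and raises an error holding
the residual trajectory rather than returning silently.

The production loop iterates the equivalent marginal-space recursion
U ← U + δ A[:,j] with the per-SNP adjustment totals accumulated, and
reconstitutes Z once at the end; with A's diagonal fixed at its analytic
value 1 this reproduces the explicit haplotype-space sweep step for step
(asserted in the tests) at a fraction of the cost, which matters inside the
2000-replicate bootstrap.

At convergence on a full-rank table the result equals the direct solve of
A V = O — the tests use that as an independent oracle — but the iteration is
the implementation: it needs no matrix inversion, extends unchanged to
rank-deficient tables, and mirrors how the marginal map is defined.

Binary traits are handled on the log-odds scale: O is then a vector of
marginal log-odds ratios and the iteration is scale-agnostic.

## Inputs and harmonization

Summary statistics come in the COJO-style `.ma` text dialect (`SNP A1 A2
freq b se p N`, A1 = effect allele); panels as phased VCF (GT with `|`) or
IMPUTE2 `.haps`. The panel is recoded so 1 means the statistics' effect
allele; when the panel's coding is flipped the column is complemented and
betas are never touched. Unphased or missing genotypes and multi-allelic
records are hard errors — the method assumes a complete pre-phased panel and
this package performs no phasing or imputation. Palindromic A/T and C/G SNPs
are accepted only when the panel frequency matches the reported frequency
within 0.2 under the chosen orientation (standard harmonization practice);
otherwise a strand-ambiguity error is raised. Rare haplotypes are never
pruned: a frequency floor would change the group-mean denominators in the
marginal map.

**Collinearity.** Before fitting, SNPs are screened by variance inflation
factor on reference-panel dosages (consecutive chromosome pairs as
individuals): the SNP with the largest VIF is dropped repeatedly until all
VIF ≤ 7 (ties to the lower column index). Near-duplicate SNPs make the
joint system ill-conditioned and the estimates explode; 7 is the package
default and overridable.

**Chunking.** The estimator targets moderately small marker sets; the `fit`
command splits larger regions into contiguous chunks of at most 20 SNPs,
optionally at user-supplied positions (e.g. recombination hotspots — hotspot
detection itself is out of scope), and fine-maps each chunk independently
without cross-chunk reconciliation.

## Bootstrap standard errors and selection

The joint estimates have no closed-form SE, so uncertainty comes from a
parametric bootstrap. Each replicate simulates a cohort of n_total
individuals by drawing two haplotypes i.i.d. from F (Hardy–Weinberg),
builds the genetic score g = dosage · V with the fitted joint effects as
weights, generates phenotypes — quantitative: y = g + Normal(0, σ²) with σ²
set so the marginal phenotype SD matches the reported one (floored at 10% of
the total variance, with a warning, if the inputs are inconsistent); binary:
Bernoulli(expit(α + g)) with α solved so the mean case probability matches
the reported case proportion — recomputes actual single-SNP regressions, and
re-fits the estimator. The SE is the SD (denominator reps−1) over
replicates, 2000 by default. Replicates that fail to converge are dropped
and counted; more than 1% drops aborts the region as unstable.

Selection proceeds in two stages. A cheap *pre-test* uses the joint
estimates with the marginal SEs — conservative, because a SNP's uncertainty
in a multivariate model is never smaller than in a single-SNP model — and
removes the highest-p SNP above the threshold one at a time, re-fitting
after each removal, until all survivors pass or one SNP remains. If two or
more survive, backward elimination then uses bootstrap SEs: t-tests with
n_total − J − 1 degrees of freedom, eliminating the highest p above the
threshold and re-fitting (estimate + bootstrap) each round. A lone surviving
SNP is tested with its marginal SE, so the final model can be empty (flagged,
not an error). The default threshold is genome-wide significance, 5e-8.

## Simulation bench

`LDModelSpec` describes a region by per-SNP allele frequencies, target
pairwise r² values, and true joint effects. `make_haplotype_frequencies`
builds a distribution over all 2^J haplotypes matching the one-locus margins
and each *specified* pair's covariance D = +√(r² p_j q_j p_l q_l) (positive
root; the sign does not affect r²), by iterative proportional fitting from
the independence product — the maximum-entropy distribution subject to those
margins. Pairs not listed are left unconstrained: forcing unspecified pairs
to r² = 0 is infeasible in general (in the reference three-SNP model below,
r² = 0.8 and 0.5 to the lead SNP force r²(2,3) ≥ ~0.16; the max-entropy fit
gives 0.4), which is itself an instance of the three-locus constraints that
motivate haplotype-based LD. Requested targets are validated against the
Lewontin bound D ≤ min(p_j q_l, p_l q_j) and IPF non-convergence is reported
as infeasibility, never papered over.

The reference three-SNP model — lead SNP with joint effect 1, bystander 0 at
r² = 0.8 to the lead, secondary 0.3 at r² = 0.5 — and a two-SNP MAF-0.08
model (one causal, one null, r² = 0.5 as a representative mid-range value)
ship as `three_snp_model()` / `rare_variant_model()`.

`mse_benchmark` scores the estimator and a pairwise-LD baseline against
multiple regression on individual-level data. Per replicate: a meta-analysis
cohort of n_meta individuals is drawn from the pool, phenotypes are
y = g + Normal(0, 1), the *gold standard* is the multiple regression on that
cohort, marginal statistics come from single-SNP regressions on it, and each
method runs on an independently drawn reference panel of each size. MSE is
the per-replicate mean over SNPs of squared error against that replicate's
gold standard; the result table reports mean, SD, and completed replicates
per method × panel size.

The *pairwise-LD baseline* standardizes marginal betas by √(2p(1−p)), solves
R v = b* with R the panel's dosage correlation matrix, and back-transforms.
It is a deliberately simplified matrix-inversion comparator (no per-SNP
sample-size reweighting), labelled `pairwise_ld` everywhere; it is not a
reimplementation of any published tool. On a panel carrying exact population
LD it provably coincides with the haplotype iteration (both solve the same
population system — a test asserts this); the two differ in how they respond
to panel sampling noise, which is what the benchmark measures.

## What the simulations do and do not show

The generator emulates: HWE genotypes from a fixed regional haplotype pool,
additive phenotypes with Gaussian noise, marginal statistics from one
homogeneous cohort. It does not emulate: mismatched ancestry between panel
and GWAS, imputation error, phasing error, genotyping batch effects,
between-cohort heterogeneity in a meta-analysis, or case-control ascertainment.
Passing tests therefore validate the estimator's internal correctness and
its behaviour under ideal sampling — not robustness to panel/GWAS mismatch,
which with real data is governed by how well the reference panel matches the
study population.

## Numerical choices and problem sizes

- Convergence: max-absolute deviation < 1e-10; iteration cap 10^6;
  argmax ties break to the lowest SNP index.
- Initial effects: seeded i.i.d. standard normal; at convergence on a
  full-rank table the result is seed-independent to 1e-8 (tested).
- IPF: sweep tolerance 1e-13, cap 10 000 sweeps, residual > 1e-8 treated as
  infeasible; haplotypes below 1e-12 mass are dropped and F renormalized.
- Haplotype rows are ordered by descending frequency then lexicographically,
  making all outputs byte-stable under a fixed seed.
- Randomized test instances draw haplotype tables whose standardized LD
  operator has condition number ≤ 100, keeping the coordinate sweeps fast
  and the linear-system oracle well-posed.
- Test/bench problem sizes: the three-SNP benchmark runs 100 replicates at
  n_meta = 100 000 with reference sizes 500–10 000 (the full design uses
  1000 replicates; 100 keeps a desk run under ten seconds while the
  Monte-Carlo SEs remain small enough for the recovery checks); bootstrap
  calibration uses 500 replicates at n = 10 000.

## Known limitations

- No proof of convergence for ill-conditioned LD beyond the SPD-similarity
  argument; the error path is documented instead.
- The bootstrap treats the reference panel's haplotype table as the truth;
  panel sampling noise is reflected only through the benchmark, not in the
  reported SEs.
- Binary-trait replicates can fail by separation at low case counts; such
  replicates are dropped and counted against the 1% budget.
- Cross-chunk joint effects are not reconciled; signals straddling a chunk
  boundary are conditioned only on SNPs within their own chunk.
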