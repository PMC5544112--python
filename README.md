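# haprap

Haplotype-based approximate conditional analysis (statistical fine mapping)
from GWAS summary statistics and a phased reference panel.

## The problem

A GWAS meta-analysis reports only *marginal* per-SNP effects — each SNP
regressed on the trait alone. In a region with several correlated variants,
the quantity of interest is the *joint* effect of each SNP adjusted for its
neighbours, which normally requires individual-level genotypes. Existing
summary-level conditional methods approximate the adjustment with pairwise
LD correlations (r²) from a reference panel; but pairwise r² is a two-locus
summary, and with three or more loci it discards LD information that the
region's haplotypes still carry.

This package estimates approximate joint SNP effects from summary statistics
using the *haplotypes* of a phased reference panel. Writing M for the K×J
matrix of distinct haplotypes by SNPs and F for the haplotype frequencies,
candidate joint effects V induce haplotype effects Z = M V, and the marginal
effect of SNP j implied by Z is the frequency-weighted mean of Z over
haplotypes carrying the effect allele minus that over haplotypes carrying
the baseline allele. The estimator iteratively adjusts Z — always at the SNP
whose implied marginal deviates most from the observed one — until the
implied marginals match the observed vector O to 10 decimal places, then
recovers V = pinv(M) Z. At convergence this solves A V = O with
A_jl = D_jl / (p_j(1−p_j)), D the haplotype-level LD covariance. Standard
errors come from a parametric bootstrap (re-simulating the meta-analysis
cohort from the haplotype table and re-fitting, 2000 replicates by default),
followed by stepwise backward elimination at a genome-wide threshold.
It is for statistical geneticists fine-mapping regions where only summary
data and a phased panel (e.g. 1000 Genomes–style haplotypes) are available.
See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Simulate a three-SNP region — a lead signal with joint effect 1, a bystander
in strong LD with it (r² = 0.8) and no effect, and a secondary signal of 0.3
(r² = 0.5 to the lead) — then fine-map it from the summary statistics alone:

```
$ cat model.cfg
mafs = 0.5,0.5,0.5
r2 = 1-2:0.8,1-3:0.5
true_v = 1,0,0.3
n_meta = 100000

$ haprap simulate --config model.cfg --out-prefix region --n-ref 10000 --seed 7
... INFO wrote region.ma (3 SNPs, n=100000) and region.vcf (10000 individuals)

$ head -4 region.ma
SNP A1 A2 freq b se p N
snp1 A G 0.500585 1.2118464225130308 0.004519439615130626 0.0 100000
snp2 A G 0.500585 1.081350946481453 0.0048304844341918104 0.0 100000
snp3 A G 0.4991 1.0030028163311597 0.0049953458522543365 0.0 100000
```

All three *marginal* betas are near 1 — the bystander looks just as
associated as the true signals because of LD. Fitting recovers the joint
picture:

```
$ haprap fit --stats region.ma --panel region.vcf --phenotype-sd 1.2 \
             --out-prefix fit --reps 2000 --seed 1
... INFO chunk 1: 3 SNPs, converged in 246 iterations, max residual 9.974e-11
... INFO retained 2 SNP(s) overall

$ cat fit.tsv
chunk  SNP   b_joint       se_joint        p_joint       step_eliminated
1      snp1  1.011216201   0.006090293573  0             NA
1      snp2                                0.6847298097  1
1      snp3  0.2810536134  0.006754217362  0             NA
```

The bystander (snp2) is eliminated at step 1 with a joint p-value of 0.68
despite its genome-wide-significant marginal association, while the two true
signals are retained with joint effects near their generating values 1 and
0.3; `se_joint` is the parametric-bootstrap standard error. Per-chunk
reports, and a log with the seed and convergence residuals, are written next
to the combined table. `haprap se` computes joint effects and bootstrap SEs
without selection, and `haprap bench` scores the method against
individual-level multiple regression by MSE across reference-panel sizes.

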