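"""Shared fixtures: tiny phased-panel files and random haplotype tables."""

from __future__ import annotations

import numpy as np
import pytest

from haprap import HaplotypeTable, MarginalStats, PhasedPanel, SnpMeta, snp_effect_operator

# The canonical tiny panel: 2 SNPs, 4 chromosomes
# [0,0], [1,0], [1,0], [1,1]  (sample1 = rows 0-1, sample2 = rows 2-3)
TINY_CHROMS = np.array([[0, 0], [1, 0], [1, 0], [1, 1]], dtype=np.uint8)

VCF_TINY = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1\tsample2
1\t1000\trs1\tG\tA\t.\tPASS\t.\tGT\t0|1\t1|1
1\t2000\trs2\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1
"""

HAPS_TINY = """\
1 rs1 1000 G A 0 1 1 1
1 rs2 2000 C T 0 0 0 1
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(VCF_TINY)
    return path


@pytest.fixture
def tiny_haps(tmp_path):
    path = tmp_path / "tiny.haps"
    path.write_text(HAPS_TINY)
    return path


@pytest.fixture
def tiny_panel():
    snps = [
        SnpMeta("rs1", "1", 1000, "A", "G"),
        SnpMeta("rs2", "1", 2000, "T", "C"),
    ]
    return PhasedPanel(snps=snps, chromosomes=TINY_CHROMS.copy())


def make_snps(J: int) -> list[SnpMeta]:
    return [SnpMeta(f"snp{j + 1}", "1", (j + 1) * 1000, "A", "G") for j in range(J)]


def random_haplotype_table(
    rng: np.random.Generator,
    max_snps: int = 8,
    max_haplotypes: int = 32,
    max_condition: float = 100.0,
) -> HaplotypeTable:
    """A random valid haplotype table with a well-conditioned LD operator.

    Rejection-samples distinct haplotypes and Dirichlet frequencies until
    every SNP is polymorphic and the standardized LD operator A is full rank
    with condition number below ``max_condition`` (keeping the iteration's
    convergence fast and the linear-system oracle meaningful).
    """
    while True:
        J = int(rng.integers(1, max_snps + 1))
        n_pool = 2**J
        K = int(rng.integers(min(2, n_pool), min(n_pool, max_haplotypes) + 1))
        if K < 2:
            K = 2
        idx = rng.choice(n_pool, size=K, replace=False)
        M = ((idx[:, None] >> np.arange(J)) & 1).astype(np.uint8)
        F = rng.dirichlet(np.ones(K))
        if (F <= 1e-6).any():
            continue
        F = F / F.sum()
        p = F @ M
        if ((p < 0.02) | (p > 0.98)).any():
            continue
        table = HaplotypeTable(M=M, F=F, snps=make_snps(J))
        A = snp_effect_operator(table)
        if np.linalg.matrix_rank(A) < J:
            continue
        if np.linalg.cond(A) > max_condition:
            continue
        return table


def quantitative_stats(
    table: HaplotypeTable,
    beta: np.ndarray,
    se: float | np.ndarray = 0.01,
    n_total: int = 10_000,
    phenotype_sd: float = 1.0,
) -> MarginalStats:
    """Wrap a marginal-beta vector in a MarginalStats for a table's SNPs."""
    J = table.n_snps
    se = np.broadcast_to(np.asarray(se, dtype=float), (J,)).copy()
    return MarginalStats(
        snp=[s.id for s in table.snps],
        a1=[s.effect_allele for s in table.snps],
        a2=[s.baseline_allele for s in table.snps],
        freq=table.freqs,
        beta=np.asarray(beta, dtype=float),
        se=se,
        p=np.ones(J),
        n=np.full(J, n_total),
        trait_type="quantitative",
        phenotype_sd=phenotype_sd,
        n_total=n_total,
    )
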