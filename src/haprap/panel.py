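"""Phased reference panels and the SNP-by-haplotype table.

The iterative estimator never touches individual chromosomes: everything it
needs from the reference panel is the K x J binary matrix ``M`` of distinct
haplotypes and their frequency vector ``F``.  This module reads phased data
(VCF with "|" genotypes, or IMPUTE2 .haps), harmonizes allele coding with the
summary statistics (1 = effect allele everywhere), collapses chromosomes into
the haplotype table, and applies the collinearity (VIF) pre-filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    AlleleMismatchError,
    InputError,
    MissingDataError,
    MissingSnpError,
    MonomorphicSnpError,
    PhaseError,
    StrandAmbiguityError,
    UnsupportedRecordError,
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


@dataclass(frozen=True)
class SnpMeta:
    """Identity and allele coding of one SNP.

    ``effect_allele`` is the allele coded 1 in haplotype vectors; by GWAS
    convention this is the allele the marginal beta refers to.
    """

    id: str
    chrom: str
    pos: int
    effect_allele: str
    baseline_allele: str

    def __post_init__(self):
        if self.effect_allele == self.baseline_allele:
            raise InputError(
                f"SNP {self.id}: effect and baseline allele are both "
                f"{self.effect_allele!r}"
            )


@dataclass
class PhasedPanel:
    """2N phased chromosomes over J SNPs, coded 1 = effect allele."""

    snps: list[SnpMeta]
    chromosomes: np.ndarray  # (2N, J) uint8

    def __post_init__(self):
        self.chromosomes = np.asarray(self.chromosomes, dtype=np.uint8)
        if self.chromosomes.ndim != 2:
            raise InputError("chromosomes must be a 2-D array")
        if self.chromosomes.shape[1] != len(self.snps):
            raise InputError(
                f"{self.chromosomes.shape[1]} chromosome columns for "
                f"{len(self.snps)} SNPs"
            )
        if self.chromosomes.shape[0] < 2:
            raise InputError("panel needs at least 2 chromosomes")
        if not np.isin(self.chromosomes, (0, 1)).all():
            raise InputError("chromosome entries must be 0/1")
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate SNP ids in panel")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_chromosomes(self) -> int:
        return self.chromosomes.shape[0]

    def dosages(self) -> np.ndarray:
        """Per-individual dosage matrix by pairing consecutive chromosomes.

        Phased panels store the two chromosomes of individual ``i`` at rows
        ``2i`` and ``2i+1``; dosage is their sum.
        """
        c = self.chromosomes
        if c.shape[0] % 2:
            c = c[:-1]
        return (c[0::2] + c[1::2]).astype(np.float64)


@dataclass
class HaplotypeTable:
    """Distinct haplotypes ``M`` (K x J) with frequencies ``F`` (sum 1)."""

    M: np.ndarray
    F: np.ndarray
    snps: list[SnpMeta] = field(default_factory=list)

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=np.uint8)
        self.F = np.asarray(self.F, dtype=np.float64)
        if self.M.ndim != 2 or self.F.ndim != 1 or self.M.shape[0] != self.F.size:
            raise InputError("M must be K x J with one frequency per row")
        if (self.F <= 0).any():
            raise InputError("haplotype frequencies must be positive")
        if abs(self.F.sum() - 1.0) > 1e-12:
            raise InputError(f"haplotype frequencies sum to {self.F.sum()!r}, not 1")
        if len({tuple(row) for row in self.M}) != self.M.shape[0]:
            raise InputError("haplotype rows must be distinct")
        p = self.freqs
        if ((p <= 0) | (p >= 1)).any():
            j = int(np.argmax((p <= 0) | (p >= 1)))
            name = self.snps[j].id if self.snps else f"column {j}"
            raise MonomorphicSnpError(f"SNP {name} is monomorphic in the table")

    @property
    def n_haplotypes(self) -> int:
        return self.M.shape[0]

    @property
    def n_snps(self) -> int:
        return self.M.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        """Implied effect-allele frequency p_j = sum_k F_k m_kj."""
        return self.F @ self.M

    def ld_covariance(self) -> np.ndarray:
        """Pairwise haplotype-level covariance D_jl = E[m_j m_l] - p_j p_l."""
        FM = self.F[:, None] * self.M
        p = self.freqs
        return FM.T @ self.M - np.outer(p, p)

    def subset(self, indices) -> "HaplotypeTable":
        """Table restricted to a subset of SNP columns.

        Haplotypes that become indistinguishable on the subset are merged and
        their frequencies summed; ordering is re-canonicalized.
        """
        indices = list(indices)
        M = self.M[:, indices]
        haps, inverse = np.unique(M, axis=0, return_inverse=True)
        F = np.zeros(haps.shape[0])
        np.add.at(F, inverse, self.F)
        snps = [self.snps[i] for i in indices] if self.snps else []
        order = _canonical_order(haps, F)
        return HaplotypeTable(M=haps[order], F=F[order], snps=snps)


def _canonical_order(haps: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Descending frequency, then lexicographic on the haplotype vector."""
    keys = [haps[:, j] for j in range(haps.shape[1] - 1, -1, -1)]
    keys.append(-freqs)
    return np.lexsort(keys)


# ---------------------------------------------------------------------------
# Readers


def read_reference_panel(path, format: str | None = None) -> PhasedPanel:
    """Read a phased panel from a VCF or an IMPUTE2 .haps file.

    Alleles are coded provisionally with the file's alternate allele
    (VCF ALT / .haps allele1) as 1; :func:`harmonize_alleles` recodes against
    the summary statistics afterwards.  Unphased or missing genotypes and
    multi-allelic records are hard errors — the method assumes a complete
    pre-phased panel.
    """
    path = Path(path)
    if format is None:
        name = path.name.lower()
        if name.endswith((".vcf", ".vcf.gz", ".vcf.bgz")):
            format = "vcf"
        elif name.endswith((".haps", ".haps.gz")):
            format = "haps"
        else:
            raise InputError(f"cannot infer panel format from {path.name!r}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "haps":
        return _read_haps(path)
    raise InputError(f"unknown panel format {format!r}")


def _read_vcf(path: Path) -> PhasedPanel:
    from cyvcf2 import VCF

    if not path.exists():
        raise InputError(f"panel file not found: {path}")
    snps: list[SnpMeta] = []
    columns: list[np.ndarray] = []
    vcf = VCF(str(path))
    try:
        for var in vcf:
            if len(var.ALT) != 1:
                raise UnsupportedRecordError(
                    f"multi-allelic record at {var.CHROM}:{var.POS} "
                    f"({var.ID or '.'}): ALT={var.ALT}"
                )
            geno = var.genotypes  # per sample: [allele0, allele1, phased]
            if any(len(g) != 3 for g in geno):
                raise UnsupportedRecordError(
                    f"non-diploid genotype at {var.CHROM}:{var.POS} "
                    f"({var.ID or '.'})"
                )
            arr = np.asarray([g[:2] for g in geno], dtype=np.int64)
            phased = np.asarray([g[2] for g in geno], dtype=bool)
            alleles = arr
            if (alleles < 0).any():
                raise MissingDataError(
                    f"missing genotype at {var.CHROM}:{var.POS} ({var.ID or '.'})"
                )
            if not phased.all():
                raise PhaseError(
                    f"unphased genotype at {var.CHROM}:{var.POS} "
                    f"({var.ID or '.'}); phased '|' genotypes required"
                )
            snps.append(
                SnpMeta(
                    id=var.ID or f"{var.CHROM}:{var.POS}",
                    chrom=str(var.CHROM),
                    pos=int(var.POS),
                    effect_allele=var.ALT[0],
                    baseline_allele=var.REF,
                )
            )
            columns.append(alleles.reshape(-1).astype(np.uint8))
    finally:
        vcf.close()
    if not snps:
        raise InputError(f"no variant records in {path}")
    return PhasedPanel(snps=snps, chromosomes=np.column_stack(columns))


def _read_haps(path: Path) -> PhasedPanel:
    # IMPUTE2 dialect: chrom id pos allele0 allele1, then 2N space-separated
    # 0/1 calls (0 = allele0, 1 = allele1).
    if not path.exists():
        raise InputError(f"panel file not found: {path}")
    snps: list[SnpMeta] = []
    columns: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 7:
                raise InputError(f"{path}:{lineno}: fewer than 7 columns")
            chrom, snp_id, pos, a0, a1 = fields[:5]
            calls = fields[5:]
            bad = [c for c in calls if c not in ("0", "1")]
            if bad:
                if bad[0] in (".", "?", "NA"):
                    raise MissingDataError(
                        f"{path}:{lineno}: missing genotype {bad[0]!r} for {snp_id}"
                    )
                raise InputError(
                    f"{path}:{lineno}: invalid haplotype call {bad[0]!r}"
                )
            snps.append(
                SnpMeta(
                    id=snp_id,
                    chrom=chrom,
                    pos=int(pos),
                    effect_allele=a1,
                    baseline_allele=a0,
                )
            )
            columns.append(np.array(calls, dtype=np.uint8))
    if not snps:
        raise InputError(f"no records in {path}")
    lengths = {c.size for c in columns}
    if len(lengths) != 1:
        raise InputError(f"{path}: rows carry differing numbers of haplotypes")
    return PhasedPanel(snps=snps, chromosomes=np.column_stack(columns))


# ---------------------------------------------------------------------------
# Harmonization and table construction


def harmonize_alleles(panel: PhasedPanel, stats) -> tuple[PhasedPanel, "object"]:
    """Recode the panel so 1 = the summary statistics' effect allele.

    SNPs are returned in summary-statistic order.  Where the panel codes the
    stats' effect allele as 0, the column is complemented (betas are never
    touched).  Palindromic A/T or C/G SNPs are accepted only when the implied
    panel frequency agrees with the reported effect-allele frequency within
    0.2 under the chosen orientation.
    """
    by_id = {s.id: j for j, s in enumerate(panel.snps)}
    cols = []
    snps = []
    panel_freq = panel.chromosomes.mean(axis=0)
    for i, snp_id in enumerate(stats.snp):
        if snp_id not in by_id:
            raise MissingSnpError(f"SNP {snp_id} absent from the reference panel")
        j = by_id[snp_id]
        meta = panel.snps[j]
        a1, a2 = str(stats.a1[i]).upper(), str(stats.a2[i]).upper()
        pe, pb = meta.effect_allele.upper(), meta.baseline_allele.upper()
        column = panel.chromosomes[:, j]
        if (a1, a2) == (pe, pb):
            flip = False
        elif (a1, a2) == (pb, pe):
            flip = True
        else:
            raise AlleleMismatchError(
                f"SNP {snp_id}: stats alleles {a1}/{a2} do not match panel "
                f"alleles {pe}/{pb} in either order"
            )
        if flip:
            column = 1 - column
            meta = replace(
                meta,
                effect_allele=meta.baseline_allele,
                baseline_allele=meta.effect_allele,
            )
        if _is_palindromic(a1, a2):
            p_panel = 1.0 - panel_freq[j] if flip else panel_freq[j]
            if abs(p_panel - float(stats.freq[i])) > 0.2:
                raise StrandAmbiguityError(
                    f"SNP {snp_id}: palindromic {a1}/{a2} with panel frequency "
                    f"{p_panel:.3f} vs reported {float(stats.freq[i]):.3f} "
                    f"(conflict > 0.2); cannot resolve strand"
                )
        cols.append(column)
        snps.append(meta)
    out = PhasedPanel(snps=snps, chromosomes=np.column_stack(cols))
    return out, stats


def build_haplotype_table(panel: PhasedPanel) -> HaplotypeTable:
    """Collapse chromosomes into distinct haplotypes with empirical frequencies.

    Rows are ordered by descending frequency then lexicographically so the
    table is byte-stable across runs.
    """
    col_means = panel.chromosomes.mean(axis=0)
    mono = (col_means == 0) | (col_means == 1)
    if mono.any():
        j = int(np.argmax(mono))
        raise MonomorphicSnpError(
            f"SNP {panel.snps[j].id} is monomorphic in the panel"
        )
    haps, counts = np.unique(panel.chromosomes, axis=0, return_counts=True)
    F = counts / counts.sum()
    order = _canonical_order(haps, F)
    return HaplotypeTable(M=haps[order], F=F[order], snps=list(panel.snps))


# ---------------------------------------------------------------------------
# Collinearity filter


def _vif(dosages: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2) of dosage column j regressed on the others."""
    X = dosages - dosages.mean(axis=0)
    J = X.shape[1]
    tss = (X**2).sum(axis=0)
    out = np.empty(J)
    for j in range(J):
        others = np.delete(X, j, axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, X[:, j], rcond=None)
        rss = ((X[:, j] - others @ coef) ** 2).sum()
        r2 = 1.0 - rss / tss[j] if tss[j] > 0 else 1.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(
    panel: PhasedPanel, threshold: float = 7.0
) -> tuple[list[str], list[str]]:
    """Iteratively drop the worst-VIF SNP until all VIFs are at or below threshold.

    Collinear SNPs blow up joint estimates, so near-duplicates must go before
    fitting.  Returns (kept ids, dropped ids); ties break toward the lower
    column index.  With fewer than 2 SNPs the VIF is undefined and everything
    is kept.
    """
    ids = [s.id for s in panel.snps]
    if panel.n_snps < 2:
        return ids, []
    dosages = panel.dosages()
    active = list(range(panel.n_snps))
    dropped: list[str] = []
    while len(active) >= 2:
        vifs = _vif(dosages[:, active])
        worst = int(np.argmax(vifs))
        if vifs[worst] <= threshold:
            break
        dropped.append(ids[active[worst]])
        del active[worst]
    kept = [ids[j] for j in active]
    return kept, dropped
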