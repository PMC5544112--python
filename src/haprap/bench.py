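"""Validation bench: controlled-LD haplotype pools, simulated meta-analyses,
and MSE scoring against the multiple-regression gold standard.

The bench builds a joint haplotype distribution realizing requested pairwise
r-squared values, simulates a large meta-analysis cohort from it, derives
marginal summary statistics by single-SNP regressions, and then compares two
summary-level estimators — the haplotype-based iterative method and a
pairwise-LD matrix-inversion baseline — against joint effects from multiple
regression on the full individual-level cohort, across reference-panel sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import marginal_gwas, simulate_cohort
from .core import run_haprap
from .errors import (
    ConditioningError,
    FeasibilityError,
    HaprapError,
    PanelDegeneracyError,
    SingularDesignError,
)
from .panel import (
    HaplotypeTable,
    PhasedPanel,
    SnpMeta,
    _canonical_order,
    build_haplotype_table,
)
from .sumstats import MarginalStats

_IPF_TOL = 1e-13
_IPF_MAX_SWEEPS = 10_000


@dataclass
class LDModelSpec:
    """A region model: allele frequencies, target pairwise LD, true effects.

    ``r2_targets`` maps 0-based SNP index pairs to target r-squared values;
    pairs not listed are left unconstrained and get whatever dependence the
    maximum-entropy fit implies (three-locus constraints can make explicit
    zeros infeasible, so absence of a pair means "free", while an explicit
    0.0 is enforced).  D is taken positive when derived from r-squared.
    """

    mafs: tuple[float, ...]
    r2_targets: dict[tuple[int, int], float] = field(default_factory=dict)
    true_V: tuple[float, ...] = ()
    pool_size: int = 100_000
    seed: int = 0

    def __post_init__(self):
        self.mafs = tuple(float(m) for m in self.mafs)
        self.true_V = tuple(float(v) for v in self.true_V) or tuple(
            0.0 for _ in self.mafs
        )
        if len(self.true_V) != len(self.mafs):
            raise HaprapError("true_V and mafs must have equal length")
        if any(not 0 < m < 1 for m in self.mafs):
            raise HaprapError("MAFs must lie in (0, 1)")
        if self.pool_size < 1000:
            raise HaprapError("pool_size must be at least 1000")
        norm = {}
        for (j, l), r2 in self.r2_targets.items():
            if j == l:
                raise HaprapError(f"r2 target for a SNP with itself: {j}")
            if not 0 <= r2 < 1:
                raise FeasibilityError(f"r2 target {r2} outside [0, 1)")
            norm[(min(j, l), max(j, l))] = float(r2)
        self.r2_targets = norm

    @property
    def n_snps(self) -> int:
        return len(self.mafs)

    def pairwise_d(self) -> dict[tuple[int, int], float]:
        """Target covariances D (positive root), checked against Lewontin bounds."""
        out = {}
        for (j, l), r2 in self.r2_targets.items():
            pj, pl = self.mafs[j], self.mafs[l]
            d = np.sqrt(r2 * pj * (1 - pj) * pl * (1 - pl))
            d_max = min(pj * (1 - pl), pl * (1 - pj))
            if d > d_max + 1e-12:
                raise FeasibilityError(
                    f"r2={r2} between SNPs {j} and {l} needs D={d:.4f} but the "
                    f"Lewontin bound for MAFs ({pj}, {pl}) is {d_max:.4f}"
                )
            out[(j, l)] = float(d)
        return out


def _synthetic_snps(J: int) -> list[SnpMeta]:
    return [SnpMeta(f"snp{j + 1}", "1", (j + 1) * 1000, "A", "G") for j in range(J)]


def make_haplotype_frequencies(spec: LDModelSpec) -> HaplotypeTable:
    """Haplotype distribution matching MAF margins and target pairwise D.

    Iterative proportional fitting over all 2^J haplotypes, starting from the
    independence product: each sweep rescales to the one-locus margins and
    then to each constrained two-locus 2x2 margin.  The fixed point is the
    maximum-entropy distribution subject to those margins.  Failure to reach
    all constraints signals an infeasible target combination.
    """
    J = spec.n_snps
    haps = np.array(list(itertools.product((0, 1), repeat=J)), dtype=np.uint8)
    f = np.ones(len(haps))
    for j in range(J):
        f *= np.where(haps[:, j] == 1, spec.mafs[j], 1 - spec.mafs[j])
    dd = spec.pairwise_d()
    pair_targets = []
    for (j, l), d in dd.items():
        p11 = spec.mafs[j] * spec.mafs[l] + d
        cells = {
            (1, 1): p11,
            (1, 0): spec.mafs[j] - p11,
            (0, 1): spec.mafs[l] - p11,
            (0, 0): 1 - spec.mafs[j] - spec.mafs[l] + p11,
        }
        if min(cells.values()) < -1e-12:
            raise FeasibilityError(
                f"pairwise target for SNPs ({j}, {l}) implies a negative "
                f"haplotype frequency"
            )
        pair_targets.append((j, l, cells))

    dev = 0.0
    for _ in range(_IPF_MAX_SWEEPS):
        dev = 0.0
        for j in range(J):
            sel = haps[:, j] == 1
            s1, s0 = f[sel].sum(), f[~sel].sum()
            dev = max(dev, abs(s1 - spec.mafs[j]))
            f[sel] *= spec.mafs[j] / s1
            f[~sel] *= (1 - spec.mafs[j]) / s0
        for j, l, cells in pair_targets:
            for (a, b), t in cells.items():
                sel = (haps[:, j] == a) & (haps[:, l] == b)
                s = f[sel].sum()
                dev = max(dev, abs(s - t))
                if s > 0:
                    f[sel] *= t / s if t > 0 else 0.0
                elif t > 1e-12:
                    raise FeasibilityError(
                        f"target mass {t:.4g} on an empty haplotype cell for "
                        f"SNP pair ({j}, {l}); LD targets jointly infeasible"
                    )
        if dev < _IPF_TOL:
            break
    if dev > 1e-8:
        raise FeasibilityError(
            f"IPF did not reach the requested LD targets (residual {dev:.3g}); "
            f"the pairwise r2 combination is infeasible for these MAFs"
        )
    keep = f > 1e-12
    f = f[keep] / f[keep].sum()
    haps = haps[keep]
    order = _canonical_order(haps, f)
    return HaplotypeTable(M=haps[order], F=f[order], snps=_synthetic_snps(J))


def draw_reference_panel(
    table: HaplotypeTable, n_ref: int, seed: int
) -> PhasedPanel:
    """Sample 2*n_ref chromosomes i.i.d. from the haplotype distribution.

    Redraws (up to 100 attempts) if a SNP comes out monomorphic — rare
    alleles in tiny panels — and errors if the panel stays degenerate.
    """
    if n_ref < 2:
        raise HaprapError("reference panel needs at least 2 individuals")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        idx = rng.choice(table.n_haplotypes, size=2 * n_ref, p=table.F)
        chroms = table.M[idx]
        means = chroms.mean(axis=0)
        if ((means > 0) & (means < 1)).all():
            return PhasedPanel(snps=list(table.snps), chromosomes=chroms)
    raise PanelDegeneracyError(
        f"panel of {n_ref} individuals monomorphic after 100 redraws "
        f"(rarest implied frequency {table.freqs.min():.4g})"
    )


def multiple_regression_gold(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    trait_type: str = "quantitative",
) -> tuple[np.ndarray, np.ndarray]:
    """Joint effects from multiple regression on individual-level data.

    The gold standard the summary-level methods are scored against.
    Returns (betas, SEs), intercept excluded.
    """
    X = np.column_stack([np.ones(len(phenotype)), dosages])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("rank-deficient design in gold-standard fit")
    if trait_type == "quantitative":
        coef, rss, *_ = np.linalg.lstsq(X, phenotype, rcond=None)
        n, k = X.shape
        resid = phenotype - X @ coef
        sigma2 = float(resid @ resid) / (n - k)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        return coef[1:], np.sqrt(np.diag(cov))[1:]
    import statsmodels.api as sm

    res = sm.Logit(phenotype, X).fit(disp=0, maxiter=200)
    return res.params[1:], res.bse[1:]


def pairwise_ld_baseline(stats: MarginalStats, panel: PhasedPanel) -> np.ndarray:
    """Joint effects from the dosage correlation matrix alone.

    Standardizes each marginal beta by sqrt(2 p (1-p)), solves R v = b* with
    R the panel's pairwise dosage correlation matrix, and back-transforms.
    A deliberately simplified stand-in for pairwise-LD conditional methods —
    an approximation used for benchmarking, not a reimplementation of any
    published tool.
    """
    ids_panel = [s.id for s in panel.snps]
    if list(stats.snp) != ids_panel:
        order = [ids_panel.index(s) for s in stats.snp]
        panel = PhasedPanel(
            snps=[panel.snps[i] for i in order],
            chromosomes=panel.chromosomes[:, order],
        )
    dosages = panel.dosages()
    J = dosages.shape[1]
    if J == 1:
        return stats.beta.copy()
    R = np.corrcoef(dosages, rowvar=False)
    cond = np.linalg.cond(R)
    if cond > 1e8:
        raise ConditioningError(
            f"LD correlation matrix condition number {cond:.3g} exceeds 1e8"
        )
    scale = np.sqrt(2.0 * stats.freq * (1.0 - stats.freq))
    v_std = np.linalg.solve(R, stats.beta * scale)
    return v_std / scale


@dataclass
class BenchResult:
    """Long-format MSE table plus raw per-replicate estimates."""

    table: pd.DataFrame
    gold: np.ndarray  # reps x J
    estimates: dict[tuple[str, int], np.ndarray]  # (method, ref_size) -> reps x J
    n_meta: int
    reps: int


def mse_benchmark(
    spec: LDModelSpec,
    n_meta: int,
    ref_sizes: list[int],
    reps: int,
    seed: int,
    noise_sd: float = 1.0,
) -> BenchResult:
    """Score both summary-level methods against the gold standard by MSE.

    Per replicate: draw a meta-analysis cohort of ``n_meta`` individuals from
    the model's haplotype pool, generate phenotypes ``y = dosage @ true_V +
    Normal(0, noise_sd)``, fit the gold standard (multiple regression on the
    cohort) and the per-SNP marginal regressions, then for every reference
    size draw an independent panel and run both summary-level methods.  MSE
    is the per-replicate mean over SNPs of squared error against that
    replicate's gold standard.
    """
    if reps < 2:
        raise HaprapError("benchmark needs at least 2 replicates")
    pool = make_haplotype_frequencies(spec)
    true_V = np.asarray(spec.true_V)
    J = spec.n_snps
    master = np.random.default_rng(seed)
    child = master.integers(0, 2**31 - 1, size=(reps, 3 + len(ref_sizes)))

    gold = np.full((reps, J), np.nan)
    est = {
        (m, n): np.full((reps, J), np.nan)
        for m in ("haprap", "pairwise_ld")
        for n in ref_sizes
    }
    failures = {key: 0 for key in est}
    for r in range(reps):
        dos = simulate_cohort(pool, n_meta, int(child[r, 0]))
        rng = np.random.default_rng(int(child[r, 1]))
        y = dos @ true_V + rng.normal(0.0, noise_sd, size=n_meta)
        gold[r], _ = multiple_regression_gold(dos, y)
        mstats = marginal_gwas(dos, y, snps=pool.snps)
        for i, n_ref in enumerate(ref_sizes):
            panel_seed = int(child[r, 3 + i])
            try:
                panel = draw_reference_panel(pool, n_ref, panel_seed)
                ref_table = build_haplotype_table(panel)
                fit = run_haprap(ref_table, mstats.beta, seed=int(child[r, 2]))
                est[("haprap", n_ref)][r] = fit.V
            except HaprapError:
                failures[("haprap", n_ref)] += 1
                continue
            try:
                est[("pairwise_ld", n_ref)][r] = pairwise_ld_baseline(
                    mstats, panel
                )
            except HaprapError:
                failures[("pairwise_ld", n_ref)] += 1

    rows = []
    for (method, n_ref), values in est.items():
        ok = ~np.isnan(values).any(axis=1)
        per_rep_mse = ((values[ok] - gold[ok]) ** 2).mean(axis=1)
        rows.append(
            {
                "method": method,
                "ref_size": n_ref,
                "mse": per_rep_mse.mean() if ok.any() else np.nan,
                "mse_sd": per_rep_mse.std(ddof=1) if ok.sum() > 1 else np.nan,
                "reps_ok": int(ok.sum()),
                "reps_failed": failures[(method, n_ref)],
            }
        )
    table = pd.DataFrame(rows).sort_values(["method", "ref_size"]).reset_index(
        drop=True
    )
    return BenchResult(
        table=table, gold=gold, estimates=est, n_meta=n_meta, reps=reps
    )


def three_snp_model(maf: float = 0.5) -> LDModelSpec:
    """The bench's reference three-SNP region: a lead signal (joint effect 1),
    a correlated bystander with no effect (r2 = 0.8 to the lead), and a
    secondary signal of 0.3 (r2 = 0.5 to the lead)."""
    return LDModelSpec(
        mafs=(maf, maf, maf),
        r2_targets={(0, 1): 0.8, (0, 2): 0.5},
        true_V=(1.0, 0.0, 0.3),
    )


def rare_variant_model(maf: float = 0.08, r2: float = 0.5) -> LDModelSpec:
    """Two-SNP low-frequency regime: one causal SNP, one correlated null."""
    return LDModelSpec(
        mafs=(maf, maf), r2_targets={(0, 1): r2}, true_V=(1.0, 0.0)
    )
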