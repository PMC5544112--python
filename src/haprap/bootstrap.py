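"""Parametric-bootstrap standard errors and stepwise model selection.

The joint-effect estimator has no closed-form SE, so uncertainty comes from a
parametric bootstrap: re-simulate the meta-analysis cohort from the haplotype
table under the fitted joint effects, recompute single-SNP marginal statistics
on each simulated cohort, re-fit the estimator, and take the SD of the joint
estimates over replicates.  A cheap pre-test on marginal SEs trims clearly
null SNPs before the expensive bootstrap; backward elimination with
bootstrap-based t-tests then prunes to a final model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats as sps
from scipy.optimize import brentq

from .core import run_haprap
from .errors import EmptyRegionError, HaprapError, NonConvergenceError
from .panel import HaplotypeTable, SnpMeta
from .sumstats import MarginalStats


@dataclass
class BootstrapSE:
    """Bootstrap SEs: SD (ddof=1) of the joint estimates over replicates."""

    se: np.ndarray
    reps: int
    seed: int
    n_failed: int = 0
    per_rep_estimates: np.ndarray | None = None


@dataclass
class SelectionStep:
    snp: str
    p_value: float
    remaining: tuple[str, ...]


@dataclass
class SelectionTrace:
    """Elimination history plus the final retained model."""

    steps: list[SelectionStep]
    final_snps: list[str]
    b_joint: np.ndarray
    se_joint: np.ndarray
    p_joint: np.ndarray


# ---------------------------------------------------------------------------
# Cohort simulation


def simulate_cohort(table: HaplotypeTable, n: int, seed: int) -> np.ndarray:
    """Genotype dosages for n individuals, two haplotypes i.i.d. from F (HWE)."""
    if n < 1:
        raise EmptyRegionError("cohort size must be at least 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(table.n_haplotypes, size=(n, 2), p=table.F)
    return (table.M[idx[:, 0]] + table.M[idx[:, 1]]).astype(np.float64)


def simulate_phenotype(
    dosages: np.ndarray,
    V: np.ndarray,
    stats: MarginalStats,
    seed: int,
) -> np.ndarray:
    """Phenotypes with the weighted genetic risk score g = dosages @ V as signal.

    Quantitative: y = g + e with residual variance chosen so the marginal
    phenotype SD matches ``stats.phenotype_sd``; if the genetic variance
    already exceeds the total, the residual variance is floored at 10% of the
    total with a warning (the inputs are then mutually inconsistent).

    Binary: case status ~ Bernoulli(expit(alpha + g)), with the intercept
    alpha solved so the mean case probability equals ``stats.case_proportion``.
    """
    import warnings

    rng = np.random.default_rng(seed)
    g = dosages @ np.asarray(V, dtype=np.float64)
    n = dosages.shape[0]
    if stats.trait_type == "quantitative":
        total_var = stats.phenotype_sd**2
        resid_var = total_var - g.var()
        floor = 0.1 * total_var
        if resid_var < floor:
            warnings.warn(
                "genetic variance exceeds 90% of the stated phenotype "
                "variance; flooring residual variance at 10% (inconsistent "
                "inputs?)",
                RuntimeWarning,
                stacklevel=2,
            )
            resid_var = floor
        return g + rng.normal(0.0, np.sqrt(resid_var), size=n)

    target = stats.case_proportion

    def mean_prob(alpha: float) -> float:
        return float(special.expit(alpha + g).mean()) - target

    alpha = brentq(mean_prob, -60.0, 60.0)
    return (rng.random(n) < special.expit(alpha + g)).astype(np.float64)


def marginal_gwas(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    trait_type: str = "quantitative",
    snps: list[SnpMeta] | None = None,
) -> MarginalStats:
    """Single-SNP marginal statistics on an individual-level cohort.

    Quantitative traits use closed-form simple linear regression per SNP
    (slope cov(y, g)/var(g), t-test on n-2 df); binary traits fit a
    single-covariate logistic regression per SNP via statsmodels, flagging
    non-converged/separated fits instead of failing the whole region.
    """
    dosages = np.asarray(dosages, dtype=np.float64)
    y = np.asarray(phenotype, dtype=np.float64)
    n, J = dosages.shape
    if n < 10:
        raise HaprapError("marginal GWAS requires at least 10 individuals")
    freq = dosages.mean(axis=0) / 2.0
    if snps is None:
        snps = [
            SnpMeta(f"snp{j + 1}", "1", (j + 1) * 1000, "A", "G")
            for j in range(J)
        ]
    ids = np.array([s.id for s in snps], dtype=object)
    a1 = np.array([s.effect_allele for s in snps], dtype=object)
    a2 = np.array([s.baseline_allele for s in snps], dtype=object)
    fit_ok = np.ones(J, dtype=bool)

    if trait_type == "quantitative":
        gc = dosages - dosages.mean(axis=0)
        yc = y - y.mean()
        sxx = (gc**2).sum(axis=0)
        sxy = gc.T @ yc
        syy = (yc**2).sum()
        beta = sxy / sxx
        rss = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(rss / (n - 2) / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p = 2.0 * sps.t.sf(np.abs(tval), df=n - 2)
        trait_block = dict(
            trait_type="quantitative", phenotype_sd=float(y.std(ddof=1))
        )
    else:
        import statsmodels.api as sm

        beta = np.empty(J)
        se = np.empty(J)
        p = np.empty(J)
        X0 = np.ones((n, 2))
        for j in range(J):
            X0[:, 1] = dosages[:, j]
            try:
                res = sm.Logit(y, X0.copy()).fit(disp=0, maxiter=100)
                if not res.mle_retvals.get("converged", True):
                    raise ValueError("no convergence")
                beta[j], se[j] = res.params[1], res.bse[1]
                p[j] = res.pvalues[1]
                if not np.isfinite(se[j]) or se[j] <= 0:
                    raise ValueError("degenerate SE")
            except Exception:
                beta[j] = se[j] = p[j] = np.nan
                fit_ok[j] = False
        trait_block = dict(trait_type="binary", case_proportion=float(y.mean()))

    return MarginalStats(
        snp=ids,
        a1=a1,
        a2=a2,
        freq=freq,
        beta=beta,
        se=se,
        p=p,
        n=np.full(J, n),
        n_total=n,
        fit_ok=fit_ok,
        **trait_block,
    )


# ---------------------------------------------------------------------------
# simHAPRAP bootstrap


def simhaprap_se(
    table: HaplotypeTable,
    V: np.ndarray,
    stats: MarginalStats,
    reps: int = 2000,
    seed: int = 0,
    keep_replicates: bool = False,
) -> BootstrapSE:
    """Parametric-bootstrap SEs for fitted joint effects V.

    Each replicate simulates a cohort of ``stats.n_total`` individuals from
    the haplotype table under HWE, generates phenotypes with genetic weights
    V, recomputes single-SNP marginal betas, and re-fits the joint estimator.
    Replicates whose re-fit does not converge are dropped; more than 1% such
    drops aborts with an unstable-region error.
    """
    if reps < 2:
        raise HaprapError("bootstrap needs at least 2 replicates")
    master = np.random.default_rng(seed)
    child = master.integers(0, 2**31 - 1, size=(reps, 3))
    estimates = []
    n_failed = 0
    for r in range(reps):
        dos = simulate_cohort(table, stats.n_total, int(child[r, 0]))
        y = simulate_phenotype(dos, V, stats, int(child[r, 1]))
        sim_stats = marginal_gwas(dos, y, stats.trait_type, snps=table.snps)
        if not sim_stats.fit_ok.all():
            n_failed += 1
            continue
        try:
            fit = run_haprap(table, sim_stats.beta, seed=int(child[r, 2]))
        except NonConvergenceError:
            n_failed += 1
            continue
        estimates.append(fit.V)
    if n_failed > 0.01 * reps:
        raise HaprapError(
            f"unstable region: {n_failed}/{reps} bootstrap replicates failed"
        )
    est = np.asarray(estimates)
    return BootstrapSE(
        se=est.std(axis=0, ddof=1),
        reps=reps,
        seed=seed,
        n_failed=n_failed,
        per_rep_estimates=est if keep_replicates else None,
    )


# ---------------------------------------------------------------------------
# Pre-test and stepwise backward elimination


def _marginal_pvalues(V: np.ndarray, se_marginal: np.ndarray) -> np.ndarray:
    """Two-sided normal test of the joint effects against the marginal SEs."""
    z = np.abs(V) / se_marginal
    return 2.0 * sps.norm.sf(z)


def pretest(
    table: HaplotypeTable,
    stats: MarginalStats,
    threshold: float,
    seed: int = 0,
) -> list[str]:
    """Cheap significance pre-screen before the bootstrap.

    Uses the fitted joint effects with the *marginal* SEs (conservative,
    since joint uncertainty is never smaller).  Removes one SNP at a time —
    the highest p above threshold — re-fitting after each removal, until all
    survivors pass or one SNP remains.  Returns retained SNP ids in input
    order.
    """
    active = list(range(table.n_snps))
    ids = [s.id for s in table.snps]
    while len(active) > 1:
        sub = table.subset(active)
        fit = run_haprap(sub, stats.beta[active], seed=seed)
        p = _marginal_pvalues(fit.V, stats.se[active])
        worst = int(np.argmax(p))
        if p[worst] <= threshold:
            break
        del active[worst]
    return [ids[j] for j in active]


def stepwise_select(
    table: HaplotypeTable,
    stats: MarginalStats,
    p_threshold: float = 5e-8,
    reps: int = 2000,
    seed: int = 0,
) -> SelectionTrace:
    """Backward elimination on bootstrap-based t-tests.

    Pipeline: marginal-SE pre-test; then, while at least two SNPs remain,
    fit joint effects, bootstrap their SEs, compute t-test p-values
    (df = n_total - J - 1) and eliminate the highest p above the threshold,
    re-fitting after every removal.  A lone surviving SNP is tested with its
    marginal SE (identical to the single-SNP bootstrap SE in expectation) and
    may still be removed, giving an empty final model.
    """
    ids = [s.id for s in table.snps]
    retained_ids = pretest(table, stats, p_threshold, seed=seed)
    steps = _pretest_steps(table, stats, p_threshold, seed)
    active = [ids.index(s) for s in retained_ids]

    while True:
        J = len(active)
        if J == 0:
            b = se = p = np.array([])
            break
        sub = table.subset(active)
        sub_stats = stats.subset(active)
        fit = run_haprap(sub, sub_stats.beta, seed=seed)
        if J == 1:
            b = fit.V
            se = sub_stats.se
            df = max(stats.n_total - 2, 1)
        else:
            boot = simhaprap_se(sub, fit.V, sub_stats, reps=reps, seed=seed)
            b = fit.V
            se = boot.se
            df = max(stats.n_total - J - 1, 1)
        p = 2.0 * sps.t.sf(np.abs(b) / se, df=df)
        worst = int(np.argmax(p))
        if p[worst] <= p_threshold:
            break
        removed = active[worst]
        del active[worst]
        steps.append(
            SelectionStep(
                snp=ids[removed],
                p_value=float(p[worst]),
                remaining=tuple(ids[a] for a in active),
            )
        )
        if not active:
            b = se = p = np.array([])
            break
    return SelectionTrace(
        steps=steps,
        final_snps=[ids[a] for a in active],
        b_joint=np.asarray(b, dtype=np.float64),
        se_joint=np.asarray(se, dtype=np.float64),
        p_joint=np.asarray(p, dtype=np.float64),
    )


def _pretest_steps(
    table: HaplotypeTable, stats: MarginalStats, threshold: float, seed: int
) -> list[SelectionStep]:
    """Replay the pre-test to record each elimination with its p-value."""
    ids = [s.id for s in table.snps]
    active = list(range(table.n_snps))
    steps: list[SelectionStep] = []
    while len(active) > 1:
        sub = table.subset(active)
        fit = run_haprap(sub, stats.beta[active], seed=seed)
        p = _marginal_pvalues(fit.V, stats.se[active])
        worst = int(np.argmax(p))
        if p[worst] <= threshold:
            break
        removed = active[worst]
        del active[worst]
        steps.append(
            SelectionStep(
                snp=ids[removed],
                p_value=float(p[worst]),
                remaining=tuple(ids[a] for a in active),
            )
        )
    return steps
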