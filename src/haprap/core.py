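"""The iterative joint-effect estimator.

Estimates approximate joint (conditional) SNP effects from marginal GWAS
betas ``O`` and a haplotype table ``(M, F)`` from a phased reference panel.

The algorithm works in haplotype-effect space.  Given candidate joint effects
``V``, every haplotype carries the additive effect ``Z = M V``.  The marginal
effect of SNP j implied by ``Z`` is the frequency-weighted mean haplotype
effect among haplotypes carrying the effect allele minus that among haplotypes
carrying the baseline allele:

    U_j = (sum_{l: m_lj=1} F_l Z_l) / (sum F_l)  -  (sum_{o: m_oj=0} F_o Z_o) / (sum F_o)

The iteration repeatedly picks the SNP whose implied marginal deviates most
from its observed value and shifts every effect-allele haplotype of that SNP
by the deviation delta = O_j - U_j, which sets U_j = O_j exactly while moving
the others only through shared haplotypes (a Gauss-Southwell coordinate
sweep).  At convergence ``Z`` still lies in the column space of ``M`` — the
start ``M V0`` and every adjustment ``delta * M[:, j]`` are column
combinations — so the joint effects are recovered by the Moore-Penrose
pseudoinverse, ``V = pinv(M) Z``.

``U`` is linear in ``Z`` (``U = W Z``) and hence linear in ``V``
(``U = A V`` with ``A = W M``); one can show ``A_jl = D_jl / (p_j (1 - p_j))``
where ``D`` is the haplotype-level LD covariance, so a converged run solves
``A V = O``.  That identity is what the tests exploit as an independent
oracle; the iteration itself never forms ``A^{-1}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, EmptyRegionError, NonConvergenceError
from .panel import HaplotypeTable

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10**6


@dataclass
class IterationState:
    """Snapshot of one sweep: counter g, joint V, haplotype Z, implied U."""

    g: int
    V: np.ndarray
    Z: np.ndarray
    U: np.ndarray
    deviations: np.ndarray


@dataclass
class JointEstimate:
    V: np.ndarray
    converged: bool
    iterations: int
    max_residual: float
    Z: np.ndarray | None = None


def init_joint_effects(n_snps: int, seed: int) -> np.ndarray:
    """Random starting joint effects, i.i.d. standard normal, seeded."""
    if n_snps < 1:
        raise EmptyRegionError("need at least one SNP to initialize")
    return np.random.default_rng(seed).standard_normal(n_snps)


def haplotype_effects(table: HaplotypeTable, V: np.ndarray) -> np.ndarray:
    """Additive haplotype effects Z = M V."""
    V = np.asarray(V, dtype=np.float64)
    if V.shape != (table.n_snps,):
        raise DimensionError(
            f"V has shape {V.shape}, table has {table.n_snps} SNPs"
        )
    return table.M @ V


def marginal_operator(table: HaplotypeTable) -> np.ndarray:
    """The J x K linear map W with U = W Z.

    Row j holds F_k / p_j on effect-allele haplotypes and -F_k / (1 - p_j)
    on baseline haplotypes (p_j = total frequency of effect-allele
    haplotypes), i.e. the difference of the two weighted group means.
    """
    p = table.freqs
    Mf = table.M.astype(np.float64)
    # broadcast: column j scaled by 1/p_j (effect group) or -1/(1-p_j) (baseline)
    return (Mf / p - (1.0 - Mf) / (1.0 - p)).T * table.F


def estimate_marginal(table: HaplotypeTable, Z: np.ndarray) -> np.ndarray:
    """Marginal SNP effects implied by haplotype effects Z."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape != (table.n_haplotypes,):
        raise DimensionError(
            f"Z has shape {Z.shape}, table has {table.n_haplotypes} haplotypes"
        )
    return marginal_operator(table) @ Z


def snp_effect_operator(table: HaplotypeTable) -> np.ndarray:
    """The J x J map A with U = A V; equals D_jl / (p_j (1 - p_j)), unit diagonal.

    The diagonal is set to exactly 1 (its analytic value) so a coordinate
    adjustment matches the observed marginal to machine precision.
    """
    p = table.freqs
    A = table.ld_covariance() / (p * (1.0 - p))[:, None]
    np.fill_diagonal(A, 1.0)
    return A


def select_worst_snp(
    U: np.ndarray, O: np.ndarray, tol: float = DEFAULT_TOL
) -> int | None:
    """Index of the SNP with the largest |U_j - O_j|, or None if converged.

    Ties break toward the lower index (``argmax`` semantics).
    """
    U = np.asarray(U, dtype=np.float64)
    O = np.asarray(O, dtype=np.float64)
    if U.shape != O.shape:
        raise DimensionError(f"U {U.shape} vs O {O.shape}")
    dev = np.abs(U - O)
    if dev.max() < tol:
        return None
    return int(np.argmax(dev))


def apply_adjustment(
    state: IterationState, j: int, O: np.ndarray, table: HaplotypeTable
) -> IterationState:
    """One adjustment step: shift SNP j's effect-allele haplotypes by O_j - U_j.

    Shifting every haplotype in the effect-allele group by delta moves that
    group's weighted mean by exactly delta and leaves the baseline group
    untouched, so the new implied marginal of SNP j equals O_j.
    """
    if not 0 <= j < table.n_snps:
        raise DimensionError(f"SNP index {j} out of range")
    delta = O[j] - state.U[j]
    Z = state.Z + delta * table.M[:, j]
    U = estimate_marginal(table, Z)
    V = state.V.copy()
    V[j] += delta
    return IterationState(
        g=state.g + 1, V=V, Z=Z, U=U, deviations=np.abs(U - O)
    )


def run_haprap(
    table: HaplotypeTable,
    O: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
) -> JointEstimate:
    """Full run: seeded random start, adjust-worst-SNP sweeps, pseudoinverse.

    The loop iterates the mathematically equivalent marginal-space recursion
    ``U <- U + delta A[:, j]`` (A has unit diagonal), accumulating the per-SNP
    adjustment totals; the haplotype effects are reconstituted at the end as
    ``Z = M (V0 + cum)``.  This keeps a 2000-replicate bootstrap affordable
    without changing a single iterate.

    Raises :class:`NonConvergenceError` (with the residual trajectory) if the
    deviation criterion is not met within ``max_iter`` sweeps.
    """
    O = np.asarray(O, dtype=np.float64)
    J = table.n_snps
    if O.shape != (J,):
        raise DimensionError(f"O has shape {O.shape}, table has {J} SNPs")
    V0 = init_joint_effects(J, seed)
    A = snp_effect_operator(table)
    U = A @ V0
    cum = np.zeros(J)
    trajectory: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = O - U
        worst = int(np.argmax(np.abs(resid)))
        max_dev = abs(resid[worst])
        trajectory.append(max_dev)
        if max_dev < tol:
            converged = True
            it -= 1
            break
        delta = resid[worst]
        cum[worst] += delta
        U = U + delta * A[:, worst]
    if not converged:
        raise NonConvergenceError(
            f"no convergence after {max_iter} iterations "
            f"(last max deviation {trajectory[-1]:.3e})",
            trajectory=np.asarray(trajectory),
        )
    Z = table.M @ (V0 + cum)
    Mf = table.M.astype(np.float64)
    if np.linalg.matrix_rank(Mf) < J:
        warnings.warn(
            "haplotype matrix is column-rank-deficient; joint effects are the "
            "minimum-norm solution and not uniquely identified",
            RuntimeWarning,
            stacklevel=2,
        )
    V, *_ = np.linalg.lstsq(Mf, Z, rcond=None)
    return JointEstimate(
        V=V,
        converged=True,
        iterations=it,
        max_residual=float(np.abs(A @ V - O).max()),
        Z=Z,
    )
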