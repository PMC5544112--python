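"""Tab-separated result tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bootstrap import SelectionTrace
from .core import JointEstimate
from .panel import HaplotypeTable
from .sumstats import MarginalStats


def joint_estimate_frame(
    table: HaplotypeTable, stats: MarginalStats, fit: JointEstimate
) -> pd.DataFrame:
    """Per-SNP joint estimates next to the marginal inputs."""
    return pd.DataFrame(
        {
            "SNP": [s.id for s in table.snps],
            "chrom": [s.chrom for s in table.snps],
            "pos": [s.pos for s in table.snps],
            "effect_allele": [s.effect_allele for s in table.snps],
            "freq": stats.freq,
            "b_marginal": stats.beta,
            "se_marginal": stats.se,
            "b_joint": fit.V,
            "iterations": fit.iterations,
            "converged": fit.converged,
        }
    )


def selection_frame(trace: SelectionTrace, all_snps: list[str]) -> pd.DataFrame:
    """Selection report: retained SNPs with bootstrap stats, eliminated
    SNPs with the step at which they left the model (step_eliminated = NA
    for retained SNPs)."""
    step_of = {s.snp: i + 1 for i, s in enumerate(trace.steps)}
    p_at = {s.snp: s.p_value for s in trace.steps}
    final = {s: i for i, s in enumerate(trace.final_snps)}
    rows = []
    for snp in all_snps:
        if snp in final:
            i = final[snp]
            rows.append(
                {
                    "SNP": snp,
                    "b_joint": trace.b_joint[i],
                    "se_joint": trace.se_joint[i],
                    "p_joint": trace.p_joint[i],
                    "step_eliminated": "NA",
                }
            )
        else:
            rows.append(
                {
                    "SNP": snp,
                    "b_joint": np.nan,
                    "se_joint": np.nan,
                    "p_joint": p_at.get(snp, np.nan),
                    "step_eliminated": step_of.get(snp, "NA"),
                }
            )
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
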