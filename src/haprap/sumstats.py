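"""Marginal summary statistics (COJO-style .ma text) and trait metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]


@dataclass
class MarginalStats:
    """Per-SNP marginal GWAS effects plus the trait block.

    ``beta`` is in trait units per effect allele (log-odds for binary traits).
    The trait block carries what the parametric bootstrap needs to re-simulate
    the meta-analysis: total N, and either the phenotype SD (quantitative) or
    the case proportion (binary).
    """

    snp: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    freq: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n: np.ndarray
    trait_type: str = "quantitative"
    phenotype_sd: float | None = None
    case_proportion: float | None = None
    n_total: int | None = None
    fit_ok: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.snp = np.asarray(self.snp, dtype=object)
        for name in ("freq", "beta", "se", "p"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.trait_type not in ("quantitative", "binary"):
            raise InputError(f"unknown trait type {self.trait_type!r}")
        if len(self.snp) == 0:
            raise InputError("no SNPs in summary statistics")
        # se == 0 can legitimately arise from a deterministic in-memory fit
        # (perfectly explained phenotype); negative is always wrong.  File
        # inputs are held to strict positivity in read_ma.
        if (self.se < 0).any():
            raise InputError("marginal SEs must be non-negative")
        if ((self.freq <= 0) | (self.freq >= 1)).any():
            raise InputError("effect-allele frequencies must be in (0, 1)")
        if self.n_total is None:
            self.n_total = int(self.n.max())
        if self.n_total < int(self.n.max()):
            raise InputError("n_total smaller than a per-SNP sample size")
        if self.trait_type == "quantitative":
            if self.phenotype_sd is None:
                raise InputError("quantitative trait requires phenotype_sd")
            if self.phenotype_sd <= 0:
                raise InputError("phenotype_sd must be positive")
        else:
            if self.case_proportion is None:
                raise InputError("binary trait requires case_proportion")
            if not 0 < self.case_proportion < 1:
                raise InputError("case_proportion must be in (0, 1)")
        if self.fit_ok is None:
            self.fit_ok = np.ones(len(self.snp), dtype=bool)

    def __len__(self) -> int:
        return len(self.snp)

    def subset(self, indices) -> "MarginalStats":
        idx = np.asarray(list(indices))
        return MarginalStats(
            snp=self.snp[idx],
            a1=np.asarray(self.a1, dtype=object)[idx],
            a2=np.asarray(self.a2, dtype=object)[idx],
            freq=self.freq[idx],
            beta=self.beta[idx],
            se=self.se[idx],
            p=self.p[idx],
            n=self.n[idx],
            trait_type=self.trait_type,
            phenotype_sd=self.phenotype_sd,
            case_proportion=self.case_proportion,
            n_total=self.n_total,
            fit_ok=self.fit_ok[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": self.snp,
                "A1": self.a1,
                "A2": self.a2,
                "freq": self.freq,
                "b": self.beta,
                "se": self.se,
                "p": self.p,
                "N": self.n,
            }
        )


def read_ma(
    path,
    trait_type: str = "quantitative",
    phenotype_sd: float | None = None,
    case_proportion: float | None = None,
    n_total: int | None = None,
) -> MarginalStats:
    """Read whitespace-delimited summary statistics with the .ma header.

    Expected header: ``SNP A1 A2 freq b se p N`` (A1 = effect allele).
    Trait metadata is not part of the .ma dialect and is passed separately.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except pd.errors.EmptyDataError:
        raise InputError(f"empty summary-statistics file: {path}") from None
    missing = [c for c in MA_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(
            f"{path}: missing columns {missing}; expected header "
            f"{' '.join(MA_COLUMNS)}"
        )
    if len(df) == 0:
        raise InputError(f"no SNP rows in {path}")
    if df["SNP"].duplicated().any():
        dup = df.loc[df["SNP"].duplicated(), "SNP"].iloc[0]
        raise InputError(f"{path}: duplicate SNP id {dup!r}")
    if (df["se"] <= 0).any():
        raise InputError(f"{path}: marginal SEs must be strictly positive")
    return MarginalStats(
        snp=df["SNP"].astype(str).to_numpy(dtype=object),
        a1=df["A1"].astype(str).to_numpy(dtype=object),
        a2=df["A2"].astype(str).to_numpy(dtype=object),
        freq=df["freq"].to_numpy(),
        beta=df["b"].to_numpy(),
        se=df["se"].to_numpy(),
        p=df["p"].to_numpy(),
        n=df["N"].to_numpy(),
        trait_type=trait_type,
        phenotype_sd=phenotype_sd,
        case_proportion=case_proportion,
        n_total=n_total,
    )


def write_ma(stats: MarginalStats, path) -> None:
    stats.to_frame().to_csv(path, sep=" ", index=False)
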