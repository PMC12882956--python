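"""Genome-wide scans on the discovery split.

``run_gweis`` fits, independently for each SNP j,

    outcome ~ intercept + exposure + [covariates] + g_j + g_j × exposure

and returns the per-SNP additive and interaction estimates with standard
errors and two-sided p-values.  ``run_gwas`` drops the exposure and
interaction terms.  Continuous traits use ordinary least squares; binary
traits (values in {0,1}) use logistic regression.  Genotypes enter as raw
0/1/2 allele counts so the resulting weights have per-allele units suitable
for polygenic scoring.

Monomorphic and non-converged SNPs are retained as flagged rows with null
estimates so SNP indices stay aligned with the genotype matrix; scoring
treats their weights as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _glm
from .errors import ContractError, DegenerateInputError
from .synthetic_data import GenotypeMatrix

__all__ = ["SummaryStats", "run_gweis", "run_gwas"]

LINEAR = "linear"
LOGISTIC = "logistic"


@dataclass
class SummaryStats:
    """Per-SNP estimated effects from a GWEIS (additive + interaction) or a
    plain GWAS (additive only; interaction fields are None)."""

    snp_ids: np.ndarray
    beta_add: np.ndarray
    se_add: np.ndarray
    p_add: np.ndarray
    n_used: np.ndarray
    trait_type: str
    flags: np.ndarray
    beta_gxe: Optional[np.ndarray] = None
    se_gxe: Optional[np.ndarray] = None
    p_gxe: Optional[np.ndarray] = None
    a1: Optional[np.ndarray] = None

    @property
    def is_gweis(self) -> bool:
        return self.beta_gxe is not None

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "SNP": self.snp_ids,
                "A1": self.a1 if self.a1 is not None else np.repeat("A", self.m),
                "BETA_ADD": self.beta_add,
                "SE_ADD": self.se_add,
                "P_ADD": self.p_add,
                "BETA_GXE": self.beta_gxe if self.is_gweis else np.full(self.m, np.nan),
                "SE_GXE": self.se_gxe if self.is_gweis else np.full(self.m, np.nan),
                "P_GXE": self.p_gxe if self.is_gweis else np.full(self.m, np.nan),
                "N": self.n_used,
                "FLAG": self.flags,
            }
        )
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, trait_type: str = LINEAR, is_gweis: Optional[bool] = None) -> "SummaryStats":
        df = pd.read_csv(path, sep="\t")
        if is_gweis is None:
            is_gweis = bool(np.isfinite(df["BETA_GXE"].to_numpy()).any())
        return cls(
            snp_ids=df["SNP"].to_numpy(dtype=str),
            a1=df["A1"].to_numpy(dtype=str),
            beta_add=df["BETA_ADD"].to_numpy(float),
            se_add=df["SE_ADD"].to_numpy(float),
            p_add=df["P_ADD"].to_numpy(float),
            beta_gxe=df["BETA_GXE"].to_numpy(float) if is_gweis else None,
            se_gxe=df["SE_GXE"].to_numpy(float) if is_gweis else None,
            p_gxe=df["P_GXE"].to_numpy(float) if is_gweis else None,
            n_used=df["N"].to_numpy(int),
            trait_type=trait_type,
            flags=df["FLAG"].to_numpy(dtype=object),
        )


def _infer_trait_type(values: np.ndarray) -> str:
    return LOGISTIC if np.isin(values, (0.0, 1.0)).all() else LINEAR


def _covariate_block(n: int, *columns: Optional[np.ndarray]) -> np.ndarray:
    parts = [np.ones((n, 1))]
    for col in columns:
        if col is None:
            continue
        arr = np.asarray(col, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != n:
            raise ContractError("covariate rows are not aligned with the phenotype")
        parts.append(arr)
    return np.hstack(parts)


def run_gweis(
    G: GenotypeMatrix,
    y: np.ndarray,
    c: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    chunk: int = 256,
) -> SummaryStats:
    """Per-SNP genotype + exposure + genotype×exposure scan of the outcome."""
    y = np.asarray(y, dtype=float)
    c = np.asarray(c, dtype=float)
    if len(y) != G.n or len(c) != G.n:
        raise ContractError("y/c are not aligned with the genotype matrix")
    if c.std() == 0:
        raise DegenerateInputError("exposure has zero variance")
    if G.has_missing():
        raise ContractError("scan requires complete genotypes (impute or drop missing first)")

    trait_type = _infer_trait_type(y)
    Z = _covariate_block(G.n, c, covariates)
    scalers = [np.ones(G.n), c]
    fit = _glm.batched_linear if trait_type == LINEAR else _glm.batched_logistic
    beta, se, pval, flags = fit(y, Z, G.counts, scalers, chunk=chunk)

    k = Z.shape[1]
    return SummaryStats(
        snp_ids=G.snp_ids,
        a1=G.a1,
        beta_add=beta[:, k],
        se_add=se[:, k],
        p_add=pval[:, k],
        beta_gxe=beta[:, k + 1],
        se_gxe=se[:, k + 1],
        p_gxe=pval[:, k + 1],
        n_used=np.full(G.m, G.n),
        trait_type=trait_type,
        flags=flags,
    )


def run_gwas(
    G: GenotypeMatrix,
    trait: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    chunk: int = 256,
) -> SummaryStats:
    """Per-SNP additive-only scan (no exposure, no interaction)."""
    trait = np.asarray(trait, dtype=float)
    if len(trait) != G.n:
        raise ContractError("trait is not aligned with the genotype matrix")
    if G.has_missing():
        raise ContractError("scan requires complete genotypes (impute or drop missing first)")

    trait_type = _infer_trait_type(trait)
    Z = _covariate_block(G.n, covariates)
    scalers = [np.ones(G.n)]
    fit = _glm.batched_linear if trait_type == LINEAR else _glm.batched_logistic
    beta, se, pval, flags = fit(trait, Z, G.counts, scalers, chunk=chunk)

    k = Z.shape[1]
    return SummaryStats(
        snp_ids=G.snp_ids,
        a1=G.a1,
        beta_add=beta[:, k],
        se_add=se[:, k],
        p_add=pval[:, k],
        n_used=np.full(G.m, G.n),
        trait_type=trait_type,
        flags=flags,
    )
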