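"""Polygenic scoring of the target split.

A polygenic risk score is the weighted sum of allele counts,
score_i = Σ_j W_ij · β̂_j, with weights taken from discovery-sample summary
statistics.  All SNPs are scored — no p-value thresholding or LD clumping by
default — though a significance filter can be requested.  A ``PRSBundle``
collects the score vectors a direction-specific model fit needs:

* ``g_hat_out``       additive PRS of the outcome (GWEIS additive weights)
* ``g_hat_out_gxe``   interaction-effect PRS of the outcome (GWEIS G×E weights)
* ``g_hat_out_gwas``  additive PRS of the outcome from a plain GWAS
* ``g_hat_exp``       additive PRS of the exposure (GWAS weights)

Scores are plain sums; with standardization on (the default for model
fitting) the sum-versus-average distinction is absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ContractError
from .gweis import SummaryStats
from .synthetic_data import GenotypeMatrix

__all__ = ["PRSBundle", "score", "build_bundle"]


def score(W: GenotypeMatrix, weights: np.ndarray) -> np.ndarray:
    """Per-individual weighted allele-count sum; NaN weights (flagged SNPs)
    contribute zero."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != W.m:
        raise ContractError(f"weight length {len(weights)} != SNP count {W.m}")
    if W.has_missing():
        raise ContractError("scoring requires complete genotypes")
    w = np.where(np.isfinite(weights), weights, 0.0)
    return W.counts @ w


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    centered = v - v.mean()
    return centered / sd if sd > 0 else centered


@dataclass
class PRSBundle:
    """Aligned per-individual score vectors for one analysis direction.

    Field names are role-relative: "out" is whichever trait is being modelled
    as the outcome in this direction, "exp" the trait acting as exposure.
    """

    individual_ids: np.ndarray
    g_hat_out: np.ndarray
    g_hat_out_gxe: np.ndarray
    g_hat_exp: np.ndarray
    g_hat_out_gwas: Optional[np.ndarray] = None
    standardized: bool = False

    def __post_init__(self) -> None:
        n = len(self.individual_ids)
        for name in ("g_hat_out", "g_hat_out_gxe", "g_hat_exp", "g_hat_out_gwas"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ContractError(f"{name} is not aligned with individual_ids")

    def to_frame(self) -> pd.DataFrame:
        data = {
            "IID": self.individual_ids,
            "SCORE_ADD": self.g_hat_out,
            "SCORE_GXE": self.g_hat_out_gxe,
            "SCORE_EXP_ADD": self.g_hat_exp,
        }
        if self.g_hat_out_gwas is not None:
            data["SCORE_ADD_GWAS"] = self.g_hat_out_gwas
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _weights(stats: SummaryStats, W: GenotypeMatrix, field: str, p_threshold: Optional[float]) -> np.ndarray:
    if not np.array_equal(np.asarray(stats.snp_ids), np.asarray(W.snp_ids)):
        missing = sorted(set(map(str, stats.snp_ids)) ^ set(map(str, W.snp_ids)))
        raise ContractError(f"SNP sets of summary statistics and target genotypes differ: {missing[:10]}")
    w = np.array(getattr(stats, field), dtype=float)
    if p_threshold is not None:
        pfield = "p_gxe" if field == "beta_gxe" else "p_add"
        pv = np.asarray(getattr(stats, pfield), dtype=float)
        w = np.where(np.isfinite(pv) & (pv <= p_threshold), w, 0.0)
    return w


def build_bundle(
    W: GenotypeMatrix,
    outcome_stats: SummaryStats,
    exposure_stats: SummaryStats,
    outcome_gwas_stats: Optional[SummaryStats] = None,
    standardize: bool = True,
    p_threshold: Optional[float] = None,
) -> PRSBundle:
    """Assemble the direction-specific score vectors on the target genotypes.

    ``outcome_stats`` must come from a GWEIS (it supplies both additive and
    interaction weights); ``exposure_stats`` from a plain GWAS of the exposure
    trait.  ``outcome_gwas_stats``, when given, supplies the plain-GWAS
    additive PRS of the outcome used by the Plomin-style model (Model 1).
    """
    if not outcome_stats.is_gweis:
        raise ContractError("outcome_stats must carry interaction estimates (GWEIS output)")

    g_out = score(W, _weights(outcome_stats, W, "beta_add", p_threshold))
    g_gxe = score(W, _weights(outcome_stats, W, "beta_gxe", p_threshold))
    g_exp = score(W, _weights(exposure_stats, W, "beta_add", p_threshold))
    g_out_gwas = None
    if outcome_gwas_stats is not None:
        g_out_gwas = score(W, _weights(outcome_gwas_stats, W, "beta_add", p_threshold))

    if standardize:
        g_out = _standardize(g_out)
        g_gxe = _standardize(g_gxe)
        g_exp = _standardize(g_exp)
        if g_out_gwas is not None:
            g_out_gwas = _standardize(g_out_gwas)

    return PRSBundle(
        individual_ids=W.individual_ids,
        g_hat_out=g_out,
        g_hat_out_gxe=g_gxe,
        g_hat_exp=g_exp,
        g_hat_out_gwas=g_out_gwas,
        standardized=standardize,
    )
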