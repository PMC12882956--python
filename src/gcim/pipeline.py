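"""End-to-end causal-direction test.

``run_gcim`` performs the full protocol on an aligned genotype/phenotype set:
one shared 80/20 discovery/target split, GWEIS and GWAS of both traits in the
discovery part, polygenic-score bundles on the target part, a forward and a
reverse GCIM (Model 4) fit, and a categorical direction call from the two
interaction p-values.

A single shared split serves both directions so that direction asymmetry
cannot arise from split noise.  In the reverse direction the observed outcome
acts as the interacting exposure during discovery-stage GWEIS; the PRS
substitution happens only in the target-sample Model-4 fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .errors import AnalysisError, ContractError
from .gweis import run_gwas, run_gweis
from .models import ModelFit, fit_model
from .prs import build_bundle
from .synthetic_data import Dataset, GenotypeMatrix, PhenotypePair, split_discovery_target

__all__ = ["DirectionResult", "run_gcim", "call_direction", "build_direction_bundles"]

CALLS = ("forward", "reverse", "bidirectional", "none")


def call_direction(p_forward: float, p_reverse: float, alpha: float = 0.05, n_tests: int = 1) -> str:
    """Categorical direction call from the two interaction p-values.

    The significance threshold is Bonferroni-adjusted to alpha/n_tests (e.g.
    a study testing 66 trait pairs uses 0.05/66).  Forward-only significance
    calls "forward", reverse-only "reverse", both "bidirectional", neither
    "none".
    """
    for name, p in (("p_forward", p_forward), ("p_reverse", p_reverse)):
        if not (0 < p <= 1):
            raise ContractError(f"{name} must be in (0,1], got {p}")
    if not (0 < alpha < 1):
        raise ContractError(f"alpha must be in (0,1), got {alpha}")
    if n_tests < 1:
        raise ContractError(f"n_tests must be >= 1, got {n_tests}")
    threshold = alpha / n_tests
    fwd = p_forward < threshold
    rev = p_reverse < threshold
    if fwd and rev:
        return "bidirectional"
    if fwd:
        return "forward"
    if rev:
        return "reverse"
    return "none"


@dataclass
class DirectionResult:
    """Forward and reverse Model-4 fits plus the direction call."""

    forward_fit: ModelFit
    reverse_fit: ModelFit
    alpha: float
    n_tests: int
    call: str
    extra_fits: Dict[str, ModelFit] = field(default_factory=dict)

    @property
    def p_forward(self) -> float:
        return self.forward_fit.interaction_p

    @property
    def p_reverse(self) -> float:
        return self.reverse_fit.interaction_p

    def to_dict(self) -> dict:
        return {
            "call": self.call,
            "alpha": self.alpha,
            "n_tests": self.n_tests,
            "p_forward": self.p_forward,
            "p_reverse": self.p_reverse,
            "forward_fit": self.forward_fit.to_dict(),
            "reverse_fit": self.reverse_fit.to_dict(),
            "extra_fits": {k: v.to_dict() for k, v in self.extra_fits.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_direction_bundles(
    discovery: Dataset,
    target: Dataset,
    standardize: bool = True,
    p_threshold: Optional[float] = None,
    chunk: int = 256,
):
    """Discovery-stage scans and target-stage score bundles for both
    directions.

    Forward: GWEIS of y with c as exposure, GWAS of c (exposure PRS) and GWAS
    of y (for the Plomin-style model).  Reverse mirrors with roles swapped;
    the two plain GWAS are shared between directions.
    """
    Gd, yd, cd = discovery.genotypes, discovery.phenotypes.y, discovery.phenotypes.c
    cov = discovery.covariates
    gweis_y = run_gweis(Gd, yd, cd, covariates=cov, chunk=chunk)
    gweis_c = run_gweis(Gd, cd, yd, covariates=cov, chunk=chunk)
    gwas_y = run_gwas(Gd, yd, covariates=cov, chunk=chunk)
    gwas_c = run_gwas(Gd, cd, covariates=cov, chunk=chunk)

    W = target.genotypes
    forward = build_bundle(W, gweis_y, gwas_c, outcome_gwas_stats=gwas_y,
                           standardize=standardize, p_threshold=p_threshold)
    reverse = build_bundle(W, gweis_c, gwas_y, outcome_gwas_stats=gwas_c,
                           standardize=standardize, p_threshold=p_threshold)
    return forward, reverse


def run_gcim(
    G: GenotypeMatrix,
    y: np.ndarray,
    c: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    split_seed: int = 0,
    alpha: float = 0.05,
    n_tests: int = 1,
    discovery_fraction: float = 0.8,
    fit_all_models: bool = False,
    standardize: bool = True,
    p_threshold: Optional[float] = None,
) -> DirectionResult:
    """Run the full two-direction G×E causal-direction test.

    Returns the forward and reverse GCIM fits and the direction call; with
    ``fit_all_models`` the three comparison models are fitted in both
    directions as well and attached as ``extra_fits`` keyed "M1_forward" etc.
    """
    y = np.asarray(y, dtype=float)
    c = np.asarray(c, dtype=float)
    phen = PhenotypePair(
        y=y,
        c=c,
        y_type="binary" if np.isin(y, (0.0, 1.0)).all() else "quantitative",
        c_type="binary" if np.isin(c, (0.0, 1.0)).all() else "quantitative",
    )
    discovery, target = split_discovery_target(
        G, phen, discovery_fraction=discovery_fraction, seed=split_seed, covariates=covariates
    )
    fwd_bundle, rev_bundle = build_direction_bundles(
        discovery, target, standardize=standardize, p_threshold=p_threshold
    )

    yt, ct = target.phenotypes.y, target.phenotypes.c
    cov_t = target.covariates
    forward_fit = reverse_fit = None
    errors = []
    try:
        forward_fit = fit_model("M4", yt, ct, fwd_bundle, cov_t, direction="forward")
    except Exception as exc:  # noqa: BLE001 - propagate jointly below
        errors.append(f"forward: {exc}")
    try:
        reverse_fit = fit_model("M4", ct, yt, rev_bundle, cov_t, direction="reverse")
    except Exception as exc:  # noqa: BLE001
        errors.append(f"reverse: {exc}")
    if forward_fit is None or reverse_fit is None:
        raise AnalysisError("direction fits failed: " + "; ".join(errors))

    extra: Dict[str, ModelFit] = {}
    if fit_all_models:
        for model_id in ("M1", "M2", "M3"):
            extra[f"{model_id}_forward"] = fit_model(model_id, yt, ct, fwd_bundle, cov_t,
                                                     direction="forward")
            extra[f"{model_id}_reverse"] = fit_model(model_id, ct, yt, rev_bundle, cov_t,
                                                     direction="reverse")

    call = call_direction(forward_fit.interaction_p, reverse_fit.interaction_p, alpha, n_tests)
    return DirectionResult(
        forward_fit=forward_fit,
        reverse_fit=reverse_fit,
        alpha=alpha,
        n_tests=n_tests,
        call=call,
        extra_fits=extra,
    )
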