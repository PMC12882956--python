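"""Target-sample PRS×E regressions.

Four nested interaction models are fitted on the held-out target split.  With
ĝ the additive PRS of the outcome, ĝ_g×e its interaction-effect PRS, c the
observed exposure and ĝ_c the exposure's PRS:

* **M1** (Plomin-style):  y ~ ĝ_gwas + c + ĝ_gwas⊙c — the additive PRS here
  comes from a plain GWAS of the outcome, and doubles as the interaction
  score.
* **M2** (Tang-style):    y ~ ĝ + c + ĝ_g×e⊙c
* **M3** (GxEprs):        y ~ ĝ + c + ĝ_g×e + ĝ_g×e⊙c
* **M4** (GCIM):          y ~ ĝ + c + ĝ_g×e + ĝ_g×e⊙ĝ_c — the exposure's PRS
  replaces its phenotype inside the interaction, removing the residual
  covariance channel that manufactures spurious interactions under
  heteroscedasticity or a misspecified causal direction.

The tested coefficient is the PRS×E product term (β₃ for M1/M2, β₄ for
M3/M4), assessed with a Wald test.  Binary outcomes use a logistic link.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, ContractError
from .prs import PRSBundle

__all__ = ["ModelFit", "fit_model", "fit_direction", "MODEL_IDS"]

MODEL_IDS = ("M1", "M2", "M3", "M4")


@dataclass
class ModelFit:
    """One fitted PRS×E regression and its interaction test."""

    model_id: str
    direction: str
    coefficients: Dict[str, float]
    ses: Dict[str, float]
    pvalues: Dict[str, float]
    interaction_term: str
    n: int
    outcome_type: str
    converged: bool = True

    @property
    def interaction_p(self) -> float:
        return self.pvalues[self.interaction_term]

    @property
    def interaction_beta(self) -> float:
        return self.coefficients[self.interaction_term]

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "direction": self.direction,
            "interaction_term": self.interaction_term,
            "coefficients": self.coefficients,
            "ses": self.ses,
            "pvalues": self.pvalues,
            "n": self.n,
            "outcome_type": self.outcome_type,
            "converged": self.converged,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": self.model_id,
                "direction": self.direction,
                "term": name,
                "beta": self.coefficients[name],
                "se": self.ses[name],
                "p": self.pvalues[name],
                "n": self.n,
            }
            for name in self.coefficients
        ]
        return pd.DataFrame(rows)


def _design(
    model_id: str,
    c: np.ndarray,
    bundle: PRSBundle,
    covariates: Optional[np.ndarray],
    omit_exposure_main: bool,
) -> Tuple[Dict[str, np.ndarray], str]:
    """Assemble named design columns and the interaction-term name."""
    if model_id not in MODEL_IDS:
        raise ContractError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")

    cols: Dict[str, np.ndarray] = {}
    if model_id == "M1":
        if bundle.g_hat_out_gwas is None:
            raise ContractError("Model 1 needs the plain-GWAS additive PRS of the outcome "
                                "(bundle.g_hat_out_gwas)")
        g = bundle.g_hat_out_gwas
        cols["prs_add"] = g
        if not omit_exposure_main:
            cols["exposure"] = c
        cols["prs_add_x_exposure"] = g * c
        inter = "prs_add_x_exposure"
    else:
        cols["prs_add"] = bundle.g_hat_out
        if not omit_exposure_main:
            cols["exposure"] = c
        if model_id in ("M3", "M4"):
            cols["prs_gxe"] = bundle.g_hat_out_gxe
        if model_id in ("M2", "M3"):
            cols["prs_gxe_x_exposure"] = bundle.g_hat_out_gxe * c
            inter = "prs_gxe_x_exposure"
        else:  # M4
            cols["prs_gxe_x_prs_exp"] = bundle.g_hat_out_gxe * bundle.g_hat_exp
            inter = "prs_gxe_x_prs_exp"

    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        for i in range(cov.shape[1]):
            cols[f"covar{i + 1}"] = cov[:, i]
    return cols, inter


def _check_rank(names: Sequence[str], X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # grow the column set and report the columns that add no rank
    aliased = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(names[j])
    raise CollinearityError(aliased)


def fit_model(
    model_id: str,
    y_t: np.ndarray,
    c_t: np.ndarray,
    bundle: PRSBundle,
    covariates: Optional[np.ndarray] = None,
    direction: str = "forward",
    omit_exposure_main: bool = False,
) -> ModelFit:
    """Fit one PRS×E model on the target split and Wald-test its interaction.

    ``c_t`` is the observed exposure phenotype; Model 4 additionally uses the
    exposure's PRS from the bundle inside the interaction term.
    """
    y_t = np.asarray(y_t, dtype=float)
    c_t = np.asarray(c_t, dtype=float)
    n = len(y_t)
    if len(c_t) != n or len(bundle.g_hat_out) != n:
        raise ContractError("outcome, exposure, and bundle are not aligned")

    cols, inter = _design(model_id, c_t, bundle, covariates, omit_exposure_main)
    names = ["const"] + list(cols)
    X = np.column_stack([np.ones(n)] + list(cols.values()))
    if n < X.shape[1] + 10:
        raise ContractError(f"target split too small (n={n}) for a {X.shape[1]}-column design")
    _check_rank(names, X)

    outcome_type = "logistic" if np.isin(y_t, (0.0, 1.0)).all() else "linear"
    converged = True
    if outcome_type == "linear":
        res = sm.OLS(y_t, X).fit()
    else:
        model = sm.GLM(y_t, X, family=sm.families.Binomial())
        res = model.fit(maxiter=100)
        converged = bool(getattr(res, "converged", True)) and np.isfinite(res.params).all()

    coeffs = dict(zip(names, map(float, res.params)))
    ses = dict(zip(names, map(float, res.bse)))
    pvals = dict(zip(names, map(float, res.pvalues)))
    return ModelFit(
        model_id=model_id,
        direction=direction,
        coefficients=coeffs,
        ses=ses,
        pvalues=pvals,
        interaction_term=inter,
        n=n,
        outcome_type=outcome_type,
        converged=converged,
    )


def fit_direction(
    direction: str,
    y_t: np.ndarray,
    c_t: np.ndarray,
    forward_bundle: PRSBundle,
    reverse_bundle: PRSBundle,
    model_id: str = "M4",
    covariates: Optional[np.ndarray] = None,
    omit_exposure_main: bool = False,
) -> ModelFit:
    """Fit a model in the requested causal direction.

    Forward models y on (its PRSs, c); reverse swaps the trait roles: c is
    modelled on its own PRSs with y acting as the exposure.  Both bundles must
    be built from the same discovery/target split.
    """
    if direction == "forward":
        return fit_model(model_id, y_t, c_t, forward_bundle, covariates,
                         direction="forward", omit_exposure_main=omit_exposure_main)
    if direction == "reverse":
        return fit_model(model_id, c_t, y_t, reverse_bundle, covariates,
                         direction="reverse", omit_exposure_main=omit_exposure_main)
    raise ContractError(f"direction must be 'forward' or 'reverse', got {direction!r}")
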