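"""Beta regression of community evenness on heterogeneity measures.

RLE evenness lives on the unit interval, so its mean is modeled with a beta
distribution and a logit link; precision phi is a single constant. Nested
models are compared with likelihood-ratio tests against the chi-squared
reference, and backward AIC elimination mirrors the count-model selection.

The likelihood machinery is statsmodels' BetaModel; this module wraps it
behind the pipeline's design/term bookkeeping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.othermod.betareg import BetaModel

from .nbglm import Design, build_design

logger = logging.getLogger(__name__)


def squeeze_unit_interval(y, n: int | None = None) -> np.ndarray:
    """Pull boundary 0/1 values strictly inside (0, 1).

    Applies the standard compression (y * (n - 1) + 0.5) / n — only when a
    boundary value is actually present; otherwise the data pass through
    unchanged. `n` defaults to the sample size.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses must lie in [0, 1]")
    if not np.any((y == 0) | (y == 1)):
        return y
    if n is None:
        n = y.size
    logger.info("boundary evenness values present; applying unit-interval squeeze (n=%d)", n)
    return (y * (n - 1) + 0.5) / n


@dataclass
class BetaRegFit:
    """Beta regression fit: logit-scale mean coefficients plus precision phi."""

    design: Design
    y: np.ndarray
    coef: pd.Series  # indexed by design columns
    phi: float
    loglik: float
    fitted: np.ndarray

    @property
    def n_params(self) -> int:
        return len(self.coef)

    @property
    def aic(self) -> float:
        # + 1 counts the precision parameter
        return -2.0 * self.loglik + 2.0 * (self.n_params + 1)


def fit_beta_logit(
    rle: pd.Series | np.ndarray,
    env: pd.DataFrame,
    terms: list[str] | None = None,
    design: Design | None = None,
) -> BetaRegFit:
    """ML beta regression of evenness on the environment design (logit link)."""
    y = squeeze_unit_interval(np.asarray(rle, dtype=float))
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("responses must be strictly inside (0, 1) after squeeze")
    if design is None:
        design = build_design(env, terms=terms)
    model = BetaModel(y, design.X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=500)
        if not res.mle_retvals.get("converged", True):
            res = model.fit(disp=0, method="bfgs", maxiter=1000,
                            start_params=res.params)
    params = np.asarray(res.params)
    mean_coefs = params[:-1]
    phi = float(np.exp(params[-1]))  # precision uses a log link internally
    if not np.isfinite(res.llf):
        raise RuntimeError("beta regression did not converge to a finite likelihood")
    eta = design.X @ mean_coefs
    fitted = 1.0 / (1.0 + np.exp(-eta))
    return BetaRegFit(
        design=design,
        y=y,
        coef=pd.Series(mean_coefs, index=design.columns),
        phi=phi,
        loglik=float(res.llf),
        fitted=fitted,
    )


def beta_lr_test(full: BetaRegFit, reduced: BetaRegFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested beta regressions: (statistic, df, p)."""
    if not set(reduced.design.term_names) <= set(full.design.term_names):
        raise ValueError("reduced model terms are not nested in the full model")
    if reduced.y.shape != full.y.shape or not np.allclose(reduced.y, full.y):
        raise ValueError("fits must share the same response")
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    df = full.n_params - reduced.n_params
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return stat, df, p


def stepwise_aic_beta(
    fit: BetaRegFit, candidate_terms: list[str] | None = None
) -> tuple[BetaRegFit, list[dict]]:
    """Backward AIC elimination for beta regression (intercept retained)."""
    current = fit
    droppable = list(candidate_terms if candidate_terms is not None else fit.design.term_names)
    path = [{"action": "start", "terms": list(droppable), "aic": current.aic}]
    while droppable:
        best_aic, best_term, best_fit = current.aic, None, None
        for t in droppable:
            sub = current.design.subset([x for x in current.design.term_names if x != t])
            trial = fit_beta_logit(current.y, env=None, design=sub)
            if trial.aic < best_aic - 1e-9:
                best_aic, best_term, best_fit = trial.aic, t, trial
        if best_term is None:
            break
        droppable.remove(best_term)
        current = best_fit
        path.append({"action": f"drop {best_term}",
                     "terms": list(current.design.term_names), "aic": best_aic})
    return current, path
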