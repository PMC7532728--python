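"""Negative-binomial regressions for the field-survey stage.

Covers the three field analyses in simplified form: (a) the cross-species
abundance association at both plot scales, (b) selection among nested
fecundity-proxy models by AIC, and (c) density dependence and
environmental effects on predicted fecundity.  All models are NB2 GLMs
with a log link fitted by maximum likelihood (dispersion estimated
jointly with the coefficients, via statsmodels).  Spatial grouping
factors (site, transect) are absorbed as categorical fixed adjustments —
a documented approximation to random intercepts that keeps the inferential
targets (fixed-effect signs and likelihood ratios) intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

__all__ = [
    "RegressionFit",
    "ModelComparison",
    "fit_nb_regression",
    "lrt",
    "aic_select",
    "predict_fecundity",
]


@dataclass
class RegressionFit:
    """An NB2 log-link regression fit with in-module AIC accounting."""

    response: str
    predictors: tuple[str, ...]
    grouping: tuple[str, ...]
    coef: dict[str, float]
    se: dict[str, float]
    loglik: float
    k: int  # parameter count including the NB dispersion
    aic: float
    converged: bool
    dispersion_alpha: float
    result: object = field(repr=False, default=None)  # statsmodels results

    @property
    def family(self) -> str:
        return "negative binomial (NB2)"

    @property
    def link(self) -> str:
        return "log"


def _formula(response: str, predictors, grouping) -> str:
    terms = list(predictors) + [f"C({g})" for g in grouping]
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def fit_nb_regression(
    table: pd.DataFrame,
    response: str,
    predictors=(),
    grouping=(),
) -> RegressionFit:
    """Fit an NB2 GLM (log link) of ``response`` on ``predictors``.

    ``grouping`` names columns absorbed as categorical fixed adjustments.
    The response must be a non-negative integer count column.  Failure to
    converge (including quasi-separation) is flagged on the result, never
    silent.
    """
    y = table[response]
    if (y < 0).any():
        raise ValueError(f"response {response!r} has negative entries; counts required")
    if not np.allclose(y, np.round(y)):
        raise ValueError(f"response {response!r} is not integer-valued")

    formula = _formula(response, predictors, grouping)
    model = sm.NegativeBinomial.from_formula(formula, data=table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="lbfgs", maxiter=500, disp=0)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res = model.fit(method="nm", maxiter=5000, disp=0)
            converged = bool(res.mle_retvals.get("converged", False))
        # polish with Newton when the first pass failed or left NaN SEs
        if not converged or not np.all(np.isfinite(res.bse)):
            try:
                res2 = model.fit(method="newton", maxiter=200, disp=0, start_params=res.params)
                if bool(res2.mle_retvals.get("converged", False)):
                    res, converged = res2, True
            except Exception:
                pass

    params = dict(res.params)
    bse = dict(res.bse)
    alpha = float(params.pop("alpha", np.nan))
    bse.pop("alpha", None)
    k = len(res.params)  # includes the dispersion parameter
    ll = float(res.llf)
    return RegressionFit(
        response=response,
        predictors=tuple(predictors),
        grouping=tuple(grouping),
        coef={str(c): float(v) for c, v in params.items()},
        se={str(c): float(v) for c, v in bse.items()},
        loglik=ll,
        k=k,
        aic=2 * k - 2 * ll,
        converged=converged,
        dispersion_alpha=alpha,
        result=res,
    )


@dataclass(frozen=True)
class ModelComparison:
    """Outcome of a likelihood-ratio test or an AIC model-selection pass."""

    rule: str  # "lrt" | "aic>threshold"
    selected: str
    statistics: dict[str, float]
    candidates: tuple[str, ...] = ()


def _label(fit: RegressionFit) -> str:
    return " + ".join(fit.predictors) if fit.predictors else "intercept-only"


def lrt(full: RegressionFit, reduced: RegressionFit) -> ModelComparison:
    """Likelihood-ratio test of a reduced model nested within a full model.

    chi2 = 2 * (ll_full - ll_reduced), df = difference in parameter
    counts, p from the chi-square upper tail.
    """
    if full.response != reduced.response:
        raise ValueError("models have different responses; not nested")
    if not set(reduced.predictors) <= set(full.predictors) or not (
        set(reduced.grouping) <= set(full.grouping)
    ):
        raise ValueError("reduced model is not nested in the full model")
    df = full.k - reduced.k
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    if df == 0 and stat == 0.0:
        p = 1.0
    return ModelComparison(
        rule="lrt",
        selected=_label(full) if (df > 0 and p < 0.05) else _label(reduced),
        statistics={"chi2": stat, "df": float(df), "p": p},
        candidates=(_label(reduced), _label(full)),
    )


def lrt_pvalue(stat: float, df: int) -> float:
    """Closed-form chi-square upper-tail p-value for a likelihood-ratio statistic."""
    return float(chi2.sf(stat, df))


def aic_select(candidates, threshold: float = 2.0) -> ModelComparison:
    """Select among nested candidates ordered from simplest to most complex.

    Walking up in complexity, a more complex model replaces the current
    choice only when its AIC is lower by more than ``threshold`` — the
    parsimony rule used for the fecundity-proxy models.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    best = candidates[0]
    for cand in candidates[1:]:
        if best.aic - cand.aic > threshold:
            best = cand
    deltas = {_label(c): float(c.aic - best.aic) for c in candidates}
    return ModelComparison(
        rule=f"aic>{threshold:g}",
        selected=_label(best),
        statistics=deltas,
        candidates=tuple(_label(c) for c in candidates),
    )


def predict_fecundity(fit: RegressionFit, table: pd.DataFrame) -> np.ndarray:
    """Predicted mean seed counts (log link => positive) for new individuals.

    Predictions can be attached back to plots for the downstream
    density-dependence regressions.  An empty table yields an empty
    array; missing predictor columns raise.
    """
    missing = [c for c in fit.predictors if c not in table.columns]
    if missing:
        raise KeyError(f"missing predictor columns: {missing}")
    if len(table) == 0:
        return np.empty(0)
    return np.asarray(fit.result.predict(table), dtype=float)
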