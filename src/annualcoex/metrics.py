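"""Coexistence metrics for a two-species Beverton--Holt annual-plant pair.

Modern coexistence theory partitions the outcome of competition between a
resident pair into a stabilizing niche difference (1 - rho) and an average
fitness ratio kappa_j / kappa_i.  For the Beverton--Holt model these are
pure functions of the fitted parameters:

    rho                  = sqrt((a_ij * a_ji) / (a_ii * a_jj))
    demographic ratio    = (lambda_j - 1) / (lambda_i - 1)
    competitive response = sqrt((a_ii * a_ij) / (a_jj * a_ji))     (i over j)
    kappa_j / kappa_i    = demographic ratio * competitive response

Coexistence requires rho < kappa_j/kappa_i < 1/rho.  The same prediction
follows from mutual invasibility: species j at vanishing density grows
against resident i at its single-species equilibrium by the factor

    IGR(j into i) = lambda_j / (1 + a_ji * (lambda_i - 1) / a_ii)

and coexistence means both invasion growth rates exceed 1.  For this model
the two routes agree exactly: kappa > rho  iff  IGR(j into i) > 1 and
kappa < 1/rho  iff  IGR(i into j) > 1.

All metric functions accept scalars or numpy arrays; invalid entries in
array input yield NaN, while invalid scalar input raises ``ValueError``.
Germination fractions are estimated elsewhere but deliberately not folded
into these formulas by default; ``eta = lambda * g`` variants are available
via the ``germination`` arguments for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "niche_overlap",
    "demographic_ratio",
    "competitive_response_ratio",
    "fitness_ratio",
    "invasion_growth_rate",
    "classify_outcome",
    "summarize_pair",
    "CoexistenceSummary",
    "OUTCOME_LABELS",
    "BOUNDARY_TOL",
]

OUTCOME_LABELS = ("coexistence", "i_excludes_j", "j_excludes_i", "priority_effect", "indeterminate")

#: classification boundary tolerance on |kappa - rho| and |kappa - 1/rho|
BOUNDARY_TOL = 1e-9


def _as_arrays(*vals):
    arrs = [np.asarray(v, dtype=float) for v in vals]
    scalar = all(a.ndim == 0 for a in arrs)
    return arrs, scalar


def _guard(result, bad, scalar, msg):
    if scalar:
        if bool(bad):
            raise ValueError(msg)
        return float(result)
    return np.where(bad, np.nan, result)


def niche_overlap(alpha_ii, alpha_ij, alpha_jj, alpha_ji):
    """Niche overlap rho; 1 - rho is the stabilizing niche difference.

    rho = 1 exactly when a_ii = a_ij and a_jj = a_ji (each species limits
    itself and its competitor identically, so there is no stabilization).
    All four coefficients must be positive.
    """
    (aii, aij, ajj, aji), scalar = _as_arrays(alpha_ii, alpha_ij, alpha_jj, alpha_ji)
    bad = (aii <= 0) | (aij <= 0) | (ajj <= 0) | (aji <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.sqrt((aij * aji) / (aii * ajj))
    return _guard(rho, bad, scalar, "niche overlap undefined: all alphas must be > 0")


def demographic_ratio(lambda_j, lambda_i):
    """Demographic-potential ratio (lambda_j - 1)/(lambda_i - 1), j over i.

    Values > 1 mean species j has the higher demographic potential.  Both
    fecundities must exceed 1 (a non-replacing population has no defined
    ratio here).
    """
    (lj, li), scalar = _as_arrays(lambda_j, lambda_i)
    bad = (li <= 1) | (lj <= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (lj - 1.0) / (li - 1.0)
    return _guard(r, bad, scalar, "demographic ratio requires lambda_i, lambda_j > 1")


def competitive_response_ratio(alpha_ii, alpha_ij, alpha_jj, alpha_ji):
    """Competitive-response (sensitivity) ratio of i over j.

    sqrt((a_ii * a_ij)/(a_jj * a_ji)); < 1 means species i is less
    sensitive to competition than species j.
    """
    (aii, aij, ajj, aji), scalar = _as_arrays(alpha_ii, alpha_ij, alpha_jj, alpha_ji)
    bad = (aii <= 0) | (aij <= 0) | (ajj <= 0) | (aji <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.sqrt((aii * aij) / (ajj * aji))
    return _guard(r, bad, scalar, "competitive response ratio undefined: all alphas must be > 0")


def fitness_ratio(lambda_i, lambda_j, alpha_ii, alpha_ij, alpha_jj, alpha_ji):
    """Average fitness ratio kappa_j / kappa_i.

    Exactly the product of the demographic ratio (j over i) and the
    competitive response ratio (i over j); > 1 favours species j absent
    niche differences.
    """
    return demographic_ratio(lambda_j, lambda_i) * competitive_response_ratio(
        alpha_ii, alpha_ij, alpha_jj, alpha_ji
    )


def invasion_growth_rate(lambda_j, lambda_i, alpha_ji, alpha_ii):
    """Low-density growth rate of invader j against resident i at equilibrium.

    lambda_j / (1 + a_ji * (lambda_i - 1)/a_ii).  Values > 1 mean j can
    invade i.  The resident needs lambda_i > 1 and a_ii > 0 to have a
    positive single-species equilibrium density (lambda_i - 1)/a_ii.
    """
    (lj, li, aji, aii), scalar = _as_arrays(lambda_j, lambda_i, alpha_ji, alpha_ii)
    bad = (li <= 1) | (aii <= 0) | (aji < 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        igr = lj / (1.0 + aji * (li - 1.0) / aii)
    return _guard(
        igr, bad, scalar, "invasion growth rate requires lambda_i > 1, alpha_ii > 0, alpha_ji >= 0"
    )


def classify_outcome(rho: float, kappa: float, tol: float = BOUNDARY_TOL) -> str:
    """Classify the long-term outcome from (rho, kappa_j/kappa_i).

    coexistence iff rho < kappa < 1/rho (possible only when rho < 1);
    kappa <= rho means i excludes j; kappa >= 1/rho means j excludes i;
    with rho > 1 and 1/rho < kappa < rho the initially commoner species
    wins (priority effect).  Values within ``tol`` of a boundary return
    "indeterminate" rather than an arbitrary side.
    """
    rho = float(rho)
    kappa = float(kappa)
    if not (rho > 0 and kappa > 0) or not (np.isfinite(rho) and np.isfinite(kappa)):
        raise ValueError("classification requires finite positive rho and kappa")
    inv = 1.0 / rho
    if abs(kappa - rho) < tol or abs(kappa - inv) < tol:
        return "indeterminate"
    if rho < 1.0:
        if kappa <= rho:
            return "i_excludes_j"
        if kappa >= inv:
            return "j_excludes_i"
        return "coexistence"
    if rho > 1.0:
        if kappa >= rho:
            return "j_excludes_i"
        if kappa <= inv:
            return "i_excludes_j"
        return "priority_effect"
    # rho == 1 exactly: no stabilization, fitness decides
    return "i_excludes_j" if kappa < 1.0 else "j_excludes_i"


# ---------------------------------------------------------------------------
# Pair summary

#: order of the joint parameter vector used for uncertainty propagation
PAIR_PARAM_NAMES = ("lambda_i", "alpha_ii", "alpha_ij", "lambda_j", "alpha_jj", "alpha_ji")

METRIC_FUNCS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    # each takes x with columns PAIR_PARAM_NAMES (last axis) and vectorises
    "rho": lambda x: niche_overlap(x[..., 1], x[..., 2], x[..., 4], x[..., 5]),
    "niche_difference": lambda x: 1.0 - niche_overlap(x[..., 1], x[..., 2], x[..., 4], x[..., 5]),
    "demographic_ratio": lambda x: demographic_ratio(x[..., 3], x[..., 0]),
    "competitive_response_ratio": lambda x: competitive_response_ratio(
        x[..., 1], x[..., 2], x[..., 4], x[..., 5]
    ),
    "fitness_ratio": lambda x: fitness_ratio(
        x[..., 0], x[..., 3], x[..., 1], x[..., 2], x[..., 4], x[..., 5]
    ),
    "igr_i_into_j": lambda x: invasion_growth_rate(x[..., 0], x[..., 3], x[..., 2], x[..., 4]),
    "igr_j_into_i": lambda x: invasion_growth_rate(x[..., 3], x[..., 0], x[..., 5], x[..., 1]),
}


@dataclass
class CoexistenceSummary:
    """All derived coexistence quantities for one treatment, with SEs."""

    treatment: str
    species_i: str
    species_j: str
    values: dict[str, float]
    se: dict[str, float]
    se_method: str
    outcome: str

    def to_frame(self):
        import pandas as pd

        row = {"treatment": self.treatment, "outcome": self.outcome, "se_method": self.se_method}
        for k, v in self.values.items():
            row[k] = v
            row[f"{k}_se"] = self.se.get(k, np.nan)
        return pd.DataFrame([row])

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.values.items()}


def pair_vector(estimates_i: dict, estimates_j: dict) -> np.ndarray:
    """Assemble the joint (lambda_i, a_ii, a_ij, lambda_j, a_jj, a_ji) vector.

    ``estimates_i`` / ``estimates_j`` are per-focal fit estimates keyed by
    lam/alpha_intra/alpha_inter (as produced by the fitting module).
    """
    return np.array(
        [
            estimates_i["lam"],
            estimates_i["alpha_intra"],
            estimates_i["alpha_inter"],
            estimates_j["lam"],
            estimates_j["alpha_jj"] if "alpha_jj" in estimates_j else estimates_j["alpha_intra"],
            estimates_j["alpha_ji"] if "alpha_ji" in estimates_j else estimates_j["alpha_inter"],
        ],
        dtype=float,
    )


def evaluate_metrics(x: np.ndarray, germination: tuple[float, float] | None = None) -> dict[str, float]:
    """Evaluate every coexistence metric at a joint parameter vector.

    With ``germination=(g_i, g_j)`` the demographic terms use the
    effective per-seed rate eta = lambda * g instead of lambda (a
    sensitivity variant; the default reporting convention uses lambda
    alone, which is how the reference estimates were published).
    """
    x = np.asarray(x, dtype=float)
    if germination is not None:
        x = x.copy()
        x[..., 0] = x[..., 0] * germination[0]
        x[..., 3] = x[..., 3] * germination[1]
    return {name: float(fn(x)) for name, fn in METRIC_FUNCS.items()}


def summarize_pair(
    fit_i,
    fit_j,
    boots_i=None,
    boots_j=None,
    *,
    se_method: str | None = None,
    germination: tuple[float, float] | None = None,
) -> CoexistenceSummary:
    """Assemble the full coexistence summary for one treatment.

    ``fit_i`` and ``fit_j`` are :class:`~annualcoex.fitting.CompetitionFit`
    results for the two focal species in the same treatment.  Standard
    errors come from the paired bootstrap when replicate sets are supplied
    (the reporting default), otherwise from first-order Taylor propagation
    through the block-diagonal observed-information covariance (fits of
    the two focal species are treated as independent).
    """
    if fit_i.treatment != fit_j.treatment:
        raise ValueError(
            f"treatment mismatch: {fit_i.treatment!r} (focal {fit_i.focal}) vs "
            f"{fit_j.treatment!r} (focal {fit_j.focal})"
        )
    from . import uncertainty

    x = pair_vector(fit_i.estimates, fit_j.estimates)
    values = evaluate_metrics(x, germination=germination)

    if se_method is None:
        se_method = "bootstrap" if boots_i is not None and boots_j is not None else "taylor1"

    se: dict[str, float] = {}
    if se_method == "bootstrap":
        if boots_i is None or boots_j is None:
            raise ValueError("bootstrap SEs requested but replicate sets missing")
        for name, fn in METRIC_FUNCS.items():
            res = uncertainty.bootstrap_metric_se(boots_i, boots_j, fn, name=name)
            se[name] = res.sd
    else:
        order = 2 if se_method == "taylor2" else 1
        cov = np.zeros((6, 6))
        cov[:3, :3] = fit_i.cov[:3, :3]
        cov[3:, 3:] = fit_j.cov[:3, :3]
        for name, fn in METRIC_FUNCS.items():
            res = uncertainty.taylor_propagate(fn, x, cov, order=order, name=name)
            se[name] = res.sd

    rho, kappa = values["rho"], values["fitness_ratio"]
    outcome = classify_outcome(rho, kappa) if np.isfinite(rho) and np.isfinite(kappa) else "indeterminate"
    return CoexistenceSummary(
        treatment=fit_i.treatment,
        species_i=fit_i.focal,
        species_j=fit_j.focal,
        values=values,
        se=se,
        se_method=se_method,
        outcome=outcome,
    )
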