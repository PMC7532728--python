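"""Maximum-likelihood Beverton--Holt competition fits to seed-count data.

For one focal species in one treatment the mean model is

    mu(N) = lambda / (1 + alpha_intra * N_intra + alpha_inter * N_inter)

with NB2 negative-binomial error (variance mu + mu^2/theta).  Both
interaction coefficients are fitted jointly in a single likelihood because
the no-neighbour pots are shared by the intraspecific and interspecific
density gradients.  lambda and theta are optimised on the log scale;
alphas are log-scaled too by default, which enforces competitive (>= 0)
interactions — a flag releases that constraint for facilitation.

Uncertainty comes from two routes: the observed-information covariance of
the ML fit, and a nonparametric bootstrap stratified within each
neighbour-type x density cell (preserving the design), whose mean/SD are
the headline estimate/SE convention used in reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import nbinom
from statsmodels.tools import numdiff

__all__ = [
    "CompetitionFit",
    "BootstrapFits",
    "GerminationEstimate",
    "nb_loglik",
    "fit_competition_model",
    "bootstrap_fit",
    "estimate_germination",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("lam", "alpha_intra", "alpha_inter", "theta")

_LOG_BOUNDS = [(-7.0, 17.0), (-19.0, 7.0), (-19.0, 7.0), (-7.0, 14.0)]


def _subset(table: pd.DataFrame, focal: str | None, treatment: str | None) -> pd.DataFrame:
    sub = table
    if focal is not None:
        sub = sub[sub["focal"] == focal]
    if treatment is not None:
        sub = sub[sub["treatment"] == treatment]
    if len(sub) == 0:
        raise ValueError(f"no rows for focal={focal!r}, treatment={treatment!r}")
    return sub


def _densities(sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = sub["neighbour_density"].to_numpy(dtype=float)
    is_con = (sub["neighbour"] == "conspecific").to_numpy()
    is_het = (sub["neighbour"] == "heterospecific").to_numpy()
    return sub["seeds"].to_numpy(dtype=float), np.where(is_con, n, 0.0), np.where(is_het, n, 0.0)


def nb_loglik(
    params,
    table: pd.DataFrame,
    focal: str | None = None,
    treatment: str | None = None,
) -> float:
    """Total NB2 log-likelihood of (lam, alpha_intra, alpha_inter, theta).

    The table must already be (or be filterable to) a single focal x
    treatment subset.  Raises on an empty subset or a non-positive mean.
    """
    lam, a_intra, a_inter, theta = (float(p) for p in params)
    if theta <= 0:
        raise ValueError("theta must be > 0")
    y, n_intra, n_inter = _densities(_subset(table, focal, treatment))
    mu = lam / (1.0 + a_intra * n_intra + a_inter * n_inter)
    if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
        raise ValueError("non-positive Beverton-Holt mean for at least one pot")
    return float(nbinom.logpmf(y, theta, theta / (theta + mu)).sum())


@dataclass
class CompetitionFit:
    """ML fit of the Beverton--Holt NB2 model for one focal x treatment."""

    focal: str
    treatment: str
    estimates: dict[str, float]
    se: dict[str, float]
    cov: np.ndarray  # 4x4, natural scale, order PARAM_NAMES
    loglik: float
    converged: bool
    n_obs: int
    n_starts: int
    message: str = ""
    # filled by callers that run a bootstrap; mirrors the reporting
    # convention of bootstrap mean as headline estimate, SD as SE
    bootstrap_mean: dict[str, float] | None = None
    bootstrap_se: dict[str, float] | None = None

    @property
    def params_array(self) -> np.ndarray:
        return np.array([self.estimates[k] for k in PARAM_NAMES])


def _check_design(sub: pd.DataFrame, focal: str, treatment: str) -> None:
    has0 = bool((sub["neighbour_density"] == 0).any())
    if not has0:
        raise ValueError(f"no N=0 pots for focal={focal}, treatment={treatment}")
    for neigh in ("conspecific", "heterospecific"):
        cell = (sub["neighbour"] == neigh) & (sub["neighbour_density"] > 0)
        if not bool(cell.any()):
            raise ValueError(
                f"degenerate design: no positive-density {neigh} pots for "
                f"focal={focal}, treatment={treatment}; alpha unidentifiable"
            )


def _neg_loglik_factory(y, n_intra, n_inter, log_alpha: bool):
    def negll(x: np.ndarray) -> float:
        lam = np.exp(x[0])
        theta = np.exp(x[3])
        a_i = np.exp(x[1]) if log_alpha else x[1]
        a_j = np.exp(x[2]) if log_alpha else x[2]
        denom = 1.0 + a_i * n_intra + a_j * n_inter
        if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
            return 1e12
        mu = lam / denom
        ll = nbinom.logpmf(y, theta, theta / (theta + mu)).sum()
        if not np.isfinite(ll):
            return 1e12
        return -float(ll)

    return negll


def fit_competition_model(
    table: pd.DataFrame,
    focal: str,
    treatment: str,
    *,
    allow_negative_alpha: bool = False,
    alpha_starts: tuple[float, ...] = (0.01, 0.1, 1.0),
    tol: float = 1e-8,
) -> CompetitionFit:
    """Jointly fit (lambda, alpha_intra, alpha_inter, theta) by ML.

    Multi-start L-BFGS-B over log-scaled parameters: lambda starts at the
    mean seed count of the no-neighbour pots, alphas at each value in
    ``alpha_starts``, theta at a method-of-moments value from the N=0
    pots.  The covariance is the inverse observed information, mapped to
    the natural scale by the delta method.  Non-convergence is flagged,
    never silent.
    """
    sub = _subset(table, focal, treatment)
    n_missing = int(sub["seeds"].isna().sum())
    if n_missing:
        logger.info("dropping %d rows with missing seed counts", n_missing)
        sub = sub.dropna(subset=["seeds"])
    _check_design(sub, focal, treatment)
    y, n_intra, n_inter = _densities(sub)

    y0 = y[(n_intra == 0) & (n_inter == 0)]
    lam0 = max(float(np.mean(y0)), 0.5)
    m = float(np.mean(y0))
    v = float(np.var(y0, ddof=1)) if len(y0) > 1 else 0.0
    theta0 = float(np.clip(m * m / (v - m), 0.2, 50.0)) if v > m > 0 else 5.0

    if allow_negative_alpha:
        warnings.warn(
            "alpha constraint released: negative (facilitative) interaction "
            "coefficients permitted",
            stacklevel=2,
        )
    log_alpha = not allow_negative_alpha
    negll = _neg_loglik_factory(y, n_intra, n_inter, log_alpha)

    best = None
    for a0 in alpha_starts:
        x0 = np.array(
            [
                np.log(lam0),
                np.log(a0) if log_alpha else a0,
                np.log(a0) if log_alpha else a0,
                np.log(theta0),
            ]
        )
        bounds = list(_LOG_BOUNDS)
        if not log_alpha:
            bounds[1] = bounds[2] = (-10.0, 1e3)
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": tol, "maxiter": 500}
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    xhat = best.x
    converged = bool(best.success)
    # observed information on the optimisation scale; relative step 1e-4
    # (second differences at machine-tiny steps are cancellation-dominated)
    try:
        H = numdiff.approx_hess1(xhat, negll, epsilon=1e-4 * np.maximum(np.abs(xhat), 1.0))
        H = 0.5 * (H + H.T)
        cov_opt = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_opt = np.full((4, 4), np.nan)
        converged = False

    if log_alpha:
        est = np.exp(xhat)
        jac = np.diag(est)
    else:
        est = np.array([np.exp(xhat[0]), xhat[1], xhat[2], np.exp(xhat[3])])
        jac = np.diag([est[0], 1.0, 1.0, est[3]])
    cov = jac @ cov_opt @ jac
    cov = 0.5 * (cov + cov.T)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    return CompetitionFit(
        focal=focal,
        treatment=treatment,
        estimates=dict(zip(PARAM_NAMES, map(float, est))),
        se=dict(zip(PARAM_NAMES, map(float, se))),
        cov=cov,
        loglik=-float(best.fun),
        converged=converged,
        n_obs=len(y),
        n_starts=len(alpha_starts),
        message=str(best.message),
    )


@dataclass
class BootstrapFits:
    """Per-replicate parameter estimates from a design-stratified bootstrap."""

    focal: str
    treatment: str
    replicates: pd.DataFrame  # columns PARAM_NAMES + converged
    n_boot: int
    n_excluded: int
    seed: int
    stratification: str = "neighbour-type x density cells, pots resampled with replacement"

    def _ok(self) -> pd.DataFrame:
        return self.replicates[self.replicates["converged"]]

    def mean(self) -> dict[str, float]:
        """Bootstrap means — the headline estimates in reporting."""
        return {k: float(self._ok()[k].mean()) for k in PARAM_NAMES}

    def sd(self) -> dict[str, float]:
        """Bootstrap SDs — reported as standard errors."""
        return {k: float(self._ok()[k].std(ddof=1)) for k in PARAM_NAMES}

    def params_matrix(self) -> np.ndarray:
        """(n_ok, 4) array of converged replicate estimates, order PARAM_NAMES."""
        return self._ok()[list(PARAM_NAMES)].to_numpy()


def bootstrap_fit(
    table: pd.DataFrame,
    focal: str,
    treatment: str,
    n_boot: int = 50,
    rng_seed: int = 0,
    **fit_kwargs,
) -> BootstrapFits:
    """Nonparametric bootstrap of the competition fit, 50 replicates by default.

    Pots are resampled with replacement within each neighbour-type x
    density stratum so every replicate keeps the experimental design.
    Replicates are warm-started at the full-data ML estimates; any
    replicate that fails to converge is flagged and excluded from the
    summaries with a logged count.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2 (bootstrap SD undefined otherwise)")
    sub = _subset(table, focal, treatment).reset_index(drop=True)
    full = fit_competition_model(sub, focal, treatment, **fit_kwargs)
    strata = [idx.to_numpy() for _, idx in sub.groupby(["neighbour", "neighbour_density"]).groups.items()]
    if any(len(s) == 0 for s in strata):
        raise ValueError("empty bootstrap stratum")

    warm = tuple(float(full.estimates[k]) for k in ("alpha_intra", "alpha_inter"))
    rng = np.random.default_rng(rng_seed)
    rows = []
    for _ in range(n_boot):
        idx = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
        boot = sub.loc[idx]
        try:
            f = fit_competition_model(
                boot, focal, treatment, alpha_starts=(max(warm[0], 1e-6),), **fit_kwargs
            )
            if not f.converged:
                f = fit_competition_model(boot, focal, treatment, **fit_kwargs)
            rows.append([f.estimates[k] for k in PARAM_NAMES] + [f.converged])
        except (ValueError, np.linalg.LinAlgError):
            rows.append([np.nan] * 4 + [False])
    reps = pd.DataFrame(rows, columns=list(PARAM_NAMES) + ["converged"])
    n_excluded = int((~reps["converged"]).sum())
    if n_excluded:
        logger.info(
            "bootstrap (%s, %s): %d/%d replicates failed to converge and were excluded",
            focal,
            treatment,
            n_excluded,
            n_boot,
        )
    return BootstrapFits(
        focal=focal,
        treatment=treatment,
        replicates=reps,
        n_boot=n_boot,
        n_excluded=n_excluded,
        seed=rng_seed,
    )


@dataclass(frozen=True)
class GerminationEstimate:
    species: str
    g: float
    se: float
    germinated: int
    sown: int


def estimate_germination(trials: pd.DataFrame) -> dict[str, GerminationEstimate]:
    """Pooled germination fraction per species with a binomial standard error."""
    out: dict[str, GerminationEstimate] = {}
    for sp, grp in trials.groupby("species"):
        sown = int(grp["sown"].sum())
        germ = int(grp["germinated"].sum())
        if sown <= 0:
            raise ValueError(f"zero seeds sown for species {sp!r}")
        g = germ / sown
        se = float(np.sqrt(g * (1.0 - g) / sown))
        out[str(sp)] = GerminationEstimate(species=str(sp), g=g, se=se, germinated=germ, sown=sown)
    return out
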