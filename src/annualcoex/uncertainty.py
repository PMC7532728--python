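"""Standard errors for derived coexistence metrics.

Three routes, all operating on a metric f of the joint parameter vector
x = (lambda_i, a_ii, a_ij, lambda_j, a_jj, a_ji):

* ``bootstrap_metric_se`` — evaluate f on paired bootstrap replicates of
  the two focal fits and report the replicate SD (the default for
  reported SEs, matching the provenance of the reference estimates);
* ``taylor_propagate`` — first- or second-order Taylor (delta-method)
  propagation through a parameter covariance matrix;
* ``mc_propagate`` — multivariate-normal Monte Carlo, used as an
  independent oracle for the Taylor approximations.

Metric callables are expected to vectorise over a trailing parameter axis
(every function in :mod:`annualcoex.metrics` does) and to return NaN for
inadmissible parameter draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tools import numdiff

__all__ = ["PropagationResult", "taylor_propagate", "mc_propagate", "bootstrap_metric_se"]

#: relative step for first-order central differences
GRAD_REL_STEP = 1e-6
#: relative step for second-difference Hessians (cancellation-limited below this)
HESS_REL_STEP = 1e-4
DEFAULT_MC_DRAWS = 100_000


@dataclass(frozen=True)
class PropagationResult:
    metric: str
    value: float
    sd: float
    method: str  # taylor1 | taylor2 | monte_carlo | bootstrap
    n: int | None = None
    n_rejected: int = 0
    corrected_mean: float | None = None  # second-order mean correction (taylor2)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("propagated SD must be >= 0")


def _check_cov(cov: np.ndarray, k: int) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (k, k):
        raise ValueError(f"covariance must be {k}x{k}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-8 * max(eig.max(), 1.0):
        raise ValueError("covariance must be positive semi-definite")
    return 0.5 * (cov + cov.T)


def taylor_propagate(metric, estimates, covariance, order: int = 1, name: str = "metric") -> PropagationResult:
    """Delta-method SD of ``metric`` at ``estimates`` under ``covariance``.

    Order 1: sd = sqrt(g' S g) with the numerical gradient g (central
    differences, relative step 1e-6).  Order 2 adds the standard
    second-order corrections: variance gains tr((H S)^2)/2 and the mean
    shifts by tr(H S)/2, with H the numerical Hessian.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    x = np.asarray(estimates, dtype=float)
    cov = _check_cov(covariance, x.size)

    f0 = float(metric(x))
    if not np.isfinite(f0):
        raise ValueError(f"metric {name!r} not finite at the evaluation point")

    eps = GRAD_REL_STEP * np.maximum(np.abs(x), 1.0)
    g = np.ravel(
        numdiff.approx_fprime(x, lambda v: float(metric(v)), epsilon=eps, centered=True)
    )
    var = float(g @ cov @ g)
    corrected_mean = None
    if order == 2:
        h_eps = HESS_REL_STEP * np.maximum(np.abs(x), 1.0)
        H = numdiff.approx_hess1(x, lambda v: float(metric(v)), epsilon=h_eps)
        H = 0.5 * (H + H.T)
        HS = H @ cov
        var += 0.5 * float(np.trace(HS @ HS))
        corrected_mean = f0 + 0.5 * float(np.trace(HS))
    if not np.isfinite(var):
        raise ValueError(f"propagation failed for metric {name!r} (singular at the estimate)")
    return PropagationResult(
        metric=name,
        value=f0,
        sd=float(np.sqrt(max(var, 0.0))),
        method=f"taylor{order}",
        corrected_mean=corrected_mean,
    )


def mc_propagate(
    metric,
    estimates,
    covariance,
    n_draws: int = DEFAULT_MC_DRAWS,
    rng_seed: int = 0,
    name: str = "metric",
    max_rejection: float = 0.5,
) -> PropagationResult:
    """Monte-Carlo SD of ``metric`` under a multivariate-normal parameter law.

    Draws violating the metric's domain (NaN results) are rejected and
    counted; a rejection fraction above ``max_rejection`` aborts, since
    the propagation regime is then invalid around the estimate.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    x = np.asarray(estimates, dtype=float)
    cov = _check_cov(covariance, x.size)
    rng = np.random.default_rng(rng_seed)
    draws = rng.multivariate_normal(x, cov, size=n_draws)
    with np.errstate(all="ignore"):
        vals = np.asarray(metric(draws), dtype=float)
    if vals.shape != (n_draws,):
        raise ValueError("metric must vectorise over draws (rows)")
    ok = np.isfinite(vals)
    n_rej = int(n_draws - ok.sum())
    if n_rej > max_rejection * n_draws:
        raise ValueError(
            f"{n_rej}/{n_draws} Monte-Carlo draws inadmissible for {name!r}; "
            "normal propagation invalid at this estimate"
        )
    return PropagationResult(
        metric=name,
        value=float(metric(x)),
        sd=float(np.std(vals[ok], ddof=1)),
        method="monte_carlo",
        n=int(ok.sum()),
        n_rejected=n_rej,
    )


def bootstrap_metric_se(boots_i, boots_j, metric, name: str = "metric") -> PropagationResult:
    """SD of a metric over paired bootstrap replicates of the two fits.

    Replicates are paired by index (same n_boot required); the metric is
    evaluated on each joint vector (lambda_i, a_ii, a_ij, lambda_j, a_jj,
    a_ji) and inadmissible replicates (NaN) are dropped with a count.
    """
    ri = boots_i.replicates
    rj = boots_j.replicates
    if len(ri) != len(rj):
        raise ValueError("replicate sets not aligned: differing n_boot")
    ok = (ri["converged"] & rj["converged"]).to_numpy()
    x = np.column_stack(
        [
            ri["lam"].to_numpy(),
            ri["alpha_intra"].to_numpy(),
            ri["alpha_inter"].to_numpy(),
            rj["lam"].to_numpy(),
            rj["alpha_intra"].to_numpy(),
            rj["alpha_inter"].to_numpy(),
        ]
    )[ok]
    with np.errstate(all="ignore"):
        vals = np.asarray(metric(x), dtype=float)
    vals = vals[np.isfinite(vals)]
    n_rej = int(ok.sum() - len(vals)) + int((~ok).sum())
    if len(vals) < 2:
        raise ValueError("fewer than 2 admissible bootstrap replicates")
    return PropagationResult(
        metric=name,
        value=float(np.mean(vals)),
        sd=float(np.std(vals, ddof=1)),
        method="bootstrap",
        n=len(vals),
        n_rejected=n_rej,
    )
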