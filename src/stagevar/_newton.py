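"""Newton-Raphson MLE for logistic regression on grouped binomial data.

Every covariate in the analysis is categorical, so a policy-holder table
collapses without loss onto covariate cells with (events, trials) counts.
The maximum-likelihood estimates on the grouped data are identical to the
individual-level Bernoulli fit; the collapse makes refitting thousands of
bootstrap replicates cheap.  The log-likelihood reported is the Bernoulli
parameterisation (no binomial coefficient), so AIC values are directly
comparable to an individual-level logistic fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

# Coefficient magnitude at which iteration stops early: expit(+-30) is
# within 1e-13 of {1, 0}, so further Newton steps are pointless.
_SEPARATION_BOUND = 30.0
# Coefficient magnitude at which a fit is *flagged* quasi-separated even if
# the gradient criterion was met (a zero-event cell converges numerically
# with an extreme, effectively infinite, coefficient).
_SEPARATION_FLAG = 20.0


@dataclass
class NewtonResult:
    params: np.ndarray
    cov_params: np.ndarray
    loglik: float
    converged: bool
    separated: bool
    n_iter: int


def bernoulli_loglik(params: np.ndarray, X: np.ndarray, events: np.ndarray,
                     trials: np.ndarray) -> float:
    eta = X @ params
    # log(p) and log(1-p) without overflow
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    return float(events @ log_p + (trials - events) @ log_q)


def fit_grouped_logit(
    X: np.ndarray,
    events: np.ndarray,
    trials: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> NewtonResult:
    """Fit a binomial-logit GLM by Newton-Raphson with step halving.

    Parameters
    ----------
    X : (cells, p) dense design matrix (first column typically the intercept).
    events, trials : per-cell success and exposure counts; cells with zero
        trials are permitted and contribute nothing.
    tol : convergence tolerance on the max-norm of the score, scaled by the
        total number of observations.
    max_iter : Newton iteration cap; hitting it flags non-convergence but the
        current estimates are still returned.

    Notes
    -----
    Quasi-separated coefficients (a region with zero events, say) drift to
    large magnitudes; iteration stops once the linear predictor passes the
    point where fitted probabilities are numerically 0/1 and the fit is
    flagged ``separated`` with the estimates retained.
    """
    X = np.asarray(X, dtype=np.float64)
    events = np.asarray(events, dtype=np.float64)
    trials = np.asarray(trials, dtype=np.float64)
    n_obs = trials.sum()
    if n_obs <= 0:
        raise ValueError("no observations (all trials are zero)")
    n_events = events.sum()
    if n_events <= 0 or n_events >= n_obs:
        raise ValueError(
            "outcome is constant (all events or all non-events); "
            "the logistic MLE does not exist"
        )

    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    # warm start on the intercept speeds up low-prevalence fits
    beta[0] = np.log(n_events / (n_obs - n_events))

    grad_tol = tol * max(1.0, n_obs)
    ll = bernoulli_loglik(beta, X, events, trials)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        grad = X.T @ (events - trials * mu)
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
        w = trials * mu * (1.0 - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(hess, grad, rcond=None)
        # step halving: never accept a decrease in log-likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = bernoulli_loglik(cand, X, events, trials)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = ll_new
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            separated = True
            break

    if np.max(np.abs(beta)) > _SEPARATION_FLAG:
        separated = True
    mu = expit(X @ beta)
    w = trials * mu * (1.0 - mu)
    hess = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    return NewtonResult(
        params=beta,
        cov_params=cov,
        loglik=bernoulli_loglik(beta, X, events, trials),
        converged=converged,
        separated=separated,
        n_iter=it,
    )
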