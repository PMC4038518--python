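"""Brute-force reference implementations used only as test oracles.

Everything here deliberately avoids the package's quadrature machinery: the
posterior integrals are evaluated on dense fixed grids (trapezoid for the
full-domain quantities, Simpson for the truncated overdose numerator, whose
integration boundary sits in the interior of the posterior's support and
would otherwise dominate the trapezoid error).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import simpson

SQRT2 = math.sqrt(2.0)


def log_quasi_likelihood_grid(alpha: np.ndarray, skeleton, n_j, Y_j) -> np.ndarray:
    """Quasi-Bernoulli log likelihood at each grid alpha (naive loop-free form)."""
    logp = np.log(np.asarray(skeleton, dtype=float))
    log_pi = np.exp(alpha)[:, None] * logp
    pi = np.exp(log_pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.asarray(Y_j) * log_pi + (np.asarray(n_j) - np.asarray(Y_j)) * np.log1p(-pi)
    return np.nan_to_num(ll, neginf=-np.inf).sum(axis=1)


def _log_prior(alpha: np.ndarray, prior_sd: float) -> np.ndarray:
    return -0.5 * (alpha / prior_sd) ** 2 - math.log(prior_sd * math.sqrt(2 * math.pi))


def grid_posterior(skeleton, n_j, Y_j, *, prior_sd: float = SQRT2,
                   target_norm: float | None = None, npts: int = 20001,
                   lo: float = -10.0, hi: float = 10.0):
    """Dense-grid posterior: (marginal, pi_hat, overdose) for one skeleton.

    Marginal likelihood and posterior-mean curve by 20,001-point trapezoid on
    [lo, hi]; Pr(pi_1 > theta* | D) by dense Simpson on the analytically
    truncated domain [lo, alpha0].
    """
    grid = np.linspace(lo, hi, npts)
    ll = log_quasi_likelihood_grid(grid, skeleton, n_j, Y_j)
    f = np.exp(ll + _log_prior(grid, prior_sd))
    marginal = np.trapezoid(f, grid)
    logp = np.log(np.asarray(skeleton, dtype=float))
    pi = np.exp(np.exp(grid)[:, None] * logp)
    pi_hat = np.trapezoid(f[:, None] * pi, grid, axis=0) / marginal

    overdose = None
    if target_norm is not None:
        alpha0 = math.log(math.log(target_norm) / math.log(skeleton[0]))
        if alpha0 <= lo:
            overdose = 0.0
        else:
            g2 = np.linspace(lo, min(alpha0, hi), npts)
            ll2 = log_quasi_likelihood_grid(g2, skeleton, n_j, Y_j)
            f2 = np.exp(ll2 + _log_prior(g2, prior_sd))
            overdose = float(simpson(f2, x=g2) / marginal)
    return float(marginal), pi_hat, overdose


def grid_model_posterior_probs(skeletons, prior_weights, n_j, Y_j,
                               prior_sd: float = SQRT2) -> np.ndarray:
    """Posterior model probabilities from dense-grid marginal likelihoods."""
    margs = np.array([
        grid_posterior(sk, n_j, Y_j, prior_sd=prior_sd)[0] for sk in skeletons
    ])
    w = np.asarray(prior_weights, dtype=float) * margs
    return w / w.sum()


def random_small_dataset(rng: np.random.Generator, n_doses: int = 6,
                         max_n: int = 20, scores=(0.0, 1 / 3, 2 / 3, 1.0)):
    """Random (n_j, Y_j) sufficient statistics from grade-like scores."""
    n = int(rng.integers(0, max_n + 1))
    doses = rng.integers(0, n_doses, size=n)
    y = rng.choice(scores, size=n)
    n_j = np.bincount(doses, minlength=n_doses).astype(float)
    Y_j = np.bincount(doses, weights=y, minlength=n_doses)
    return n_j, Y_j, doses + 1, y
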