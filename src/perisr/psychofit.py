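"""Maximum-likelihood fitting of the 4AFC logistic psychometric function.

The model is

    p(correct | x) = 0.25 + 0.75 / (1 + exp((mu - x) / sigma))

with size threshold ``mu`` (arcmin) and slope parameter ``sigma``; the
lower asymptote is the 4AFC guess rate and the upper asymptote is fixed
at 1 (no lapse parameter).  Fitting maximizes the Bernoulli likelihood
of pooled trials via a coarse grid initialisation followed by local
refinement (L-BFGS-B on (mu, log sigma) with analytic gradients).
Confidence intervals for ``mu`` come from a nonparametric bootstrap
that resamples trials with replacement and refits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import NonIdentifiableError, ParameterError, UnstableFitError

_GRID_MU = np.linspace(1.0, 30.0, 40)
_GRID_SIGMA = np.geomspace(0.1, 10.0, 25)


def psychometric_p(x, mu: float, sigma: float):
    """p(correct) = 0.25 + 0.75 / (1 + exp((mu - x) / sigma))."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    u = np.clip((mu - x) / sigma, -500, 500)
    p = 0.25 + 0.75 / (1.0 + np.exp(u))
    return p if p.ndim else float(p)


@dataclass
class PsychometricFit:
    """ML estimate of (mu, sigma) with optional bootstrap CI for mu."""

    mu: float
    sigma: float
    log_likelihood: float
    n_trials: int
    ci_mu: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None
    boundary: bool = False
    n_failed_boot: int = 0

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "log_likelihood": self.log_likelihood,
            "n_trials": self.n_trials,
            "ci_mu": list(self.ci_mu) if self.ci_mu is not None else None,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _extract(trials) -> tuple[np.ndarray, np.ndarray]:
    """Gap sizes and correctness from records/DataFrame/array pair."""
    if isinstance(trials, pd.DataFrame):
        return trials["gap_arcmin"].to_numpy(float), trials["correct"].to_numpy(bool)
    if isinstance(trials, tuple) and len(trials) == 2:
        return np.asarray(trials[0], float), np.asarray(trials[1], bool)
    x = np.array([t.gap for t in trials], dtype=float)
    c = np.array([t.correct for t in trials], dtype=bool)
    return x, c


def _aggregate(x: np.ndarray, c: np.ndarray):
    levels, inv = np.unique(x, return_inverse=True)
    n = np.bincount(inv, minlength=levels.size).astype(float)
    k = np.bincount(inv, weights=c.astype(float), minlength=levels.size)
    return levels, n, k


def _nll_and_grad(theta, levels, n, k):
    mu, log_sigma = theta
    sigma = np.exp(log_sigma)
    u = np.clip((mu - levels) / sigma, -500, 500)
    s = 1.0 / (1.0 + np.exp(u))
    p = np.clip(0.25 + 0.75 * s, 1e-12, 1 - 1e-12)
    nll = -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))
    # dp/du = -0.75 s(1-s); du/dmu = 1/sigma; du/dlogsigma = -u
    w = k / p - (n - k) / (1.0 - p)
    dp_du = -0.75 * s * (1.0 - s)
    g_mu = -np.sum(w * dp_du) / sigma
    g_ls = -np.sum(w * dp_du * (-u))
    return nll, np.array([g_mu, g_ls])


def _nll_grid(levels, n, k, mus, sigmas):
    u = (mus[:, None, None] - levels[None, None, :]) / sigmas[None, :, None]
    p = np.clip(0.25 + 0.75 / (1.0 + np.exp(np.clip(u, -500, 500))),
                1e-12, 1 - 1e-12)
    return -(k * np.log(p) + (n - k) * np.log1p(-p)).sum(axis=-1)


def fit_ml(trials, warm_start: tuple[float, float] | None = None) -> PsychometricFit:
    """ML fit of (mu, sigma) to pooled trials.

    Without a warm start, a coarse grid over mu in [1, 30] arcmin and
    sigma in [0.1, 10] seeds three local refinements and the best result
    is kept, making the fit deterministic given the data.  With a warm
    start (bootstrap refits), a single local refinement is run.
    """
    x, c = _extract(trials)
    if x.size == 0:
        raise NonIdentifiableError("no trials")
    if c.all() or (~c).all():
        raise NonIdentifiableError(
            f"all trials {'correct' if c.all() else 'incorrect'}: "
            "threshold not identifiable"
        )
    if np.unique(x).size < 2:
        raise NonIdentifiableError("need >= 2 distinct gap levels")
    levels, n, k = _aggregate(x, c)

    if warm_start is not None:
        starts = [np.array([warm_start[0], np.log(warm_start[1])])]
    else:
        nll = _nll_grid(levels, n, k, _GRID_MU, _GRID_SIGMA)
        order = np.argsort(nll, axis=None)
        starts = []
        for flat in order[:3]:
            i, j = np.unravel_index(flat, nll.shape)
            starts.append(np.array([_GRID_MU[i], np.log(_GRID_SIGMA[j])]))

    best = None
    for s0 in starts:
        res = minimize(_nll_and_grad, s0, args=(levels, n, k), jac=True,
                       method="L-BFGS-B",
                       bounds=[(-60.0, 120.0), (np.log(1e-3), np.log(1e3))],
                       options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    mu, sigma = best.x[0], float(np.exp(best.x[1]))
    boundary = bool(
        sigma <= 1.1e-3 or sigma >= 0.9e3 or mu <= -59 or mu >= 119
    )
    return PsychometricFit(mu=float(mu), sigma=sigma,
                           log_likelihood=float(-best.fun),
                           n_trials=int(x.size), boundary=boundary)


def bootstrap_ci(trials, n_boot: int = 1000, seed=None,
                 max_fail_frac: float = 0.2) -> PsychometricFit:
    """Percentile bootstrap 95% CI for mu (trials as exchangeable unit).

    Resamples the pooled trials with replacement (same n), refits each
    resample warm-started at the original ML solution, and takes the
    2.5th/97.5th percentiles of the bootstrap mu distribution.  Failed
    refits are dropped; more than ``max_fail_frac`` failures raises.
    """
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    x, c = _extract(trials)
    base = fit_ml((x, c))
    rng = np.random.default_rng(seed)
    mus = []
    failed = 0
    n = x.size
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            fit = fit_ml((x[idx], c[idx]), warm_start=(base.mu, base.sigma))
            mus.append(fit.mu)
        except NonIdentifiableError:
            failed += 1
    if failed > max_fail_frac * n_boot:
        raise UnstableFitError(
            f"{failed}/{n_boot} bootstrap refits failed")
    lo, hi = np.percentile(mus, [2.5, 97.5])
    return PsychometricFit(
        mu=base.mu, sigma=base.sigma, log_likelihood=base.log_likelihood,
        n_trials=base.n_trials, ci_mu=(float(lo), float(hi)),
        n_boot=n_boot, seed=seed if seed is None else int(seed),
        boundary=base.boundary, n_failed_boot=failed,
    )
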