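"""Bayesian circular regression of flowering angle on year.

Model
-----
For observation i with angle theta_i in (-pi, pi] and centered year
z_i = x_i - x_center:

    theta_i ~ VonMises(mu_i, kappa),
    mu_i = beta0 + 2*arctan(beta1 * z_i).

The tan-half link 2*arctan maps the real line into (-pi, pi), so the
regression mean can approach but never wrap past one full turn from the
intercept.  beta1 is the link-scale slope per centered-year unit; for
small beta1 and dates away from the wrap point, 2*beta1 is approximately
the slope in radians per year.

Priors (all configurable): beta0 uniform on the circle, kappa flat on
(0, inf), and beta1 ~ Normal(0, 0.1) by default.  A fully flat beta1
prior is available but yields an improper posterior: because the link
saturates, the likelihood tends to a positive constant as
|beta1| -> inf (every huge slope fits the data as the same step
function), so the beta1 prior must have integrable tails for the
posterior to exist — and light ones for it to be concentrated when the
data are weak.  Scale 0.1 is vague on the scale of real phenology:
|beta1| = 0.1 per centered year corresponds to shifts above ten days
per decade at the series midpoint, an order of magnitude beyond
typical herbarium-documented shifts, while slopes so large that the
mean direction saturates within a few years get negligible mass.

Posterior sampling mixes a Gibbs update for beta0 (its full conditional
is itself Von Mises) with random-walk Metropolis-Hastings updates for
beta1 and log(kappa); proposal scales adapt during burn-in only, so the
retained chain is a valid Markov chain with the posterior invariant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e, i1e

from .records_io import CircularObservation

logger = logging.getLogger(__name__)

__all__ = [
    "CircularGLMConfig",
    "CircularGLMFit",
    "loglik",
    "fit",
    "predict_mean_direction",
    "grid_posterior",
]


def _log_i0(kappa):
    """log I0(kappa), stable for large kappa (i0e = exp(-k) I0(k))."""
    return np.log(i0e(kappa)) + kappa


def circular_mean(theta: np.ndarray) -> float:
    return float(np.arctan2(np.sin(theta).sum(), np.cos(theta).sum()))


def wrap_angle(theta):
    """Wrap into (-pi, pi]."""
    return -(np.mod(-np.asarray(theta, float) + np.pi, 2.0 * np.pi) - np.pi)


def estimate_kappa(rbar: float, n: int) -> float:
    """Maximum-likelihood kappa from the mean resultant length.

    Best & Fisher's approximation with the standard small-sample bias
    correction; clipped away from 0 so it can seed a sampler.
    """
    rbar = min(max(rbar, 1e-8), 1 - 1e-12)
    if rbar < 0.53:
        k = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar < 0.85:
        k = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        k = 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
    if n <= 15 and k < 2:
        k = max(k - 2.0 / (n * k), 1e-3)
    return max(float(k), 1e-3)


@dataclass
class CircularGLMConfig:
    """MCMC settings.  Defaults: 4 chains, burn-in 200, 2500 retained
    iterations per chain; chain c is seeded with ``seed + c``."""

    n_chains: int = 4
    burnin: int = 200
    iterations: int = 2500
    seed: int = 0
    beta1_proposal_scale: float | None = None  # None -> from curvature at init
    log_kappa_proposal_scale: float | None = None
    beta1_prior_scale: float | None = 0.1  # Normal SD; None -> improper flat
    rhat_threshold: float = 1.1

    def __post_init__(self):
        if self.n_chains < 1 or self.burnin < 0 or self.iterations < 1:
            raise ValueError("chain counts and iterations must be positive")


@dataclass
class CircularGLMFit:
    """Posterior draws and summaries for one species' regression."""

    beta0_samples: np.ndarray  # (n_chains * iterations,)
    beta1_samples: np.ndarray
    kappa_samples: np.ndarray
    x_center: float
    x_range: tuple[int, int]
    n_obs: int
    n_chains: int
    iterations: int
    rhat: dict[str, float] = field(default_factory=dict)

    @property
    def beta0_mean(self) -> float:
        """Circular posterior mean of the intercept."""
        return circular_mean(self.beta0_samples)

    @property
    def beta1_mean(self) -> float:
        return float(self.beta1_samples.mean())

    @property
    def beta1_sd(self) -> float:
        return float(self.beta1_samples.std(ddof=1))

    @property
    def kappa_mean(self) -> float:
        return float(self.kappa_samples.mean())

    @property
    def converged(self) -> bool:
        return all(r <= 1.1 for r in self.rhat.values())


def loglik(theta_vec, x_vec, beta0, beta1, kappa, x_center=None) -> float:
    """Von Mises log-likelihood of the circular regression.

    sum_i kappa*cos(theta_i - mu_i) - log(2 pi I0(kappa)), with
    mu_i = beta0 + 2*arctan(beta1*(x_i - x_center)).  ``x_center``
    defaults to the mean of ``x_vec``.
    """
    theta = np.asarray(theta_vec, float)
    x = np.asarray(x_vec, float)
    if theta.shape != x.shape:
        raise ValueError("theta and x must have the same length")
    if not kappa > 0:
        raise ValueError("kappa must be > 0")
    if x_center is None:
        x_center = x.mean()
    mu = beta0 + 2.0 * np.arctan(beta1 * (x - x_center))
    return float(kappa * np.cos(theta - mu).sum() - theta.size * (_log_i0(kappa) + math.log(2 * math.pi)))


def _log_prior_beta1(beta1, prior_scale):
    if prior_scale is None:
        return 0.0
    return -0.5 * (beta1 / prior_scale) ** 2


def _run_chain(theta, z, n_keep, burnin, rng, beta1_scale, logk_scale, init, prior_scale):
    """One MCMC chain; returns (beta0, beta1, kappa) arrays of n_keep draws."""
    n = theta.size
    beta0, beta1, kappa = init
    out0 = np.empty(n_keep)
    out1 = np.empty(n_keep)
    outk = np.empty(n_keep)
    log_i0_k = _log_i0(kappa)
    # sufficient pieces for the current beta1: a_i = theta_i - g_i
    g = 2.0 * np.arctan(beta1 * z)
    C = np.cos(theta - g).sum()
    S = np.sin(theta - g).sum()
    wide_scale = 1.5 * prior_scale if prior_scale else 100.0 * beta1_scale
    # adaptation (burn-in only) targets ~0.44 acceptance for the 1-d walks
    acc1 = acck = 0.0
    n_local = 0
    total = burnin + n_keep
    for t in range(total):
        # --- Gibbs: beta0 | rest ~ VonMises(atan2(S, C), kappa * R)
        R = math.hypot(C, S)
        beta0 = float(rng.vonmises(math.atan2(S, C), max(kappa * R, 1e-12)))
        W = C * math.cos(beta0) + S * math.sin(beta0)  # = sum cos(theta - mu)

        # --- MH: beta1 — mixture of a locally tuned walk and an
        # occasional wide step.  Weak data leave the posterior
        # multimodal (central mode plus saturated-link plateaus), and a
        # purely local walk cannot traverse between those modes.  The
        # mixture kernel is still symmetric, so the acceptance ratio is
        # unchanged.
        local = rng.random() >= 0.1
        step_scale = beta1_scale if local else wide_scale
        prop = beta1 + step_scale * rng.standard_normal()
        gp = 2.0 * np.arctan(prop * z)
        Cp = np.cos(theta - gp).sum()
        Sp = np.sin(theta - gp).sum()
        Wp = Cp * math.cos(beta0) + Sp * math.sin(beta0)
        log_ratio = kappa * (Wp - W) + _log_prior_beta1(prop, prior_scale) - _log_prior_beta1(beta1, prior_scale)
        if math.log(rng.random()) < log_ratio:
            beta1, C, S, W = prop, Cp, Sp, Wp
            if local:
                acc1 += 1
        n_local += local

        # --- MH: log(kappa) walk, flat prior on kappa (Jacobian: +log k'/k)
        logk_prop = math.log(kappa) + logk_scale * rng.standard_normal()
        k_prop = math.exp(logk_prop)
        log_i0_prop = _log_i0(k_prop)
        delta = (k_prop - kappa) * W - n * (log_i0_prop - log_i0_k) + (logk_prop - math.log(kappa))
        if math.log(rng.random()) < delta:
            kappa, log_i0_k = k_prop, log_i0_prop
            acck += 1

        if t < burnin:
            if (t + 1) % 25 == 0:  # Robbins-Monro style scale adaptation
                rate1 = acc1 / max(n_local, 1)
                ratek = acck / 25.0
                beta1_scale *= math.exp(0.8 * (rate1 - 0.44))
                logk_scale *= math.exp(0.8 * (ratek - 0.44))
                acc1 = acck = 0.0
                n_local = 0
        else:
            j = t - burnin
            out0[j] = beta0
            out1[j] = beta1
            outk[j] = kappa
    return out0, out1, outk


def _split_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction on split chains.

    ``chains``: (n_chains, n_draws).
    """
    n_chains, n = chains.shape
    half = n // 2
    if half < 2:
        return float("nan")
    split = chains[:, : 2 * half].reshape(n_chains * 2, half)
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    w = variances.mean()
    b = half * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_hat = (half - 1) / half * w + b / half
    return float(math.sqrt(var_hat / w))


def fit(series: list[CircularObservation], config: CircularGLMConfig) -> CircularGLMFit:
    """Sample the posterior for one species' observation series.

    Requires at least 3 observations spanning at least 2 distinct years.
    Non-convergence (split R-hat > threshold) is flagged on the result,
    not fatal.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 observations")
    x = np.array([o.year for o in series], dtype=float)
    theta = np.array([o.theta for o in series], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("no temporal contrast: all observations share one year")
    x_center = float(x.mean())
    z = x - x_center

    # data-driven initialization
    m0 = circular_mean(theta)
    rbar = float(np.hypot(np.cos(theta).sum(), np.sin(theta).sum())) / theta.size
    k0 = estimate_kappa(rbar, theta.size)
    b1_scale = config.beta1_proposal_scale
    if b1_scale is None:
        # 2.4 / sqrt(curvature); curvature of the log-likelihood in beta1
        # at beta1=0 is ~ 4 * kappa * sum z^2
        b1_scale = 2.4 / math.sqrt(max(4.0 * k0 * float((z**2).sum()), 1e-12))
    lk_scale = config.log_kappa_proposal_scale
    if lk_scale is None:
        lk_scale = max(2.4 * math.sqrt(2.0 / theta.size), 0.05)

    keep = config.iterations
    b0_all = np.empty((config.n_chains, keep))
    b1_all = np.empty((config.n_chains, keep))
    kp_all = np.empty((config.n_chains, keep))
    for c in range(config.n_chains):
        rng = np.random.default_rng(config.seed + c)
        # overdispersed starts around the data-driven center
        init = (
            wrap_angle(m0 + 0.2 * rng.standard_normal()),
            2.0 * b1_scale * rng.standard_normal(),
            k0 * math.exp(0.3 * rng.standard_normal()),
        )
        b0_all[c], b1_all[c], kp_all[c] = _run_chain(
            theta, z, keep, config.burnin, rng, b1_scale, lk_scale, init,
            config.beta1_prior_scale,
        )

    # circular parameter: compute R-hat on the recentered, unwrapped angle
    b0_centered = wrap_angle(b0_all - circular_mean(b0_all.ravel()))
    rhat = {
        "beta0": _split_rhat(b0_centered),
        "beta1": _split_rhat(b1_all),
        "kappa": _split_rhat(np.log(kp_all)),
    }
    result = CircularGLMFit(
        beta0_samples=b0_all.ravel(),
        beta1_samples=b1_all.ravel(),
        kappa_samples=kp_all.ravel(),
        x_center=x_center,
        x_range=(int(x.min()), int(x.max())),
        n_obs=len(series),
        n_chains=config.n_chains,
        iterations=keep,
        rhat=rhat,
    )
    bad = {k: v for k, v in rhat.items() if not (v <= config.rhat_threshold)}
    if bad:
        logger.warning("possible non-convergence (R-hat > %.2f): %s", config.rhat_threshold, bad)
    return result


def predict_mean_direction(fit_result: CircularGLMFit, year: float) -> float:
    """Posterior mean direction of mu(year) = beta0 + 2*arctan(beta1*z)."""
    mu = fit_result.beta0_samples + 2.0 * np.arctan(
        fit_result.beta1_samples * (year - fit_result.x_center)
    )
    return circular_mean(mu)


def grid_posterior(
    theta_vec,
    x_vec,
    beta0_grid,
    beta1_grid,
    kappa_grid,
    x_center=None,
    beta1_prior_scale: float | None = 0.1,
):
    """Brute-force joint posterior on a dense (beta0, beta1, kappa) grid.

    Returns the normalized joint probability mass over grid cells, shape
    (len(beta0_grid), len(beta1_grid), len(kappa_grid)), under the same
    priors the sampler defaults to.  Intended as an independent check of
    the MCMC on small series; cost is O(grid * n).
    """
    theta = np.asarray(theta_vec, float)
    x = np.asarray(x_vec, float)
    if x_center is None:
        x_center = x.mean()
    z = x - x_center
    b0 = np.asarray(beta0_grid, float)[:, None]
    b1 = np.asarray(beta1_grid, float)[None, :]
    kap = np.asarray(kappa_grid, float)
    # W[i,j] = sum_t cos(theta_t - b0_i - 2 atan(b1_j z_t))
    W = np.zeros((b0.size, b1.size))
    for th, zt in zip(theta, z):
        W += np.cos(th - b0 - 2.0 * np.arctan(b1 * zt))
    logpost = kap[None, None, :] * W[:, :, None] - theta.size * _log_i0(kap)[None, None, :]
    if beta1_prior_scale is not None:
        logpost += (-0.5 * (b1[0] / beta1_prior_scale) ** 2)[None, :, None]
    logpost -= logpost.max()
    post = np.exp(logpost)
    return post / post.sum()
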