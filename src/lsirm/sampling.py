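"""Posterior sampling for the latent space item response model.

The sampler is a blocked adaptive random-walk Metropolis scheme with one
block per parameter family: abilities theta (all persons proposed and
accepted independently in parallel, since the likelihood factorizes over
rows given everything else), item intercepts b (columns, likewise),
log(sigma^2), log(lambda), person positions xi (row-parallel), and item
positions zeta (column-parallel).  Proposal scales adapt per coordinate
during burn-in toward a target acceptance rate and are frozen afterwards,
so retained draws come from a fixed Markov kernel.

Because the spike-and-slab mixture on log(lambda) can be bimodal, the
log(lambda) block mixes random-walk steps with an occasional symmetric
mode-jump proposal that translates by the spike-to-slab gap
(mu_slab - mu_spike), letting chains cross between components.

Chains are independent given sub-seeds spawned from the master seed, so a
run is exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .model import (
    ModelConfig,
    ResponseMatrix,
    bernoulli_loglik,
    distance_matrix,
    half_cauchy_logpdf,
    log_lambda_mixture_logpdf,
    slab_responsibility,
)

__all__ = [
    "RunConfig",
    "PosteriorSamples",
    "ConvergenceSummary",
    "fit_lsirm",
    "fit_rasch",
    "split_rhat",
    "convergence_summary",
    "slab_probability",
    "summarize",
]

_TARGET_ACCEPT = 0.35
_LOG_LAMBDA_INIT = -2.25  # midpoint of the spike (-5) and slab (0.5) means


@dataclass
class RunConfig:
    """MCMC run settings: 3 chains of 1500 iterations, 500 burn-in by default."""

    n_chains: int = 3
    n_iter: int = 1500
    n_burnin: int = 500
    seed: int = 0
    thin: int = 1
    #: probability of a spike<->slab translation proposal for log(lambda)
    jump_prob: float = 0.2

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin


@dataclass
class PosteriorSamples:
    """Retained draws, stacked as (chain, draw, ...) arrays.

    ``xi``/``zeta`` are None for a Rasch-only fit.  ``log_posterior`` holds
    the joint log density (likelihood + prior) of every retained draw.
    """

    theta: np.ndarray
    b: np.ndarray
    sigma2: np.ndarray
    log_lambda: np.ndarray | None
    xi: np.ndarray | None
    zeta: np.ndarray | None
    log_posterior: np.ndarray
    person_ids: list[str]
    item_ids: list[str]
    model_config: ModelConfig
    run_config: RunConfig

    @property
    def n_chains(self) -> int:
        return int(self.theta.shape[0])

    @property
    def n_retained(self) -> int:
        return int(self.theta.shape[1])

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled over chains, chain-major order."""
        arr = getattr(self, name)
        if arr is None:
            raise ValueError(f"{name} was not sampled in this fit")
        return arr.reshape((-1,) + arr.shape[2:])

    @property
    def is_rasch(self) -> bool:
        return self.xi is None


@dataclass
class ConvergenceSummary:
    rhat: pd.Series
    cutoff: float = 1.1
    all_converged: bool = field(init=False)

    def __post_init__(self) -> None:
        self.all_converged = bool((self.rhat < self.cutoff).all())


def split_rhat(draws_by_chain: np.ndarray) -> float:
    """Split potential scale reduction factor for one scalar parameter.

    Each chain is split in half; R-hat compares between- and within-half
    variances.  Values near 1 indicate the chains agree.
    """
    draws = np.asarray(draws_by_chain, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("split_rhat needs >= 2 chains of draws")
    n = draws.shape[1] // 2
    if n < 2:
        raise ValueError("chains too short to split")
    halves = np.concatenate([draws[:, :n], draws[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    within = halves.var(axis=1, ddof=1)
    W = within.mean()
    B = n * halves.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def convergence_summary(s: PosteriorSamples, cutoff: float = 1.1) -> ConvergenceSummary:
    """Split R-hat for every scalar parameter (theta, b, sigma^2, log lambda).

    Latent positions are excluded: before Procrustes alignment their
    coordinates are only identified up to a rigid transform, so chainwise
    coordinate comparisons are not meaningful.
    """
    rh: dict[str, float] = {}
    for p in range(s.theta.shape[2]):
        rh[f"theta[{s.person_ids[p]}]"] = split_rhat(s.theta[:, :, p])
    for i in range(s.b.shape[2]):
        rh[f"b[{s.item_ids[i]}]"] = split_rhat(s.b[:, :, i])
    rh["sigma2"] = split_rhat(s.sigma2)
    if s.log_lambda is not None:
        rh["log_lambda"] = split_rhat(s.log_lambda)
    return ConvergenceSummary(rhat=pd.Series(rh), cutoff=cutoff)


def slab_probability(s: PosteriorSamples, c: ModelConfig | None = None) -> float:
    """Posterior slab probability P(delta = 1 | Y).

    Estimated as the posterior mean of the mixture responsibility of
    log(lambda) under the spike-and-slab prior.
    """
    if s.log_lambda is None:
        raise ValueError("Rasch-only fit has no lambda draws")
    c = c or s.model_config
    return float(np.mean(slab_responsibility(s.pooled("log_lambda"), c)))


def summarize(s: PosteriorSamples) -> pd.DataFrame:
    """Posterior means, SDs and central 95% intervals for scalar parameters.

    lambda is summarized on the natural scale (draws exponentiated before
    averaging).
    """
    rows = {}

    def add(name: str, draws: np.ndarray) -> None:
        q = np.quantile(draws, [0.025, 0.5, 0.975])
        rows[name] = {
            "mean": float(np.mean(draws)),
            "sd": float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0,
            "q2.5": float(q[0]),
            "median": float(q[1]),
            "q97.5": float(q[2]),
        }

    th = s.pooled("theta")
    for p, pid in enumerate(s.person_ids):
        add(f"theta[{pid}]", th[:, p])
    bb = s.pooled("b")
    for i, iid in enumerate(s.item_ids):
        add(f"b[{iid}]", bb[:, i])
    add("sigma2", s.pooled("sigma2"))
    if s.log_lambda is not None:
        add("lambda", np.exp(s.pooled("log_lambda")))
    return pd.DataFrame.from_dict(rows, orient="index")


def _initial_state(Y: ResponseMatrix, K: int, rng: np.random.Generator, rasch: bool):
    """Data-informed start.

    theta and b come from standardized logit margins.  Positions start at a
    truncated-SVD embedding of the standardized response residuals (jittered
    per chain): person-item pairs with positive residual association get
    nearby positions, so the distance-weight block sees an informative
    gradient from the first iteration.  On exchangeable (Rasch-like) data
    the embedding is noise and the weight falls into the spike instead.
    log(lambda) starts at the spike/slab midpoint.
    """
    obs = Y.observed
    y = np.asarray(Y.values, dtype=float)
    p_row = (np.where(obs, y, 0.0).sum(axis=1) + 0.5) / (obs.sum(axis=1) + 1.0)
    p_col = (np.where(obs, y, 0.0).sum(axis=0) + 0.5) / (obs.sum(axis=0) + 1.0)
    theta = logit(p_row)
    theta = theta - theta.mean() + 0.1 * rng.standard_normal(theta.shape)
    b = logit(p_col) + 0.1 * rng.standard_normal(p_col.shape)
    sigma2 = float(np.clip(np.var(theta), 0.1, 25.0))
    if rasch:
        return theta, b, sigma2, None, None, None
    mu = expit(theta[:, None] + b[None, :])
    resid = np.where(obs, (y - mu) / np.sqrt(mu * (1.0 - mu)), 0.0)
    try:
        U, sv, Vt = np.linalg.svd(resid, full_matrices=False)
        # shrink at the pure-noise singular-value floor (~sqrt(P)+sqrt(I));
        # exchangeable data collapses to the origin, real structure survives
        floor = np.sqrt(resid.shape[0]) + np.sqrt(resid.shape[1])
        sv_eff = np.sqrt(np.maximum(sv[:K] ** 2 - floor**2, 0.0))
        xi = U[:, :K] * np.sqrt(sv_eff)
        zeta = Vt[:K].T * np.sqrt(sv_eff)
        rms = np.sqrt(np.mean(np.vstack([xi, zeta]) ** 2))
        if rms > 1.0:  # keep starts inside the prior's scale
            xi = xi / rms
            zeta = zeta / rms
    except np.linalg.LinAlgError:  # pragma: no cover - SVD essentially never fails here
        xi = np.zeros((Y.n_persons, K))
        zeta = np.zeros((Y.n_items, K))
    xi = xi + 0.1 * rng.standard_normal(xi.shape)
    zeta = zeta + 0.1 * rng.standard_normal(zeta.shape)
    return theta, b, sigma2, _LOG_LAMBDA_INIT, xi, zeta


def _run_chain(
    Y: ResponseMatrix,
    c: ModelConfig,
    r: RunConfig,
    rng: np.random.Generator,
    rasch: bool,
    fix: Mapping[str, np.ndarray | float],
):
    P, I, K = Y.n_persons, Y.n_items, c.K
    obs = np.asarray(Y.observed, dtype=float)
    y = np.asarray(Y.values, dtype=float) * obs

    theta, b, sigma2, log_lam, xi, zeta = _initial_state(Y, K, rng, rasch)
    for name, val in fix.items():
        if name == "theta":
            theta = np.array(val, dtype=float)
        elif name == "b":
            b = np.array(val, dtype=float)
        elif name == "sigma2":
            sigma2 = float(val)
        elif name == "log_lambda":
            log_lam = float(val)
        elif name == "xi":
            xi = np.array(val, dtype=float)
        elif name == "zeta":
            zeta = np.array(val, dtype=float)
        else:
            raise ValueError(f"unknown parameter to fix: {name!r}")

    lam = 0.0 if rasch else float(np.exp(log_lam))
    D = np.zeros((P, I)) if rasch else distance_matrix(xi, zeta)

    def cell_ll(eta: np.ndarray) -> np.ndarray:
        return obs * bernoulli_loglik(eta, y)

    L = cell_ll(theta[:, None] + b[None, :] - lam * D)

    # per-coordinate random-walk scales, adapted during burn-in only
    s_theta = np.full(P, 0.5)
    s_b = np.full(I, 0.5)
    s_sig = 0.5
    s_lam = 0.5
    s_xi = np.full(P, 0.3)
    s_zeta = np.full(I, 0.3)
    s_scale = 0.3
    s_shift = 0.3
    s_ridge = 0.2
    s_breathe = 0.1
    gap = c.mu_slab - c.mu_spike
    joint_moves = not rasch and not any(k in fix for k in ("xi", "zeta", "log_lambda"))

    n_keep = r.n_retained
    out_theta = np.empty((n_keep, P))
    out_b = np.empty((n_keep, I))
    out_sigma2 = np.empty(n_keep)
    out_loglam = None if rasch else np.empty(n_keep)
    out_xi = None if rasch else np.empty((n_keep, P, K))
    out_zeta = None if rasch else np.empty((n_keep, I, K))
    out_lp = np.empty(n_keep)

    def prior_terms() -> float:
        lp = -0.5 * P * np.log(2 * np.pi * sigma2) - np.sum(theta**2) / (2 * sigma2)
        lp += -0.5 * I * np.log(2 * np.pi * c.sigma_b**2) - np.sum(b**2) / (2 * c.sigma_b**2)
        if c.cauchy_on_sigma:
            sig = np.sqrt(sigma2)
            lp += half_cauchy_logpdf(sig, c.sigma_cauchy_scale) - np.log(2.0 * sig)
        else:
            lp += half_cauchy_logpdf(sigma2, c.sigma_cauchy_scale)
        if not rasch:
            lp += -0.5 * xi.size * np.log(2 * np.pi) - 0.5 * np.sum(xi**2)
            lp += -0.5 * zeta.size * np.log(2 * np.pi) - 0.5 * np.sum(zeta**2)
            lp += log_lambda_mixture_logpdf(log_lam, c)
        return float(lp)

    kept = 0
    for t in range(r.n_iter):
        adapting = t < r.n_burnin
        rate = (t + 1.0) ** -0.6

        if "theta" not in fix:
            prop = theta + s_theta * rng.standard_normal(P)
            L_new = cell_ll(prop[:, None] + b[None, :] - lam * D)
            dlp = (L_new - L).sum(axis=1) + (theta**2 - prop**2) / (2 * sigma2)
            alpha = np.exp(np.minimum(0.0, dlp))
            acc = rng.random(P) < alpha
            theta = np.where(acc, prop, theta)
            L[acc] = L_new[acc]
            if adapting:
                s_theta *= np.exp(rate * (alpha - _TARGET_ACCEPT))

        if "b" not in fix:
            prop = b + s_b * rng.standard_normal(I)
            L_new = cell_ll(theta[:, None] + prop[None, :] - lam * D)
            dlp = (L_new - L).sum(axis=0) + (b**2 - prop**2) / (2 * c.sigma_b**2)
            alpha = np.exp(np.minimum(0.0, dlp))
            acc = rng.random(I) < alpha
            b = np.where(acc, prop, b)
            L[:, acc] = L_new[:, acc]
            if adapting:
                s_b *= np.exp(rate * (alpha - _TARGET_ACCEPT))

        if "sigma2" not in fix:
            # log-scale walk; target includes the Jacobian e^x of x = log sigma^2
            x = np.log(sigma2)
            x_new = x + s_sig * rng.standard_normal()
            s2_new = np.exp(x_new)
            if c.cauchy_on_sigma:
                pr_old = half_cauchy_logpdf(np.sqrt(sigma2), c.sigma_cauchy_scale) - 0.5 * np.log(sigma2) - np.log(2.0)
                pr_new = half_cauchy_logpdf(np.sqrt(s2_new), c.sigma_cauchy_scale) - 0.5 * np.log(s2_new) - np.log(2.0)
            else:
                pr_old = half_cauchy_logpdf(sigma2, c.sigma_cauchy_scale)
                pr_new = half_cauchy_logpdf(s2_new, c.sigma_cauchy_scale)
            ss = float(np.sum(theta**2))
            dlp = (
                -0.5 * P * (np.log(s2_new) - np.log(sigma2))
                - ss / (2 * s2_new)
                + ss / (2 * sigma2)
                + pr_new
                - pr_old
                + (x_new - x)
            )
            alpha = float(np.exp(min(0.0, dlp)))
            if rng.random() < alpha:
                sigma2 = float(s2_new)
            if adapting:
                s_sig *= np.exp(rate * (alpha - _TARGET_ACCEPT))

        if not rasch and "log_lambda" not in fix:
            # spike<->slab translation proposals carry the intercepts along
            # (b absorbs the lambda*mean-distance shift), otherwise a jump
            # out of a fitted slab mode is essentially never accepted
            # jumps only after burn-in: a half-organized chain that falls
            # into the spike early loses its configuration and cannot return
            if not adapting and rng.random() < r.jump_prob and "b" not in fix:
                prop_ll = log_lam + gap * (1.0 if rng.random() < 0.5 else -1.0)
                walk = False
            else:
                prop_ll = log_lam + s_lam * rng.standard_normal()
                walk = True
            lam_new = float(np.exp(prop_ll))
            if walk or "b" in fix:
                b_new = b
            else:
                b_new = b + (lam_new - lam) * D.mean(axis=0)
            L_new = cell_ll(theta[:, None] + b_new[None, :] - lam_new * D)
            dlp = (
                (L_new - L).sum()
                + np.sum(b**2 - b_new**2) / (2 * c.sigma_b**2)
                + log_lambda_mixture_logpdf(prop_ll, c)
                - log_lambda_mixture_logpdf(log_lam, c)
            )
            alpha = float(np.exp(min(0.0, dlp)))
            if rng.random() < alpha:
                log_lam, lam, L, b = float(prop_ll), lam_new, L_new, b_new
            if adapting and walk:
                s_lam *= np.exp(rate * (alpha - _TARGET_ACCEPT))

        if not rasch and "xi" not in fix:
            # person-position rows move with their ability absorbing the
            # lambda*mean-distance change, so a person can drift toward or
            # away from the items without fighting the theta_p estimate
            prop = xi + s_xi[:, None] * rng.standard_normal((P, K))
            D_new = distance_matrix(prop, zeta)
            if "theta" not in fix:
                theta_new = theta + lam * (D_new.mean(axis=1) - D.mean(axis=1))
            else:
                theta_new = theta
            L_new = cell_ll(theta_new[:, None] + b[None, :] - lam * D_new)
            dlp = (
                (L_new - L).sum(axis=1)
                + 0.5 * (np.sum(xi**2, axis=1) - np.sum(prop**2, axis=1))
                + (theta**2 - theta_new**2) / (2 * sigma2)
            )
            alpha = np.exp(np.minimum(0.0, dlp))
            acc = rng.random(P) < alpha
            xi = np.where(acc[:, None], prop, xi)
            theta = np.where(acc, theta_new, theta)
            D[acc] = D_new[acc]
            L[acc] = L_new[acc]
            if adapting:
                s_xi *= np.exp(rate * (alpha - _TARGET_ACCEPT))

        if not rasch and "zeta" not in fix:
            # item-position columns likewise carry their intercept along
            prop = zeta + s_zeta[:, None] * rng.standard_normal((I, K))
            D_new = distance_matrix(xi, prop)
            if "b" not in fix:
                b_new = b + lam * (D_new.mean(axis=0) - D.mean(axis=0))
            else:
                b_new = b
            L_new = cell_ll(theta[:, None] + b_new[None, :] - lam * D_new)
            dlp = (
                (L_new - L).sum(axis=0)
                + 0.5 * (np.sum(zeta**2, axis=1) - np.sum(prop**2, axis=1))
                + (b**2 - b_new**2) / (2 * c.sigma_b**2)
            )
            alpha = np.exp(np.minimum(0.0, dlp))
            acc = rng.random(I) < alpha
            zeta = np.where(acc[:, None], prop, zeta)
            b = np.where(acc, b_new, b)
            D[:, acc] = D_new[:, acc]
            L[:, acc] = L_new[:, acc]
            if adapting:
                s_zeta *= np.exp(rate * (alpha - _TARGET_ACCEPT))

        if joint_moves and "b" not in fix:
            # lambda-b ridge: changing lambda shifts every eta by roughly
            # -dlam * mean distance, which the intercepts absorb; propose
            # both together so the common-offset ridge mixes fast.  The map
            # (b, loglam) -> (b + dlam*colmean(D), loglam + dl) is volume-
            # preserving and self-inverse under dl -> -dl.
            dl = s_ridge * rng.standard_normal()
            loglam_new = log_lam + dl
            lam_new = float(np.exp(loglam_new))
            b_new = b + (lam_new - lam) * D.mean(axis=0)
            L_new = cell_ll(theta[:, None] + b_new[None, :] - lam_new * D)
            dlp = (
                (L_new - L).sum()
                + np.sum(b**2 - b_new**2) / (2 * c.sigma_b**2)
                + log_lambda_mixture_logpdf(loglam_new, c)
                - log_lambda_mixture_logpdf(log_lam, c)
            )
            alpha = float(np.exp(min(0.0, dlp)))
            if rng.random() < alpha:
                b, log_lam, lam, L = b_new, float(loglam_new), lam_new, L_new
            if adapting:
                s_ridge *= np.exp(rate * (alpha - _TARGET_ACCEPT))

        if joint_moves:
            # rescale move along the likelihood-invariant ridge: positions
            # times s, lambda over s, so lambda*d (and the likelihood) is
            # unchanged; only the priors and the Jacobian s^{(P+I)K} enter.
            ls = s_scale * rng.standard_normal()
            sfac = np.exp(ls)
            ssq = float(np.sum(xi**2) + np.sum(zeta**2))
            dlp = (
                -0.5 * ssq * (sfac**2 - 1.0)
                + log_lambda_mixture_logpdf(log_lam - ls, c)
                - log_lambda_mixture_logpdf(log_lam, c)
                + (P + I) * K * ls
            )
            alpha = float(np.exp(min(0.0, dlp)))
            if rng.random() < alpha:
                xi = xi * sfac
                zeta = zeta * sfac
                D = D * sfac
                log_lam = float(log_lam - ls)
                lam = float(np.exp(log_lam))
            if adapting:
                s_scale *= np.exp(rate * (alpha - _TARGET_ACCEPT))

            # breathing move: rescale positions holding lambda fixed, with
            # the intercepts absorbing the lambda*mean-distance shift; the
            # residual eta change lambda(1-s)(d - dbar) is mean-zero.
            if "b" not in fix:
                ls = s_breathe * rng.standard_normal()
                sfac = np.exp(ls)
                dbar = D.mean()
                b_new = b + lam * dbar * (sfac - 1.0)
                D_new = D * sfac
                L_new = cell_ll(theta[:, None] + b_new[None, :] - lam * D_new)
                ssq = float(np.sum(xi**2) + np.sum(zeta**2))
                dlp = (
                    (L_new - L).sum()
                    - 0.5 * ssq * (sfac**2 - 1.0)
                    + np.sum(b**2 - b_new**2) / (2 * c.sigma_b**2)
                    + (P + I) * K * ls
                )
                alpha = float(np.exp(min(0.0, dlp)))
                if rng.random() < alpha:
                    xi = xi * sfac
                    zeta = zeta * sfac
                    D, b, L = D_new, b_new, L_new
                if adapting:
                    s_breathe *= np.exp(rate * (alpha - _TARGET_ACCEPT))

            # joint translation of all positions (likelihood-invariant too)
            shift = s_shift * rng.standard_normal(K)
            dlp = -0.5 * (
                np.sum((xi + shift) ** 2)
                - np.sum(xi**2)
                + np.sum((zeta + shift) ** 2)
                - np.sum(zeta**2)
            )
            alpha = float(np.exp(min(0.0, dlp)))
            if rng.random() < alpha:
                xi = xi + shift
                zeta = zeta + shift
            if adapting:
                s_shift *= np.exp(rate * (alpha - _TARGET_ACCEPT))

        if t >= r.n_burnin and (t - r.n_burnin) % r.thin == 0 and kept < n_keep:
            out_theta[kept] = theta
            out_b[kept] = b
            out_sigma2[kept] = sigma2
            if not rasch:
                out_loglam[kept] = log_lam
                out_xi[kept] = xi
                out_zeta[kept] = zeta
            out_lp[kept] = L.sum() + prior_terms()
            kept += 1

    return out_theta, out_b, out_sigma2, out_loglam, out_xi, out_zeta, out_lp


def _warn_degenerate(Y: ResponseMatrix) -> None:
    y = np.asarray(Y.values, dtype=float)
    obs = Y.observed
    row_mean = np.where(obs, y, 0.0).sum(axis=1) / obs.sum(axis=1)
    col_mean = np.where(obs, y, 0.0).sum(axis=0) / obs.sum(axis=0)
    if np.any((row_mean == 0) | (row_mean == 1)):
        warnings.warn("some persons have all-0 or all-1 responses", stacklevel=3)
    if np.any((col_mean == 0) | (col_mean == 1)):
        warnings.warn("some items have all-0 or all-1 responses", stacklevel=3)


def _fit(
    Y: ResponseMatrix,
    c: ModelConfig,
    r: RunConfig,
    rasch: bool,
    fix: Mapping[str, np.ndarray | float] | None,
) -> PosteriorSamples:
    _warn_degenerate(Y)
    fix = dict(fix or {})
    seeds = np.random.SeedSequence(r.seed).spawn(r.n_chains)
    chains = [
        _run_chain(Y, c, r, np.random.default_rng(s), rasch, fix) for s in seeds
    ]
    stack = lambda k: np.stack([ch[k] for ch in chains])
    return PosteriorSamples(
        theta=stack(0),
        b=stack(1),
        sigma2=stack(2),
        log_lambda=None if rasch else stack(3),
        xi=None if rasch else stack(4),
        zeta=None if rasch else stack(5),
        log_posterior=stack(6),
        person_ids=list(Y.person_ids),
        item_ids=list(Y.item_ids),
        model_config=c,
        run_config=r,
    )


def fit_lsirm(
    Y: ResponseMatrix,
    c: ModelConfig | None = None,
    r: RunConfig | None = None,
    fix: Mapping[str, np.ndarray | float] | None = None,
) -> PosteriorSamples:
    """Sample the LSIRM posterior.

    ``fix`` holds parameter blocks at given values (no update), which is
    useful for conditional-posterior validation on tiny instances.
    """
    return _fit(Y, c or ModelConfig(), r or RunConfig(), rasch=False, fix=fix)


def fit_rasch(
    Y: ResponseMatrix,
    c: ModelConfig | None = None,
    r: RunConfig | None = None,
    fix: Mapping[str, np.ndarray | float] | None = None,
) -> PosteriorSamples:
    """Sample the Rasch baseline posterior (lambda = 0, no latent space)."""
    return _fit(Y, c or ModelConfig(), r or RunConfig(), rasch=True, fix=fix)
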