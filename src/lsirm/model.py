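"""Joint density of the latent space item response model (LSIRM).

The model extends the Rasch model for a binary person-by-item response
matrix with a K-dimensional latent metric space in which both persons and
items have positions.  The log-odds of a correct response is

    logit P(Y_pi = 1) = theta_p + b_i - lambda * d(xi_p, zeta_i),

where ``theta_p`` is the ability of person p, ``b_i`` the easiness
intercept of item i, ``d`` the Euclidean distance, and ``lambda >= 0`` a
weight on the distance effect.  Distances absorb person-item interactions
(conditional dependence) that the Rasch main effects cannot represent.

Priors: theta_p ~ N(0, sigma^2) with a half-Cauchy hyperprior on the
variance, b_i ~ N(0, sigma_b^2), positions standard normal per coordinate,
and a spike-and-slab two-component normal mixture on log(lambda) that lets
the data decide whether the distance effect is needed at all.  The binary
slab indicator delta is marginalized out; its posterior probability is
recovered from the mixture responsibility of each log(lambda) draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ResponseMatrix",
    "ModelConfig",
    "ParameterState",
    "euclidean_distance",
    "linear_predictor",
    "bernoulli_loglik",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "slab_responsibility",
    "lognormal_moments",
]

_LOG_2_OVER_PI = float(np.log(2.0 / np.pi))


@dataclass
class ResponseMatrix:
    """P x I binary responses with an observed-data mask.

    ``values`` must be 0/1 wherever ``observed`` is True; masked cells are
    ignored by the likelihood.  Every person and every item must have at
    least one observed response.
    """

    values: np.ndarray
    observed: np.ndarray | None = None
    person_ids: list[str] = field(default_factory=list)
    item_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("response matrix must be 2-dimensional")
        P, I = self.values.shape
        if P < 2 or I < 2:
            raise ValueError(f"need at least 2 persons and 2 items, got {P}x{I}")
        if self.observed is None:
            self.observed = ~np.isnan(np.asarray(self.values, dtype=float))
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.observed.shape != self.values.shape:
            raise ValueError("observed mask shape must match values")
        vals = np.asarray(self.values, dtype=float)[self.observed]
        if not np.all((vals == 0) | (vals == 1)):
            bad = np.argwhere(
                self.observed
                & ~((np.asarray(self.values, dtype=float) == 0) | (np.asarray(self.values, dtype=float) == 1))
            )[0]
            raise ValueError(
                f"non-binary observed value at row {bad[0]}, column {bad[1]}"
            )
        if not self.observed.any(axis=1).all():
            raise ValueError("at least one person has no observed responses")
        if not self.observed.any(axis=0).all():
            raise ValueError("at least one item has no observed responses")
        clean = np.where(self.observed, np.asarray(self.values, dtype=float), 0.0)
        self.values = clean.astype(np.int8)
        if not self.person_ids:
            self.person_ids = [f"p{p + 1}" for p in range(P)]
        if not self.item_ids:
            self.item_ids = [f"i{i + 1}" for i in range(I)]
        if len(self.person_ids) != P or len(self.item_ids) != I:
            raise ValueError("id lists must match matrix dimensions")
        if len(set(self.person_ids)) != P:
            raise ValueError("duplicate person ids")
        if len(set(self.item_ids)) != I:
            raise ValueError("duplicate item ids")

    @property
    def n_persons(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_items(self) -> int:
        return int(self.values.shape[1])


@dataclass
class ModelConfig:
    """Latent dimension and prior hyperparameters.

    Defaults follow the recommended specification: item intercepts
    N(0, 5^2), half-Cauchy(25) on the ability variance, standard-normal
    latent coordinates, and a spike N(-5, 1) / slab N(0.5, 1) mixture on
    log(lambda) with prior slab weight 0.5.
    """

    K: int = 2
    sigma_b: float = 5.0
    sigma_cauchy_scale: float = 25.0
    mu_spike: float = -5.0
    mu_slab: float = 0.5
    sd_spike: float = 1.0
    sd_slab: float = 1.0
    slab_prior_weight: float = 0.5
    #: place the half-Cauchy on sigma rather than on the variance sigma^2
    cauchy_on_sigma: bool = False

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("latent dimension K must be >= 1")
        for name in ("sigma_b", "sigma_cauchy_scale", "sd_spike", "sd_slab"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.slab_prior_weight < 1.0:
            raise ValueError("slab_prior_weight must be in (0, 1)")


@dataclass
class ParameterState:
    """One full parameter configuration (theta, b, sigma^2, log lambda, Xi, Z)."""

    theta: np.ndarray
    b: np.ndarray
    sigma2: float
    log_lambda: float
    xi: np.ndarray
    zeta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        self.zeta = np.asarray(self.zeta, dtype=float)
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        P, I = self.theta.shape[0], self.b.shape[0]
        if self.xi.shape[0] != P or self.zeta.shape[0] != I:
            raise ValueError("position row counts must match theta/b lengths")
        if self.xi.shape[1] != self.zeta.shape[1]:
            raise ValueError("xi and zeta must share the latent dimension K")

    @property
    def lam(self) -> float:
        return float(np.exp(self.log_lambda))


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two K-vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def distance_matrix(xi: np.ndarray, zeta: np.ndarray) -> np.ndarray:
    """All pairwise person-item distances, shape (P, I)."""
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    zeta = np.atleast_2d(np.asarray(zeta, dtype=float))
    if xi.shape[1] != zeta.shape[1]:
        raise ValueError("xi and zeta must share the latent dimension K")
    diff = xi[:, None, :] - zeta[None, :, :]
    return np.sqrt(np.einsum("pik,pik->pi", diff, diff))


def linear_predictor(
    theta_p: float, b_i: float, lam: float, xi_p: np.ndarray, zeta_i: np.ndarray
) -> float:
    """Log-odds of a correct response: theta_p + b_i - lambda * d(xi_p, zeta_i)."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    return float(theta_p + b_i - lam * euclidean_distance(xi_p, zeta_i))


def bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Elementwise Bernoulli log-probability with logit ``eta``.

    Uses y*eta - log(1 + exp(eta)) via logaddexp, stable for large |eta|.
    """
    eta = np.asarray(eta, dtype=float)
    return y * eta - np.logaddexp(0.0, eta)


def log_likelihood(Y: ResponseMatrix, s: ParameterState) -> float:
    """Sum of Bernoulli log-probabilities over observed cells."""
    if s.theta.shape[0] != Y.n_persons or s.b.shape[0] != Y.n_items:
        raise ValueError("state dimensions do not match the response matrix")
    lam = s.lam
    eta = s.theta[:, None] + s.b[None, :]
    if lam != 0.0:
        eta = eta - lam * distance_matrix(s.xi, s.zeta)
    cell = bernoulli_loglik(eta, np.asarray(Y.values, dtype=float))
    return float(np.sum(cell[Y.observed]))


def _normal_logpdf_sum(x: np.ndarray, sd: float) -> float:
    x = np.asarray(x, dtype=float)
    return float(-0.5 * x.size * np.log(2.0 * np.pi * sd * sd) - np.sum(x * x) / (2.0 * sd * sd))


def half_cauchy_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return _LOG_2_OVER_PI - np.log(scale) - np.log1p((x / scale) ** 2)


def log_lambda_mixture_logpdf(log_lambda: float, c: ModelConfig) -> float:
    """Marginal spike-and-slab mixture log-density of log(lambda).

    log[(1-w) N(mu_spike, sd_spike) + w N(mu_slab, sd_slab)], computed with
    log-sum-exp.
    """
    w = c.slab_prior_weight
    a0 = np.log1p(-w) + stats.norm.logpdf(log_lambda, c.mu_spike, c.sd_spike)
    a1 = np.log(w) + stats.norm.logpdf(log_lambda, c.mu_slab, c.sd_slab)
    return float(np.logaddexp(a0, a1))


def log_prior(s: ParameterState, c: ModelConfig) -> float:
    """Log prior density of a full parameter state.

    The density of sigma^2 is half-Cauchy on the variance by default; with
    ``cauchy_on_sigma`` it is half-Cauchy on sigma, transformed to the
    sigma^2 coordinate (Jacobian 1/(2 sigma)).
    """
    if s.sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    lp = _normal_logpdf_sum(s.theta, np.sqrt(s.sigma2))
    lp += _normal_logpdf_sum(s.b, c.sigma_b)
    if c.cauchy_on_sigma:
        sigma = float(np.sqrt(s.sigma2))
        lp += half_cauchy_logpdf(sigma, c.sigma_cauchy_scale) - np.log(2.0 * sigma)
    else:
        lp += half_cauchy_logpdf(float(s.sigma2), c.sigma_cauchy_scale)
    lp += _normal_logpdf_sum(s.xi, 1.0)
    lp += _normal_logpdf_sum(s.zeta, 1.0)
    lp += log_lambda_mixture_logpdf(s.log_lambda, c)
    return float(lp)


def log_posterior(Y: ResponseMatrix, s: ParameterState, c: ModelConfig) -> float:
    return log_likelihood(Y, s) + log_prior(s, c)


def slab_responsibility(log_lambda, c: ModelConfig):
    """Posterior probability that log(lambda) came from the slab component.

    w * N_slab / [(1-w) * N_spike + w * N_slab], evaluated elementwise;
    increasing in log_lambda when the slab mean exceeds the spike mean.
    """
    ll = np.asarray(log_lambda, dtype=float)
    w = c.slab_prior_weight
    a0 = np.log1p(-w) + stats.norm.logpdf(ll, c.mu_spike, c.sd_spike)
    a1 = np.log(w) + stats.norm.logpdf(ll, c.mu_slab, c.sd_slab)
    out = 1.0 / (1.0 + np.exp(a0 - a1))
    if np.ndim(log_lambda) == 0:
        return float(out)
    return out


def lognormal_moments(mu: float, sd: float) -> dict[str, float]:
    """Mean, mode and SD of exp(X) for X ~ N(mu, sd^2).

    For the default slab N(0.5, 1) these are 2.718 / 0.607 / 3.563; for the
    spike N(-5, 1) they are 0.011 / 0.002 / 0.015.
    """
    s2 = sd * sd
    mean = float(np.exp(mu + s2 / 2.0))
    mode = float(np.exp(mu - s2))
    var = (np.exp(s2) - 1.0) * np.exp(2.0 * mu + s2)
    return {"mean": mean, "mode": mode, "sd": float(np.sqrt(var))}
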