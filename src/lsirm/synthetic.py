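"""Seeded generators for recovery studies and operating characteristics.

Three regimes:

``lsirm``
    Forward simulation of the full model: abilities N(0, sigma_theta^2),
    easiness intercepts N(0, b_sd^2), person positions standard normal,
    item positions either Gaussian or clustered (blob centers equally
    spaced on a circle), responses Bernoulli(logistic(theta + b - gamma*d)).
``rasch``
    Same main effects with no latent space (gamma = 0).
``multifactor``
    Simple-structure multidimensional data: each item loads (with one
    common loading) on exactly one of several correlated person factors.
    A unidimensional fit to such data shows the unmodeled factors as item
    clusters in the latent space, which is the phenomenon the cluster
    analytics are designed to surface.

Defaults are the conditions used throughout the test suite: sigma_theta=1,
b ~ N(0,1), 3 item blobs of SD 0.3 on a circle of radius 2, and a 7-factor
x 8-item battery with factor correlation 0.5 and loading 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.metrics import adjusted_rand_score

from .model import ResponseMatrix, distance_matrix

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "simulate_lsirm",
    "simulate_rasch",
    "simulate_multifactor",
    "recovery_metrics",
]


@dataclass
class GeneratorConfig:
    n_persons: int = 200
    n_items: int = 20
    K: int = 2
    regime: str = "lsirm"
    gamma: float = 2.0
    sigma_theta: float = 1.0
    b_sd: float = 1.0
    position_model: str = "clustered"  # or "gaussian"
    n_blobs: int = 3
    blob_sd: float = 0.3
    blob_radius: float = 2.0
    n_factors: int = 7
    items_per_factor: int = 8
    factor_corr: float = 0.5
    loading: float = 1.5
    missing_rate: float = 0.0
    #: offset intercepts by gamma * mean(d) so the distance effect perturbs
    #: accuracy around the Rasch level instead of collapsing it to ~0
    center_intercepts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 2 or self.n_items < 2:
            raise ValueError("need at least 2 persons and 2 items")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.regime not in ("lsirm", "rasch", "multifactor"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "rasch":
            self.gamma = 0.0
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SyntheticDataset:
    """Responses plus every generating truth, for recovery scoring."""

    responses: ResponseMatrix
    theta: np.ndarray
    b: np.ndarray
    gamma: float
    xi: np.ndarray | None = None
    zeta: np.ndarray | None = None
    item_labels: np.ndarray | None = None
    factors: np.ndarray | None = None
    seed: int = 0
    config: GeneratorConfig | None = None


def _bernoulli_matrix(eta: np.ndarray, rng: np.random.Generator, missing_rate: float):
    y = (rng.random(eta.shape) < expit(eta)).astype(np.int8)
    observed = np.ones(eta.shape, dtype=bool)
    if missing_rate > 0:
        observed = rng.random(eta.shape) >= missing_rate
        # keep every row and column at least partly observed
        for p in np.where(~observed.any(axis=1))[0]:
            observed[p, rng.integers(eta.shape[1])] = True
        for i in np.where(~observed.any(axis=0))[0]:
            observed[rng.integers(eta.shape[0]), i] = True
    return y, observed


def _blob_positions(g: GeneratorConfig, rng: np.random.Generator):
    angles = 2.0 * np.pi * np.arange(g.n_blobs) / g.n_blobs
    centers = g.blob_radius * np.column_stack([np.cos(angles), np.sin(angles)])
    if g.K != 2:
        extra = np.zeros((g.n_blobs, g.K - 2))
        centers = np.column_stack([centers[:, : min(2, g.K)], extra])[:, : g.K]
    labels = np.repeat(np.arange(g.n_blobs), int(np.ceil(g.n_items / g.n_blobs)))[
        : g.n_items
    ]
    zeta = centers[labels] + g.blob_sd * rng.standard_normal((g.n_items, g.K))
    return zeta, labels


def simulate_lsirm(g: GeneratorConfig) -> SyntheticDataset:
    """Forward-simulate the full model with a latent space."""
    if g.regime != "lsirm":
        raise ValueError("config regime must be 'lsirm'")
    rng = np.random.default_rng(g.seed)
    theta = g.sigma_theta * rng.standard_normal(g.n_persons)
    b = g.b_sd * rng.standard_normal(g.n_items)
    xi = rng.standard_normal((g.n_persons, g.K))
    if g.position_model == "clustered":
        zeta, labels = _blob_positions(g, rng)
    elif g.position_model == "gaussian":
        zeta = rng.standard_normal((g.n_items, g.K))
        labels = None
    else:
        raise ValueError(f"unknown position model {g.position_model!r}")
    D = distance_matrix(xi, zeta)
    if g.center_intercepts and g.gamma > 0:
        # without this, eta has mean -gamma*E[d]: nearly every response fails
        # and the data carry almost no information about theta
        b = b + g.gamma * float(D.mean())
    eta = theta[:, None] + b[None, :] - g.gamma * D
    y, observed = _bernoulli_matrix(eta, rng, g.missing_rate)
    return SyntheticDataset(
        responses=ResponseMatrix(values=y, observed=observed),
        theta=theta,
        b=b,
        gamma=g.gamma,
        xi=xi,
        zeta=zeta,
        item_labels=labels,
        seed=g.seed,
        config=g,
    )


def simulate_rasch(g: GeneratorConfig) -> SyntheticDataset:
    """Rasch-only data: main effects, no person-item interaction."""
    if g.regime != "rasch":
        raise ValueError("config regime must be 'rasch'")
    rng = np.random.default_rng(g.seed)
    theta = g.sigma_theta * rng.standard_normal(g.n_persons)
    b = g.b_sd * rng.standard_normal(g.n_items)
    eta = theta[:, None] + b[None, :]
    y, observed = _bernoulli_matrix(eta, rng, g.missing_rate)
    return SyntheticDataset(
        responses=ResponseMatrix(values=y, observed=observed),
        theta=theta,
        b=b,
        gamma=0.0,
        seed=g.seed,
        config=g,
    )


def simulate_multifactor(g: GeneratorConfig) -> SyntheticDataset:
    """Simple-structure correlated-factor data (one factor per item block)."""
    if g.regime != "multifactor":
        raise ValueError("config regime must be 'multifactor'")
    if g.n_factors * g.items_per_factor != g.n_items:
        raise ValueError(
            f"{g.n_items} items cannot be split into {g.n_factors} factors "
            f"of {g.items_per_factor}"
        )
    rng = np.random.default_rng(g.seed)
    corr = np.full((g.n_factors, g.n_factors), g.factor_corr)
    np.fill_diagonal(corr, 1.0)
    # eigh handles the singular corr = 1 boundary (all factors identical)
    factors = rng.multivariate_normal(
        np.zeros(g.n_factors), corr, size=g.n_persons, method="eigh"
    )
    labels = np.repeat(np.arange(g.n_factors), g.items_per_factor)
    b = g.b_sd * rng.standard_normal(g.n_items)
    eta = g.loading * factors[:, labels] + b[None, :]
    y, observed = _bernoulli_matrix(eta, rng, g.missing_rate)
    return SyntheticDataset(
        responses=ResponseMatrix(values=y, observed=observed),
        theta=factors.mean(axis=1),
        b=b,
        gamma=0.0,
        item_labels=labels,
        factors=factors,
        seed=g.seed,
        config=g,
    )


def recovery_metrics(
    truth: SyntheticDataset,
    theta_hat: np.ndarray,
    b_hat: np.ndarray,
    xi_hat: np.ndarray | None = None,
    zeta_hat: np.ndarray | None = None,
    item_labels_hat=None,
) -> dict[str, float]:
    """Score a fit against generating truth.

    Positions are scored only through the person-item distance matrix,
    which is invariant to the rigid transforms the model cannot identify;
    raw coordinates are never compared.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    b_hat = np.asarray(b_hat, dtype=float)
    if theta_hat.shape != truth.theta.shape or b_hat.shape != truth.b.shape:
        raise ValueError("estimate shapes do not match the truth")
    out: dict[str, float] = {
        "theta_corr": float(np.corrcoef(truth.theta, theta_hat)[0, 1]),
        "theta_rmse": float(np.sqrt(np.mean((truth.theta - theta_hat) ** 2))),
        "b_corr": float(np.corrcoef(truth.b, b_hat)[0, 1]),
        "b_rmse": float(np.sqrt(np.mean((truth.b - b_hat) ** 2))),
    }
    if xi_hat is not None and zeta_hat is not None and truth.xi is not None:
        D_true = distance_matrix(truth.xi, truth.zeta)
        D_hat = distance_matrix(np.asarray(xi_hat), np.asarray(zeta_hat))
        out["distance_corr"] = float(
            np.corrcoef(D_true.ravel(), D_hat.ravel())[0, 1]
        )
    if item_labels_hat is not None and truth.item_labels is not None:
        out["ari"] = float(
            adjusted_rand_score(truth.item_labels, np.asarray(item_labels_hat))
        )
    return out
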