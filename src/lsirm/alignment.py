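"""Procrustes alignment of posterior latent-position draws.

The distance effect is invariant to any common translation, rotation or
reflection of the person and item positions, so raw position draws from
different iterations live in arbitrarily rotated frames.  Following the
standard multidimensional-scaling remedy, the draw with the highest joint
log-posterior is chosen as a reference configuration, and every other draw
(persons and items stacked into one matrix, so person-item distances are
preserved) is matched to it by an orthogonal Procrustes transform without
scaling.  Point estimates of the positions are the elementwise means of
the aligned draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .sampling import PosteriorSamples

__all__ = [
    "Configuration",
    "AlignedPosterior",
    "select_reference",
    "procrustes_transform",
    "align_posterior",
]


@dataclass
class Configuration:
    """A stacked (P+I) x K matrix of person positions over item positions."""

    coords: np.ndarray
    n_persons: int
    n_items: int
    source_index: int | None = None  # pooled draw index this came from

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape[0] != self.n_persons + self.n_items:
            raise ValueError("row count must equal n_persons + n_items")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("configuration contains non-finite entries")

    @property
    def persons(self) -> np.ndarray:
        return self.coords[: self.n_persons]

    @property
    def items(self) -> np.ndarray:
        return self.coords[self.n_persons :]


@dataclass
class AlignedPosterior:
    """Aligned position draws (pooled over chains) and their means."""

    xi: np.ndarray  # (N, P, K)
    zeta: np.ndarray  # (N, I, K)
    xi_mean: np.ndarray  # (P, K)
    zeta_mean: np.ndarray  # (I, K)
    reference_index: int
    samples: PosteriorSamples


def select_reference(s: PosteriorSamples) -> Configuration:
    """Configuration of the retained draw with the highest joint log-posterior.

    Draws are pooled over chains in chain-major order; ties resolve to the
    earliest (chain, iteration).
    """
    if s.xi is None:
        raise ValueError("Rasch-only fit has no latent positions to align")
    lp = s.pooled("log_posterior")
    if lp.size == 0:
        raise ValueError("no retained draws")
    idx = int(np.argmax(lp))  # argmax returns the first maximal index
    xi = s.pooled("xi")[idx]
    zeta = s.pooled("zeta")[idx]
    return Configuration(
        coords=np.vstack([xi, zeta]),
        n_persons=xi.shape[0],
        n_items=zeta.shape[0],
        source_index=idx,
    )


def procrustes_transform(x: Configuration, ref: Configuration) -> Configuration:
    """Rigidly match ``x`` to ``ref``: center, rotate/reflect (no scaling),
    then restore the reference centroid.  All pairwise distances within
    ``x`` are preserved exactly."""
    if x.coords.shape != ref.coords.shape:
        raise ValueError("configurations must share a shape")
    xc = x.coords - x.coords.mean(axis=0)
    rc = ref.coords - ref.coords.mean(axis=0)
    if np.allclose(xc, 0.0):
        aligned = x.coords - x.coords.mean(axis=0) + ref.coords.mean(axis=0)
    else:
        R, _ = orthogonal_procrustes(xc, rc)
        aligned = xc @ R + ref.coords.mean(axis=0)
    return Configuration(
        coords=aligned,
        n_persons=x.n_persons,
        n_items=x.n_items,
        source_index=x.source_index,
    )


def align_posterior(s: PosteriorSamples) -> AlignedPosterior:
    """Match every retained draw to the highest-posterior reference draw.

    Only positions change; theta, b, sigma^2 and lambda draws pass through
    untouched in ``samples``.
    """
    ref = select_reference(s)
    xi_draws = s.pooled("xi")
    zeta_draws = s.pooled("zeta")
    N, P, K = xi_draws.shape
    I = zeta_draws.shape[1]
    xi_out = np.empty_like(xi_draws)
    zeta_out = np.empty_like(zeta_draws)
    for n in range(N):
        conf = Configuration(
            coords=np.vstack([xi_draws[n], zeta_draws[n]]),
            n_persons=P,
            n_items=I,
        )
        aligned = procrustes_transform(conf, ref)
        xi_out[n] = aligned.persons
        zeta_out[n] = aligned.items
    return AlignedPosterior(
        xi=xi_out,
        zeta=zeta_out,
        xi_mean=xi_out.mean(axis=0),
        zeta_mean=zeta_out.mean(axis=0),
        reference_index=int(ref.source_index),
        samples=s,
    )
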