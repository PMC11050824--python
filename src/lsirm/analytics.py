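"""Interaction-map analytics.

Once a latent space has been estimated, everything of applied interest is
a function of person-item distances: item distance matrices and item
clusters, cluster centers and inter-cluster distances, person-wise mean
distances and their association with external covariates, perceived
per-person item difficulty intervals, and personalized feedback records.
All quantities here operate on point estimates (aligned posterior means);
plots, when wanted, are thin renderings of these tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering

from .alignment import AlignedPosterior
from .model import ResponseMatrix

__all__ = [
    "ClusterSummary",
    "PersonClusterDistances",
    "PerceivedDifficulty",
    "OverlayResult",
    "person_item_distances",
    "item_distance_matrix",
    "cluster_centers",
    "inter_cluster_distance_table",
    "person_cluster_distances",
    "person_mean_distance",
    "perceived_difficulty",
    "covariate_overlay",
    "feedback_report",
    "cluster_items",
]


@dataclass
class ClusterSummary:
    """Cluster centers (mean member positions), pairwise center distances,
    and each cluster's mean distance to the other clusters."""

    cluster_ids: list
    centers: np.ndarray  # (C, K)
    distances: np.ndarray | None = None  # (C, C)
    mean_distance: np.ndarray | None = None  # (C,)

    def to_frame(self) -> pd.DataFrame:
        K = self.centers.shape[1]
        cols = {f"center_dim{k + 1}": self.centers[:, k] for k in range(K)}
        df = pd.DataFrame(cols, index=pd.Index(self.cluster_ids, name="cluster"))
        if self.distances is not None:
            for j, cid in enumerate(self.cluster_ids):
                df[f"d_to_{cid}"] = self.distances[:, j]
            df["mean_distance"] = self.mean_distance
        return df


@dataclass
class PersonClusterDistances:
    """P x C table of person-to-cluster distances plus, per person, the
    farthest cluster (argmax; ties resolve to the lowest cluster index)."""

    table: pd.DataFrame  # index person ids, columns cluster ids
    method: str
    farthest: pd.Series  # person id -> cluster id


@dataclass
class PerceivedDifficulty:
    """Per-item effects b_i - lambda * d(xi_p, zeta_i) across persons.

    ``mean_effect`` is the Rasch-comparable per-item average; ``low`` and
    ``high`` bound the between-person spread.  With lambda = 0 every
    interval collapses to b_i.
    """

    effects: pd.DataFrame  # P x I per-person effects
    summary: pd.DataFrame  # per item: b_hat, mean_effect, low, high

    def to_frame(self) -> pd.DataFrame:
        return self.summary


@dataclass
class OverlayResult:
    """Per-person (position, covariate, mean distance) records plus group
    summaries (categorical) or a correlation (continuous)."""

    records: pd.DataFrame
    group_summary: pd.DataFrame | None
    correlation: float | None
    unmatched_ids: list


def person_item_distances(xi: np.ndarray, zeta: np.ndarray) -> np.ndarray:
    """P x I Euclidean distances between person and item positions."""
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    zeta = np.atleast_2d(np.asarray(zeta, dtype=float))
    if xi.shape[1] != zeta.shape[1]:
        raise ValueError("xi and zeta must share the latent dimension")
    return cdist(xi, zeta)


def item_distance_matrix(zeta: np.ndarray) -> np.ndarray:
    """I x I inter-item distance matrix (symmetric, zero diagonal)."""
    zeta = np.atleast_2d(np.asarray(zeta, dtype=float))
    if zeta.shape[0] < 2:
        raise ValueError("need at least two items")
    D = cdist(zeta, zeta)
    np.fill_diagonal(D, 0.0)
    return D


def _cluster_ids(labels) -> list:
    return sorted(pd.unique(np.asarray(labels)).tolist())


def cluster_centers(zeta: np.ndarray, labels) -> ClusterSummary:
    """Cluster center = arithmetic mean of the member item positions."""
    zeta = np.atleast_2d(np.asarray(zeta, dtype=float))
    labels = np.asarray(labels)
    if labels.shape[0] != zeta.shape[0]:
        raise ValueError("one label per item required")
    ids = _cluster_ids(labels)
    centers = np.vstack([zeta[labels == cid].mean(axis=0) for cid in ids])
    if np.isnan(centers).any():
        raise ValueError("empty cluster")
    return ClusterSummary(cluster_ids=ids, centers=centers)


def inter_cluster_distance_table(centers: ClusterSummary | np.ndarray) -> ClusterSummary:
    """Pairwise center distances and per-cluster means over the others."""
    if isinstance(centers, ClusterSummary):
        summary = centers
    else:
        arr = np.atleast_2d(np.asarray(centers, dtype=float))
        summary = ClusterSummary(cluster_ids=list(range(1, arr.shape[0] + 1)), centers=arr)
    C = summary.centers.shape[0]
    if C < 2:
        raise ValueError("need at least two clusters")
    D = cdist(summary.centers, summary.centers)
    np.fill_diagonal(D, 0.0)
    mean = D.sum(axis=1) / (C - 1)
    return ClusterSummary(
        cluster_ids=summary.cluster_ids,
        centers=summary.centers,
        distances=D,
        mean_distance=mean,
    )


def person_cluster_distances(
    xi: np.ndarray,
    zeta: np.ndarray,
    labels,
    method: str = "per-item-mean",
    person_ids: list | None = None,
) -> PersonClusterDistances:
    """Distances from each person to each item cluster.

    ``per-item-mean`` averages the person's distances to the cluster's
    items; ``centroid`` measures the distance to the cluster center.  The
    per-item mean is never smaller than the centroid distance (convexity
    of the norm).
    """
    if method not in ("per-item-mean", "centroid"):
        raise ValueError(f"unknown method {method!r}")
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    labels = np.asarray(labels)
    ids = _cluster_ids(labels)
    if method == "centroid":
        centers = cluster_centers(zeta, labels).centers
        table = cdist(xi, centers)
    else:
        D = person_item_distances(xi, zeta)
        table = np.column_stack([D[:, labels == cid].mean(axis=1) for cid in ids])
    pids = person_ids if person_ids is not None else list(range(1, xi.shape[0] + 1))
    df = pd.DataFrame(table, index=pd.Index(pids, name="person"), columns=ids)
    farthest = pd.Series(
        [ids[j] for j in np.argmax(table, axis=1)], index=df.index, name="farthest_cluster"
    )
    return PersonClusterDistances(table=df, method=method, farthest=farthest)


def person_mean_distance(D: np.ndarray) -> np.ndarray:
    """Person-wise mean distance to all items (row means)."""
    return np.asarray(D, dtype=float).mean(axis=1)


def perceived_difficulty(
    b_hat: np.ndarray,
    lambda_hat: float,
    D: np.ndarray,
    item_ids: list | None = None,
    person_ids: list | None = None,
) -> PerceivedDifficulty:
    """Between-person variation in item difficulty via distance effects.

    For item i the per-person effect is b_i - lambda * d(xi_p, zeta_i);
    its spread across persons is the perceived-difficulty interval, and
    its per-person average b_i - lambda * mean_p d is directly comparable
    to a Rasch intercept estimate.
    """
    if lambda_hat < 0:
        raise ValueError("lambda must be nonnegative")
    b_hat = np.asarray(b_hat, dtype=float)
    D = np.asarray(D, dtype=float)
    if D.shape[1] != b_hat.shape[0]:
        raise ValueError("D columns must match the number of items")
    effects = b_hat[None, :] - lambda_hat * D
    iids = item_ids if item_ids is not None else list(range(1, b_hat.shape[0] + 1))
    pids = person_ids if person_ids is not None else list(range(1, D.shape[0] + 1))
    eff = pd.DataFrame(effects, index=pd.Index(pids, name="person"), columns=iids)
    summary = pd.DataFrame(
        {
            "b_hat": b_hat,
            "mean_effect": effects.mean(axis=0),
            "low": effects.min(axis=0),
            "high": effects.max(axis=0),
        },
        index=pd.Index(iids, name="item"),
    )
    return PerceivedDifficulty(effects=eff, summary=summary)


def covariate_overlay(
    xi: np.ndarray,
    mean_distances: np.ndarray,
    person_ids: list,
    covariates: pd.DataFrame,
    variable: str,
    id_column: str = "person",
) -> OverlayResult:
    """Join a covariate onto person positions and mean distances.

    Categorical covariates yield per-group mean/SD/count of the person
    mean distance; numeric covariates yield the Pearson correlation with
    it.  Persons without a covariate row are dropped and reported.
    """
    if variable not in covariates.columns:
        raise KeyError(f"covariate {variable!r} not found")
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    base = pd.DataFrame(
        {
            "person": person_ids,
            "mean_distance": np.asarray(mean_distances, dtype=float),
            **{f"dim{k + 1}": xi[:, k] for k in range(xi.shape[1])},
        }
    )
    cov = covariates[[id_column, variable]].rename(columns={id_column: "person"})
    cov["person"] = cov["person"].astype(str)
    base["person"] = base["person"].astype(str)
    merged = base.merge(cov, on="person", how="left")
    unmatched = merged.loc[merged[variable].isna(), "person"].tolist()
    records = merged.dropna(subset=[variable]).reset_index(drop=True)
    group_summary = None
    correlation = None
    if pd.api.types.is_numeric_dtype(records[variable]):
        if records.shape[0] >= 2 and records[variable].nunique() >= 2:
            correlation = float(
                np.corrcoef(records[variable], records["mean_distance"])[0, 1]
            )
    else:
        group_summary = (
            records.groupby(variable, observed=True)["mean_distance"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
    return OverlayResult(
        records=records,
        group_summary=group_summary,
        correlation=correlation,
        unmatched_ids=unmatched,
    )


def cluster_items(item_D: np.ndarray, n_clusters: int) -> np.ndarray:
    """Average-linkage agglomerative grouping of the item distance matrix.

    Convenience for exploratory use when no cluster labels are supplied.
    """
    model = AgglomerativeClustering(
        n_clusters=n_clusters, metric="precomputed", linkage="average"
    )
    return model.fit_predict(np.asarray(item_D, dtype=float))


def feedback_report(
    person_id,
    aligned: AlignedPosterior,
    Y: ResponseMatrix,
    labels=None,
    cluster_method: str = "per-item-mean",
) -> dict:
    """Personalized feedback from person-item distances.

    Ranks items (and clusters, when labels are given) by distance,
    farthest first: larger distance means the person underperformed on
    that material relative to what ability and item easiness predict.
    """
    if person_id not in Y.person_ids:
        raise KeyError(f"unknown person id {person_id!r}")
    p = Y.person_ids.index(person_id)
    s = aligned.samples
    theta_hat = float(s.pooled("theta")[:, p].mean())
    d_row = person_item_distances(aligned.xi_mean[p : p + 1], aligned.zeta_mean)[0]
    order = np.argsort(-d_row, kind="stable")
    obs = Y.observed[p]
    acc = float(np.asarray(Y.values, dtype=float)[p][obs].mean())
    report = {
        "person_id": person_id,
        "theta_hat": theta_hat,
        "position": aligned.xi_mean[p].tolist(),
        "accuracy": acc,
        "items_by_distance": [
            {"item_id": Y.item_ids[i], "distance": float(d_row[i])} for i in order
        ],
    }
    if labels is not None:
        pcd = person_cluster_distances(
            aligned.xi_mean[p : p + 1],
            aligned.zeta_mean,
            labels,
            method=cluster_method,
        )
        row = pcd.table.iloc[0]
        ranked = row.sort_values(ascending=False, kind="stable")
        report["clusters_by_distance"] = [
            {"cluster": cid, "distance": float(val)} for cid, val in ranked.items()
        ]
        report["farthest_cluster"] = pcd.farthest.iloc[0]
    return report
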