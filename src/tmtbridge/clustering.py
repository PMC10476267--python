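"""Trajectory vectors, k-means clustering, and cross-condition matching.

Each regulated protein is summarized by a three-component trajectory: its
log2 mean myoblast abundance, then the EM_vs_M and LM_vs_M log2 fold changes,
with every component column standardized over the clustered set to median 0
and (population) SD 1. k = 5 clusters capture the canonical expression
trends; clusters from two conditions are matched by minimum-cost assignment
on centroid Euclidean distances, which formalizes matching "the same trend"
across treatments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .errors import ClusteringError
from .normalize import BridgedAbundance

TRAJECTORY_COLUMNS = ("m_log2_std", "log2fc_em_std", "log2fc_lm_std")


def build_trajectories(
    bridged: BridgedAbundance, mr_ids: list[str] | set[str], condition: str
) -> pd.DataFrame:
    """Standardized trajectory vectors for a regulated-protein set.

    Components are computed from the condition's own replicate groups, then
    each column is median-centered and scaled by its population SD over the
    given set. Raises if any column has zero spread (degenerate input).
    """
    ids = sorted(mr_ids)
    if not ids:
        raise ClusteringError("empty protein set for trajectory building")
    missing = [p for p in ids if p not in bridged.log2.index]
    if missing:
        raise ClusteringError(f"proteins absent from bridged data: {missing[:5]}")

    m = bridged.group_values(condition, "M").loc[ids].mean(axis=1)
    em = bridged.group_values(condition, "EM").loc[ids].mean(axis=1)
    lm = bridged.group_values(condition, "LM").loc[ids].mean(axis=1)
    raw = pd.DataFrame(
        {"m_log2": m, "log2fc_em": em - m, "log2fc_lm": lm - m}, index=ids
    )
    if raw.isna().any().any():
        bad = raw.index[raw.isna().any(axis=1)].tolist()
        raise ClusteringError(f"incomplete trajectories (missing group means): {bad[:5]}")

    out = {}
    for src, dst in zip(raw.columns, TRAJECTORY_COLUMNS):
        col = raw[src]
        sd = float(np.std(col.to_numpy(), ddof=0))
        # spread at float round-off level carries no information either
        if sd <= 1e-12 * max(1.0, float(np.max(np.abs(col.to_numpy())))):
            raise ClusteringError(f"column {src!r} has zero spread; cannot standardize")
        out[dst] = (col - float(np.median(col))) / sd
    traj = pd.DataFrame(out, index=ids)
    traj.index.name = "protein_id"
    return traj


@dataclass
class ClusterModel:
    """Fitted k-means model over trajectory vectors."""

    k: int
    centroids: np.ndarray = field(repr=False)
    assignments: pd.Series = field(repr=False)  # protein_id -> cluster label (0-based)
    inertia: float = 0.0
    seed: int = 0
    n_restarts: int = 50

    @property
    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    def members(self, label: int) -> set[str]:
        return set(self.assignments.index[self.assignments == label])


def kmeans_cluster(
    trajectories: pd.DataFrame, k: int = 5, seed: int = 17, n_restarts: int = 50
) -> ClusterModel:
    """Lloyd's k-means with k-means++ seeding, best of ``n_restarts`` by WCSS."""
    X = trajectories.to_numpy(dtype=float)
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k:
        raise ClusteringError(f"only {n_distinct} distinct trajectory vectors for k={k}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_restarts,
        algorithm="lloyd", random_state=seed,
    ).fit(X)
    assignments = pd.Series(km.labels_, index=trajectories.index, name="cluster")
    return ClusterModel(
        k=k, centroids=km.cluster_centers_, assignments=assignments,
        inertia=float(km.inertia_), seed=seed, n_restarts=n_restarts,
    )


@dataclass
class ClusterMatch:
    """One-to-one cluster correspondence between two conditions."""

    mapping: dict[int, int]  # label in A -> label in B
    total_distance: float
    overlap: pd.DataFrame  # per matched pair: shared/only_a/only_b counts

    def permutation(self) -> list[int]:
        return [self.mapping[i] for i in sorted(self.mapping)]


def match_clusters(model_a: ClusterModel, model_b: ClusterModel) -> ClusterMatch:
    """Optimal label correspondence minimizing total centroid distance.

    Overlap counts are computed over the proteins the two models share:
    |A_i ∩ B_j|, |A_i \\ B_j| and |B_j \\ A_i| for each matched pair (i, j).
    """
    if model_a.k != model_b.k:
        raise ClusteringError(f"cluster count mismatch: {model_a.k} vs {model_b.k}")
    shared = model_a.assignments.index.intersection(model_b.assignments.index)
    if shared.empty:
        raise ClusteringError("models share no proteins")
    cost = cdist(model_a.centroids, model_b.centroids)
    rows, cols = linear_sum_assignment(cost)
    mapping = {int(i): int(j) for i, j in zip(rows, cols)}
    total = float(cost[rows, cols].sum())

    records = []
    for i, j in mapping.items():
        a = model_a.members(i) & set(shared)
        b = model_b.members(j) & set(shared)
        records.append(
            {
                "cluster_a": i, "cluster_b": j,
                "centroid_distance": float(cost[i, j]),
                "shared": len(a & b), "only_a": len(a - b), "only_b": len(b - a),
            }
        )
    overlap = pd.DataFrame.from_records(records).sort_values("cluster_a").reset_index(drop=True)
    return ClusterMatch(mapping=mapping, total_distance=total, overlap=overlap)


def brute_force_match_distance(model_a: ClusterModel, model_b: ClusterModel) -> float:
    """Minimum total centroid distance over all k! label permutations.

    Exponential; independent oracle for the assignment solution at small k.
    """
    cost = cdist(model_a.centroids, model_b.centroids)
    k = model_a.k
    return min(sum(cost[i, perm[i]] for i in range(k)) for perm in permutations(range(k)))
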