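"""Developmental expression clustering across the endosperm time course.

Per-gene expression trajectories (replicate-mean RPM per time point for one
cross direction) are max-normalized to [0, 1] — 1 marks the time point of
peak expression — and clustered with k-means (k = 9 by default). Cluster
assignments fitted on one cross direction can be transferred to the
reciprocal direction to check that developmental dynamics are consistent
regardless of which parent contributed the allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io_tables import ExpressionMatrix

__all__ = ["ClusterModel", "max_normalize", "fit_kmeans", "transfer_clusters"]


@dataclass
class ClusterModel:
    """A fitted k-means model over normalized trajectories."""

    k: int
    centroids: pd.DataFrame  # cluster x time point
    assignments: pd.Series  # gene -> cluster label (1..k)
    inertia: float
    seed: int


def max_normalize(
    expr: ExpressionMatrix | pd.DataFrame, maternal: str | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each gene's trajectory so its maximum time point equals 1.

    Accepts either a gene x time-point mean-RPM DataFrame, or an
    :class:`ExpressionMatrix` with the maternal genotype of the direction to
    average. All-zero genes are dropped. Ties at the maximum all receive
    1.0; the reported peak time point is the earliest. Returns the
    normalized trajectories and the per-gene peak time point.
    """
    if isinstance(expr, ExpressionMatrix):
        if maternal is None:
            raise ValueError("maternal genotype required with an ExpressionMatrix")
        df = expr.dap_means(maternal)
    else:
        df = expr.astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError("expression values must be nonnegative")
    rowmax = df.max(axis=1)
    kept = df[rowmax > 0]
    traj = kept.div(rowmax[rowmax > 0], axis=0)
    max_dap = traj.apply(lambda r: r.index[np.argmax(r.to_numpy())], axis=1)
    max_dap.name = "max_dap"
    return traj, max_dap


def fit_kmeans(
    trajectories: pd.DataFrame,
    k: int = 9,
    seed: int = 0,
    restarts: int = 25,
) -> ClusterModel:
    """Lloyd's k-means with k-means++ starts over normalized trajectories.

    ``restarts`` independent initializations are run and the lowest
    within-cluster sum of squares kept, so the fit is deterministic given
    the seed. Cluster labels are canonicalized 1..k by centroid peak time
    point and then by decreasing peak sharpness (max minus mean), making
    labels stable under gene-order permutations.
    """
    if len(trajectories) < k:
        raise ValueError(f"need at least k={k} trajectories, got {len(trajectories)}")
    X = trajectories.sort_index().to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    centroids = km.cluster_centers_

    peak = centroids.argmax(axis=1)
    sharpness = centroids.max(axis=1) - centroids.mean(axis=1)
    order = np.lexsort((-sharpness, peak))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)

    assignments = pd.Series(
        relabel[labels], index=trajectories.sort_index().index, name="cluster"
    ).reindex(trajectories.index)
    centroid_df = pd.DataFrame(
        centroids[order], index=np.arange(1, k + 1), columns=trajectories.columns
    )
    centroid_df.index.name = "cluster"
    return ClusterModel(
        k=k,
        centroids=centroid_df,
        assignments=assignments,
        inertia=float(km.inertia_),
        seed=seed,
    )


def transfer_clusters(
    model: ClusterModel, reciprocal_trajectories: pd.DataFrame
) -> pd.Series:
    """Carry fitted cluster labels over to the reciprocal cross direction.

    Each gene in the reciprocal direction inherits the cluster of the same
    gene in the fitted direction (identity transfer), enabling the visual
    consistency check of per-cluster reciprocal trajectories. Genes absent
    from either direction are dropped.
    """
    shared = reciprocal_trajectories.index.intersection(model.assignments.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between the two cross directions")
    return model.assignments.loc[shared]
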