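"""Clustering of developmental expression trajectories.

Per-gene stage-mean expression is row-standardised (subtract mean, divide by
sample SD across stages) and partitioned by K-means (best of 20 random
initialisations, at most 20 Lloyd iterations).  A scree table of total
within-cluster sum of squares over a k range supports the elbow choice; the
automatic suggestion is advisory and never applied silently.  Clusters are
then tested for GWAS enrichment both absolutely and conditional on the
parent set they partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .geneset_assoc import SetResult, competitive_test, conditional_subset_test
from .io import DevgsaError

logger = logging.getLogger(__name__)


@dataclass
class TrajectoryMatrix:
    """Row-standardised genes x stages matrix (each row mean 0, SD 1)."""

    values: pd.DataFrame
    dropped_constant: list[str]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClusterAssignment:
    """Gene -> 1-based cluster labels, canonicalised by descending size."""

    labels: pd.Series
    k: int
    within_ss: float
    seed: int
    n_restarts: int = 0

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def scale_trajectories(stage_means: pd.DataFrame) -> TrajectoryMatrix:
    """Standardise each gene's trajectory to mean 0, sample SD 1.

    Rows with zero SD (flat trajectories) carry no shape information and are
    dropped with a warning list; an all-constant input is fatal.
    """
    if stage_means.shape[1] < 2:
        raise DevgsaError("scale_trajectories needs >= 2 stages")
    vals = stage_means.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = list(stage_means.index[~keep])
    if dropped:
        logger.warning("dropping %d constant-trajectory genes", len(dropped))
    if not keep.any():
        raise DevgsaError("all trajectories constant; nothing to scale")
    vals = vals[keep]
    scaled = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return TrajectoryMatrix(
        pd.DataFrame(scaled, index=stage_means.index[keep], columns=stage_means.columns),
        dropped,
    )


def _canonicalise(labels: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by descending size, ties by centroid lexicographic order."""
    ids = np.unique(labels)
    sizes = {c: int((labels == c).sum()) for c in ids}
    order = sorted(ids, key=lambda c: (-sizes[c], tuple(np.round(centers[c], 10))))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping[c] for c in labels])


def kmeans_trajectories(
    tm: TrajectoryMatrix,
    k: int,
    n_starts: int = 20,
    max_iter: int = 20,
    seed: int = 0,
) -> ClusterAssignment:
    """Best-of-``n_starts`` Lloyd K-means on the scaled trajectories.

    Deterministic given the seed; labels are canonicalised so permuting
    gene order cannot change the reported partition.
    """
    X = tm.values.to_numpy(dtype=float)
    if not (2 <= k < X.shape[0]):
        raise DevgsaError(f"k={k} must satisfy 2 <= k < n_genes={X.shape[0]}")
    km = KMeans(
        n_clusters=k, init="random", n_init=n_starts, max_iter=max_iter,
        random_state=seed, algorithm="lloyd",
    ).fit(X)
    # sklearn's Lloyd implementation relocates empty clusters internally, so
    # the restart-on-empty branch never fires; the counter is kept for the
    # output contract.
    labels = _canonicalise(km.labels_, km.cluster_centers_)
    series = pd.Series(labels, index=tm.values.index, name="cluster")
    # sort genes for stable output regardless of input order
    series = series.loc[sorted(series.index)]
    return ClusterAssignment(series, k=k, within_ss=float(km.inertia_), seed=seed)


def scree(
    tm: TrajectoryMatrix,
    k_range: Sequence[int] = range(1, 11),
    n_starts: int = 20,
    max_iter: int = 20,
    seed: int = 0,
    drop_threshold: float = 0.10,
) -> pd.DataFrame:
    """Total within-cluster SS over ``k_range``, with an advisory elbow.

    The suggestion is the smallest k whose relative SS drop to k+1 falls
    below ``drop_threshold``; it is reported in a column, never applied.
    At k = 1 the within-SS equals the total variance around the grand
    centroid.
    """
    X = tm.values.to_numpy(dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 1 or k > X.shape[0] for k in ks):
        raise DevgsaError("scree: k_range outside [1, n_genes]")
    ss = []
    for k in ks:
        if k == 1:
            center = X.mean(axis=0, keepdims=True)
            ss.append(float(((X - center) ** 2).sum()))
        else:
            km = KMeans(
                n_clusters=k, init="random", n_init=n_starts, max_iter=max_iter,
                random_state=seed, algorithm="lloyd",
            ).fit(X)
            ss.append(float(km.inertia_))
    # enforce monotone non-increase (restart noise can leave tiny bumps)
    ss = list(np.minimum.accumulate(ss))
    suggestion = ks[-1]
    for i in range(len(ks) - 1):
        prev, nxt = ss[i], ss[i + 1]
        rel_drop = (prev - nxt) / prev if prev > 0 else 0.0
        if rel_drop < drop_threshold:
            suggestion = ks[i]
            break
    df = pd.DataFrame({"k": ks, "within_ss": ss})
    df["suggested_k"] = suggestion
    return df


def cluster_enrichment(
    assignment: ClusterAssignment,
    parent_set: Sequence[str],
    gene_z: Mapping[str, float] | pd.Series,
    covariates: pd.DataFrame | None = None,
    min_cluster_size: int = 5,
    parent_name: str = "parent",
) -> pd.DataFrame:
    """Absolute and conditional-on-parent enrichment for every cluster.

    For each cluster of the parent's genes: a competitive test of the
    cluster against the all-gene background, and the same test conditioning
    on the full parent set (does the cluster carry more signal than the
    parent as a whole?).  Clusters below ``min_cluster_size`` are flagged.
    """
    rows = []
    for c in sorted(assignment.labels.unique()):
        members = assignment.members(c)
        name = f"{parent_name}_cluster{c}"
        absolute = competitive_test(gene_z, members, covariates=covariates, set_name=name)
        conditional = conditional_subset_test(
            members, parent_set, gene_z, covariates=covariates,
            child_name=name, parent_name=parent_name,
        )
        rows.append(
            {
                "cluster": int(c),
                "n_genes": len(members),
                "small": len(members) < min_cluster_size,
                "beta": absolute.beta,
                "p": absolute.pvalue,
                "beta_conditional": conditional.beta,
                "p_conditional": conditional.pvalue,
                "degenerate": absolute.degenerate or conditional.degenerate,
            }
        )
    return pd.DataFrame(rows)


def cluster_child_crosstab(
    assignment: ClusterAssignment,
    children: Mapping[str, Sequence[str]],
    parent_set: Sequence[str],
    gene_z: Mapping[str, float] | pd.Series,
    covariates: pd.DataFrame | None = None,
    parent_name: str = "parent",
) -> pd.DataFrame:
    """Cluster x child-term table of conditional enrichments.

    For each (cluster, child term) cell, the genes in the intersection are
    tested conditionally on the full parent set.  Cells with no genes are
    skipped.
    """
    rows = []
    for c in sorted(assignment.labels.unique()):
        members = set(assignment.members(c))
        for child_name, child_genes in children.items():
            cell = [g for g in child_genes if g in members]
            if not cell:
                continue
            res = conditional_subset_test(
                cell, parent_set, gene_z, covariates=covariates,
                child_name=f"{child_name}_cluster{c}", parent_name=parent_name,
            )
            rows.append(
                {
                    "cluster": int(c),
                    "child": child_name,
                    "n_genes": len(cell),
                    "beta_conditional": res.beta,
                    "p_conditional": res.pvalue,
                    "degenerate": res.degenerate,
                }
            )
    return pd.DataFrame(rows)
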