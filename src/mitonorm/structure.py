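"""Unsupervised structure discovery: row scaling, hierarchical clustering
with a fixed-k cut, classical (Torgerson) MDS, timepoint profile summaries
and hypergeometric over-representation of feature sets."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import SampleDesign, ValidationError
from .de import adjust_bh

logger = logging.getLogger("mitonorm")

__all__ = [
    "ClusterResult",
    "EnrichmentResult",
    "classical_mds",
    "hierarchical_cluster",
    "overrepresentation_test",
    "profile_summary",
    "zscore_rows",
]


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to mean 0 and sd 1 (sample-sd, n-1 convention).

    Constant rows (sd == 0) are dropped with a warning. Scaling a row by any
    positive factor leaves its z-scores unchanged.
    """
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("dropping %d constant row(s) before z-scoring",
                       int(constant.sum()))
    kept = matrix.loc[~constant]
    return kept.sub(mean[~constant], axis=0).div(sd[~constant], axis=0)


@dataclass
class ClusterResult:
    assignments: pd.Series  # feature -> cluster id in 1..k
    linkage_method: str
    metric: str
    merge_tree: np.ndarray  # scipy linkage matrix (children, heights)
    leaf_order: list = field(default_factory=list)  # dendrogram row order

    @property
    def k(self) -> int:
        return int(self.assignments.max())


def hierarchical_cluster(matrix: pd.DataFrame, linkage: str = "complete",
                         k: int = 6, metric: str = "euclidean",
                         zscore: bool = True) -> ClusterResult:
    """Agglomerative clustering of rows with a fixed-k cut.

    Rows are z-scored (sample-sd convention) before computing distances
    unless ``zscore=False``; distances are Euclidean by default with a
    correlation-distance switch. The merge tree, the k-cluster assignment
    and the dendrogram leaf order (the heatmap row order) are returned.
    Ties in the distance matrix are broken by scipy's deterministic
    agglomeration order, so results depend only on the data, not on run.
    """
    if linkage not in {"complete", "average"}:
        raise ValidationError("linkage must be 'complete' or 'average'")
    data = zscore_rows(matrix) if zscore else matrix
    if k > len(data.index):
        raise ValidationError(
            f"k={k} exceeds the {len(data.index)} clusterable rows"
        )
    dist = pdist(data.to_numpy(dtype=float), metric=metric)
    tree = hierarchy.linkage(dist, method=linkage)
    flat = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    leaves = hierarchy.leaves_list(tree)
    return ClusterResult(
        assignments=pd.Series(flat, index=data.index, name="cluster"),
        linkage_method=linkage,
        metric=metric,
        merge_tree=tree,
        leaf_order=[data.index[i] for i in leaves],
    )


def classical_mds(matrix: pd.DataFrame, n_dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling of samples.

    Double-centres the squared Euclidean sample-sample distance matrix and
    embeds samples on the top eigenvectors scaled by sqrt(eigenvalue). The
    embedding is deterministic up to sign; each axis's sign is fixed by
    making its largest-magnitude coordinate positive. If fewer positive
    eigenvalues than ``n_dims`` exist, the available dimensions are
    returned with a warning.
    """
    if matrix.shape[1] < 3:
        raise ValidationError("MDS needs at least 3 samples")
    x = matrix.to_numpy(dtype=float).T  # samples x features
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    n = sq.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-12, 1e-9 * abs(eigval[0]))
    avail = int(positive.sum())
    if avail < n_dims:
        logger.warning("only %d positive eigenvalue(s); returning %d dim(s)",
                       avail, avail)
    dims = min(n_dims, avail)
    coords = eigvec[:, :dims] * np.sqrt(eigval[:dims])
    for d in range(dims):
        if coords[np.argmax(np.abs(coords[:, d])), d] < 0:
            coords[:, d] = -coords[:, d]
    return pd.DataFrame(coords, index=matrix.columns,
                        columns=[f"dim{i + 1}" for i in range(dims)])


def profile_summary(matrix: pd.DataFrame, design: SampleDesign,
                    feature_sets: dict[str, set]) -> pd.DataFrame:
    """Per-set, per-timepoint mean z-score profiles.

    Rows are z-scored; for each feature the per-timepoint mean over that
    timepoint's samples is taken, then averaged over the set's features.
    Returns a tidy table (set, timepoint, mean_z, sd_z, n_features); empty
    sets yield missing values with a warning.
    """
    z = zscore_rows(matrix)
    tp = design.timepoint_of().reindex(z.columns)
    timepoints = [t for t in design.timepoints if t in set(tp)]
    per_tp = pd.DataFrame(
        {t: z.loc[:, (tp == t).to_numpy()].mean(axis=1) for t in timepoints}
    )
    rows = []
    for name, members in feature_sets.items():
        idx = per_tp.index.intersection(pd.Index(list(members)))
        if len(idx) == 0:
            logger.warning("profile set %r has no features in the matrix",
                           name)
            for t in timepoints:
                rows.append((name, t, np.nan, np.nan, 0))
            continue
        block = per_tp.loc[idx]
        for t in timepoints:
            rows.append((name, t, float(block[t].mean()),
                         float(block[t].std(ddof=1)) if len(idx) > 1 else 0.0,
                         len(idx)))
    return pd.DataFrame(rows, columns=["set", "timepoint", "mean_z",
                                       "sd_z", "n_features"])


@dataclass
class EnrichmentResult:
    pathway: str
    overlap: int
    cluster_size: int
    pathway_size: int
    universe_size: int
    p_value: float
    adj_p: float = np.nan


def overrepresentation_test(cluster_features, pathway_sets: dict,
                            universe) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each pathway in a feature set.

    The upper-tail probability of drawing at least the observed overlap when
    sampling ``len(cluster)`` features from the universe; pathways are
    intersected with the universe first; BH adjustment across pathways.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    cluster = set(cluster_features) & universe
    results = []
    for name, members in pathway_sets.items():
        pw = set(members) & universe
        overlap = len(cluster & pw)
        # P(X >= overlap), X ~ Hypergeom(N=|U|, K=|pw|, n=|cluster|)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(pw),
                                     len(cluster)))
        results.append(EnrichmentResult(
            pathway=name, overlap=overlap, cluster_size=len(cluster),
            pathway_size=len(pw), universe_size=len(universe),
            p_value=min(p, 1.0),
        ))
    adj = adjust_bh(np.array([r.p_value for r in results])) if results else []
    for r, a in zip(results, adj):
        r.adj_p = float(a)
    return results
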