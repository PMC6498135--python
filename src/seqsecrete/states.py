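"""Two-state clustering of dynamic secretion profiles.

Complete time courses are flattened into an n_cells x (T*K) matrix of
log2-gated signals (window-major: all proteins at window 0, then window 1,
...).  Two independent routes partition the population into two activation
states:

* agglomerative hierarchical clustering (Euclidean distance, Ward linkage,
  dendrogram cut at k = 2), and
* a 2-D t-SNE embedding followed by k-means (k = 2) on the embedding
  coordinates.

In both results cluster 1 is, by convention, the more secretion-active one
(higher grand-mean log2 signal).  Agreement between two partitions is the
maximum over the two label alignments of the fraction of cells on which they
coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

__all__ = ["StatesError", "ClusterResult", "OverlapReport",
           "build_feature_matrix", "hierarchical_states", "embedding_states",
           "cluster_overlap"]


class StatesError(ValueError):
    """Raised for invalid clustering inputs."""


def build_feature_matrix(courses, panel) -> pd.DataFrame:
    """n_cells x (T*K) matrix of log2 signals from complete courses.

    Columns are window-major (``<protein>_t0`` ... then t1, ...); rows are
    indexed by cell id.  Incomplete courses are rejected.
    """
    if not courses:
        raise StatesError("no courses given")
    bad = [c.cell_id for c in courses if not c.complete]
    if bad:
        raise StatesError(f"incomplete courses in feature matrix: {bad[:3]}...")
    T = courses[0].n_timepoints
    columns = [f"{p}_t{t}" for t in range(T) for p in panel]
    data = np.stack([c.log2.reshape(-1) for c in courses])
    return pd.DataFrame(data, columns=columns,
                        index=pd.Index([c.cell_id for c in courses],
                                       name="cell_id"))


@dataclass
class ClusterResult:
    """A 2-cluster partition; labels are 1 (more active) and 2."""

    method: str
    labels: pd.Series
    sizes: dict
    params: dict
    seed: int | None = None

    def aligned_to(self, other_labels: pd.Series) -> pd.Series:
        """Relabel (possibly swapping 1<->2) to best match other labels."""
        swapped = self.labels.map({1: 2, 2: 1})
        if (self.labels == other_labels).mean() >= (swapped == other_labels).mean():
            return self.labels
        return swapped


def _activity_ordered(labels: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Return labels in {1, 2} with cluster 1 the higher-mean-signal one."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise StatesError(f"expected 2 clusters, found {len(uniq)}")
    means = {u: X[labels == u].mean() for u in uniq}
    active = max(uniq, key=lambda u: means[u])
    return np.where(labels == active, 1, 2)


def hierarchical_states(matrix: pd.DataFrame, k: int = 2) -> ClusterResult:
    """Ward-linkage hierarchical clustering cut at k clusters.

    Deterministic; invariant to row order up to the activity-based label
    convention (which makes it fully invariant for k = 2).
    """
    X = np.asarray(matrix, dtype=float)
    if k > X.shape[0]:
        raise StatesError(f"k={k} exceeds n_cells={X.shape[0]}")
    if k != 2:
        raise StatesError("two-state analysis requires k=2")
    Z = linkage(X, method="ward", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = _activity_ordered(raw, X)
    series = pd.Series(labels, index=matrix.index, name="hierarchical")
    return ClusterResult(method="hierarchical", labels=series,
                         sizes={1: int((labels == 1).sum()),
                                2: int((labels == 2).sum())},
                         params={"linkage": "ward", "metric": "euclidean"})


def embedding_states(matrix: pd.DataFrame, k: int = 2, seed: int = 0, *,
                     perplexity: float = 30.0) -> ClusterResult:
    """2-D t-SNE embedding + k-means partition of the embedding.

    The perplexity is capped at (n_cells - 1) / 3 for small inputs.  Fixed
    seed gives identical labels across runs.
    """
    X = np.asarray(matrix, dtype=float)
    if k != 2:
        raise StatesError("two-state analysis requires k=2")
    if np.allclose(X, X[0]):
        raise StatesError("degenerate (constant) feature matrix")
    perplexity = min(perplexity, (X.shape[0] - 1) / 3)
    if perplexity < 2:
        raise StatesError(f"too few cells ({X.shape[0]}) for an embedding")
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=int(seed))
    emb = tsne.fit_transform(X)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed))
    raw = km.fit_predict(emb)
    labels = _activity_ordered(raw, X)
    series = pd.Series(labels, index=matrix.index, name="embedding")
    return ClusterResult(method="embedding", labels=series,
                         sizes={1: int((labels == 1).sum()),
                                2: int((labels == 2).sum())},
                         params={"perplexity": float(perplexity),
                                 "kmeans_n_init": 10},
                         seed=int(seed))


@dataclass
class OverlapReport:
    """Aligned agreement between two 2-cluster partitions."""

    agreement: float
    contingency: pd.DataFrame
    alignment: str  # "direct" or "swapped"


def cluster_overlap(a: ClusterResult, b: ClusterResult) -> OverlapReport:
    """Maximum aligned agreement between two partitions of the same cells."""
    if not a.labels.index.equals(b.labels.index):
        if set(a.labels.index) != set(b.labels.index):
            raise StatesError("cluster results cover different cell ids")
        b_labels = b.labels.reindex(a.labels.index)
    else:
        b_labels = b.labels
    direct = float((a.labels == b_labels).mean())
    swapped = float((a.labels == b_labels.map({1: 2, 2: 1})).mean())
    agreement = max(direct, swapped)
    contingency = pd.crosstab(a.labels, b_labels)
    return OverlapReport(agreement=agreement, contingency=contingency,
                         alignment="direct" if direct >= swapped else "swapped")
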