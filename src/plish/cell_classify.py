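"""Unsupervised classification of per-cell expression profiles.

Profiles come from :mod:`plish.image_quant` as mean intensities per gene. Each
gene is normalized onto a 0:10 scale against the largest value observed in any
cell over all fields of view, then log-transformed with log10(0.1 + x), which
maps the [0, 10] range onto roughly [-1, 1]. Clustering (k-means and
hierarchical), t-SNE embedding, marker-rule cell-type labeling and spatial
pseudocolor remapping all operate downstream of that transform. No spatial
information enters the clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

LOG_OFFSET = 0.1
NORM_SCALE = 10.0


def normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene onto 0:10 by its maximum over all cells and FOVs.

    ``x -> 10 * x / max(gene)``; the brightest cell of every gene maps to
    exactly 10. A gene whose values are all zero has no defined scale and
    raises, naming the gene.
    """
    out = matrix.copy().astype(float)
    for gene in out.columns:
        m = out[gene].max()
        if not m > 0:
            raise ValueError(f"gene {gene!r} is zero in every cell; normalization undefined")
        # clip the 1-ulp overshoot of (10*x)/max so the top cell is exactly 10
        out[gene] = np.minimum(NORM_SCALE * out[gene] / m, NORM_SCALE)
    return out


def log_transform(normalized: pd.DataFrame) -> pd.DataFrame:
    """Apply ``log10(0.1 + x)`` to a 0:10-normalized matrix.

    Maps 0 to -1 and 10 to log10(10.1) ~ 1.004; strictly monotone, so per-gene
    rank order is preserved.
    """
    vals = normalized.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > NORM_SCALE):
        bad = vals[(vals < 0) | (vals > NORM_SCALE)].flat[0]
        raise ValueError(f"value {bad} outside the normalized range [0, {NORM_SCALE}]")
    return np.log10(LOG_OFFSET + normalized)


@dataclass
class Classification:
    """K-means partition of cells with centroids in log-expression space."""

    labels: pd.Series  # per-cell cluster id, 1..k
    centroids: pd.DataFrame  # k x genes, rows indexed by cluster id
    cluster_names: dict[int, str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.centroids)

    def centroid_heatmap_table(self) -> pd.DataFrame:
        tbl = self.centroids.copy()
        tbl.insert(0, "cluster", tbl.index)
        if self.cluster_names:
            tbl.insert(1, "label", [self.cluster_names.get(c, "other") for c in tbl.index])
        return tbl.reset_index(drop=True)


def kmeans_classify(
    log_matrix: pd.DataFrame, k: int = 10, seed: int = 0, n_init: int = 50
) -> Classification:
    """Partition cells into k classes by k-means on log-expression profiles.

    Euclidean k-means with ``n_init`` restarts and a fixed seed, so identical
    input yields identical assignments. Cluster ids are 1..k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(log_matrix):
        raise ValueError(f"k={k} exceeds the number of cells ({len(log_matrix)})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(log_matrix.to_numpy(dtype=float)) + 1
    centroids = pd.DataFrame(
        km.cluster_centers_, columns=log_matrix.columns, index=range(1, k + 1)
    )
    return Classification(
        labels=pd.Series(labels, index=log_matrix.index, name="cluster"),
        centroids=centroids,
    )


def hierarchical_cluster(
    log_matrix: pd.DataFrame, method: str = "average", metric: str = "euclidean"
) -> tuple[np.ndarray, list]:
    """Agglomerative clustering of cells for heat-map ordering.

    Returns the scipy linkage matrix and the dendrogram leaf order (cell
    index labels).
    """
    if len(log_matrix) < 2:
        raise ValueError("need at least two cells to cluster")
    Z = hierarchy.linkage(log_matrix.to_numpy(dtype=float), method=method, metric=metric)
    order = hierarchy.leaves_list(Z)
    return Z, [log_matrix.index[i] for i in order]


def tsne_embed(
    log_matrix: pd.DataFrame, seed: int = 0, perplexity: float = 30.0
) -> pd.DataFrame:
    """Two-dimensional t-SNE embedding of log-expression profiles.

    Visualization only — embeddings never feed classification. Deterministic
    for a fixed seed. Requires more than 3x perplexity cells.
    """
    n = len(log_matrix)
    if n <= 3 * perplexity:
        raise ValueError(f"perplexity {perplexity} too large for {n} cells (need n > 3*perplexity)")
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    coords = ts.fit_transform(log_matrix.to_numpy(dtype=float))
    return pd.DataFrame(coords, columns=["tsne1", "tsne2"], index=log_matrix.index)


# ---------------------------------------------------------------------------
# marker rules


@dataclass(frozen=True)
class MarkerRule:
    """Label a cluster whose centroid is high in all listed marker genes.

    ``precedence`` breaks ties between matching rules: higher wins, so a
    double-positive rule (e.g. Sftpc+Scgb1a1 -> BASC) can dominate the
    single-positive rules it overlaps. By default precedence equals the number
    of markers.
    """

    label: str
    markers: tuple[str, ...]
    threshold: float = 0.0
    precedence: int | None = None

    @property
    def rank(self) -> int:
        return self.precedence if self.precedence is not None else len(self.markers)

    def matches(self, centroid: Mapping[str, float]) -> bool:
        return all(centroid[m] > self.threshold for m in self.markers)


def assign_cell_type(
    centroids: pd.DataFrame, rules: Sequence[MarkerRule]
) -> dict[int, str]:
    """Deterministically label clusters from marker-gene threshold rules.

    For each cluster centroid, the matching rule of highest precedence wins;
    clusters matching no rule are labeled "other". Two distinct labels matching
    at equal precedence is a configuration error and raises, listing the
    conflict.
    """
    out: dict[int, str] = {}
    for cid, row in centroids.iterrows():
        matched = [r for r in rules if r.matches(row)]
        if not matched:
            out[int(cid)] = "other"
            continue
        top = max(r.rank for r in matched)
        winners = {r.label for r in matched if r.rank == top}
        if len(winners) > 1:
            raise ValueError(
                f"cluster {cid}: rules {sorted(winners)} conflict at precedence {top}"
            )
        out[int(cid)] = winners.pop()
    return out


def pseudocolor_map(
    boundary_index_image: np.ndarray,
    classification: Classification,
    palette: Mapping[int, tuple[int, int, int]],
) -> np.ndarray:
    """Paint each nucleus boundary with its cluster's palette color.

    ``boundary_index_image`` carries the integer cell index on boundary
    pixels (zero elsewhere). Returns an RGB uint8 image with the background
    black. Every boundary index must be present in the classification.
    """
    bidx = np.asarray(boundary_index_image)
    rgb = np.zeros(bidx.shape + (3,), dtype=np.uint8)
    cells = np.unique(bidx)
    cells = cells[cells > 0]
    labels = classification.labels
    for cell in cells:
        if cell not in labels.index:
            raise ValueError(f"cell {int(cell)} in the boundary image has no classification")
        cluster = int(labels.loc[cell])
        rgb[bidx == cell] = palette[cluster]
    return rgb


def classify_profiles(
    profiles: pd.DataFrame,
    gene_columns: Sequence[str] | None = None,
    k: int = 10,
    seed: int = 0,
    n_init: int = 50,
) -> tuple[Classification, pd.DataFrame]:
    """Normalize, log-transform and k-means-classify a cell-profile table.

    ``profiles`` is the table from :func:`plish.image_quant.measure_profiles`
    (gene columns prefixed ``mean_``). Returns the classification and the
    log-transformed matrix indexed by cell id.
    """
    if gene_columns is None:
        gene_columns = [c for c in profiles.columns if c.startswith("mean_")]
    mat = profiles.set_index("cell")[list(gene_columns)]
    mat.columns = [c.removeprefix("mean_") for c in mat.columns]
    logm = log_transform(normalize(mat))
    return kmeans_classify(logm, k=k, seed=seed, n_init=n_init), logm
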