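"""Meta-clustering of pooled single cells and immune annotation.

Clustering follows the Phenograph recipe: an exact k-nearest-neighbor graph
(Euclidean distance over per-cell marker intensities, k = 75 by default),
edges reweighted by the Jaccard overlap of the two endpoints' neighbor
sets, then Louvain modularity maximization with a fixed seed. Clustering
runs on raw, untransformed per-cell mean intensities; z-scaling is applied
only for the cluster x marker heatmap (column-standardized medians,
population SD).

A meta-cluster is called immune when at least one immune-role marker stands
out in its profile (max column z >= 1 by default); remaining clusters are
collapsed into the single category "not immune cell". Immune clusters are
named by their dominant marker pattern (CD20 -> B-cell, CD68 -> Macrophage,
CD3+CD8 -> CTL, CD3 -> Other T-cell, CD45RA -> Naive T-cell, CD66a ->
Neutrophil, HLA-DR -> HLADR+, CD45 alone -> Other Leukocyte), with clusters
sharing a pattern numbered -1, -2, ... by decreasing size — the convention
for lineages that split into bright and dim variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .panel import MarkerPanel

logger = logging.getLogger(__name__)

NON_IMMUNE_LABEL = "not immune cell"

#: (marker requirements, base label) decision chain for immune clusters.
_LABEL_RULES = [
    (("CD20",), "B-cell"),
    (("CD68",), "Macrophage"),
    (("CD3", "CD8"), "CTL"),
    (("CD3",), "Other T-cell"),
    (("CD45RA",), "Naive T-cell"),
    (("CD66a",), "Neutrophil"),
    (("HLA-DR",), "HLADR+"),
    (("CD45",), "Other Leukocyte"),
]
#: Families the chain may number when several clusters share the pattern.
_NUMBERED = {"Macrophage", "CTL", "Other T-cell"}


@dataclass
class ClusterAssignment:
    """Per-cell meta-cluster ids plus per-cluster annotation.

    ``cell_cluster`` holds 1-based cluster ids aligned with the cell table;
    ``clusters`` has one row per meta-cluster (id, size, and — after
    annotation — immune flag and phenotype label).
    """

    cell_cluster: np.ndarray
    clusters: pd.DataFrame

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cell_labels(self) -> np.ndarray:
        """Per-cell phenotype label (annotation required)."""
        if "phenotype_label" not in self.clusters.columns:
            raise ValueError("assignment has not been annotated")
        lut = self.clusters.set_index("meta_cluster")["phenotype_label"]
        return lut.reindex(self.cell_cluster).to_numpy()

    def immune_cell_mask(self) -> np.ndarray:
        if "immune" not in self.clusters.columns:
            raise ValueError("assignment has not been annotated")
        lut = self.clusters.set_index("meta_cluster")["immune"]
        return lut.reindex(self.cell_cluster).to_numpy(dtype=bool)


@dataclass
class ClusterProfile:
    """Cluster x marker median matrix and its column-standardized z form."""

    medians: pd.DataFrame
    z: pd.DataFrame


def _jaccard_edges(indices: np.ndarray) -> list[tuple[int, int, float]]:
    """Jaccard-weighted edges of the exact kNN graph.

    ``indices``: (n, k) neighbor lists (self excluded). Every kNN link
    becomes a candidate edge weighted by |N_i & N_j| / |N_i | N_j|;
    zero-weight edges are dropped.
    """
    n, k = indices.shape
    nbr_sets = [set(row) for row in indices]
    edges = {}
    for i in range(n):
        for j in indices[i]:
            j = int(j)
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in edges:
                continue
            inter = len(nbr_sets[a] & nbr_sets[b])
            if inter == 0:
                continue
            union = 2 * k - inter
            edges[(a, b)] = inter / union
    return [(a, b, w) for (a, b), w in edges.items()]


def phenograph_cluster(
    cells: pd.DataFrame,
    markers: list[str],
    k: int = 75,
    seed: int = 0,
) -> ClusterAssignment:
    """kNN-Jaccard-Louvain clustering of cells in marker space.

    Cluster ids are 1-based and ordered by decreasing size. Deterministic
    for fixed input and seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(cells[list(markers)], dtype=np.float64)
    n = len(X)
    if n < 2:
        return ClusterAssignment(
            cell_cluster=np.ones(n, dtype=int),
            clusters=pd.DataFrame({"meta_cluster": [1][:n], "size": [n][:n]}),
        )
    if k >= n:
        logger.warning("k=%d >= n=%d cells; lowering k to %d", k, n, n - 1)
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto").fit(X)
    _, idx = nn.kneighbors(X)
    # drop self-neighbor; with duplicate points self may not be first
    cleaned = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = idx[i][idx[i] != i][:k]
        if len(row) < k:  # duplicates collapsed onto i itself
            row = np.concatenate([row, idx[i][idx[i] == i][: k - len(row)]])
        cleaned[i] = row[:k]
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    graph.add_weighted_edges_from(_jaccard_edges(cleaned))
    communities = nx.community.louvain_communities(graph, weight="weight", seed=seed)
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    cell_cluster = np.zeros(n, dtype=int)
    for cid, members in enumerate(communities, start=1):
        cell_cluster[list(members)] = cid
    clusters = pd.DataFrame(
        {
            "meta_cluster": np.arange(1, len(communities) + 1),
            "size": [len(c) for c in communities],
        }
    )
    return ClusterAssignment(cell_cluster=cell_cluster, clusters=clusters)


def tsne_embed(
    cells: pd.DataFrame,
    markers: list[str],
    perplexity: float = 30.0,
    theta: float = 0.5,
    seed: int = 0,
    initial_dims: int = 110,
) -> np.ndarray:
    """Barnes-Hut tSNE of cells in marker space; seeded and reproducible.

    The historical ``initial_dims`` cap (a PCA pre-reduction to 110
    dimensions) is a no-op for panels of <= 110 markers and is only
    recorded here for provenance.
    """
    X = np.asarray(cells[list(markers)], dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("marker values must be finite for tSNE")
    n = len(X)
    if n <= 3 * perplexity:
        new_p = max(2.0, (n - 1) / 3.0)
        logger.warning(
            "perplexity %.0f too large for n=%d; lowering to %.1f", perplexity, n, new_p
        )
        perplexity = new_p
    if X.shape[1] > initial_dims:  # pragma: no cover - panels are small
        logger.info("capping input dimensions at %d via PCA", initial_dims)
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        angle=theta,
        method="barnes_hut",
        init="pca",
        random_state=seed,
    ).fit_transform(X)
    return np.asarray(emb)


def profile_clusters(
    cells: pd.DataFrame,
    assignment: ClusterAssignment,
    markers: list[str],
) -> ClusterProfile:
    """Cluster x marker medians of per-cell mean intensity, with
    column-standardized z-scores (population SD; zero-SD columns -> 0)."""
    if assignment.n_clusters < 1:
        raise ValueError("at least one cluster required")
    df = cells[list(markers)].copy()
    df["meta_cluster"] = assignment.cell_cluster
    medians = df.groupby("meta_cluster")[list(markers)].median()
    from .quantify import _column_z

    return ClusterProfile(medians=medians, z=_column_z(medians))


def annotate_immune(
    assignment: ClusterAssignment,
    profile: ClusterProfile,
    panel: MarkerPanel,
    z_threshold: float = 1.0,
    half_max_frac: float = 0.5,
    min_median: float = 1.0,
) -> ClusterAssignment:
    """Flag immune meta-clusters and assign phenotype labels.

    A cluster is immune iff some immune-role marker both stands out
    relatively (column z >= ``z_threshold``) and carries real signal
    (median >= ``min_median`` counts) — the absolute floor keeps
    column-standardization from flagging pure noise when few clusters
    exist. Labels follow the dominant-marker decision
    chain; marker positivity for the chain uses median >= ``half_max_frac``
    x the column's maximum median, which keeps dim variants of a lineage
    positive for their defining markers. Non-immune clusters collapse to
    the single label "not immune cell".
    """
    immune_markers = [m for m in panel.immune_markers if m in profile.z.columns]
    if not immune_markers:
        raise ValueError("panel has no immune-role markers present in the profile")
    z = profile.z[immune_markers]
    med = profile.medians[immune_markers]
    col_max = med.max(axis=0)
    immune = ((z >= z_threshold) & (med >= min_median)).any(axis=1).to_dict()

    def positive(cluster, marker):
        if marker not in med.columns or col_max[marker] <= 0:
            return False
        return med.loc[cluster, marker] >= half_max_frac * col_max[marker]

    base_label = {}
    for cluster in profile.medians.index:
        if not immune[cluster]:
            base_label[cluster] = NON_IMMUNE_LABEL
            continue
        for required, label in _LABEL_RULES:
            if all(positive(cluster, m) for m in required):
                base_label[cluster] = label
                break
        else:
            base_label[cluster] = "Immune-other"

    clusters = assignment.clusters.copy()
    clusters["immune"] = clusters["meta_cluster"].map(immune)
    labels = {}
    by_base: dict[str, list[int]] = {}
    for cluster, base in base_label.items():
        by_base.setdefault(base, []).append(cluster)
    sizes = clusters.set_index("meta_cluster")["size"]
    for base, members in by_base.items():
        if base == NON_IMMUNE_LABEL:
            for c in members:
                labels[c] = base
        elif len(members) > 1 or base in _NUMBERED:
            ordered = sorted(members, key=lambda c: (-sizes[c], c))
            for rank, c in enumerate(ordered, start=1):
                labels[c] = f"{base}-{rank}"
        else:
            labels[c0 := members[0]] = base
    clusters["phenotype_label"] = clusters["meta_cluster"].map(labels)
    return replace(assignment, clusters=clusters)
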