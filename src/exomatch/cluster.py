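"""Single-linkage clustering of genes on constraint-metric profiles.

Genes are matched to controls by hierarchical clustering on ten z-scored
constraint metrics with the dissimilarity ``1 - |cor(x_i, x_j)|``, where
``cor`` is the Pearson correlation of two genes' 10-long metric profiles.
Single linkage agglomeration starts from singletons and repeatedly joins
the two least dissimilar clusters; cutting the tree at a height ``h`` in
[0, 1] applies every merge at height <= h.  Branches containing at least
one gene of interest (GOI) are clusters of interest (COIs); their non-GOI
members are the matched controls.

Cut heights are absolute dissimilarity units (the metric is bounded by 1),
so ``h = 1`` always yields the single whole-universe cluster.

Memory note: the dissimilarity is held as a condensed upper-triangle float64
array — about 1.5 GB at p ≈ 19k genes; tests and desk-scale fixtures run at
p <= 5,000.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .constraints import METRICS, ConstraintUniverse
from .sets import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "MetricMatrix",
    "MergeTree",
    "ClusterPartition",
    "COISelection",
    "normalize_metrics",
    "gene_dissimilarity",
    "dissimilarity_matrix",
    "build_tree",
    "cut_tree",
    "select_coi",
    "height_scan",
]

#: Soft guidance for choosing a cut height: keep COIs under ~20% of the
#: universe while aiming for a usable median cluster size (~8 genes).
MAX_RECOMMENDED_PROPORTION = 0.20
TARGET_MEDIAN_CLUSTER_SIZE = 8


@dataclass
class MetricMatrix:
    """q x p matrix of normalized metrics (rows) by genes (columns)."""

    values: np.ndarray
    gene_order: tuple[str, ...]
    metric_names: tuple[str, ...] = METRICS

    def __post_init__(self):
        q, p = self.values.shape
        if p != len(self.gene_order):
            raise ValueError("column count does not match gene_order")
        if q != len(self.metric_names):
            raise ValueError("row count does not match metric_names")


@dataclass
class MergeTree:
    """Single-linkage agglomeration history in scipy linkage-matrix form.

    ``linkage[i] = (left, right, height, size)``; heights live in [0, 1]
    and are non-decreasing (single-linkage monotonicity).
    """

    linkage: np.ndarray
    leaves: tuple[str, ...]

    def __post_init__(self):
        h = self.heights
        if len(h) and (h.min() < -1e-12 or h.max() > 1.0 + 1e-12):
            raise ValueError("merge heights outside [0, 1]")
        if np.any(np.diff(h) < -1e-12):
            raise ValueError("merge heights are not monotone non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths (parent height - child height)."""
        root = hierarchy.to_tree(self.linkage)

        def render(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return render(root, root.dist) + ";"


@dataclass
class ClusterPartition:
    """A flat cut of the tree: every gene in exactly one cluster."""

    cut_height: float
    labels: np.ndarray  # integer cluster id per gene, aligned to genes
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.genes):
            raise ValueError("labels and genes length mismatch")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    @property
    def assignment(self) -> dict[str, int]:
        return dict(zip(self.genes, (int(c) for c in self.labels)))

    def cluster_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


@dataclass
class COISelection:
    """Clusters of interest for one GOI set at one cut height."""

    goi: frozenset[str]
    coi_cluster_ids: frozenset[int]
    control_genes: frozenset[str]
    median_coi_size: float
    total_genes: int
    proportion: float
    partition: ClusterPartition

    @property
    def analysis_genes(self) -> tuple[str, ...]:
        """GOI + control genes, in universe order."""
        keep = self.goi | self.control_genes
        return tuple(g for g in self.partition.genes if g in keep)

    def summary(self) -> dict:
        return {
            "n_coi": len(self.coi_cluster_ids),
            "median_coi_size": self.median_coi_size,
            "total_genes": self.total_genes,
            "proportion": round(self.proportion, 3),
        }

    def to_frame(self) -> pd.DataFrame:
        """Per-gene table (gene, cluster_id, is_goi, is_control) over the COIs."""
        part = self.partition
        rows = [
            (g, int(c), g in self.goi, g in self.control_genes)
            for g, c in zip(part.genes, part.labels)
            if int(c) in self.coi_cluster_ids
        ]
        return pd.DataFrame(rows, columns=["gene", "cluster_id", "is_goi", "is_control"])


def normalize_metrics(universe: ConstraintUniverse) -> MetricMatrix:
    """z-score each metric across genes (sample standard deviation).

    Idempotent up to numerical tolerance; a metric constant across genes is
    an error because it cannot be scaled to unit variance.
    """
    if universe.size < 2:
        raise ValueError("need at least 2 genes to normalize")
    m = universe.metrics().to_numpy(dtype=np.float64).T  # q x p
    mean = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    constant = np.isclose(sd[:, 0], 0.0)
    if constant.any():
        names = [METRICS[i] for i in np.flatnonzero(constant)]
        raise ValueError(f"metric(s) constant across genes, cannot normalize: {names}")
    return MetricMatrix((m - mean) / sd, universe.symbols)


def gene_dissimilarity(xi: np.ndarray, xj: np.ndarray) -> float:
    """``1 - |Pearson cor|`` between two genes' metric profiles, in [0, 1]."""
    xi = np.asarray(xi, float)
    xj = np.asarray(xj, float)
    if xi.shape != xj.shape or xi.ndim != 1:
        raise ValueError("metric vectors must be 1-D with equal length")
    si, sj = xi.std(), xj.std()
    if si == 0.0 or sj == 0.0:
        raise ValueError("zero-variance metric vector: correlation undefined")
    r = float(np.mean((xi - xi.mean()) * (xj - xj.mean())) / (si * sj))
    return float(min(max(1.0 - abs(r), 0.0), 1.0))


def dissimilarity_matrix(matrix: MetricMatrix) -> np.ndarray:
    """Condensed (upper-triangle) 1 - |cor| dissimilarities over gene pairs."""
    c = np.corrcoef(matrix.values, rowvar=False)
    if not np.isfinite(c).all():
        raise ValueError("non-finite gene-gene correlation (zero-variance profile?)")
    d = 1.0 - np.abs(c)
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, 1.0, out=d)
    return squareform(d, checks=False)


def build_tree(matrix: MetricMatrix) -> MergeTree:
    """Single-linkage agglomeration over the 1 - |cor| dissimilarities."""
    if len(matrix.gene_order) < 2:
        raise ValueError("need at least 2 genes to build a tree")
    condensed = dissimilarity_matrix(matrix)
    linkage = hierarchy.linkage(condensed, method="single")
    # guard against fp round-off pushing heights past the [0, 1] bound
    linkage[:, 2] = np.clip(linkage[:, 2], 0.0, 1.0)
    return MergeTree(linkage, matrix.gene_order)


def cut_tree(tree: MergeTree, h: float) -> ClusterPartition:
    """Apply all merges at height <= ``h``; genes share a cluster iff the
    maximum merge height on their tree path is <= h."""
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"cut height must be in [0, 1], got {h}")
    labels = hierarchy.fcluster(tree.linkage, t=h, criterion="distance")
    return ClusterPartition(cut_height=h, labels=labels, genes=tree.leaves)


def select_coi(partition: ClusterPartition, goi: GeneSet | frozenset[str] | set[str]) -> COISelection:
    """Flag clusters containing >= 1 GOI and collect their control genes."""
    goi_symbols = frozenset(goi.members if isinstance(goi, GeneSet) else goi)
    if not goi_symbols:
        raise ValueError("GOI set is empty")
    gene_index = {g: i for i, g in enumerate(partition.genes)}
    missing = sorted(goi_symbols - gene_index.keys())
    if missing:
        raise ValueError(f"GOI absent from the partition: {missing}")
    goi_idx = np.fromiter((gene_index[g] for g in goi_symbols), dtype=np.intp)
    coi_ids = frozenset(int(c) for c in np.unique(partition.labels[goi_idx]))
    in_coi = np.isin(partition.labels, sorted(coi_ids))
    members = [partition.genes[i] for i in np.flatnonzero(in_coi)]
    controls = frozenset(members) - goi_symbols
    sizes = [
        c for lab, c in partition.cluster_sizes().items() if lab in coi_ids
    ]
    total = int(sum(sizes))
    return COISelection(
        goi=goi_symbols,
        coi_cluster_ids=coi_ids,
        control_genes=controls,
        median_coi_size=float(np.median(sizes)),
        total_genes=total,
        proportion=total / len(partition.genes),
        partition=partition,
    )


def height_scan(tree: MergeTree, goi: GeneSet | set[str], heights) -> pd.DataFrame:
    """COI summaries over a list of cut heights (one row per height).

    Columns mirror the usual cut-height table: median COI size, total genes
    across COIs and the proportion of the universe they cover, plus a
    ``meets_guidance`` flag for the <= 20%-of-universe recommendation.
    Proportion is non-decreasing in height (cut refinement).
    """
    heights = list(heights)
    if not heights:
        raise ValueError("height list is empty")
    rows = []
    for h in sorted(heights):
        sel = select_coi(cut_tree(tree, h), goi)
        rows.append(
            {
                "height": h,
                "n_coi": len(sel.coi_cluster_ids),
                "median_coi_size": sel.median_coi_size,
                "total_genes": sel.total_genes,
                "proportion": round(sel.proportion, 3),
                "meets_guidance": sel.proportion <= MAX_RECOMMENDED_PROPORTION,
            }
        )
    return pd.DataFrame(rows)
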