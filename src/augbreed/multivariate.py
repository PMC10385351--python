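"""Multivariate characterization of selected genotypes.

All analyses operate on the Z-score standardized genotype x trait matrix:
dual Euclidean/UPGMA dendrograms (genotypes and traits) for a clustered
heatmap, principal component analysis with per-trait contributions and a
biplot, and a Pearson correlation network of the traits.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizedMatrix:
    """Z-scores with the column means and sample SDs used."""

    z: pd.DataFrame
    means: pd.Series
    sds: pd.Series


def zscore(matrix: pd.DataFrame) -> StandardizedMatrix:
    """Columnwise Z = (x - xbar) / s with the sample SD (n-1 denominator).

    Puts traits measured on different scales onto a common one.  A
    constant column is an error naming the trait.
    """
    means = matrix.mean()
    sds = matrix.std(ddof=1)
    constant = list(sds.index[(sds == 0) | sds.isna()])
    if constant:
        raise ValueError(
            f"constant (or single-value) traits cannot be standardized: "
            f"{constant}")
    z = (matrix - means) / sds
    return StandardizedMatrix(z=z, means=means, sds=sds)


# ---------------------------------------------------------------------------
# UPGMA clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """UPGMA merge tree: scipy linkage matrix plus the leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def leaf_order(self) -> list[str]:
        if len(self.labels) == 1:
            return list(self.labels)
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def upgma(dist: pd.DataFrame | np.ndarray,
          labels: list[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of a square distance matrix.

    Merge heights equal the unweighted mean inter-cluster distance, so
    the dendrogram is ultrametric: heights are non-decreasing along any
    root path.
    """
    if isinstance(dist, pd.DataFrame):
        labels = [str(x) for x in dist.index]
        dist = dist.to_numpy(dtype=float)
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = dist.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if n == 1:
        return Dendrogram(linkage=np.empty((0, 4)), labels=list(labels))
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=linkage, labels=list(labels))


def upgma_from_data(matrix: pd.DataFrame) -> Dendrogram:
    """UPGMA on pairwise Euclidean distances between the matrix rows."""
    n = matrix.shape[0]
    labels = [str(x) for x in matrix.index]
    if n == 1:
        return Dendrogram(linkage=np.empty((0, 4)), labels=labels)
    condensed = pdist(matrix.to_numpy(dtype=float), metric="euclidean")
    linkage = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=linkage, labels=labels)


def cut_clusters(tree: Dendrogram, k: int) -> pd.Series:
    """Cut the dendrogram into k clusters (labels 1..k by first leaf)."""
    n = len(tree.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be within [1, {n}], got {k}")
    if n == 1:
        raw = np.array([1])
    else:
        raw = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=pd.Index(tree.labels, name="id"),
                       name="cluster")
    # renumber clusters in order of first appearance for stable output
    remap = {old: new + 1 for new, old in
             enumerate(dict.fromkeys(labels.tolist()))}
    return labels.map(remap)


# ---------------------------------------------------------------------------
# heatmap layout
# ---------------------------------------------------------------------------

@dataclass
class HeatmapLayout:
    """Dual-dendrogram heatmap: trees, leaf orders, reordered Z matrix."""

    row_tree: Dendrogram
    col_tree: Dendrogram
    reordered: pd.DataFrame


def heatmap_layout(z: StandardizedMatrix | pd.DataFrame) -> HeatmapLayout:
    """Cluster genotypes (rows) and traits (columns) by Euclidean/UPGMA.

    The trait tree is built on the transposed matrix; the returned matrix
    is the Z matrix permuted to both leaf orders.
    """
    frame = z.z if isinstance(z, StandardizedMatrix) else z
    row_tree = upgma_from_data(frame)
    col_tree = upgma_from_data(frame.T)
    reordered = frame.loc[row_tree.leaf_order, col_tree.leaf_order]
    return HeatmapLayout(row_tree=row_tree, col_tree=col_tree,
                         reordered=reordered)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    """PCA of the standardized matrix (equivalently, of the trait
    correlation structure).

    ``loadings`` are variance-scaled (eigenvector * sqrt(eigenvalue)):
    the correlation of each trait with each component; ``contributions``
    are 100 * squared eigenvector entries, summing to 100 per component.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    eigenvectors: pd.DataFrame
    explained_pct: pd.Series
    contributions: pd.DataFrame
    eigenvalues: np.ndarray


def pca(z: StandardizedMatrix | pd.DataFrame) -> PcaResult:
    """Principal components of the Z-score matrix via SVD.

    Deterministic sign convention: each component's largest-magnitude
    eigenvector entry is made positive.  Rank-deficient input yields
    trailing zero-variance components; explained percentages sum to 100.
    """
    frame = z.z if isinstance(z, StandardizedMatrix) else z
    X = frame.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 genotypes")
    n_comp = min(n - 1, p)
    U, s, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    U, s, Vt = U[:, :n_comp], s[:n_comp], Vt[:n_comp]

    # sign convention: dominant entry of each eigenvector positive
    flip = np.sign(Vt[np.arange(n_comp), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]

    eigvals = s**2 / (n - 1)
    total = eigvals.sum()
    explained = 100.0 * eigvals / total if total > 0 else np.zeros(n_comp)

    comps = [f"PC{i + 1}" for i in range(n_comp)]
    scores = pd.DataFrame(U * s, index=frame.index, columns=comps)
    eigenvectors = pd.DataFrame(Vt.T, index=frame.columns, columns=comps)
    loadings = eigenvectors * np.sqrt(eigvals)
    contributions = 100.0 * eigenvectors**2
    return PcaResult(
        scores=scores, loadings=loadings, eigenvectors=eigenvectors,
        explained_pct=pd.Series(explained, index=comps, name="explained_pct"),
        contributions=contributions, eigenvalues=eigvals)


# ---------------------------------------------------------------------------
# correlation network
# ---------------------------------------------------------------------------

@dataclass
class CorrelationGraph:
    """Pearson correlations among traits plus the display graph.

    All pairwise r values are kept in ``corr``; the ``displayed`` edge
    attribute merely flags edges at or above the display threshold.
    """

    corr: pd.DataFrame
    graph: nx.Graph
    display_threshold: float


def correlation_network(values: pd.DataFrame,
                        display_threshold: float = 0.3) -> CorrelationGraph:
    """All pairwise Pearson correlations among traits as a graph.

    The threshold is cosmetic: sub-threshold edges stay in the graph
    (and in the matrix) but are flagged for visual de-emphasis.  A
    constant trait yields undefined correlations, kept as NaN and logged.
    """
    if values.shape[0] < 3:
        raise ValueError("correlation network requires >= 3 genotypes")
    corr = values.corr(method="pearson")
    constant = list(values.columns[values.std(ddof=1) == 0])
    if constant:
        logger.warning("constant traits with undefined correlations: %s",
                       constant)
    graph = nx.Graph()
    graph.add_nodes_from(corr.columns)
    for i, t1 in enumerate(corr.columns):
        for t2 in corr.columns[i + 1:]:
            r = corr.at[t1, t2]
            if pd.isna(r):
                continue
            graph.add_edge(t1, t2, r=float(r),
                           displayed=bool(abs(r) >= display_threshold))
    return CorrelationGraph(corr=corr, graph=graph,
                            display_threshold=display_threshold)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def plot_heatmap(z: StandardizedMatrix | pd.DataFrame,
                 path: str | Path) -> HeatmapLayout:
    """Clustered heatmap with the dual UPGMA dendrograms; writes a file."""
    import seaborn as sns
    import matplotlib.pyplot as plt

    frame = z.z if isinstance(z, StandardizedMatrix) else z
    layout = heatmap_layout(frame)
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        # degenerate layout: plain heatmap, no trees
        fig, ax = plt.subplots(figsize=(6, 4))
        sns.heatmap(layout.reordered, cmap="vlag", center=0, ax=ax)
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return layout
    grid = sns.clustermap(
        frame, row_linkage=layout.row_tree.linkage,
        col_linkage=layout.col_tree.linkage, cmap="vlag", center=0,
        figsize=(8, max(6, 0.16 * frame.shape[0])))
    grid.savefig(path, dpi=150)
    plt.close(grid.fig)
    return layout


def plot_biplot(result: PcaResult, path: str | Path,
                clusters: pd.Series | None = None) -> None:
    """PC1 x PC2 biplot: genotype scores plus trait loading vectors."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    pcs = result.scores.columns[:2]
    if len(pcs) < 2:
        raise ValueError("biplot requires at least two components")
    xs, ys = result.scores[pcs[0]], result.scores[pcs[1]]
    if clusters is not None:
        colors = clusters.reindex(result.scores.index).to_numpy()
        sc = ax.scatter(xs, ys, c=colors, cmap="Set1", s=18, alpha=0.8)
        ax.legend(*sc.legend_elements(), title="cluster", loc="best")
    else:
        ax.scatter(xs, ys, s=18, alpha=0.8)
    scale = 0.9 * max(xs.abs().max(), ys.abs().max())
    for trait in result.loadings.index:
        lx, ly = result.loadings.loc[trait, pcs[0]], result.loadings.loc[
            trait, pcs[1]]
        ax.annotate("", xy=(lx * scale, ly * scale), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="gray"))
        ax.annotate(trait, xy=(lx * scale * 1.07, ly * scale * 1.07),
                    color="black", fontsize=9, ha="center")
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    ax.set_xlabel(f"{pcs[0]} ({result.explained_pct[pcs[0]]:.1f}%)")
    ax.set_ylabel(f"{pcs[1]} ({result.explained_pct[pcs[1]]:.1f}%)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_network(graph: CorrelationGraph, path: str | Path) -> None:
    """Correlation network: edge colour encodes sign, width encodes |r|;
    sub-threshold edges are drawn faintly."""
    import matplotlib.pyplot as plt

    g = graph.graph
    pos = nx.circular_layout(g)
    fig, ax = plt.subplots(figsize=(6, 6))
    for u, v, data in g.edges(data=True):
        r = data["r"]
        alpha = 0.9 if data["displayed"] else 0.15
        color = "tab:green" if r >= 0 else "tab:red"
        ax.plot(*zip(pos[u], pos[v]), color=color, alpha=alpha,
                lw=0.5 + 4.0 * abs(r))
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color="lightsteelblue",
                           node_size=900)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=9)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
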