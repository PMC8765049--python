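"""Cluster-composition statistics, centroid similarity, and over-representation.

Covers the tumor-microenvironment bookkeeping questions asked of a
two-condition atlas: which side (left vs right tumor) each cluster's cells
came from, fold ratios of cell counts between conditions, the ratio-of-ratios
statistic comparing within-side preexhausted:exhausted CD8+ T-cell ratios,
Pearson-correlation similarity networks between cell-type centroids, average
linkage (UPGMA) dendrograms on correlation distance, and an upper-tail
hypergeometric over-representation test with BH correction across gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CompositionTable",
    "SimilarityNetwork",
    "composition_by_side",
    "fold_ratio",
    "exhaustion_ratio_of_ratios",
    "exhaustion_ratio_from_fractions",
    "cell_type_centroids",
    "centroid_correlation_network",
    "hclust_centroids",
    "dendrogram_newick",
    "ora_hypergeometric",
    "ora_collection",
]


@dataclass
class CompositionTable:
    """Cluster x side and cluster x sample cell counts with derived fractions."""

    by_side: pd.DataFrame          # clusters x sides, integer counts
    by_sample: pd.DataFrame        # clusters x samples, integer counts
    side_of_origin: pd.DataFrame   # clusters x sides, rows sum to 1
    cluster_mixture: pd.DataFrame  # clusters x sides, columns sum to 1


def composition_by_side(cell_meta: pd.DataFrame) -> CompositionTable:
    """Tabulate cells per cluster by side and by sample.

    ``cell_meta`` needs columns ``cluster``, ``side`` and ``sample_id``; any
    cell missing one of them is an error listing the offending barcodes.
    """
    required = ["cluster", "side", "sample_id"]
    missing_cols = [c for c in required if c not in cell_meta.columns]
    if missing_cols:
        raise ValueError(f"cell metadata lacks columns: {missing_cols}")
    bad = cell_meta.index[cell_meta[required].isna().any(axis=1)]
    if len(bad):
        shown = ", ".join(map(str, bad[:10]))
        raise ValueError(f"{len(bad)} cell(s) lack cluster/side/sample labels: {shown}")

    by_side = pd.crosstab(cell_meta["cluster"], cell_meta["side"])
    by_sample = pd.crosstab(cell_meta["cluster"], cell_meta["sample_id"])
    side_of_origin = by_side.div(by_side.sum(axis=1), axis=0)
    cluster_mixture = by_side.div(by_side.sum(axis=0), axis=1)
    return CompositionTable(by_side, by_sample, side_of_origin, cluster_mixture)


def fold_ratio(count_a: int, count_b: int) -> float:
    """count_a / count_b; NaN (an "undefined" marker, not a crash) if b == 0."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if count_b == 0:
        return float("nan")
    return count_a / count_b


def exhaustion_ratio_of_ratios(
    pre_left: int, pre_right: int, exh_left: int, exh_right: int
) -> float:
    """Left:right fold of the within-side preexhausted:exhausted cell ratio.

    (pre_left/exh_left) / (pre_right/exh_right).  Because cluster totals
    cancel, the same number follows from side-of-origin fractions alone:
    (fL_pre * fR_exh) / (fR_pre * fL_exh).
    """
    counts = {
        "pre_left": pre_left, "pre_right": pre_right,
        "exh_left": exh_left, "exh_right": exh_right,
    }
    for name, c in counts.items():
        if c <= 0:
            raise ValueError(f"count {name} must be positive, got {c}")
    return (pre_left / exh_left) / (pre_right / exh_right)


def exhaustion_ratio_from_fractions(pre_left_frac: float, exh_right_frac: float) -> float:
    """Same statistic from the two printed side-of-origin fractions.

    ``pre_left_frac`` is the left fraction of the preexhausted cluster and
    ``exh_right_frac`` the right fraction of the exhausted cluster; the two
    complements are implied.
    """
    for f in (pre_left_frac, exh_right_frac):
        if not 0 < f < 1:
            raise ValueError("fractions must lie strictly between 0 and 1")
    pre_right = 1.0 - pre_left_frac
    exh_left = 1.0 - exh_right_frac
    return (pre_left_frac * exh_right_frac) / (pre_right * exh_left)


@dataclass
class SimilarityNetwork:
    """Cell-type centroid similarity: nodes, centroid matrix, Pearson weights."""

    nodes: list[str]
    centroids: pd.DataFrame   # types x genes
    weights: pd.DataFrame     # types x types, Pearson r

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for i, a in enumerate(self.nodes):
            for b in self.nodes[i + 1 :]:
                g.add_edge(a, b, weight=float(self.weights.loc[a, b]))
        return g

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.nodes):
            for b in self.nodes[i + 1 :]:
                rows.append((a, b, float(self.weights.loc[a, b])))
        return pd.DataFrame(rows, columns=["type_a", "type_b", "pearson_r"])


def cell_type_centroids(
    expr: np.ndarray, features: list[str], labels, gene_space: list[str] | None = None
) -> pd.DataFrame:
    """Per-type mean expression (types x genes), restricted to ``gene_space``."""
    x = np.asarray(expr, dtype=float)  # genes x cells
    labels = pd.Series(list(labels))
    if gene_space is not None:
        absent = sorted(set(gene_space) - set(features))
        if absent:
            raise ValueError(f"gene space members absent from features: {absent[:5]}")
        idx = [features.index(g) for g in gene_space]
        x = x[idx, :]
        genes = list(gene_space)
    else:
        genes = list(features)
    out = {}
    for t in sorted(labels.unique()):
        mask = (labels == t).to_numpy()
        if mask.sum() == 0:
            warnings.warn(f"cell type {t!r} has no cells; dropped")
            continue
        out[t] = x[:, mask].mean(axis=1)
    return pd.DataFrame(out, index=genes).T


def centroid_correlation_network(
    expr: np.ndarray,
    features: list[str],
    labels,
    gene_space: list[str] | None = None,
) -> SimilarityNetwork:
    """Pearson correlation between per-type centroids over the gene space."""
    centroids = cell_type_centroids(expr, features, labels, gene_space)
    if centroids.shape[0] < 2:
        raise ValueError("need at least 2 cell types")
    if centroids.shape[1] < 3:
        raise ValueError("need at least 3 genes in the gene space")
    w = np.corrcoef(centroids.to_numpy())
    nodes = list(centroids.index)
    weights = pd.DataFrame(w, index=nodes, columns=nodes)
    return SimilarityNetwork(nodes, centroids, weights)


def hclust_centroids(centroids: pd.DataFrame) -> list[tuple[frozenset, frozenset, float]]:
    """UPGMA on correlation distance (1 - Pearson r) between centroids.

    Returns the merge list: each entry is (members of cluster A, members of
    cluster B, merge height).  Ties in the minimum distance are broken by the
    lexicographically smallest pair of cluster-member tuples, so the result
    is independent of input order.
    """
    names = list(centroids.index)
    if len(names) < 2:
        raise ValueError("need at least 2 centroids")
    x = centroids.to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = [names[i] for i in range(len(names)) if sd[i] == 0]
    if flat:
        raise ValueError(f"constant centroid(s), correlation undefined: {flat}")
    r = np.corrcoef(x)
    dist = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            dist[frozenset([names[i], names[j]])] = 1.0 - r[i, j]

    # active clusters as frozensets of leaf names; average linkage over leaf pairs
    active: list[frozenset] = [frozenset([n]) for n in names]
    leafdist = {(a, b): dist[frozenset([a, b])] for a in names for b in names if a < b}

    def d_leaf(a: str, b: str) -> float:
        return leafdist[(a, b)] if a < b else leafdist[(b, a)]

    def d_avg(ca: frozenset, cb: frozenset) -> float:
        return sum(d_leaf(a, b) for a in ca for b in cb) / (len(ca) * len(cb))

    def key(c: frozenset) -> tuple:
        return tuple(sorted(c))

    merges: list[tuple[frozenset, frozenset, float]] = []
    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                ca, cb = active[i], active[j]
                if key(cb) < key(ca):
                    ca, cb = cb, ca
                d = d_avg(ca, cb)
                cand = (d, key(ca), key(cb), ca, cb)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        d, _, _, ca, cb = best
        merges.append((ca, cb, d))
        active = [c for c in active if c is not ca and c is not cb] + [ca | cb]
    return merges


def dendrogram_newick(merges: list[tuple[frozenset, frozenset, float]]) -> str:
    """Newick string for a UPGMA merge list (ultrametric heights)."""
    node: dict[frozenset, str] = {}
    height: dict[frozenset, float] = {}
    for ca, cb, d in merges:
        for c in (ca, cb):
            if c not in node:
                if len(c) == 1:
                    node[c] = next(iter(c))
                    height[c] = 0.0
        h = d / 2.0
        sa = f"{node[ca]}:{h - height[ca]:.6g}"
        sb = f"{node[cb]}:{h - height[cb]:.6g}"
        merged = ca | cb
        node[merged] = f"({sa},{sb})"
        height[merged] = h
    return node[merges[-1][0] | merges[-1][1]] + ";"


def ora_hypergeometric(
    n_hits: int, n_set: int, overlap: int, universe: int
) -> float:
    """Upper-tail hypergeometric over-representation p-value, P(X >= overlap).

    ``n_hits`` genes of interest and a ``n_set``-gene set drawn from a
    ``universe``-gene background sharing ``overlap`` genes.
    """
    from scipy.stats import hypergeom

    if not (0 <= n_set <= universe and 0 <= n_hits <= universe):
        raise ValueError("set and hit list must fit inside the universe")
    if overlap > min(n_set, n_hits):
        raise ValueError("overlap exceeds set or hit-list size: inconsistent inputs")
    return float(hypergeom.sf(overlap - 1, universe, n_set, n_hits))


def ora_collection(
    hit_genes: set[str], gene_sets: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """ORA over a collection of gene sets with BH correction across sets."""
    from statsmodels.stats.multitest import multipletests

    hits = set(hit_genes)
    if not hits <= universe:
        raise ValueError("hit genes must be a subset of the universe")
    rows = []
    for name in sorted(gene_sets):
        gs = set(gene_sets[name])
        if not gs <= universe:
            raise ValueError(f"gene set {name!r} is not a subset of the universe")
        ov = len(gs & hits)
        p = ora_hypergeometric(len(hits), len(gs), ov, len(universe))
        rows.append((name, len(gs), ov, p))
    out = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p"])
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = []
    return out


def binomial_interval(fraction: float, n: int, conf: float = 0.99) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial interval for an expected fraction.

    Used by recovery checks: the realized fraction of n draws at success
    probability ``fraction`` should fall inside this interval.
    """
    from scipy.stats import binom

    alpha = 1.0 - conf
    lo = binom.ppf(alpha / 2, n, fraction) / n
    hi = binom.ppf(1 - alpha / 2, n, fraction) / n
    return float(lo), float(hi)
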