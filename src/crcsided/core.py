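"""Expression core: normalization, HVG selection, clustering, DEG rules.

The container throughout is :class:`anndata.AnnData` in scanpy orientation
(cells x genes), with raw counts preserved in ``layers["counts"]`` and
per-cell metadata (``sample_id``, ``side``, optional ``cluster``) in
``.obs``.

The differential-expression rules are the study's printed ones:

* cluster markers / side DEGs — two-sided Wilcoxon rank-sum, BH adjustment
  across genes within a comparison, retain |logFC| > 0.5 (natural-log scale,
  difference of group means of log-normalized expression) and adjusted
  P < 0.05;
* the enrichment-input filter — BH-adjusted P < 0.01 and |log2 FC| > 1.
"""

from __future__ import annotations

import itertools
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "read_tenx_like",
    "filter_cells",
    "normalize_log_cp10k",
    "select_hvg",
    "cluster_cells",
    "wilcoxon_rank_sum",
    "benjamini_hochberg",
    "find_cluster_markers",
    "side_degs_per_cluster",
    "filter_degs_for_enrichment",
]


def read_tenx_like(directory: str | Path) -> AnnData:
    """Load a 10x-style bundle: matrix.mtx + features/barcodes/cell_meta TSVs.

    The matrix on disk is genes x cells; the returned AnnData is cells x
    genes with raw counts both in ``.X`` and ``layers["counts"]``.
    """
    from scipy.io import mmread

    directory = Path(directory)
    m = sp.csr_matrix(mmread(directory / "matrix.mtx").T)
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in bundle")
    meta_path = directory / "cell_meta.tsv"
    if meta_path.exists():
        obs = pd.read_csv(meta_path, sep="\t", index_col=0)
        obs.index = obs.index.astype(str)
        obs = obs.loc[barcodes]
    else:
        obs = pd.DataFrame(index=barcodes)
    adata = AnnData(X=m, obs=obs, var=pd.DataFrame(index=features))
    adata.layers["counts"] = adata.X.copy()
    return adata


def filter_cells(adata: AnnData, min_genes: int = 200) -> AnnData:
    """Drop cells expressing fewer than ``min_genes`` genes (pre-normalization QC)."""
    counts = adata.layers.get("counts", adata.X)
    n_genes = np.asarray((counts > 0).sum(axis=1)).ravel()
    keep = n_genes >= min_genes
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} cell(s) with < {min_genes} expressed genes")
    return adata[keep].copy()


def normalize_log_cp10k(adata: AnnData, target_sum: float = 1e4) -> AnnData:
    """log1p of counts-per-10,000 per cell; all-zero cells are excluded.

    Returns a new AnnData whose ``.X`` holds the normalized values; raw
    counts stay in ``layers["counts"]``.
    """
    counts = adata.layers.get("counts", adata.X)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        warnings.warn(f"excluded {int(zero.sum())} all-zero cell(s) from normalization")
        adata = adata[~zero].copy()
        counts = adata.layers.get("counts", adata.X)
        totals = np.asarray(counts.sum(axis=1)).ravel()
    scale = sp.diags(target_sum / totals)
    x = scale @ sp.csr_matrix(counts, dtype=float)
    x.data = np.log1p(x.data)
    out = adata.copy()
    out.layers["counts"] = sp.csr_matrix(counts)
    out.X = x
    return out


def select_hvg(adata: AnnData, n_top: int = 500, n_bins: int = 20) -> list[str]:
    """Top ``n_top`` genes by binned dispersion of normalized expression.

    Dispersion = variance/mean of log-normalized expression, standardized
    within bins of comparable mean expression (so selection is not a pure
    mean effect).  Ordering is deterministic: binned dispersion descending,
    then raw dispersion descending (this also settles degenerate bins with a
    single gene), then gene name ascending.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > adata.n_vars:
        raise ValueError("n_top exceeds the number of genes")
    x = adata.X
    dense = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)
    mu = dense.mean(axis=0)
    var = dense.var(axis=0, ddof=1) if dense.shape[0] > 1 else np.zeros_like(mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mu > 0, var / mu, 0.0)
    # normalize dispersion within mean bins (rank by within-bin z of dispersion)
    order = np.argsort(mu, kind="stable")
    n_genes = len(mu)
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(n_genes) * n_bins) // max(n_genes, 1), n_bins - 1
    )
    norm_disp = np.zeros(n_genes)
    for b in range(n_bins):
        mask = bin_of == b
        if not mask.any():
            continue
        d = disp[mask]
        sd = d.std(ddof=1) if mask.sum() > 1 else 0.0
        norm_disp[mask] = (d - d.mean()) / sd if sd > 0 else 0.0
    names = np.asarray(adata.var_names)
    ranked = sorted(zip(-norm_disp, -disp, names))
    return [g for _, _, g in ranked[:n_top]]


def cluster_cells(
    adata: AnnData,
    hvgs: list[str],
    n_pcs: int = 20,
    resolution: float = 0.6,
    n_neighbors: int = 15,
    seed: int = 0,
) -> pd.Series:
    """Graph clustering of cells in PC space at the given resolution.

    Z-scales the HVG submatrix, runs PCA, builds a kNN graph (Euclidean in
    PC space) and partitions it by Leiden modularity optimization.  Returns
    cluster labels (strings) indexed by barcode; deterministic given seed.
    """
    import scanpy as sc

    if n_pcs < 2:
        raise ValueError("n_pcs must be >= 2")
    if adata.n_obs <= n_pcs:
        raise ValueError("fewer cells than principal components")
    sub = adata[:, hvgs].copy()
    dense = _dense(sub.X)
    if np.allclose(dense, dense[0]):
        # every cell identical on the HVG space: one trivial cluster
        return pd.Series(["0"] * adata.n_obs, index=adata.obs_names,
                         name="cluster")
    sc.pp.scale(sub)
    sc.tl.pca(sub, n_comps=min(n_pcs, sub.n_vars - 1), svd_solver="arpack",
              random_state=seed)
    sc.pp.neighbors(sub, n_neighbors=n_neighbors, use_rep="X_pca", random_state=seed)
    sc.tl.leiden(
        sub, resolution=resolution, random_state=seed, key_added="cluster",
        flavor="leidenalg",
    )
    return pd.Series(sub.obs["cluster"].astype(str).to_numpy(), index=adata.obs_names,
                     name="cluster")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum and BH

def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumeration of group assignments.

    Two-sided p = min(1, 2 * min(P(W <= w), P(W >= w))) over all
    C(n+m, n) equally likely assignments, with midranks for ties.
    """
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    total = 0
    le = 0
    ge = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        w = ranks[list(combo)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when the pooled sample size is at most 10, otherwise
    the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) + len(y) <= 10:
        return _exact_ranksum_p(x, y)
    from scipy.stats import mannwhitneyu

    return float(mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic", use_continuity=False).pvalue)


def _wilcoxon_genes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-gene two-sided rank-sum p for two cells x genes blocks (vectorized)."""
    if a.shape[0] + b.shape[0] <= 10:
        return np.array([
            _exact_ranksum_p(a[:, j], b[:, j]) for j in range(a.shape[1])
        ])
    from scipy.stats import mannwhitneyu

    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                       use_continuity=False, axis=0)
    return np.asarray(res.pvalue, dtype=float)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def _deg_one_comparison(
    dense: np.ndarray, features, mask_a: np.ndarray, mask_b: np.ndarray,
    group: str, lfc_cut: float, alpha: float,
) -> pd.DataFrame:
    a = dense[mask_a, :]
    b = dense[mask_b, :]
    p = _wilcoxon_genes(a, b)
    p = np.nan_to_num(p, nan=1.0)
    p_adj = benjamini_hochberg(p)
    lfc = a.mean(axis=0) - b.mean(axis=0)
    keep = (np.abs(lfc) > lfc_cut) & (p_adj < alpha)
    out = pd.DataFrame({
        "gene": np.asarray(features)[keep],
        "group": group,
        "log_fc": lfc[keep],
        "p": p[keep],
        "p_adj": p_adj[keep],
    })
    out["direction"] = np.where(out["log_fc"] > 0, "up", "down")
    return out


def find_cluster_markers(
    adata: AnnData,
    labels: pd.Series | None = None,
    lfc_cut: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Marker genes per cluster (cluster vs rest) under the printed DEG rule.

    Two-sided Wilcoxon per gene, BH across genes within each comparison,
    retained when |logFC| > ``lfc_cut`` (natural log) and adjusted
    P < ``alpha``.  Clusters with fewer than 2 cells are skipped.
    """
    labels = labels if labels is not None else adata.obs["cluster"]
    labels = pd.Series(np.asarray(labels, dtype=object), index=adata.obs_names)
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    dense = _dense(adata.X)
    frames = []
    for cl in uniq:
        mask = (labels == cl).to_numpy()
        if mask.sum() < 2:
            warnings.warn(f"cluster {cl!r} has < 2 cells; skipped")
            continue
        frames.append(_deg_one_comparison(
            dense, adata.var_names, mask, ~mask, str(cl), lfc_cut, alpha))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["gene", "group", "log_fc", "p", "p_adj", "direction"])


def side_degs_per_cluster(
    adata: AnnData,
    labels: pd.Series | None = None,
    sides: pd.Series | None = None,
    lfc_cut: float = 0.5,
    alpha: float = 0.05,
    min_cells: int = 2,
) -> pd.DataFrame:
    """Left-vs-right DEG count within each cluster under the same rule.

    Returns a frame with columns ``cluster``, ``n_left``, ``n_right``,
    ``n_degs``; clusters with one side absent (fewer than ``min_cells``
    cells) get ``n_degs`` = NA and are flagged, never counted.
    """
    labels = pd.Series(np.asarray(
        labels if labels is not None else adata.obs["cluster"], dtype=object),
        index=adata.obs_names)
    sides = pd.Series(np.asarray(
        sides if sides is not None else adata.obs["side"], dtype=object),
        index=adata.obs_names)
    dense = _dense(adata.X)
    rows = []
    for cl in sorted(labels.unique()):
        in_cl = (labels == cl).to_numpy()
        left = in_cl & (sides == "left").to_numpy()
        right = in_cl & (sides == "right").to_numpy()
        if left.sum() < min_cells or right.sum() < min_cells:
            rows.append((str(cl), int(left.sum()), int(right.sum()), pd.NA))
            continue
        degs = _deg_one_comparison(
            dense, adata.var_names, left, right, str(cl), lfc_cut, alpha)
        rows.append((str(cl), int(left.sum()), int(right.sum()), len(degs)))
    return pd.DataFrame(rows, columns=["cluster", "n_left", "n_right", "n_degs"])


def filter_degs_for_enrichment(
    deg: pd.DataFrame, lfc2_cut: float = 1.0, alpha: float = 0.01,
    log2_fc_col: str = "log2_fc",
) -> list[str]:
    """Genes passing the enrichment-input filter: p_adj < 0.01 and |log2 FC| > 1.

    Both thresholds are strict; the frame must carry base-2 fold changes in
    ``log2_fc_col``.
    """
    if len(deg) == 0:
        return []
    if log2_fc_col not in deg.columns:
        raise ValueError(f"DEG table lacks a {log2_fc_col!r} column (base-2 scale)")
    keep = (deg["p_adj"] < alpha) & (deg[log2_fc_col].abs() > lfc2_cut)
    return deg.loc[keep, "gene"].tolist()
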