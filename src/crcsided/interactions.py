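"""Permutation-based ligand-receptor interaction scoring between clusters.

For each ligand-receptor pair and each ordered (sender, receiver) cluster
pair, the statistic is the average of the ligand entity's mean normalized
expression in the sender and the receptor entity's mean in the receiver.
Multi-subunit complexes score as the minimum over subunit means; an entity
expressed in fewer than ``min_expr_frac`` of a cluster's cells is masked to
zero there, and a masked entity zeroes the whole statistic.  The null is
built by shuffling cluster labels over cells and recomputing everything;
p = (1 + #{null >= observed}) / (1 + n_perm).  Pairs with p > 0.05 are
filtered; the others are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "LRPair",
    "builtin_lr_pairs",
    "read_lr_pairs_tsv",
    "write_lr_pairs_tsv",
    "cluster_mean_expression",
    "entity_mean",
    "lr_statistic",
    "permutation_test_lr",
    "filter_significant_pairs",
]


@dataclass(frozen=True)
class LRPair:
    """A ligand-receptor pair; either partner may be a multi-subunit complex."""

    pair_id: str
    ligand: tuple[str, ...]
    receptor: tuple[str, ...]
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError(f"pair {self.pair_id!r}: empty partner")
        for g in (*self.ligand, *self.receptor):
            if not g:
                raise ValueError(f"pair {self.pair_id!r}: empty subunit name")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys((*self.ligand, *self.receptor)))


_BUILTIN_ROWS = [
    # (pair_id, ligand subunits, receptor subunits, annotation)
    ("TNF_TNFRSF1A", "TNF", "TNFRSF1A", "TNF signaling"),
    ("TNF_TNFRSF1B", "TNF", "TNFRSF1B", "TNF signaling"),
    ("TNFSF10_TNFRSF10A", "TNFSF10", "TNFRSF10A", "TRAIL apoptosis"),
    ("TNFSF10_TNFRSF10B", "TNFSF10", "TNFRSF10B", "TRAIL apoptosis"),
    ("TGFB1_TGFBR1", "TGFB1", "TGFBR1", "TGF-beta"),
    ("TGFB1_TGFBR1;TGFBR2", "TGFB1", "TGFBR1;TGFBR2", "TGF-beta receptor complex"),
    ("COL1A1_a1b1", "COL1A1", "ITGA1;ITGB1", "collagen to integrin a1b1 complex"),
    ("COL1A2_a1b1", "COL1A2", "ITGA1;ITGB1", "collagen to integrin a1b1 complex"),
    ("COL4A1_a1b1", "COL4A1", "ITGA1;ITGB1", "collagen to integrin a1b1 complex"),
    ("COL6A2_a1b1", "COL6A2", "ITGA1;ITGB1", "collagen to integrin a1b1 complex"),
    ("EGF_EGFR", "EGF", "EGFR", "EGFR signaling"),
    ("TGFA_EGFR", "TGFA", "EGFR", "EGFR signaling"),
    ("AREG_EGFR", "AREG", "EGFR", "EGFR signaling"),
    ("HBEGF_EGFR", "HBEGF", "EGFR", "EGFR signaling"),
    ("VEGFA_KDR", "VEGFA", "KDR", "VEGF angiogenesis"),
    ("VEGFA_FLT1", "VEGFA", "FLT1", "VEGF angiogenesis"),
    ("NRG1_ERBB3", "NRG1", "ERBB3", "ErbB signaling"),
    ("CXCL12_CXCR4", "CXCL12", "CXCR4", "chemokine recruitment"),
    ("CCL2_CCR2", "CCL2", "CCR2", "monocyte recruitment"),
    ("CCL5_CCR5", "CCL5", "CCR5", "T cell recruitment"),
    ("CXCL9_CXCR3", "CXCL9", "CXCR3", "Th1 recruitment"),
    ("CXCL10_CXCR3", "CXCL10", "CXCR3", "Th1 recruitment"),
    ("IL6_IL6R", "IL6", "IL6R", "IL-6"),
    ("IL10_IL10RA", "IL10", "IL10RA", "IL-10 immunosuppression"),
    ("IL1B_IL1R1", "IL1B", "IL1R1", "IL-1"),
    ("CD274_PDCD1", "CD274", "PDCD1", "PD-L1 checkpoint"),
    ("PDCD1LG2_PDCD1", "PDCD1LG2", "PDCD1", "PD-L2 checkpoint"),
    ("CD80_CTLA4", "CD80", "CTLA4", "checkpoint"),
    ("CD86_CTLA4", "CD86", "CTLA4", "checkpoint"),
    ("LGALS9_HAVCR2", "LGALS9", "HAVCR2", "TIM-3 checkpoint"),
    ("FASLG_FAS", "FASLG", "FAS", "apoptosis"),
    ("MIF_CD74;CXCR4", "MIF", "CD74;CXCR4", "MIF receptor complex"),
]


def builtin_lr_pairs() -> list[LRPair]:
    """Packaged ~30-pair interaction list (curated database stand-in)."""
    return [
        LRPair(pid, tuple(l.split(";")), tuple(r.split(";")), ann)
        for pid, l, r, ann in _BUILTIN_ROWS
    ]


def read_lr_pairs_tsv(path: str | Path) -> list[LRPair]:
    df = pd.read_csv(path, sep="\t")
    pairs = [
        LRPair(row["pair_id"], tuple(str(row["ligand"]).split(";")),
               tuple(str(row["receptor"]).split(";")),
               str(row.get("annotation", "")))
        for _, row in df.iterrows()
    ]
    ids = [p.pair_id for p in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate pair ids in pair database")
    return pairs


def write_lr_pairs_tsv(pairs: list[LRPair], path: str | Path) -> None:
    pd.DataFrame(
        [(p.pair_id, ";".join(p.ligand), ";".join(p.receptor), p.annotation)
         for p in pairs],
        columns=["pair_id", "ligand", "receptor", "annotation"],
    ).to_csv(path, sep="\t", index=False)


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def _group_stats(expr: np.ndarray, counts: np.ndarray, codes: np.ndarray,
                 n_clusters: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster mean expression and expressed fraction (clusters x genes)."""
    onehot = np.zeros((len(codes), n_clusters))
    onehot[np.arange(len(codes)), codes] = 1.0
    sizes = onehot.sum(axis=0)
    means = (onehot.T @ expr) / sizes[:, None]
    frac = (onehot.T @ (counts > 0)) / sizes[:, None]
    return means, frac


def cluster_mean_expression(
    adata: AnnData,
    labels: pd.Series | None = None,
    min_expr_frac: float = 0.1,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Masked mean normalized expression per (gene, cluster).

    A gene with a nonzero raw count in fewer than ``min_expr_frac`` of a
    cluster's cells is masked to 0 for that cluster.  Returns genes x
    clusters.  Empty clusters are dropped with a warning.
    """
    labels = pd.Series(np.asarray(
        labels if labels is not None else adata.obs["cluster"], dtype=object),
        index=adata.obs_names)
    uniq = sorted(labels.unique())
    empty = [u for u in uniq if (labels == u).sum() == 0]
    if empty:
        warnings.warn(f"empty cluster(s) dropped: {empty}")
        uniq = [u for u in uniq if u not in empty]
    codes = np.array([uniq.index(v) for v in labels])
    if genes is not None:
        sub = adata[:, genes]
    else:
        sub = adata
        genes = list(adata.var_names)
    expr = _dense(sub.X)
    counts = _dense(sub.layers.get("counts", sub.X))
    means, frac = _group_stats(expr, counts, codes, len(uniq))
    means = np.where(frac >= min_expr_frac, means, 0.0)
    return pd.DataFrame(means.T, index=genes, columns=[str(u) for u in uniq])


def entity_mean(cluster_means: pd.DataFrame, entity: tuple[str, ...],
                cluster: str) -> float:
    """Entity expression in one cluster: minimum over subunit masked means."""
    missing = [g for g in entity if g not in cluster_means.index]
    if missing:
        raise KeyError(f"gene(s) missing from the matrix: {missing}")
    return float(min(cluster_means.loc[g, cluster] for g in entity))


def lr_statistic(pair: LRPair, sender: str, receiver: str,
                 cluster_means: pd.DataFrame) -> float:
    """(ligand mean in sender + receptor mean in receiver)/2; 0 if either is masked out."""
    lig = entity_mean(cluster_means, pair.ligand, sender)
    rec = entity_mean(cluster_means, pair.receptor, receiver)
    if lig == 0.0 or rec == 0.0:
        return 0.0
    return (lig + rec) / 2.0


def permutation_test_lr(
    adata: AnnData,
    labels: pd.Series | None = None,
    pairs: list[LRPair] | None = None,
    n_perm: int = 1000,
    min_expr_frac: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test of every (pair, sender, receiver) combination.

    Shuffles cluster labels over cells ``n_perm`` times, recomputing masked
    cluster means and the statistic each time; p uses the add-one estimator
    (never 0, floor 1/(n_perm+1)).  Rows with observed statistic 0 get p = 1
    and are flagged ``degenerate``.  Columns: pair_id, sender, receiver,
    statistic, p, significant, degenerate.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    pairs = pairs if pairs is not None else builtin_lr_pairs()
    labels = pd.Series(np.asarray(
        labels if labels is not None else adata.obs["cluster"], dtype=object),
        index=adata.obs_names)
    uniq = sorted(map(str, labels.unique()))
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    code_of = {u: i for i, u in enumerate(uniq)}
    codes = np.array([code_of[str(v)] for v in labels])

    genes_needed = sorted({g for p in pairs for g in p.genes})
    missing = [g for g in genes_needed if g not in adata.var_names]
    usable = [p for p in pairs if all(g in adata.var_names for g in p.genes)]
    if missing:
        warnings.warn(f"{len(pairs) - len(usable)} pair(s) skipped; "
                      f"genes absent: {missing[:8]}")
    if not usable:
        raise ValueError("no ligand-receptor pair has all genes in the matrix")
    genes_used = sorted({g for p in usable for g in p.genes})
    sub = adata[:, genes_used]
    expr = _dense(sub.X)
    counts = _dense(sub.layers.get("counts", sub.X))

    def stats_for(codes_now: np.ndarray) -> np.ndarray:
        means, frac = _group_stats(expr, counts, codes_now, len(uniq))
        masked = np.where(frac >= min_expr_frac, means, 0.0)  # clusters x genes
        gi = {g: j for j, g in enumerate(genes_used)}
        out = np.empty((len(usable), len(uniq), len(uniq)))
        for k, pair in enumerate(usable):
            lig = masked[:, [gi[g] for g in pair.ligand]].min(axis=1)
            rec = masked[:, [gi[g] for g in pair.receptor]].min(axis=1)
            s = (lig[:, None] + rec[None, :]) / 2.0
            s[(lig[:, None] == 0) | (rec[None, :] == 0)] = 0.0
            out[k] = s
        return out

    observed = stats_for(codes)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        exceed += stats_for(perm) >= observed
    p = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for k, pair in enumerate(usable):
        for i, snd in enumerate(uniq):
            for j, rcv in enumerate(uniq):
                stat = float(observed[k, i, j])
                degenerate = stat == 0.0
                pv = 1.0 if degenerate else float(p[k, i, j])
                rows.append((pair.pair_id, snd, rcv, stat, pv,
                             pv <= alpha, degenerate))
    return pd.DataFrame(rows, columns=[
        "pair_id", "sender", "receiver", "statistic", "p", "significant",
        "degenerate"])


def filter_significant_pairs(result: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Retain rows with p <= alpha (p > 0.05 is filtered, 0.05 itself retained)."""
    if len(result) == 0:
        return result
    return result[result["p"] <= alpha].reset_index(drop=True)


def per_side_interactions(
    adata: AnnData,
    labels: pd.Series | None = None,
    pairs: list[LRPair] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Run the permutation test separately on left- and right-side cells.

    Reproduces the left/right contrast structure of per-side interaction
    maps; adds a ``side`` column to the long result table.
    """
    frames = []
    for side in ("left", "right"):
        mask = (adata.obs["side"] == side).to_numpy()
        if mask.sum() == 0:
            continue
        sub = adata[mask].copy()
        lab = None if labels is None else labels[sub.obs_names]
        res = permutation_test_lr(sub, lab, pairs, n_perm=n_perm, seed=seed, **kwargs)
        res.insert(0, "side", side)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
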