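"""Gene-program scoring for T-cell and macrophage functional states.

A signature score for a cell is the unweighted mean, over the signature's
genes, of gene-wise Z-scored log-normalized expression.  Z-scores are
computed over the population of cells being scored (typically one immune
compartment, e.g. all CD8+ T cells), so scores are relative functional
positions within that compartment and average to ~0 across it.

Shipped programs: naiveness (CCR7/TCF7/LEF1/SELL), cytotoxicity (12 effector
genes), a 24-gene coinhibition program, a configurable 90-slot exhaustion
program, and illustrative M1/M2 macrophage polarization panels.

Score-versus-pseudotime trends are fitted with first-degree LOESS (tricube
weights) on a 100-point grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

__all__ = [
    "GeneSignature",
    "ScoreResult",
    "TrendFit",
    "zscore_genes",
    "score_signature",
    "score_all",
    "builtin_signatures",
    "panel_fold_change",
    "fit_score_trend",
    "pseudotime_surrogate",
    "NAIVENESS_GENES",
    "CYTOTOXICITY_GENES",
    "COINHIBITION_GENES",
    "EXHAUSTION_GENES_DEFAULT",
    "M1_PANEL_DEFAULT",
    "M2_PANEL_DEFAULT",
]


NAIVENESS_GENES = ["CCR7", "TCF7", "LEF1", "SELL"]

CYTOTOXICITY_GENES = [
    "PRF1", "IFNG", "GNLY", "NKG7", "GZMB", "GZMA",
    "GZMH", "KLRK1", "KLRB1", "KLRD1", "CTSW", "CST7",
]

COINHIBITION_GENES = [
    "CTLA4", "PDCD1", "TIGIT", "HAVCR2", "LAG3", "BTLA", "PDPN", "CD160",
    "GP49A", "LILRB4", "CD274", "CD200", "CD244", "PILRA", "SIRPB1", "LAIR1",
    "CEACAM1", "KLRA7", "KLRA3", "KLRA9", "PTGER4", "KLRD1", "KLRC1", "PROCR",
]

# Default 90-slot exhaustion program.  The published score is built on a
# 90-gene tumor-infiltrating exhausted-CD8 program from the lung
# adenocarcinoma literature whose membership is not printed in full anywhere
# we reproduce; this default is a placeholder assembled from well-known
# exhaustion/dysfunction-associated symbols and is meant to be replaced by a
# user-supplied list via configuration.  No result in this package depends on
# its exact membership.
EXHAUSTION_GENES_DEFAULT = [
    "PDCD1", "CTLA4", "LAG3", "HAVCR2", "TIGIT", "BTLA", "CD160", "CD244",
    "ENTPD1", "ITGAE", "TOX", "TOX2", "EOMES", "NR4A1", "NR4A2", "NR4A3",
    "CXCL13", "CXCR6", "LAYN", "PHLDA1", "SNAP47", "MYO7A", "MYO1E", "RAB27A",
    "TNFRSF9", "TNFRSF18", "TNFRSF1B", "CD27", "ICOS", "CD200", "CD200R1",
    "VSIR", "ADORA2A", "IL10", "IL10RA", "IL21", "IL2RB", "IL12RB2", "IFNG",
    "FASLG", "CASP8", "BATF", "IRF4", "PRDM1", "MAF", "VDR", "IKZF3",
    "EGR2", "EGR3", "NFATC1", "GATA3", "HIF1A", "FOXP1", "BHLHE40", "ID2",
    "ID3", "TBX21", "ZEB2", "RBPJ", "PTPN11", "PTPN6", "SH2D1A", "UBASH3B",
    "DGKA", "DGKZ", "CBLB", "ITCH", "RNF128", "SOCS1", "SOCS3", "CISH",
    "DUSP4", "DUSP16", "CCL3", "CCL4", "CCL5", "XCL1", "XCL2", "CD38",
    "CD101", "CD82", "SIRPG", "LGALS1", "LGALS3", "GZMB", "KIR2DL4", "KLRD1",
    "CREM", "PRKCH", "TNFSF4",
]
assert len(EXHAUSTION_GENES_DEFAULT) == 90

# Illustrative macrophage polarization panels (configurable; the study shows
# its panels only graphically).
M1_PANEL_DEFAULT = [
    "IL1B", "TNF", "IL6", "CXCL9", "CXCL10", "NOS2", "CD80", "CD86",
    "IL12B", "PTGS2",
]
M2_PANEL_DEFAULT = [
    "MRC1", "CD163", "MSR1", "CCL22", "CCL17", "IL10", "TGFB1", "ARG1",
    "MAF", "VEGFA",
]


@dataclass
class GeneSignature:
    """A named, unweighted gene program."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            dups = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"signature {self.name!r} has duplicate genes: {dups}")


@dataclass
class ScoreResult:
    """Per-cell scores plus provenance of which signature genes were found."""

    name: str
    scores: np.ndarray
    genes_found: list[str] = field(default_factory=list)
    genes_missing: list[str] = field(default_factory=list)


def builtin_signatures(exhaustion_genes: list[str] | None = None) -> list[GeneSignature]:
    """The packaged signatures; exhaustion membership is overridable."""
    return [
        GeneSignature("naiveness", list(NAIVENESS_GENES)),
        GeneSignature("cytotoxicity", list(CYTOTOXICITY_GENES)),
        GeneSignature("coinhibition", list(COINHIBITION_GENES)),
        GeneSignature("exhaustion", list(exhaustion_genes or EXHAUSTION_GENES_DEFAULT)),
        GeneSignature("M1", list(M1_PANEL_DEFAULT)),
        GeneSignature("M2", list(M2_PANEL_DEFAULT)),
    ]


def _dense(matrix) -> np.ndarray:
    import scipy.sparse as sp

    if sp.issparse(matrix):
        return np.asarray(matrix.todense(), dtype=float)
    return np.asarray(matrix, dtype=float)


def zscore_genes(expr: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Gene-wise Z-transform of a genes x cells expression matrix.

    Uses the sample (n-1) standard deviation.  Zero-variance genes map to
    all-zero rows with a warning.  A single cell is rejected (sd undefined).
    """
    x = np.asarray(expr, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a genes x cells matrix")
    if x.shape[1] < 2:
        raise ValueError("Z-scoring needs at least 2 cells")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s) set to Z=0")
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd
    z[flat, :] = 0.0
    return z


def score_signature(
    z: np.ndarray, features: list[str], signature: GeneSignature
) -> ScoreResult:
    """Per-cell mean of Z values over the signature genes present.

    Missing genes are reported in the result, never imputed.  A signature
    with no gene present in ``features`` is an error.
    """
    index = {g: i for i, g in enumerate(features)}
    found = [g for g in signature.genes if g in index]
    missing = [g for g in signature.genes if g not in index]
    if not found:
        raise ValueError(f"no gene of signature {signature.name!r} is in the matrix")
    rows = [index[g] for g in found]
    scores = np.asarray(z)[rows, :].mean(axis=0)
    return ScoreResult(signature.name, scores, found, missing)


def score_all(
    adata: AnnData,
    signatures: list[GeneSignature],
    layer: str | None = None,
    on_missing: str = "error",
) -> pd.DataFrame:
    """Score several signatures over one population (one shared Z-transform).

    ``adata`` holds log-normalized expression (cells x genes, scanpy
    orientation) in ``.X`` or the named layer; the Z-transform is computed
    over exactly the cells in ``adata``, which should be the compartment
    being scored.  A signature with no gene in the matrix raises by default,
    or is dropped with a warning when ``on_missing="skip"``.
    """
    if on_missing not in ("error", "skip"):
        raise ValueError("on_missing must be 'error' or 'skip'")
    x = adata.layers[layer] if layer else adata.X
    z = zscore_genes(_dense(x).T)
    features = list(adata.var_names)
    out = {}
    for sig in signatures:
        try:
            out[sig.name] = score_signature(z, features, sig).scores
        except ValueError:
            if on_missing == "error":
                raise
            warnings.warn(f"signature {sig.name!r} has no gene in the matrix; "
                          "skipped")
    return pd.DataFrame(out, index=adata.obs_names)


def panel_fold_change(
    adata: AnnData,
    panel: GeneSignature,
    group_a: np.ndarray,
    group_b: np.ndarray,
    layer: str | None = None,
    linear: bool = True,
) -> float:
    """Ratio of mean normalized panel expression, group A over group B.

    The mean is taken over panel genes and cells jointly; the result is a
    plain ratio, no log.  With ``linear=True`` (default) the log1p-normalized
    matrix is mapped back to the linear counts-per-10k scale via expm1 before
    averaging, so a k-fold expression boost yields a ~k-fold ratio.
    """
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if not group_a.any() or not group_b.any():
        raise ValueError("both groups must be non-empty")
    present = [g for g in panel.genes if g in adata.var_names]
    if not present:
        raise ValueError(f"no gene of panel {panel.name!r} is in the matrix")
    x = adata.layers[layer] if layer is not None else adata.X
    sub = _dense(x)[:, [adata.var_names.get_loc(g) for g in present]]
    if linear:
        sub = np.expm1(sub)
    num = sub[group_a, :].mean()
    den = sub[group_b, :].mean()
    if den == 0:
        raise ValueError("denominator group has zero mean panel expression")
    return float(num / den)


@dataclass
class TrendFit:
    """A LOESS trend of a score along one trajectory component."""

    component: str
    grid: np.ndarray
    fitted: np.ndarray
    span: float


def fit_score_trend(
    component: np.ndarray,
    scores: np.ndarray,
    span: float = 0.5,
    component_name: str = "component",
    n_grid: int = 100,
) -> TrendFit:
    """First-degree LOESS (tricube weights) of score on component.

    Evaluated on an ``n_grid``-point grid spanning the component range.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    comp = np.asarray(component, dtype=float)
    sc = np.asarray(scores, dtype=float)
    if comp.shape != sc.shape or comp.ndim != 1:
        raise ValueError("component and scores must be equal-length 1-D arrays")
    if comp.size < 10:
        raise ValueError("need at least 10 cells to fit a trend")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    lo, hi = comp.min(), comp.max()
    if lo == hi:
        raise ValueError("component is constant; trend undefined")
    grid = np.linspace(lo, hi, n_grid)
    fitted = lowess(sc, comp, frac=span, it=0, xvals=grid)
    return TrendFit(component_name, grid, np.asarray(fitted, dtype=float), span)


def pseudotime_surrogate(adata: AnnData, n_comps: int = 2, seed: int = 0) -> pd.DataFrame:
    """Plumbing surrogate for trajectory components: first PCs of the compartment.

    This is a stand-in coordinate system so score-trend fitting can run
    end-to-end; it is a PCA embedding, not a trajectory inference method.
    """
    import scanpy as sc

    ad = adata.copy()
    sc.pp.scale(ad)
    sc.tl.pca(ad, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    cols = {f"component_{i + 1}": ad.obsm["X_pca"][:, i] for i in range(n_comps)}
    return pd.DataFrame(cols, index=ad.obs_names)
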