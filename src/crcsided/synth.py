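"""Synthetic 10x-style data with the structure of a two-condition CRC atlas.

Generates gene x cell count matrices for a multi-sample, two-side (left vs
right tumor) design: each sample contributes cells whose types are drawn
from a side-specific composition table; counts are negative-binomial with a
log-normal library size per cell, a multiplicative marker boost for each
type's marker genes, and a log-normal per-(sample, gene) random effect that
mimics donor variation.  Ground truth (true type, realized composition) is
returned alongside for recovery testing.

Also provides paired-FASTQ read fixtures with planted adapters and
low-quality tails, and a truth sidecar computed by an independent naive
per-read trace of the five-step QC so QC implementations can be validated
against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "CellTypeSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_counts",
    "write_tenx_like",
    "default_config",
    "paper_composition_config",
    "generate_read_fixture",
]

SIDES = ("left", "right")


@dataclass
class CellTypeSpec:
    """One simulated cell type: its marker genes and baseline expression."""

    name: str
    marker_genes: list[str]
    baseline_logmean: float = 0.0

    def __post_init__(self) -> None:
        if not self.marker_genes:
            raise ValueError(f"cell type {self.name!r} has no marker genes")
        if len(set(self.marker_genes)) != len(self.marker_genes):
            raise ValueError(f"cell type {self.name!r} has duplicate marker genes")


@dataclass
class SimulationConfig:
    """Full description of a synthetic two-side multi-sample dataset.

    ``composition[(type, side)]`` is the expected fraction of that side's
    cells belonging to the type; the fractions of each side must sum to 1.
    ``dispersion`` is the negative-binomial overdispersion phi in
    var = mu + phi * mu^2 (phi = 0 gives Poisson).  ``sample_effect_sd`` is
    the standard deviation of a per-(sample, gene) normal effect on the log
    mean, emulating donor-to-donor variation.
    """

    n_genes: int
    cell_types: list[CellTypeSpec]
    composition: dict[tuple[str, str], float]
    samples: list[tuple[str, str, int]]  # (sample_id, side, n_cells)
    marker_boost: float = 8.0
    library_size_mean: float = 2000.0
    library_size_cv: float = 0.3
    dispersion: float = 0.5
    sample_effect_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def type_names(self) -> list[str]:
        return [ct.name for ct in self.cell_types]

    def feature_names(self) -> list[str]:
        markers: list[str] = []
        seen = set()
        for ct in self.cell_types:
            for g in ct.marker_genes:
                if g not in seen:
                    seen.add(g)
                    markers.append(g)
        if len(markers) > self.n_genes:
            raise ValueError("more distinct marker genes than n_genes features")
        fillers = []
        i = 1
        while len(markers) + len(fillers) < self.n_genes:
            name = f"G{i:05d}"
            if name not in seen:
                fillers.append(name)
            i += 1
        return markers + fillers

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.marker_boost < 1:
            raise ValueError("marker_boost must be >= 1")
        if self.library_size_mean <= 0 or self.dispersion < 0 or self.sample_effect_sd < 0:
            raise ValueError("library size must be positive; dispersion and "
                             "sample_effect_sd non-negative")
        names = self.type_names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell type names")
        for _, side, n in self.samples:
            if side not in SIDES:
                raise ValueError(f"unknown side label {side!r} (expected left|right)")
            if n <= 0:
                raise ValueError("each sample needs a positive cell count")
        sides_used = {side for _, side, _ in self.samples}
        for side in sides_used:
            row = [self.composition.get((t, side), 0.0) for t in names]
            if any(f < 0 for f in row):
                raise ValueError(f"negative composition fraction for side {side!r}")
            total = sum(row)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"composition row for side {side!r} sums to {total!r}, not 1")
        self.feature_names()  # raises if markers do not fit


@dataclass
class GroundTruth:
    """Per-cell truth and realized composition of one simulated dataset."""

    cells: pd.DataFrame                 # barcode-indexed: sample_id, side, cell_type
    realized_counts: pd.DataFrame       # cell_type x side integer counts

    def realized_side_fraction(self, cell_type: str, side: str) -> float:
        row = self.realized_counts.loc[cell_type]
        return float(row[side] / row.sum())


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with var = mu + phi mu^2 (phi=0 -> Poisson)."""
    mean = np.maximum(mean, 1e-12)
    if phi == 0:
        return rng.poisson(mean)
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_counts(config: SimulationConfig) -> tuple[AnnData, GroundTruth]:
    """Simulate the count matrix and its ground truth.

    Deterministic given ``config.seed``.  Returns an AnnData (cells x genes,
    raw counts in ``.X`` and ``layers["counts"]``, metadata in ``.obs``)
    plus the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    features = config.feature_names()
    gene_index = {g: i for i, g in enumerate(features)}
    type_names = config.type_names()

    # per-type gene weights (marker boost on baseline)
    type_weights = {}
    for ct in config.cell_types:
        w = np.full(config.n_genes, np.exp(ct.baseline_logmean))
        for g in ct.marker_genes:
            w[gene_index[g]] *= config.marker_boost
        type_weights[ct.name] = w

    sigma2 = np.log1p(config.library_size_cv ** 2)
    lib_mu = np.log(config.library_size_mean) - sigma2 / 2

    blocks = []
    obs_rows = []
    truth_rows = []
    for sample_id, side, n_cells in config.samples:
        probs = np.array([config.composition.get((t, side), 0.0) for t in type_names])
        assignments = rng.choice(len(type_names), size=n_cells, p=probs)
        sample_effect = rng.normal(0.0, config.sample_effect_sd, size=config.n_genes)
        libs = rng.lognormal(lib_mu, np.sqrt(sigma2), size=n_cells)
        counts = np.zeros((n_cells, config.n_genes), dtype=np.int64)
        for ti, tname in enumerate(type_names):
            mask = assignments == ti
            if not mask.any():
                continue
            w = type_weights[tname] * np.exp(sample_effect)
            rel = w / w.sum()
            mu = np.outer(libs[mask], rel)
            counts[mask, :] = _nb_sample(rng, mu, config.dispersion)
        blocks.append(sp.csr_matrix(counts))
        for i in range(n_cells):
            bc = f"{sample_id}_C{i + 1:05d}"
            tname = type_names[assignments[i]]
            obs_rows.append((bc, sample_id, side, tname))
            truth_rows.append((tname, side))

    x = sp.vstack(blocks).tocsr()
    obs = pd.DataFrame(obs_rows, columns=["barcode", "sample_id", "side", "cell_type"]
                       ).set_index("barcode")
    adata = AnnData(X=x, obs=obs, var=pd.DataFrame(index=features))
    adata.layers["counts"] = adata.X.copy()

    truth_df = pd.DataFrame(truth_rows, columns=["cell_type", "side"])
    realized = pd.crosstab(truth_df["cell_type"], truth_df["side"]).reindex(
        index=type_names, columns=list(SIDES), fill_value=0)
    truth = GroundTruth(cells=obs.copy(), realized_counts=realized)
    return adata, truth


def write_tenx_like(adata: AnnData, directory: str | Path) -> None:
    """Write a matrix.mtx + features.tsv + barcodes.tsv + cell_meta.tsv bundle.

    The MTX holds the genes x cells integer matrix; round-trips losslessly
    through :func:`crcsided.core.read_tenx_like`.
    """
    from scipy.io import mmwrite

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    barcodes = list(adata.obs_names)
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes; refusing to write bundle")
    counts = adata.layers.get("counts", adata.X)
    m = sp.coo_matrix(counts.T)  # genes x cells on disk
    if not np.isfinite(m.data).all():
        raise ValueError("matrix contains non-finite values")
    mmwrite(str(directory / "matrix.mtx"), m, field="integer")
    pd.Series(list(adata.var_names)).to_csv(
        directory / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(barcodes).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False, header=False)
    adata.obs.to_csv(directory / "cell_meta.tsv", sep="\t")


# ---------------------------------------------------------------------------
# Packaged configurations

def default_config(seed: int = 0, cells_per_sample: int = 500,
                   n_genes: int = 2000) -> SimulationConfig:
    """Desk-scale default: 6 samples (3 left, 3 right), 5 cell types."""
    types = [
        CellTypeSpec("T_cell", ["CD3D", "CD3E", "CD3G", "TRAC", "TRBC2", "IL7R",
                                "LCK", "CD2", "CD7", "LTB", "CCL5", "GZMA"]),
        CellTypeSpec("B_cell", ["CD79A", "CD79B", "MS4A1", "CD19", "IGHM",
                                "IGKC", "BANK1", "TNFRSF13B", "VPREB3", "FCRL5"]),
        CellTypeSpec("myeloid", ["LYZ", "CD68", "CD14", "AIF1", "FCGR3A", "CSF1R",
                                 "ITGAM", "FCN1", "S100A8", "S100A9", "TYROBP",
                                 "FCER1G"]),
        CellTypeSpec("epithelial", ["EPCAM", "KRT18", "KRT8", "KRT19", "CDH1",
                                    "CLDN4", "CLDN7", "LGALS4", "TFF3", "MUC2",
                                    "CEACAM5"]),
        CellTypeSpec("stromal", ["COL1A1", "COL1A2", "COL3A1", "DCN", "LUM",
                                 "PDGFRB", "ACTA2", "THY1", "FAP", "SPARC",
                                 "VIM"]),
    ]
    composition = {}
    left = {"T_cell": 0.30, "B_cell": 0.15, "myeloid": 0.15,
            "epithelial": 0.25, "stromal": 0.15}
    right = {"T_cell": 0.20, "B_cell": 0.10, "myeloid": 0.25,
             "epithelial": 0.30, "stromal": 0.15}
    for t, f in left.items():
        composition[(t, "left")] = f
    for t, f in right.items():
        composition[(t, "right")] = f
    samples = [(f"L{i}", "left", cells_per_sample) for i in (1, 2, 3)] + \
              [(f"R{i}", "right", cells_per_sample) for i in (1, 2, 3)]
    return SimulationConfig(
        n_genes=n_genes, cell_types=types, composition=composition,
        samples=samples, seed=seed)


def paper_composition_config(seed: int = 0, cells_per_sample: int = 500,
                             n_genes: int = 2000) -> SimulationConfig:
    """Fixture whose cluster side-of-origin fractions match the printed atlas.

    With equal cells per side, the expected side-of-origin right fraction of
    a cluster is cR/(cR+cL) where cL/cR are its within-side composition
    fractions.  The mast, exhausted-CD8 (CD8-C4-like) and preexhausted-CD8
    (CD8-C6-like) rows are parameterized to the published 71.5% / 67.9%
    right and 86.8% left side-of-origin figures.
    """
    types = [
        CellTypeSpec("mast", ["TPSAB1", "TPSB2", "CPA3", "MS4A2", "KIT", "HPGDS",
                              "GATA2", "HDC", "RGS13", "SLC18A2"]),
        CellTypeSpec("CD8_exhausted", ["PDCD1", "LAG3", "HAVCR2", "CTLA4", "TIGIT",
                                       "GZMB", "GNLY", "PRF1", "LAYN", "ENTPD1",
                                       "CXCL13", "TOX"]),
        CellTypeSpec("CD8_preexhausted", ["GZMK", "GZMH", "CCL4", "CCL3", "IFNG",
                                          "NKG7", "KLRG1", "CST7", "CCL4L2",
                                          "CCL3L3"]),
        CellTypeSpec("cancer", ["EPCAM", "KRT18", "KRT8", "CEACAM5", "TFF3",
                                "LGALS4", "CLDN4", "CDH1", "MUC2", "SPINK4"]),
        CellTypeSpec("other_immune", ["PTPRC", "CD52", "SRGN", "CD3D", "IL7R",
                                      "LYZ", "CD14", "MS4A1", "CD79A", "HLA-DRA"]),
    ]
    # overall cluster weight w and printed right side-of-origin fraction fR:
    # within-side fractions are cL = 2 w (1-fR), cR = 2 w fR.
    spec_rows = {
        "mast": (0.08, 0.715),
        "CD8_exhausted": (0.10, 0.679),
        "CD8_preexhausted": (0.10, 1.0 - 0.868),
        "cancer": (0.30, 0.5),
    }
    composition: dict[tuple[str, str], float] = {}
    for t, (w, f_right) in spec_rows.items():
        composition[(t, "right")] = 2 * w * f_right
        composition[(t, "left")] = 2 * w * (1 - f_right)
    for side in SIDES:
        rest = 1.0 - sum(composition[(t, side)] for t in spec_rows)
        composition[("other_immune", side)] = rest
    samples = [(f"L{i}", "left", cells_per_sample) for i in (1, 2, 3)] + \
              [(f"R{i}", "right", cells_per_sample) for i in (1, 2, 3)]
    return SimulationConfig(
        n_genes=n_genes, cell_types=types, composition=composition,
        samples=samples, seed=seed)


def interaction_config(seed: int = 0, cells_per_sample: int = 100,
                       n_genes: int = 600) -> SimulationConfig:
    """Fixture with planted ligand-receptor structure between cell types.

    Fibroblasts express collagens and TGFB1; macrophages TNF-family ligands;
    cancer cells the matching receptors (integrin a1b1 complex, TNF
    receptors, EGFR) plus VEGFA; endothelium the VEGF receptors.  Expected
    significant sender->receiver routes include fibroblast->cancer collagen/
    integrin and macrophage->cancer TNF-family pairs.
    """
    types = [
        CellTypeSpec("fibroblast", ["COL1A1", "COL1A2", "COL4A1", "COL6A2",
                                    "TGFB1", "DCN", "LUM", "ACTA2"]),
        CellTypeSpec("macrophage", ["TNF", "TNFSF10", "IL1B", "IL6", "CD68",
                                    "LYZ", "AIF1", "CXCL9"]),
        CellTypeSpec("cancer", ["ITGA1", "ITGB1", "TNFRSF1A", "TNFRSF10B",
                                "TGFBR1", "EGFR", "VEGFA", "EPCAM", "KRT18"]),
        CellTypeSpec("endothelial", ["KDR", "FLT1", "PECAM1", "VWF", "CDH5",
                                     "CLDN5"]),
    ]
    composition = {(t.name, side): 0.25 for t in types for side in SIDES}
    samples = [(f"L{i}", "left", cells_per_sample) for i in (1, 2, 3)] + \
              [(f"R{i}", "right", cells_per_sample) for i in (1, 2, 3)]
    return SimulationConfig(
        n_genes=n_genes, cell_types=types, composition=composition,
        samples=samples, seed=seed)


# ---------------------------------------------------------------------------
# Paired-read fixtures for QC validation

DEFAULT_ADAPTER = "AGATCGGAAGAGC"


@dataclass
class ReadFixtureTruth:
    """Sidecar truth for a read fixture: per-pair survival under the QC rules."""

    survives: pd.DataFrame   # pair_id-indexed, column "survives" (bool)

    @property
    def n_surviving(self) -> int:
        return int(self.survives["survives"].sum())

    def to_tsv(self, path: str | Path) -> None:
        self.survives.astype(int).to_csv(path, sep="\t")


def _naive_qc_keep_length(bases: str, quals: list[int], window: int, window_q: float,
                          trail_q: int, adapter: str | None, min_overlap: int) -> int:
    """Independent per-read trace of QC steps (a)-(c), written naively.

    Deliberately separate from :mod:`crcsided.readqc` (plain per-base loops,
    no shared code) so fixture truth is an independent oracle.  Like the QC
    module, the (a)->(b)->(c) cycle repeats until the read stops shrinking.
    """
    prev = None
    while prev != len(bases):
        prev = len(bases)
        bases, quals = _naive_trim_cycle(bases, quals, window, window_q,
                                         trail_q, adapter, min_overlap)
    return len(bases)


def _naive_trim_cycle(bases, quals, window, window_q, trail_q, adapter,
                      min_overlap):
    # (a) sliding window
    keep = len(quals)
    for start in range(0, len(quals) - window + 1):
        mean_q = 0.0
        for k in range(window):
            mean_q += quals[start + k]
        if mean_q / window < window_q:
            keep = start
            break
    bases, quals = bases[:keep], quals[:keep]
    # (b) trailing low-quality or N
    keep = len(quals)
    for i in range(len(quals) - 1, -1, -1):
        if quals[i] < trail_q or bases[i].upper() == "N":
            keep = i
        else:
            break
    bases, quals = bases[:keep], quals[:keep]
    # (c) adapter: leftmost full match, else 3'-terminal prefix >= min_overlap
    if adapter:
        pos = -1
        for start in range(0, len(bases) - len(adapter) + 1):
            if bases[start:start + len(adapter)] == adapter:
                pos = start
                break
        if pos >= 0:
            bases = bases[:pos]
        else:
            best = None
            for ov in range(min(len(adapter) - 1, len(bases)), min_overlap - 1, -1):
                if bases[len(bases) - ov:] == adapter[:ov]:
                    best = len(bases) - ov
                    break
            if best is not None:
                bases = bases[:best]
    return bases, quals[: len(bases)]


def generate_read_fixture(
    n_pairs: int,
    length_range: tuple[int, int] = (80, 100),
    quality_profile=None,
    adapter: str = DEFAULT_ADAPTER,
    seed: int = 0,
    out_dir: str | Path | None = None,
    p_adapter: float = 0.3,
    p_low_tail: float = 0.3,
    p_bad_read: float = 0.15,
    min_length: int = 26,
    window: int = 4,
    window_q: float = 10.0,
    trail_q: int = 3,
    min_overlap: int = 3,
):
    """Paired FASTQ with planted adapters/low-quality tails plus survival truth.

    ``quality_profile`` is ``callable(rng, length) -> int array`` of Phred
    values in [0, 41] for a clean read; the default is Normal(38, 2) clipped.
    Each mate independently receives, with the stated probabilities, a
    planted adapter (adapter + random bases appended at a random position),
    a low-quality 3' tail, or is made globally bad (all qualities ~2, which
    the window trim removes entirely).  The truth sidecar marks each pair's
    survival under the five-step QC, computed by an independent naive trace.

    Returns ``(pairs, truth)``; if ``out_dir`` is given also writes
    ``reads_1.fastq``, ``reads_2.fastq`` and ``truth.tsv`` there.
    """
    from .readqc import Read, ReadPair, write_fastq

    lo, hi = length_range
    if lo < 1:
        raise ValueError("length_range lower bound must be >= 1")
    if n_pairs < 1:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(seed)
    if quality_profile is None:
        def quality_profile(r, n):
            return np.clip(np.rint(r.normal(38, 2, size=n)), 0, 41).astype(int)

    bases_alphabet = np.array(list("ACGT"))

    def one_read(name: str) -> Read:
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(bases_alphabet, size=length))
        quals = np.asarray(quality_profile(rng, length), dtype=int)
        if quals.min() < 0 or quals.max() > 41:
            raise ValueError("quality profile produced Phred values outside [0, 41]")
        quals = quals.tolist()
        if rng.random() < p_bad_read:
            quals = [2] * length
        else:
            if rng.random() < p_adapter and length > len(adapter) + 5:
                pos = int(rng.integers(1, length - len(adapter)))
                tail_len = length - pos - len(adapter)
                tail = "".join(rng.choice(bases_alphabet, size=tail_len))
                seq = seq[:pos] + adapter + tail
            if rng.random() < p_low_tail:
                tail_len = int(rng.integers(1, max(2, length // 3)))
                for i in range(length - tail_len, length):
                    quals[i] = int(rng.integers(0, trail_q))
        return Read(name, seq, quals)

    pairs = []
    rows = []
    for i in range(n_pairs):
        pid = f"pair{i + 1:05d}"
        r1 = one_read(f"{pid}/1")
        r2 = one_read(f"{pid}/2")
        pairs.append(ReadPair(r1, r2))
        ok = True
        for r in (r1, r2):
            keep = _naive_qc_keep_length(
                r.bases, list(r.qualities), window, window_q, trail_q,
                adapter, min_overlap)
            if keep < min_length:
                ok = False
        rows.append((pid, ok))
    truth = ReadFixtureTruth(
        pd.DataFrame(rows, columns=["pair_id", "survives"]).set_index("pair_id"))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fastq([p.read1 for p in pairs], out_dir / "reads_1.fastq")
        write_fastq([p.read2 for p in pairs], out_dir / "reads_2.fastq")
        truth.to_tsv(out_dir / "truth.tsv")
    return pairs, truth
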