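# Methods

This note documents the models, conventions and numerical choices behind
`crcsided`, in the spirit of a statistical-software methods appendix. It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## The synthetic data model

The generator (`crcsided.synth`) emulates a two-condition, multi-donor
droplet scRNA-seq design: `S` samples, each labelled `left` or `right`, each
contributing `n_cells` cells whose types are drawn i.i.d. from the
side-specific composition row. Counts for cell *c* of type *t* in sample
*s* are

```
w_g      = exp(b_t + ε_{s,g}) · boost^{1[g ∈ markers(t)]}
μ_{g,c}  = L_c · w_g / Σ_g w_g          L_c ~ LogNormal(mean, CV)
X_{g,c}  ~ NB(μ_{g,c}, φ)               Var = μ + φ·μ²
```

with `b_t` the type's baseline log-mean, `ε_{s,g} ~ N(0, σ_s²)` a
per-(sample, gene) donor effect, and `φ` the overdispersion (`φ = 0` gives
Poisson). Everything is driven by one `numpy` `Generator` seeded from the
config, so identical configs give byte-identical matrices.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| cells, genes | 3,000 cells / 2,000 genes | desk scale; the real atlas' 27,927 cells is a scale target, not a requirement |
| samples | 6 (3 left, 3 right), equal cells | matches the study design; per-sample totals are unpublished, so cells split equally |
| `marker_boost` | 8 | cell types in tissue differ by roughly an order of magnitude on marker programs |
| markers per type | 10–12 | realistic programs; clusters in real data differ over dozens of genes, not 3 |
| `library_size_mean`, CV | 2,000 counts, 0.3 | typical 10x v3 per-cell depth; a non-trivial CV exercises depth normalization |
| `dispersion` φ | 0.5 | mid-range scRNA-seq overdispersion |
| `sample_effect_sd` | 0.1 | mild donor effects, consistent with concatenating samples without integration |

The `paper_composition` preset pins the within-side composition rows so the
expected side-of-origin fractions of three clusters equal the published
percentages (mast 71.5% right; exhausted CD8 67.9% right; preexhausted CD8
86.8% left). With equal per-side totals, a cluster with within-side
fractions `c_L, c_R` has expected right side-of-origin fraction
`c_R / (c_L + c_R)`; the preset inverts this relation at a chosen overall
cluster weight.

**What the generator does not emulate:** ambient RNA, doublets, UMI
collisions, batch-specific dropout curves, gene–gene correlation beyond the
type/donor structure, and any real biology in the filler genes. Passing
tests therefore demonstrate correctness and calibration of the *procedures*
under a clean generative model — not robustness to every artifact of real
droplet data.

## Read-level QC

The five steps run per mate: (a) 4-base sliding-window scan 5′→3′, cutting
at the start of the first window with mean Phred < 10 (windows shorter than
4 at the 3′ end are not evaluated); (b) removal of the maximal trailing run
of bases with quality < 3 or base N; (c) adapter removal — leftmost exact
match, else the longest adapter *prefix* of ≥ 3 bases flush with the 3′ end
(no mismatches; no default adapter is assumed); (d) drop mates shorter than
26 bases; (e) drop pairs with a dropped mate. Qualities are Phred+33.

One pass of (a)–(c) is not idempotent: truncation can expose a 3′ end that
an earlier rule would now act on (a low-quality base uncovered by adapter
removal, or a coincidental adapter-prefix at the new end). Since an
idempotent filter is the defensible contract for a trimmer, the (a)→(b)→(c)
cycle repeats until the read stops shrinking; the step order is preserved
within each cycle. The synthetic read fixture's truth sidecar is computed
by a deliberately independent, naive per-base re-implementation of the same
contract, so the QC module is validated against a second code path.

## Expression core

* **Normalization**: log1p of counts-per-10,000 — the de-facto convention
  of the Seurat/scanpy toolchain; all-zero cells are excluded with a
  warning; a minimum-expressed-genes cell filter (default 200) is available
  upstream.
* **HVG selection**: dispersion = var/mean of normalized expression,
  standardized within 20 equal-occupancy mean bins; ranking is binned
  dispersion ↓, then raw dispersion ↓ (this settles single-gene bins), then
  gene name ↑ — fully deterministic.
* **Clustering**: Z-scale HVG columns, PCA (arpack), kNN graph (k = 15,
  Euclidean in PC space), Leiden modularity at resolution 0.6 (seeded).
  Cross-sample integration is deliberately plain concatenation: the donor
  effect in the generator is mild, and integration internals are out of
  scope.
* **Wilcoxon rank-sum**: exact enumeration of all C(n+m, n) group
  assignments (midranks for ties; two-sided p = 2·min(tails), capped at 1)
  when n+m ≤ 10; the tie-corrected normal approximation (no continuity
  correction) otherwise. The cutover keeps the exact path testable against
  an independent enumeration oracle while staying fast on real group sizes.
* **DEG rules**: log fold change is the difference of group means of
  log-normalized expression (natural log) for the marker and per-cluster
  side contrasts (|logFC| > 0.5, BH-adjusted P < 0.05); the
  enrichment-input filter uses base-2 fold changes (|log₂FC| > 1,
  BH-adjusted P < 0.01). BH is the only multiplicity correction used
  anywhere in the package.

## Signature scores and trends

Scores are unweighted means of gene-wise Z-scores (sample sd, n−1;
zero-variance genes map to Z = 0 with a warning) of log-normalized
expression. The Z-transform is computed **over the population passed in**
— score a compartment (e.g. all CD8⁺ T cells) by passing exactly those
cells; this matches per-compartment score figures and makes the scoring
population an explicit argument rather than a hidden global.

Shipped programs: naiveness (4 genes), cytotoxicity (12), coinhibition (24)
as published; the exhaustion program is a *90-slot configurable list whose
default is a placeholder* assembled from well-known exhaustion-associated
symbols, because the original 90-gene membership is cited but not printed —
no shipped result or test depends on its composition. The M1/M2 macrophage
panels are likewise illustrative defaults and configurable.

Panel fold changes are plain ratios of mean panel expression computed on
the linear CP10K scale (expm1 of the log-normalized values), so a planted
k-fold boost is estimated near k; `fold(a,b)·fold(b,a) = 1` exactly.

Score-vs-pseudotime trends use first-degree LOESS with tricube weights
(statsmodels `lowess`, no robustness iterations), evaluated on a 100-point
grid over the component range; span defaults to 0.5. Trajectory components
are accepted as plain numeric per-cell vectors from any source;
`pseudotime_surrogate` provides a PCA-based stand-in coordinate system so
the pipeline runs end to end — it is an embedding, not trajectory
inference.

## Composition statistics

Composition tables report both side-of-origin fractions per cluster and
cluster-mixture fractions per side; ratio statistics always consume raw
counts (fractions only in the documented printed-fraction reproduction
mode, where cluster totals cancel algebraically). `fold_ratio` returns NaN
— an explicit "undefined" — on a zero denominator. Centroid similarity is
Pearson correlation between per-type mean expression vectors over a stated
gene space (defaulting to the clustering HVG set; the choice is exposed
because published legends do not state it). The dendrogram is UPGMA on
1 − r with a lexicographic tie-break on cluster member tuples, making the
tree independent of input order; it is cross-checked against SciPy's
average-linkage heights in the tests. Over-representation is the
upper-tail hypergeometric P(X ≥ overlap) with BH across the supplied set
collection.

## Ligand–receptor permutation test

For pair *p* with ligand entity ℓ and receptor entity *r* and ordered
cluster pair (A, B): entity expression is the minimum over subunit means of
the cluster's mean normalized expression, masked to 0 when the gene is
detected in < 10% of the cluster's cells; the statistic is
(ℓ̄_A + r̄_B)/2, set to 0 if either side is masked. The null shuffles
cluster labels over cells `n_perm` times (default 1000) recomputing masks
and means each time; p = (1 + #{null ≥ obs})/(1 + n_perm) — never 0, floor
1/(n_perm+1). Pairs with p > 0.05 are filtered (p = 0.05 retained); a pair
whose observed statistic is 0 is reported degenerate with p = 1. These
conventions mirror the cited tool's published ones; each is a parameter. A
~30-pair packaged interaction list (TNF/TRAIL/TGFβ axes, collagen→integrin
α1β1 complexes, checkpoint and chemokine pairs) stands in for the external
curated database, and a per-side mode runs the test separately on left and
right cells.

## Problem sizes used in validation

The suite validates at deliberately small scale, chosen as the smallest
sizes at which each check is statistically meaningful: composition recovery
at 10,002 cells (exact binomial 99% bands), panel-fold recovery at 500
cells/group (±10%), two-type clustering recovery at 300 cells (ARI = 1.0),
marker-program power at ~1,000 cells (every planted marker recovered), null
calibration of the side-DEG rule at 200 exchangeable cells (0 DEGs) and of
the permutation test on a 50-pair, 200-cell exchangeable fixture at
n_perm = 1000 (KS-uniform p's; significant fraction ≤ 0.07). Seeds are
fixed throughout.

## Known limitations

* The exhaustion program default is a placeholder list (above); supply the
  real 90-gene program for substantive use.
* The asymptotic Wilcoxon path (groups > 10) is approximate for heavily
  tied sparse genes, exactly as in the standard toolchain.
* Leiden partitions are deterministic per seed but can differ across
  igraph/leidenalg versions.
* The simulator's independence assumptions (above) mean calibration results
  transfer to real data only to the extent real data meet them.
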