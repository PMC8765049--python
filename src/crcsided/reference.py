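"""Printed summary statistics from the left- vs right-sided CRC study.

These are the published desk-reference numbers (cell totals per side,
side-of-origin percentages of selected clusters, reported fold changes) that
the composition operations are demonstrated against and that the synthetic
``paper_composition`` fixture is parameterized from.  They are inputs, not
results: every statistic this package reports is recomputed from data at run
time.
"""

from __future__ import annotations

#: High-quality single cells profiled per tumor side.
CELLS_PER_SIDE = {"left": 13_488, "right": 14_439}

#: Total high-quality cells reported for the atlas.
TOTAL_CELLS = 27_927

#: Side-of-origin fractions of selected clusters (fraction of the cluster's
#: cells contributed by each side).  Mast cells are atlas cluster 13; CD8-C4
#: is the exhausted and CD8-C6 the preexhausted CD8+ T-cell subcluster.
SIDE_OF_ORIGIN = {
    "mast": {"right": 0.715, "left": 0.285},
    "CD8-C4_exhausted": {"right": 0.679, "left": 0.321},
    "CD8-C6_preexhausted": {"left": 0.868, "right": 0.132},
}

#: Reported macrophage marker-panel fold changes:
#: (panel, numerator group, denominator group) -> fold.
PANEL_FOLDS = {
    ("M1", "cluster8", "cluster6"): 2.43,
    ("M2", "cluster6", "cluster8"): 3.04,
    ("M1", "M1-like_left", "M1-like_right"): 1.43,
    ("M2", "M2-like_left", "M2-like_right"): 2.03,
}

#: Reported left:right fold of the within-side preexhausted:exhausted ratio.
PREEXHAUSTED_EXHAUSTED_FOLD = 13.8

#: Compartment sizes used when reclustering (cells per lineage).
COMPARTMENT_CELLS = {"CD4_T": 4310, "CD8_T": 2351, "Treg": 1742, "cancer": 2196}
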