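import warnings

import numpy as np
import pandas as pd
import pytest

from crcsided import core, synth

warnings.filterwarnings("ignore", message="zero-centering a sparse")
warnings.filterwarnings("ignore", category=FutureWarning, module="scanpy")


@pytest.fixture(scope="session")
def null_dataset():
    """200 exchangeable cells (one type, no sample effect) + interleaved labels."""
    cfg = synth.SimulationConfig(
        n_genes=300,
        cell_types=[synth.CellTypeSpec("only", ["G00001"])],
        composition={("only", "left"): 1.0, ("only", "right"): 1.0},
        samples=[("L1", "left", 100), ("R1", "right", 100)],
        marker_boost=1.0,
        sample_effect_sd=0.0,
        seed=0,
    )
    adata, _ = synth.generate_counts(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = core.normalize_log_cp10k(adata)
    labels = pd.Series(
        np.where(np.arange(norm.n_obs) % 2 == 0, "c0", "c1"), index=norm.obs_names
    )
    return norm, labels


@pytest.fixture(scope="session")
def two_type_dataset():
    """Two well-separated planted cell types (strong marker boost)."""
    types = [
        synth.CellTypeSpec("X", [f"XM{i}" for i in range(12)]),
        synth.CellTypeSpec("Y", [f"YM{i}" for i in range(12)]),
    ]
    comp = {(t, s): 0.5 for t in ("X", "Y") for s in ("left", "right")}
    cfg = synth.SimulationConfig(
        n_genes=300, cell_types=types, composition=comp,
        samples=[("L1", "left", 150), ("R1", "right", 150)],
        marker_boost=20.0, seed=0,
    )
    adata, truth = synth.generate_counts(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = core.normalize_log_cp10k(adata)
    return norm, truth


@pytest.fixture(scope="session")
def interaction_dataset():
    """Planted ligand-receptor structure between four cell types."""
    cfg = synth.interaction_config(seed=2, cells_per_sample=60)
    adata, _ = synth.generate_counts(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = core.normalize_log_cp10k(adata)
    return norm
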