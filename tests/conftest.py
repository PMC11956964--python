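import warnings

import numpy as np
import pytest

from synospace import SimConfig, generate_tissue
from synospace.io import GenePanel, make_cell_table
from synospace.preprocess import (assign_cell_types, classify_fibroblast_subtypes,
                                  normalize, qc_filter)


@pytest.fixture(scope="session")
def tissue():
    """One default simulated tissue (no transcript points) with ground truth."""
    return generate_tissue(SimConfig(seed=42, transcript_genes=()))


@pytest.fixture(scope="session")
def typed_tissue(tissue):
    """QC'd, normalized, typed and subtyped copy of the default tissue."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cells = qc_filter(tissue.cells, min_features=5)
        normalize(cells)
        assign_cell_types(cells)
        classify_fibroblast_subtypes(cells)
    truth = tissue.truth.cells.loc[cells.obs_names]
    return cells, truth


@pytest.fixture
def toy_panel():
    return GenePanel(("G1", "G2", "G3", "G4", "G5", "G6"), panel_kind="custom50")


def make_toy_cells(counts, panel, sample_id="s1", **obs):
    counts = np.asarray(counts)
    n = counts.shape[0]
    xy = np.arange(n, dtype=float)
    return make_cell_table(counts, panel.genes, [f"c{i}" for i in range(n)],
                          sample_id, xy, xy, **obs)


@pytest.fixture
def toy_cells_factory(toy_panel):
    def factory(counts, **kw):
        return make_toy_cells(counts, toy_panel, **kw)

    return factory
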