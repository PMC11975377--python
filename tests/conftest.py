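"""Shared fixtures: the default synthetic tissue and derived objects.

Session-scoped so the (seconds-long) default simulation and diffusion
map are computed once and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from plateaxes.diffusion import diffusion_map
from plateaxes.preprocess import normalize_median_log1p
from plateaxes.simulate import SimConfig, simulate_tissue


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic tissue: 3000 cells, 2000 genes, amplitude 4, seed 0."""
    return simulate_tissue(SimConfig())


@pytest.fixture(scope="session")
def default_norm(default_sim):
    counts, _ = default_sim
    return normalize_median_log1p(counts)


@pytest.fixture(scope="session")
def late_subset(default_sim, default_norm):
    """Pooled late-stage (stages 4-5) cells: norm matrix plus truth arrays."""
    _, truth = default_sim
    late = (truth.cells["stage"] >= 4).to_numpy()
    sub = default_norm.subset_cells(late)
    ap = truth.cells["ap"].to_numpy()[late]
    ml = truth.cells["ml"].to_numpy()[late]
    return sub, ap, ml


@pytest.fixture(scope="session")
def late_diffusion(late_subset):
    sub, ap, ml = late_subset
    _, res = diffusion_map(sub)
    return res


@pytest.fixture(scope="session")
def lowq_sim():
    """Fixture with 20% injected low-quality cells for the QC cascade."""
    return simulate_tissue(SimConfig(lowq_frac=0.2))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
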