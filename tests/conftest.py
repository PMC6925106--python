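"""Shared fixtures: desk-scale simulated experiments reused across tests."""

import numpy as np
import pytest

from acidsel.simulate import scaled_config, run_experiment
from acidsel.variant_io import SampleMeta, build_snp_panel


@pytest.fixture(scope="session")
def selection_sim():
    """One desk-scale run of the default (selection) experiment."""
    return run_experiment(scaled_config(n_offspring=40_000, n_snps=2_001), seed=3)


@pytest.fixture(scope="session")
def selection_panel(selection_sim):
    """Filtered panel + pooled-sample metadata for the selection run."""
    sim = selection_sim
    founder_ids = sim.meta.select(treatment="founder")
    pooled_ids = [s for s in sim.meta.table["sample_id"] if s not in set(founder_ids)]
    panel, report = build_snp_panel(
        sim.counts.select_samples(pooled_ids), sim.counts.select_samples(founder_ids)
    )
    pooled_meta = SampleMeta(
        table=sim.meta.table[sim.meta.table["sample_id"].isin(pooled_ids)].reset_index(
            drop=True
        )
    )
    return panel, pooled_meta, report


@pytest.fixture(scope="session")
def tiny_sim():
    """A very small neutral run for topology/determinism checks."""
    cfg = scaled_config(n_offspring=2_000, n_snps=300, with_selection=False,
                        with_growth_loci=False)
    return run_experiment(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
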