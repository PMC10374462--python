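"""Shared fixtures: a small cheap cohort for unit tests and one default-scale
synthetic study reused by the recovery tests."""

from __future__ import annotations

import pytest

from microcontam import normalize, scoring
from microcontam import simulate as sim

SMALL = dict(n_genes=300, n_neuron_types=3, n_donors=10, cells_per_donor=12,
             reference_cells_per_type=40, markers_per_type=20,
             activated_program_size=15, n_mito_genes=5, seed=11)


@pytest.fixture(scope="session")
def small_config() -> sim.SimulationConfig:
    return sim.SimulationConfig(**SMALL)


@pytest.fixture(scope="session")
def small_catalog(small_config):
    return sim.build_gene_catalog(small_config)


@pytest.fixture(scope="session")
def small_reference(small_catalog, small_config):
    return sim.simulate_reference(small_catalog, small_config, seed=101)


@pytest.fixture(scope="session")
def small_patchseq(small_catalog, small_config):
    return sim.simulate_patchseq(small_catalog, small_config, seed=102)


@pytest.fixture(scope="session")
def default_run():
    """Default study conditions: 1000 Patch-seq cells, 50 donors, 5 neuron
    types — scored against a simulated dissociated reference."""
    cfg = sim.SimulationConfig(seed=0)
    catalog = sim.build_gene_catalog(cfg)
    reference = sim.simulate_reference(catalog, cfg, seed=1)
    patchseq, truth = sim.simulate_patchseq(catalog, cfg, seed=2)
    reference_f = normalize.filter_genes(reference, {"mito"})
    patchseq_f = normalize.filter_genes(patchseq, {"mito"})
    panel = normalize.select_markers(reference_f, sim.MICROGLIA, n=50, mode="off")
    scores = scoring.score_dataset(patchseq_f, reference_f, panel)
    return {"config": cfg, "catalog": catalog, "reference": reference,
            "patchseq": patchseq, "truth": truth,
            "reference_f": reference_f, "patchseq_f": patchseq_f,
            "panel": panel, "scores": scores}
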