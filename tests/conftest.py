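"""Shared fixtures: small simulated screens reused across test modules."""

import warnings

import pytest

from gipool.pipeline import PipelineConfig, analyze_counts
from gipool.simulate import SimulationConfig, simulate_pool


@pytest.fixture(scope="session")
def small_screen():
    """A small two-condition screen with one planted negative interaction."""
    cfg = SimulationConfig(
        n_repair_genes=6,
        n_neutral_genes=4,
        replicates_per_gene=2,
        reads_per_sample=200_000,
        seed=42,
        true_single_fitness={"RPR01": 1.0, "RPR02": 1.0},
        true_epsilon={("RPR01", "RPR02", "MMS"): -0.4},
    )
    truth, table, library = simulate_pool(cfg)
    return cfg, truth, table, library


@pytest.fixture(scope="session")
def small_results(small_screen):
    """Full analysis of the small screen."""
    _, _, table, library = small_screen
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_counts(table, library, PipelineConfig())
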