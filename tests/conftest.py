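"""Shared fixtures: a default synthetic dataset and one full pipeline run.

The end-to-end fixtures are session-scoped because several tests score the
same run (site recovery, profile recovery, report round-trips) and the
pipeline is deterministic for a fixed config.
"""

from __future__ import annotations

import pandas as pd
import pytest

from clipmti.pipeline import PipelineConfig, run_pipeline
from clipmti.preprocess import PreprocessParams
from clipmti.simulate import SimulationConfig, simulate_dataset, write_simulation

DEFAULT_SEED = 1234


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """(utrs, mirnas, truth, reads) from the default study conditions."""
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, default_config):
    """Full PAR-CLIP pipeline run on the default simulation.

    Returns (sim_paths, result, truth_sites DataFrame, sim config).
    """
    base = tmp_path_factory.mktemp("e2e")
    paths = write_simulation(default_config, base / "sim")
    config = PipelineConfig(
        mode="parclip",
        preprocess=PreprocessParams(adapter=default_config.adapter),
    )
    result = run_pipeline(
        config,
        reads_path=paths["reads"],
        utrs_path=paths["utrs"],
        mirnas_path=paths["mirnas"],
        out_dir=base / "out",
        expression_path=paths["expression"],
        validated_path=paths["validated"],
        conservation_path=paths["conservation"],
    )
    truth = pd.read_csv(paths["truth_sites"], sep="\t")
    return paths, result, truth, config
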