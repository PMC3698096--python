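"""Shared fixtures: one small and one full-scale synthetic study per session."""

from __future__ import annotations

import dataclasses

import pytest

from mirmos.config import PipelineConfig
from mirmos.pipeline import run_all
from mirmos.synthetic_data import SimulationConfig


SMALL_SIM = dict(seed=7, contig_length=60_000, n_planted=10,
                 n_exon_controls=2, reads_per_library=8_000)


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    return SimulationConfig(**SMALL_SIM)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, small_sim_config):
    """Full pipeline run on a reduced synthetic study (~15 s once)."""
    out = tmp_path_factory.mktemp("small_run")
    config = PipelineConfig(out_dir=str(out), seed=small_sim_config.seed)
    results = run_all(config, simulate=small_sim_config)
    results["config"] = config
    results["sim"] = small_sim_config
    return results


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline run at the study's default scale (seed 42, six
    libraries of 100k reads, 40 planted genes).  Built once per session;
    the expensive acceptance-level checks all read from here."""
    sim = SimulationConfig(seed=42)
    out = tmp_path_factory.mktemp("default_run")
    config = PipelineConfig(out_dir=str(out), seed=42)
    results = run_all(config, simulate=sim)
    results["config"] = config
    results["sim"] = sim
    return results


@pytest.fixture()
def truth_table(small_run):
    import pandas as pd
    return pd.read_csv(
        f"{small_run['config'].out_dir}/data/truth.tsv", sep="\t")
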