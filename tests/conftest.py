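"""Shared fixtures: seeded synthetic communities at three scales.

All fixture data is generated at test time by the package's own
community simulator; nothing is stored on disk in the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from covbin import (
    ProfileStore,
    SimulationConfig,
    build_profile_store,
    make_core_bins,
    recruit_contigs,
    simulate_community,
)
from covbin.cli import write_assignments
from covbin.coverage_transform import add_transforms


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Tiny 3-genome community for parsing/IO tests (seconds to build)."""
    config = SimulationConfig(
        n_genomes=3,
        genome_length_range=(20_000, 40_000),
        depth_factor=3.0,
        profile_separation="high",
        seed=7,
    )
    return simulate_community(config, tmp_path_factory.mktemp("small_sim"))


@pytest.fixture(scope="session")
def small_store(small_sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_store") / "store.h5"
    store = build_profile_store(small_sim.fasta, small_sim.bams, out_path=out)
    add_transforms(store)
    store.save()
    return store


@pytest.fixture(scope="session")
def core_sim(tmp_path_factory):
    """3 well-separated genomes at a scale where coring defaults apply."""
    config = SimulationConfig(
        n_genomes=3,
        genome_length_range=(100_000, 160_000),
        depth_factor=10.0,
        profile_separation="high",
        seed=42,
    )
    return simulate_community(config, tmp_path_factory.mktemp("core_sim"))


@pytest.fixture(scope="session")
def core_store(core_sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("core_store") / "store.h5"
    store = build_profile_store(core_sim.fasta, core_sim.bams, out_path=out)
    add_transforms(store)
    store.save()
    return store


@pytest.fixture(scope="session")
def core_binset(core_store):
    return make_core_bins(core_store)


def run_pipeline(config: SimulationConfig, workdir):
    """simulate -> parse -> core -> recruit; returns (store, binset, truth, csv)."""
    sim = simulate_community(config, workdir / "sim")
    store = build_profile_store(sim.fasta, sim.bams, out_path=workdir / "store.h5")
    add_transforms(store)
    binset = make_core_bins(store)
    recruit_contigs(binset, store)
    store.save()
    csv = write_assignments(store, workdir / "assignments.csv")
    truth = sim.truth[sim.truth["contig_id"].isin(store.contig_ids)]
    return store, binset, truth, csv


@pytest.fixture(scope="session")
def pipeline42(tmp_path_factory):
    """The reference 10-genome pipeline, run twice with identical seeds."""
    config = SimulationConfig()  # 10 genomes, 3 samples, high separation, seed 42
    run_a = run_pipeline(config, tmp_path_factory.mktemp("pipe_a"))
    run_b = run_pipeline(config, tmp_path_factory.mktemp("pipe_b"))
    return {"config": config, "a": run_a, "b": run_b}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
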