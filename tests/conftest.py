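"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import pytest

from longumi.preprocess import preprocess_reads, default_min_length
from longumi.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def zero_error_dataset():
    """Error-free reads: every stage should invert the simulator exactly."""
    config = SimConfig(
        reference_length=500,
        n_molecules=8,
        mutation_rate=2e-3,
        depth_mean=6.0,
        depth_min=2,
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
        chimera_fraction=0.0,
        seed=7,
    )
    reference, design, reads, manifest = simulate_dataset(config)
    return config, reference, design, reads, manifest


@pytest.fixture(scope="session")
def zero_error_polymorphic_pipeline(tmp_path_factory):
    """Error-free run with shared (polymorphic) variants planted in every
    molecule, plus private heteroplasmic mutations."""
    from longumi.pipeline import PipelineConfig, run_pipeline

    config = SimConfig(
        reference_length=400,
        n_molecules=6,
        mutation_rate=4e-3,
        n_polymorphisms=2,
        depth_mean=5.0,
        depth_min=3,
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
        chimera_fraction=0.0,
        seed=29,
    )
    result = run_pipeline(
        PipelineConfig(
            outdir=str(tmp_path_factory.mktemp("polymorphic_run")),
            seed=config.seed,
            simulate=config,
            min_depth=2,
            write_cluster_fastq=False,
        )
    )
    return result, result.manifest


@pytest.fixture(scope="session")
def noisy_dataset():
    """Study-condition reads (15% combined error) at a reduced scale."""
    config = SimConfig(
        reference_length=1000,
        n_molecules=25,
        depth_mean=20.0,
        depth_min=5,
        chimera_fraction=0.04,
        seed=5,
    )
    reference, design, reads, manifest = simulate_dataset(config)
    return config, reference, design, reads, manifest


@pytest.fixture(scope="session")
def zero_error_pipeline(zero_error_dataset, tmp_path_factory):
    """Full pipeline run on the error-free dataset (shared across tests)."""
    from longumi.pipeline import PipelineConfig, run_pipeline

    config, _reference, _design, _reads, _manifest = zero_error_dataset
    return run_pipeline(
        PipelineConfig(
            outdir=str(tmp_path_factory.mktemp("zero_error_run")),
            seed=config.seed,
            simulate=config,
            min_depth=2,
            write_cluster_fastq=False,
        )
    )


@pytest.fixture(scope="session")
def noisy_preprocessed(noisy_dataset):
    config, reference, design, reads, manifest = noisy_dataset
    result = preprocess_reads(reads, design, default_min_length(design, len(reference)))
    return result
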