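from types import SimpleNamespace

import pytest

from hemolnc.synthetic_data import (
    SyntheticConfig,
    generate_counts,
    generate_genome,
    generate_qpcr,
    generate_transcripts,
)


@pytest.fixture(scope="session")
def default_cfg() -> SyntheticConfig:
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def synth(default_cfg):
    """One full synthetic dataset (seed 1), shared across the suite."""
    genome = generate_genome(default_cfg)
    sequences, truth, hits = generate_transcripts(default_cfg, genome)
    counts, lengths = generate_counts(default_cfg, truth, sequences, genome.genes)
    dilution, ct = generate_qpcr(default_cfg, truth)
    return SimpleNamespace(
        cfg=default_cfg,
        genome=genome,
        sequences=sequences,
        truth=truth,
        hits=hits,
        counts=counts,
        lengths=lengths,
        dilution=dilution,
        ct=ct,
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A complete default pipeline run (seed 1)."""
    from hemolnc.pipeline import run_all

    outdir = tmp_path_factory.mktemp("pipeline_run")
    report = run_all(SyntheticConfig(seed=1), outdir)
    return SimpleNamespace(report=report, outdir=outdir)
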