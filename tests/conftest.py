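"""Shared fixtures: synthetic datasets at the default and power-analysis
scales, plus hand-built gene models for coordinate arithmetic tests."""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("default", database=None, derandomize=True)
settings.load_profile("default")

from pooldiff.effects import GeneModel
from pooldiff.pipeline import PipelineConfig, run_pipeline
from pooldiff.simulate import SimulationConfig, simulate_dataset

_REVCOMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def power_config() -> SimulationConfig:
    """Larger dataset for recall/power checks: 200 genes (40 planted at
    |log2FC| = 2), 200 variant sites at a 50-point frequency difference."""
    return SimulationConfig(seed=5, n_contigs=3, contig_length=130_000,
                            n_genes=200, n_de_genes=40, n_variant_sites=200)


@pytest.fixture(scope="session")
def power_bundle(power_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("power")
    return run_pipeline(PipelineConfig(outdir=out, seed=power_config.seed,
                                       sim=power_config))


@pytest.fixture(scope="session")
def default_bundle(default_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("default_run")
    return run_pipeline(PipelineConfig(outdir=out, seed=default_config.seed,
                                       sim=default_config))


def make_single_cds_gene(cds: str, strand: str, flank: str = "GGGGG",
                         gene_id: str = "g1", contig: str = "chrT"
                         ) -> tuple[GeneModel, dict[str, str]]:
    """A single-exon gene whose CDS is ``cds`` (coding orientation), embedded
    between flanks; returns the model and its one-contig genome."""
    body = cds if strand == "+" else revcomp(cds)
    seq = flank + body + flank
    a, b = len(flank), len(flank) + len(body)
    model = GeneModel(gene_id=gene_id, contig=contig, strand=strand,
                      exons=[(a, b)], cds=[(a, b)])
    return model, {contig: seq}
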