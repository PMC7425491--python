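import pathlib

import pytest

from spliceneo.fixtures import generate_fixture
from spliceneo.models import TranscriptModel
from spliceneo.pipeline import PipelineConfig, run_pipeline

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> pathlib.Path:
    d = tmp_path_factory.mktemp("bundle")
    generate_fixture(d, seed=FIXTURE_SEED)
    return d


@pytest.fixture(scope="session")
def manifest(fixture_dir):
    import json

    return json.loads((fixture_dir / "manifest.json").read_text())


def make_config(fixture_dir, manifest, **overrides) -> PipelineConfig:
    base = dict(
        genome=str(fixture_dir / "genome.fa"),
        annotation=str(fixture_dir / "annotation.refgene.txt"),
        junctions=str(fixture_dir / "junctions.sj.tab"),
        epitope_library=str(fixture_dir / "epitopes.fa"),
        hla_alleles=tuple(manifest["alleles"]),
        panel=str(fixture_dir / "panel.tsv"),
        counts=str(fixture_dir / "counts.tsv"),
        total_mapped_reads=manifest["total_mapped_reads"],
        seed=manifest["seed"],
    )
    base.update(overrides)
    return PipelineConfig(**base)


@pytest.fixture(scope="session")
def fixture_run(fixture_dir, manifest):
    """One shared full pipeline run over the session fixture bundle."""
    return run_pipeline(make_config(fixture_dir, manifest))


@pytest.fixture
def toy_model() -> TranscriptModel:
    """4-exon plus-strand transcript with a CDS spanning exons 1-4."""
    return TranscriptModel(
        transcript_id="TOY1",
        gene_id="TOYG",
        chrom="chrT",
        strand="+",
        exons=((100, 200), (300, 400), (500, 560), (700, 800)),
        cds_start=130,
        cds_end=760,
    )
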