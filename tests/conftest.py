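import json
from types import SimpleNamespace

import pytest

from exomescreen import catalogue as cat
from exomescreen import depthqc as dq
from exomescreen import screen as scr
from exomescreen import synthetic

#: fixed seed for the shared synthetic study used across the suite
STUDY_SEED = 1


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One default-scale synthetic study (49 samples, 352 valid variants)."""
    outdir = tmp_path_factory.mktemp("study")
    paths = synthetic.simulate_study(outdir, seed=STUDY_SEED)
    with open(paths.truth) as fh:
        truth = json.load(fh)
    return SimpleNamespace(paths=paths, truth=truth)


@pytest.fixture(scope="session")
def curated(study):
    records = cat.parse_catalogue(study.paths.raw_catalogue)
    variants, report = cat.curate(records)
    return SimpleNamespace(records=records, variants=variants, report=report)


@pytest.fixture(scope="session")
def tracks(study):
    return [
        dq.DepthTrack.from_tsv(p, sample_id=p.name.removesuffix(".depth.tsv"))
        for p in sorted(study.paths.depth_dir.glob("*.depth.tsv"))
    ]


@pytest.fixture(scope="session")
def qmatrix(tracks, curated):
    return dq.build_qualification_matrix(tracks, curated.variants)


@pytest.fixture(scope="session")
def metadata(study):
    return scr.read_metadata(study.paths.metadata)


@pytest.fixture(scope="session")
def calls(study, curated, metadata, qmatrix):
    return scr.scan_vcf(study.paths.vcf, curated.variants, metadata, qm=qmatrix)


@pytest.fixture
def mkvar():
    """Factory for catalogue variants with sensible defaults."""

    def _make(
        record_id="V1",
        chromosome="chr1",
        position=100,
        ref="A",
        alt="G",
        category=None,
        inheritance=cat.Inheritance.AUTOSOMAL_RECESSIVE,
        publication_year=2010,
        is_disease=True,
        location_class="CDS",
    ):
        size = max(len(ref), len(alt))
        if category is None:
            category = cat.classify(size, location_class)
        return cat.CatalogueVariant(
            record_id=record_id,
            gene_symbol="GENE1",
            chromosome=chromosome,
            position=position,
            ref_allele=ref,
            alt_allele=alt,
            size_bp=size,
            category=category,
            inheritance=inheritance,
            publication_year=publication_year,
            phene="trait",
            is_disease=is_disease,
        )

    return _make
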