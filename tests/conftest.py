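import numpy as np
import pytest

from chipdiff import (
    CoverageTrack,
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    generate_annotation,
)


@pytest.fixture(scope="session")
def small_annotation() -> GenomeAnnotation:
    """Hand-built two-chromosome annotation for worked examples."""
    genes = [
        Gene("geneA", GenomicInterval("chr1", 4000, 9000, "+"), has_cgi=True),
        Gene("geneB", GenomicInterval("chr1", 7500, 20000, "+")),
        Gene("geneC", GenomicInterval("chr1", 30000, 36000, "-")),
        Gene("geneD", GenomicInterval("chr2", 1000, 5000, "+"), has_cgi=True),
    ]
    cgis = [
        GenomicInterval("chr1", 3600, 4200),
        GenomicInterval("chr2", 600, 1200),
    ]
    return GenomeAnnotation(
        genes=genes, cgis=cgis, chrom_sizes={"chr1": 50000, "chr2": 30000}
    )


@pytest.fixture(scope="session")
def random_annotation() -> GenomeAnnotation:
    return generate_annotation(n_genes=120, n_chroms=3, chrom_len=2_000_000, seed=7)


def make_track(records, chrom_sizes, scale_factor=1.0) -> CoverageTrack:
    return CoverageTrack.from_records(records, chrom_sizes, scale_factor)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
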