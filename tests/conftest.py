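import numpy as np
import pytest

from didymascan.catalog import Genome, MutationCatalog, MutationRecord
from didymascan.synth import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic co-mutagenesis dataset (1 Mb, 50 didyma pairs)."""
    return generate_dataset(SyntheticConfig(seed=1234))


@pytest.fixture(scope="session")
def toy_genome():
    """A 10 kb single-contig random genome for context arithmetic."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    return Genome(sequences={"chr1": seq})


def make_record(chrom="chr1", pos=100, ref="C", alt="T", vaf=0.4, sample="s1",
                alt_reads=20, depth=60, callers=3):
    return MutationRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, vaf=vaf,
                          alt_reads=alt_reads, depth=depth,
                          caller_support=callers, sample=sample)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def motif_genome_factory():
    """Build a genome embedding a given motif at position 50 of a 200 bp contig."""

    def build(motif: str) -> tuple[Genome, int]:
        filler = "AGGAG"  # no C/T pyrimidine motifs that collide with TCW
        seq = (filler * 40)[:49] + motif
        seq = seq + (filler * 40)[: 200 - len(seq)]
        return Genome(sequences={"chr1": seq}), 50

    return build
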