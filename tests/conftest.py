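import numpy as np
import pytest

from polybench.reference import DictReference
from polybench.variants import Genotype, VariantRecord

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def make_record(chrom="chr1", pos=1, ref="A", alts=("T",), gt=None, info=None):
    genotype = Genotype(tuple(gt)) if gt is not None else None
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alts=tuple(alts), genotype=genotype,
        info=dict(info or {}),
    )


@pytest.fixture
def toy_reference():
    # 60 bp with a homopolymer run and a dinucleotide repeat to exercise
    # left-alignment: positions are 1-based in comments.
    seq = "ACTTTGACGTACGTATATATGCCCCCGTACGTAAGGTTCCAAGGTTCCGGATCGATCGAT"
    return DictReference({"chr1": seq})


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
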