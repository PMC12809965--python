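"""Reference-sequence accessors.

Everything downstream (normalization, harmonization, fixture generation)
talks to a reference through a minimal protocol: ``fetch(chrom, start, end)``
returning the uppercase sequence of the 0-based half-open interval, plus
``chrom_length`` / ``chrom_names``.  Two concrete accessors are provided:
an in-memory dict of strings (fixtures, tests) and a FASTA file backed by
pyfaidx.
"""

from __future__ import annotations

from typing import Mapping, Protocol, runtime_checkable

from pyfaidx import Fasta


@runtime_checkable
class Reference(Protocol):
    def fetch(self, chrom: str, start: int, end: int) -> str: ...

    def chrom_length(self, chrom: str) -> int: ...

    def chrom_names(self) -> list[str]: ...


class DictReference:
    """Reference held as an in-memory mapping chrom -> sequence string."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self._seqs[chrom][start:end]

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]


class FastaReference:
    """Reference backed by an (indexed-on-demand) FASTA file via pyfaidx."""

    def __init__(self, path: str):
        self._fasta = Fasta(path, as_raw=True, sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self._fasta[chrom][start:end])

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def chrom_names(self) -> list[str]:
        return list(self._fasta.keys())


def as_reference(obj) -> Reference:
    """Coerce a mapping, FASTA path, or Reference into a Reference."""
    if isinstance(obj, (DictReference, FastaReference)):
        return obj
    if isinstance(obj, Mapping):
        return DictReference(obj)
    if isinstance(obj, str):
        return FastaReference(obj)
    if isinstance(obj, Reference):
        return obj
    raise TypeError(f"cannot interpret {type(obj)!r} as a reference accessor")
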