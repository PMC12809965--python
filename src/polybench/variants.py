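"""Small-variant domain types, VCF I/O, normalization, and classification.

The central objects are :class:`VariantRecord` (one normalized VCF site with
a single polyploid sample genotype) and :class:`Genotype` (an unphased
multiset of allele indices whose size is the ploidy).  Polyploid genotypes
are treated purely as dosage vectors: phase separators are discarded on
read, and all comparisons elsewhere in the package are dosage comparisons.

Coordinate convention: VCF positions are 1-based; every internal interval
is 0-based half-open.  ``VariantRecord.pos`` keeps the 1-based VCF value and
``start0``/``end0`` expose the reference footprint for interval arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Sequence

import pysam

from .errors import (
    ConsistencyError,
    ContractError,
    OrderingError,
    PloidyError,
    VcfParseError,
)
from .reference import as_reference

logger = logging.getLogger(__name__)

_VALID_ALLELE = set("ACGTN")

#: INFO keys carried through read/write round trips when present.
INFO_KEYS = ("QD", "MQM", "DP")


@dataclass(frozen=True)
class Genotype:
    """Unphased polyploid genotype: a multiset of allele indices.

    Index 0 is the REF allele; indices 1..n_alts address ALT alleles of the
    owning record.  The canonical text form lists indices ascending,
    '/'-separated (``0/0/0/1`` for a simplex tetraploid site).
    """

    alleles: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))
        if not self.alleles:
            raise ContractError("genotype must contain at least one allele")
        if any(a < 0 for a in self.alleles):
            raise ContractError("allele indices must be non-negative")

    @property
    def ploidy(self) -> int:
        return len(self.alleles)

    def dosage(self, allele_index: int) -> int:
        """Number of copies of the given allele index."""
        return self.alleles.count(allele_index)

    def alt_indices(self) -> tuple[int, ...]:
        """Distinct non-reference allele indices present, ascending."""
        return tuple(sorted({a for a in self.alleles if a > 0}))

    def __str__(self) -> str:
        return "/".join(str(a) for a in self.alleles)


class VariantKind(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    MNV = "MNV"


@dataclass(frozen=True)
class VariantClass:
    kind: VariantKind
    indel_len: int  # |len(ref) - len(alt)| for INS/DEL, 0 otherwise


class GenotypeClass(str, Enum):
    """Dosage class of a genotype with respect to a single ALT allele.

    ``simplex`` .. ``sextuplex`` label a single distinct ALT allele at
    dosage 1..6 (AAAa, AAaa, ... in the tetraploid nomenclature);
    ``multi_allelic`` marks >=2 distinct ALT alleles in one genotype.
    """

    HOM_REF = "hom_ref"
    SIMPLEX = "simplex"
    DUPLEX = "duplex"
    TRIPLEX = "triplex"
    QUADRUPLEX = "quadruplex"
    QUINTUPLEX = "quintuplex"
    SEXTUPLEX = "sextuplex"
    MULTI_ALLELIC = "multi_allelic"
    MISSING = "missing"


_DOSAGE_LABELS = {
    1: GenotypeClass.SIMPLEX,
    2: GenotypeClass.DUPLEX,
    3: GenotypeClass.TRIPLEX,
    4: GenotypeClass.QUADRUPLEX,
    5: GenotypeClass.QUINTUPLEX,
    6: GenotypeClass.SEXTUPLEX,
}


@dataclass
class VariantRecord:
    """One small-variant site with an optional single-sample genotype.

    ``info`` maps annotation names (QD, MQM, DP, QUAL, ...) to numeric
    values; annotations absent from the source record are simply absent
    from the map.
    """

    chrom: str
    pos: int  # 1-based position of the first REF base
    ref: str
    alts: tuple[str, ...]
    genotype: Genotype | None = None
    info: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.ref = self.ref.upper()
        self.alts = tuple(a.upper() for a in self.alts)
        if not self.ref:
            raise ContractError("REF allele must be non-empty")
        if not self.alts:
            raise ContractError("at least one ALT allele is required")
        seen = set()
        for alt in self.alts:
            if not alt:
                raise ContractError("ALT allele must be non-empty")
            if alt == self.ref:
                raise ContractError(f"ALT equals REF at {self.chrom}:{self.pos}")
            if alt in seen:
                raise ContractError(f"duplicate ALT at {self.chrom}:{self.pos}")
            seen.add(alt)
        if self.genotype is not None:
            if any(a > len(self.alts) for a in self.genotype.alleles):
                raise ContractError(
                    f"genotype index out of range at {self.chrom}:{self.pos}"
                )

    @property
    def start0(self) -> int:
        """0-based start of the REF footprint."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        """0-based half-open end of the REF footprint."""
        return self.pos - 1 + len(self.ref)

    def dosage_map(self) -> dict[str, int]:
        """ALT allele string -> copy number in the genotype (0s omitted)."""
        if self.genotype is None:
            return {}
        out: dict[str, int] = {}
        for idx in self.genotype.alt_indices():
            out[self.alts[idx - 1]] = self.genotype.dosage(idx)
        return out

    def sort_key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alts)


# ---------------------------------------------------------------------------
# classification


def classify_variant(ref: str, alt: str) -> VariantClass:
    """Classify a normalized REF/ALT pair as SNV, INS, DEL, or MNV."""
    if not ref or not alt:
        raise ContractError("alleles must be non-empty")
    if len(ref) == len(alt):
        if len(ref) == 1:
            return VariantClass(VariantKind.SNV, 0)
        return VariantClass(VariantKind.MNV, 0)
    if len(alt) > len(ref):
        return VariantClass(VariantKind.INS, len(alt) - len(ref))
    return VariantClass(VariantKind.DEL, len(ref) - len(alt))


def record_kind(record: VariantRecord) -> str:
    """Variant-type label of a whole record.

    Biallelic records get their ALT's class; records whose ALTs fall in
    different classes are labelled ``MIXED``.
    """
    kinds = {classify_variant(record.ref, alt).kind.value for alt in record.alts}
    if len(kinds) == 1:
        return kinds.pop()
    return "MIXED"


def classify_genotype(gt: Genotype | None) -> GenotypeClass:
    """Dosage class of a genotype (simplex = exactly one ALT copy, etc.)."""
    if gt is None:
        return GenotypeClass.MISSING
    alt_idx = gt.alt_indices()
    if not alt_idx:
        return GenotypeClass.HOM_REF
    if len(alt_idx) > 1:
        return GenotypeClass.MULTI_ALLELIC
    return _DOSAGE_LABELS[gt.dosage(alt_idx[0])]


# ---------------------------------------------------------------------------
# normalization


def apply_to_sequence(record: VariantRecord, sequence: str, alt_index: int = 1) -> str:
    """Apply one ALT allele of a record to a full chromosome sequence.

    This is the ground-truth semantics of a VCF record and serves as the
    independent oracle for normalization and harmonization: two spellings
    describe the same variant iff they produce the same mutated sequence.
    """
    s = record.start0
    alt = record.alts[alt_index - 1]
    if sequence[s : record.end0].upper() != record.ref:
        raise ConsistencyError(
            f"REF mismatch at {record.chrom}:{record.pos}: "
            f"reference has {sequence[s:record.end0]!r}, record has {record.ref!r}"
        )
    return sequence[:s] + alt + sequence[record.end0 :]


def normalize(record: VariantRecord, reference) -> VariantRecord:
    """Left-align and trim a record to its minimal VCF representation.

    Shared trailing bases are trimmed first (extending left through the
    reference when an allele would become empty, which is what shifts
    indels leftmost), then shared leading bases are trimmed.  All alleles
    of a multiallelic record move together.  Idempotent; SNVs are fixed
    points.
    """
    ref_acc = as_reference(reference)
    pos0 = record.pos - 1
    alleles = [record.ref] + list(record.alts)
    if pos0 < 0 or record.end0 > ref_acc.chrom_length(record.chrom):
        raise ConsistencyError(
            f"record footprint outside reference at {record.chrom}:{record.pos}"
        )
    fetched = ref_acc.fetch(record.chrom, pos0, record.end0)
    if fetched != record.ref:
        raise ConsistencyError(
            f"REF mismatch at {record.chrom}:{record.pos}: "
            f"reference has {fetched!r}, record has {record.ref!r}"
        )

    while True:
        last = {a[-1] for a in alleles}
        if len(last) == 1:
            if all(len(a) >= 2 for a in alleles):
                alleles = [a[:-1] for a in alleles]
                continue
            if pos0 > 0:
                pad = ref_acc.fetch(record.chrom, pos0 - 1, pos0)
                alleles = [pad + a[:-1] for a in alleles]
                pos0 -= 1
                continue
        break
    while all(len(a) >= 2 for a in alleles) and len({a[0] for a in alleles}) == 1:
        alleles = [a[1:] for a in alleles]
        pos0 += 1

    if alleles[0] == record.ref and pos0 == record.pos - 1:
        return record
    return replace(record, pos=pos0 + 1, ref=alleles[0], alts=tuple(alleles[1:]))


def decompose_mnv(record: VariantRecord) -> list[VariantRecord]:
    """Optionally decompose a biallelic MNV into per-base SNV records.

    Positions where REF and ALT agree are skipped.  Records that are not
    biallelic MNVs are returned unchanged (callers opt in per record).
    """
    if len(record.alts) != 1:
        return [record]
    alt = record.alts[0]
    if len(record.ref) != len(alt) or len(record.ref) == 1:
        return [record]
    out = []
    for i, (r, a) in enumerate(zip(record.ref, alt)):
        if r != a:
            out.append(replace(record, pos=record.pos + i, ref=r, alts=(a,)))
    return out


# ---------------------------------------------------------------------------
# VCF I/O


def _is_symbolic(alt: str | None) -> bool:
    if alt is None:
        return True
    return alt == "*" or alt.startswith("<") or "[" in alt or "]" in alt


def read_vcf(
    path: str,
    expected_ploidy: int | None = None,
    sample: str | None = None,
) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a VCF (plain or bgzipped).

    One sample is selected (``sample`` by name, else the first); its GT is
    parsed as an unphased multiset.  Symbolic ALTs, breakends, and spanning
    deletions ('*') are skipped with a warning: only small sequence-resolved
    variants are in scope.  Raises :class:`PloidyError` if a genotype's
    ploidy differs from ``expected_ploidy``.
    """
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    with vcf:
        sample_names = list(vcf.header.samples)
        if sample is not None:
            if sample not in sample_names:
                raise VcfParseError(f"sample {sample!r} not found in {path}")
            selected = sample
        else:
            selected = sample_names[0] if sample_names else None

        last_key: tuple[str, int] | None = None
        for rec in vcf:
            if rec.ref is None or rec.alts is None:
                logger.warning("skipping ALT-less record at %s:%s", rec.chrom, rec.pos)
                continue
            if any(_is_symbolic(a) for a in rec.alts):
                logger.warning(
                    "skipping symbolic/breakend record at %s:%s", rec.chrom, rec.pos
                )
                continue
            if last_key is not None and rec.chrom == last_key[0] and rec.pos < last_key[1]:
                raise OrderingError(
                    f"VCF {path} not coordinate-sorted at {rec.chrom}:{rec.pos}"
                )
            last_key = (rec.chrom, rec.pos)

            genotype = None
            if selected is not None:
                gt = rec.samples[selected].get("GT")
                if gt is not None and not all(a is None for a in gt):
                    if any(a is None for a in gt):
                        genotype = None  # partially missing -> missing
                    else:
                        genotype = Genotype(tuple(gt))
                if genotype is not None and expected_ploidy is not None:
                    if genotype.ploidy != expected_ploidy:
                        raise PloidyError(
                            f"{rec.chrom}:{rec.pos}: genotype ploidy "
                            f"{genotype.ploidy} != expected {expected_ploidy}"
                        )
            info: dict[str, float] = {}
            if rec.qual is not None:
                info["QUAL"] = float(rec.qual)
            for key in INFO_KEYS:
                if key in rec.info:
                    val = rec.info[key]
                    if isinstance(val, tuple):
                        val = val[0]
                    if val is not None:
                        info[key] = float(val)
            yield VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alts=tuple(rec.alts),
                genotype=genotype,
                info=info,
            )


def _build_header(
    contigs: Sequence[tuple[str, int]], sample_name: str
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(name, length=length)
    header.info.add("QD", 1, "Float", "Variant confidence normalized by depth")
    header.info.add("MQM", 1, "Float", "Mean mapping quality of observed alternate alleles")
    header.info.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample_name)
    return header


def write_vcf(
    records: Iterable[VariantRecord],
    path: str,
    ploidy: int,
    contigs: Sequence[tuple[str, int]],
    sample_name: str = "SAMPLE",
) -> None:
    """Write coordinate-sorted records as single-sample VCF 4.2.

    ``contigs`` is a list of (name, length) pairs for the header.  Records
    must arrive sorted; unsorted input raises :class:`OrderingError`.
    Output is bgzipped when the path ends in ``.gz``.
    """
    header = _build_header(contigs, sample_name)
    contig_rank = {name: i for i, (name, _) in enumerate(contigs)}
    mode = "wz" if str(path).endswith(".gz") else "w"
    last: tuple[int, int] | None = None
    with pysam.VariantFile(str(path), mode, header=header) as out:
        for record in records:
            if record.chrom not in contig_rank:
                raise ContractError(f"contig {record.chrom} missing from header")
            key = (contig_rank[record.chrom], record.pos)
            if last is not None and key < last:
                raise OrderingError(
                    f"records not coordinate-sorted at {record.chrom}:{record.pos}"
                )
            last = key
            rec = out.new_record(
                contig=record.chrom,
                start=record.start0,
                alleles=(record.ref,) + record.alts,
            )
            if "QUAL" in record.info:
                rec.qual = record.info["QUAL"]
            for key_ in INFO_KEYS:
                if key_ in record.info:
                    value = record.info[key_]
                    rec.info[key_] = int(value) if key_ == "DP" else value
            if record.genotype is not None:
                rec.samples[sample_name]["GT"] = record.genotype.alleles
                rec.samples[sample_name].phased = False
            else:
                rec.samples[sample_name]["GT"] = tuple([None] * ploidy)
            out.write(rec)


def sort_records(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Canonical coordinate sort (chrom lexicographic, then pos/ref/alts)."""
    return sorted(records, key=VariantRecord.sort_key)


def check_sorted(records: Sequence[VariantRecord], what: str = "records") -> None:
    for prev, cur in zip(records, records[1:]):
        if cur.chrom == prev.chrom and cur.pos < prev.pos:
            raise OrderingError(f"{what} not coordinate-sorted at {cur.chrom}:{cur.pos}")


def genotype_from_dosages(
    alt_dosages: Sequence[int], ploidy: int
) -> Genotype:
    """Build a genotype from per-ALT dosages, padding with REF copies."""
    total = sum(alt_dosages)
    if total > ploidy:
        raise ContractError(f"ALT dosage sum {total} exceeds ploidy {ploidy}")
    alleles: list[int] = [0] * (ploidy - total)
    for idx, d in enumerate(alt_dosages, start=1):
        alleles.extend([idx] * d)
    return Genotype(tuple(alleles))
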