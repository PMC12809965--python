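"""Post-call hard filters and the reliable-region read filter.

Two variant-record filters are provided: the community per-type QD
(quality-by-depth) hard filter used with GATK output (QD < 2 drops SNVs
and indels longer than 1 bp; QD < 5 drops 1-bp indels), and configurable
threshold policies for FreeBayes callsets loaded from YAML presets.

The read filter implements the reliable-region retention rule used to
probe reference bias: a read is kept iff strictly more than ``min_frac``
of its bases fall inside reliable regions (intervals with one-to-one
reference/sample homology).  The boundary is compared in exact rational
arithmetic so a read at exactly 50% is dropped, never a float accident.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Iterable, Sequence

import yaml

from .errors import ContractError
from .regions import RegionSet
from .variants import VariantKind, VariantRecord, classify_variant

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GATK per-type QD filter


def gatk_qd_filter(record: VariantRecord) -> bool:
    """True = keep.  Per-type QD hard thresholds, strict inequality.

    SNVs, MNVs, and indels longer than 1 bp drop below QD 2; 1-bp indels
    drop below QD 5.  A multiallelic record uses the most stringent
    threshold applicable to any of its alleles.  Records without a QD
    annotation are kept with a warning (QD is only emitted for variant
    sites; punishing absence would silently drop valid records).
    """
    qd = record.info.get("QD")
    if qd is None:
        logger.warning("no QD at %s:%s; keeping record", record.chrom, record.pos)
        return True
    threshold = 2.0
    for alt in record.alts:
        vc = classify_variant(record.ref, alt)
        if vc.kind in (VariantKind.INS, VariantKind.DEL) and vc.indel_len == 1:
            threshold = 5.0
            break
    return not qd < threshold


# ---------------------------------------------------------------------------
# configurable threshold policies (FreeBayes post hoc filtering)


@dataclass(frozen=True)
class FilterRule:
    """Keep a record iff ``info[annotation] >= min_value``."""

    annotation: str
    min_value: float

    def passes(self, record: VariantRecord) -> bool | None:
        value = record.info.get(self.annotation)
        if value is None:
            return None
        return value >= self.min_value


@dataclass
class FilterPolicy:
    name: str
    rules: tuple[FilterRule, ...] = ()
    missing_fails: bool = False  # fail-closed: absent annotation drops

    def evaluate(self, record: VariantRecord) -> tuple[bool, str | None]:
        """(keep, name of first rule that fired or None)."""
        for rule in self.rules:
            ok = rule.passes(record)
            if ok is None:
                if self.missing_fails:
                    return False, f"{rule.annotation} missing"
                logger.warning(
                    "no %s at %s:%s; rule skipped",
                    rule.annotation,
                    record.chrom,
                    record.pos,
                )
                continue
            if not ok:
                return False, f"{rule.annotation} < {rule.min_value}"
        return True, None


def load_presets(path: str | None = None) -> dict[str, FilterPolicy]:
    """Load named FilterPolicies from YAML (packaged presets by default)."""
    if path is None:
        text = (
            resources.files("polybench").joinpath("freebayes_presets.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    policies = {}
    for name, rules in raw.items():
        policies[name] = FilterPolicy(
            name=name,
            rules=tuple(
                FilterRule(annotation=ann, min_value=float(spec["min"]))
                for ann, spec in rules.items()
            ),
        )
    return policies


def freebayes_filter(record: VariantRecord, policy: FilterPolicy) -> bool:
    """True = keep under the given policy (all rules must pass)."""
    keep, _ = policy.evaluate(record)
    return keep


@dataclass
class DropLogEntry:
    chrom: str
    pos: int
    rule: str


def filter_vcf(
    records: Iterable[VariantRecord], policy: FilterPolicy
) -> tuple[list[VariantRecord], list[DropLogEntry]]:
    """Order-preserving policy application with a drop log."""
    kept: list[VariantRecord] = []
    dropped: list[DropLogEntry] = []
    for record in records:
        keep, rule = policy.evaluate(record)
        if keep:
            kept.append(record)
        else:
            dropped.append(DropLogEntry(record.chrom, record.pos, rule or "?"))
    return kept, dropped


# ---------------------------------------------------------------------------
# reliable-region read filter


@dataclass(frozen=True)
class ReadPlacement:
    """Reference projection of one aligned read.

    ``aligned_ref_intervals`` holds only match/mismatch blocks (CIGAR
    M/=/X); inserted and clipped read bases contribute to ``read_length``
    but never to region overlap.
    """

    read_id: str
    chrom: str
    aligned_ref_intervals: tuple[tuple[int, int], ...]
    read_length: int

    def __post_init__(self):
        if self.read_length <= 0:
            raise ContractError(f"read {self.read_id}: non-positive read_length")
        prev_end = -1
        total = 0
        for s, e in self.aligned_ref_intervals:
            if s >= e:
                raise ContractError(f"read {self.read_id}: empty aligned interval")
            if s < prev_end:
                raise ContractError(f"read {self.read_id}: intervals overlap/unsorted")
            prev_end = e
            total += e - s
        if total > self.read_length:
            raise ContractError(
                f"read {self.read_id}: aligned bases exceed read length"
            )


def reliable_read_filter(
    read: ReadPlacement,
    reliable: RegionSet,
    min_frac: float | Fraction = Fraction(1, 2),
) -> bool:
    """True = keep: overlap/read_length strictly exceeds ``min_frac``.

    Comparison is exact (integer cross-multiplication through
    ``fractions.Fraction``): a 100-base read with 50 reliable bases is
    dropped at the default threshold, 51 is kept.
    """
    overlap = sum(
        reliable.overlap_length(read.chrom, s, e)
        for s, e in read.aligned_ref_intervals
    )
    return Fraction(overlap, read.read_length) > Fraction(min_frac)


def filter_reads(
    reads: Iterable[ReadPlacement],
    reliable: RegionSet,
    min_frac: float | Fraction = Fraction(1, 2),
) -> tuple[list[ReadPlacement], list[ReadPlacement]]:
    """(kept, dropped) partition under the reliable-region rule."""
    kept, dropped = [], []
    for read in reads:
        (kept if reliable_read_filter(read, reliable, min_frac) else dropped).append(read)
    return kept, dropped


def read_placements_tsv(path: str) -> list[ReadPlacement]:
    """Read the simple tabular placement format.

    Columns: read_id, chrom, read_length, then semicolon-joined
    ``start-end`` aligned reference intervals (0-based half-open).
    """
    out: list[ReadPlacement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ContractError(f"{path}:{lineno}: placement line has <4 columns")
            ivs = tuple(
                (int(s), int(e))
                for s, e in (part.split("-") for part in fields[3].split(";"))
            )
            out.append(
                ReadPlacement(
                    read_id=fields[0],
                    chrom=fields[1],
                    read_length=int(fields[2]),
                    aligned_ref_intervals=ivs,
                )
            )
    return out


def write_placements_tsv(reads: Sequence[ReadPlacement], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tchrom\tread_length\taligned_ref_intervals\n")
        for r in reads:
            ivs = ";".join(f"{s}-{e}" for s, e in r.aligned_ref_intervals)
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.read_length}\t{ivs}\n")


def placements_from_bam(path: str) -> list[ReadPlacement]:
    """Project BAM/SAM alignments to ReadPlacements (CIGAR M/=/X blocks)."""
    import pysam

    out: list[ReadPlacement] = []
    with pysam.AlignmentFile(path) as bam:
        for aln in bam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            ivs: list[tuple[int, int]] = []
            ref_pos = aln.reference_start
            for op, length in aln.cigartuples:
                if op in (0, 7, 8):  # M, =, X consume both
                    ivs.append((ref_pos, ref_pos + length))
                    ref_pos += length
                elif op in (2, 3):  # D, N consume reference only
                    ref_pos += length
            read_length = aln.infer_read_length() or aln.query_length
            if not ivs or not read_length:
                continue
            out.append(
                ReadPlacement(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    aligned_ref_intervals=tuple(ivs),
                    read_length=read_length,
                )
            )
    return out
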