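"""Genomic interval algebra and assembly-based confidence regions.

A :class:`RegionSet` holds, per chromosome, a sorted list of disjoint
0-based half-open intervals.  On top of plain set algebra (union,
intersection, subtraction) this module implements the confidence-region
construction used for assembly-based truth sets: for each haplotype
assembly, keep the reference positions covered by *exactly one* retained
alignment block (``unique_cover``), then intersect across all haplotypes
(``intersect_all``).  The result is the mask of reference sequence that is
uniquely and consistently represented by every haplotype — the
generalization of diploid assembly benchmarking to arbitrary ploidy.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import ContractError, PolybenchError
from .variants import VariantRecord

Interval = tuple[int, int]


@dataclass(frozen=True)
class AlignmentBlock:
    """One assembly-to-reference alignment interval on the reference."""

    haplotype_id: str
    chrom: str
    ref_start: int
    ref_end: int
    query_name: str = ""
    mapq: int = 60

    def __post_init__(self):
        if self.ref_start >= self.ref_end:
            raise ContractError(
                f"empty alignment block {self.chrom}:{self.ref_start}-{self.ref_end}"
            )
        if self.mapq < 0:
            raise ContractError("mapq must be non-negative")

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


def _merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping/touching intervals (union semantics)."""
    merged: list[Interval] = []
    for start, end in sorted(intervals):
        if start >= end:
            raise ContractError(f"invalid interval [{start},{end})")
        if merged and start <= merged[-1][1]:
            if end > merged[-1][1]:
                merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


class RegionSet:
    """Per-chromosome sorted disjoint half-open intervals (0-based)."""

    def __init__(self, intervals: Mapping[str, Iterable[Interval]] | None = None):
        self._ivs: dict[str, list[Interval]] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                merged = _merge_intervals(ivs)
                if merged:
                    self._ivs[chrom] = merged

    # -- inspection ---------------------------------------------------------

    def chroms(self) -> list[str]:
        return sorted(self._ivs)

    def intervals(self, chrom: str) -> list[Interval]:
        return list(self._ivs.get(chrom, []))

    def items(self) -> Iterator[tuple[str, int, int]]:
        for chrom in self.chroms():
            for start, end in self._ivs[chrom]:
                yield chrom, start, end

    def total_length(self) -> int:
        return sum(e - s for ivs in self._ivs.values() for s, e in ivs)

    def is_empty(self) -> bool:
        return not self._ivs

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self._ivs == other._ivs

    def __repr__(self) -> str:
        n = sum(len(v) for v in self._ivs.values())
        return f"RegionSet({len(self._ivs)} chroms, {n} intervals, {self.total_length()} bp)"

    # -- membership ---------------------------------------------------------

    def contains_interval(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start,end) lies entirely within one stored interval."""
        ivs = self._ivs.get(chrom)
        if not ivs:
            return False
        i = bisect_right(ivs, (start, float("inf"))) - 1
        if i < 0:
            return False
        s, e = ivs[i]
        return s <= start and end <= e

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        """Total number of bases of [start,end) inside this set."""
        ivs = self._ivs.get(chrom)
        if not ivs:
            return 0
        total = 0
        for s, e in ivs:
            if e <= start:
                continue
            if s >= end:
                break
            total += min(e, end) - max(s, start)
        return total

    # -- algebra ------------------------------------------------------------

    def union(self, other: "RegionSet") -> "RegionSet":
        out: dict[str, list[Interval]] = {}
        for chrom in set(self._ivs) | set(other._ivs):
            out[chrom] = self._ivs.get(chrom, []) + other._ivs.get(chrom, [])
        return RegionSet(out)

    def intersect(self, other: "RegionSet") -> "RegionSet":
        out: dict[str, list[Interval]] = {}
        for chrom in set(self._ivs) & set(other._ivs):
            a, b = self._ivs[chrom], other._ivs[chrom]
            res: list[Interval] = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if s < e:
                    res.append((s, e))
                if a[i][1] <= b[j][1]:
                    i += 1
                else:
                    j += 1
            if res:
                out[chrom] = res
        return RegionSet(out)

    def subtract(self, other: "RegionSet") -> "RegionSet":
        out: dict[str, list[Interval]] = {}
        for chrom, ivs in self._ivs.items():
            cuts = other._ivs.get(chrom, [])
            res: list[Interval] = []
            j = 0
            for s, e in ivs:
                cur = s
                while j < len(cuts) and cuts[j][1] <= cur:
                    j += 1
                k = j
                while k < len(cuts) and cuts[k][0] < e:
                    cs, ce = cuts[k]
                    if cs > cur:
                        res.append((cur, cs))
                    cur = max(cur, ce)
                    if ce >= e:
                        break
                    k += 1
                if cur < e:
                    res.append((cur, e))
            if res:
                out[chrom] = res
        return RegionSet(out)


def intersect_all(sets: Sequence[RegionSet]) -> RegionSet:
    """Positions present in every input set; associative and commutative."""
    if not sets:
        raise ContractError("intersect_all requires at least one RegionSet")
    result = sets[0]
    for s in sets[1:]:
        result = result.intersect(s)
    return result


def subtract(a: RegionSet, b: RegionSet) -> RegionSet:
    """Positions in ``a`` and not in ``b``."""
    return a.subtract(b)


def unique_cover(
    blocks: Sequence[AlignmentBlock],
    min_len: int = 50_000,
    min_mapq: int = 5,
) -> RegionSet:
    """Reference positions covered by exactly one retained block.

    Blocks shorter than ``min_len`` or with mapq below ``min_mapq`` are
    dropped first; positions covered zero times (unaligned) or two or more
    times (ambiguously aligned, e.g. a duplicated segment) are excluded.
    All blocks must belong to one haplotype.
    """
    hap_ids = {b.haplotype_id for b in blocks}
    if len(hap_ids) > 1:
        raise ContractError(f"unique_cover expects one haplotype, got {sorted(hap_ids)}")
    events: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        if b.length < min_len or b.mapq < min_mapq:
            continue
        events.setdefault(b.chrom, []).append((b.ref_start, +1))
        events[b.chrom].append((b.ref_end, -1))
    out: dict[str, list[Interval]] = {}
    for chrom, evs in events.items():
        evs.sort()
        ivs: list[Interval] = []
        depth = 0
        prev = None
        for pos, delta in evs:
            if prev is not None and depth == 1 and pos > prev:
                ivs.append((prev, pos))
            depth += delta
            prev = pos
        if ivs:
            out[chrom] = ivs
    return RegionSet(out)


def derive_confidence_regions(
    blocks: Sequence[AlignmentBlock],
    min_len: int = 50_000,
    min_mapq: int = 5,
) -> RegionSet:
    """Full confidence-region construction across all haplotypes.

    Groups blocks by haplotype, takes each haplotype's uniquely-covered
    reference positions, and intersects across haplotypes.
    """
    by_hap: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_hap.setdefault(b.haplotype_id, []).append(b)
    if not by_hap:
        return RegionSet()
    covers = [
        unique_cover(hap_blocks, min_len=min_len, min_mapq=min_mapq)
        for _, hap_blocks in sorted(by_hap.items())
    ]
    return intersect_all(covers)


def mask_vcf(
    records: Iterable[VariantRecord], regions: RegionSet
) -> Iterator[VariantRecord]:
    """Keep records whose full REF footprint lies within one interval.

    An insertion (1-base footprint) is inside iff its anchor base is
    inside; deletions must be fully contained so no variant is evaluated
    half in, half out of the mask.
    """
    for record in records:
        if regions.contains_interval(record.chrom, record.start0, record.end0):
            yield record


# ---------------------------------------------------------------------------
# file formats


def read_bed(path: str) -> RegionSet:
    """Read BED3 (0-based half-open); overlapping intervals are unioned."""
    intervals: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PolybenchError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PolybenchError(f"{path}:{lineno}: non-integer BED coordinate") from exc
            intervals.setdefault(fields[0], []).append((start, end))
    return RegionSet(intervals)


def write_bed(regions: RegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions.items():
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_paf(path: str, min_columns: int = 12) -> list[AlignmentBlock]:
    """Read minimap2-style PAF alignment lines into AlignmentBlocks.

    Target columns 6-9 map to the reference interval; column 12 is mapq.
    The query name doubles as the haplotype label (one assembly contig set
    per haplotype), matching how per-haplotype PAFs are produced.
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < min_columns:
                raise PolybenchError(f"{path}:{lineno}: PAF line has <{min_columns} columns")
            try:
                blocks.append(
                    AlignmentBlock(
                        haplotype_id=fields[0].split("_")[0],
                        chrom=fields[5],
                        ref_start=int(fields[7]),
                        ref_end=int(fields[8]),
                        query_name=fields[0],
                        mapq=int(fields[11]),
                    )
                )
            except (ValueError, ContractError) as exc:
                raise PolybenchError(f"{path}:{lineno}: bad PAF line: {exc}") from exc
    return blocks


def write_paf(
    blocks: Sequence[AlignmentBlock], path: str, chrom_lengths: Mapping[str, int]
) -> None:
    """Write blocks as minimal valid PAF (query side synthesized)."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        b.query_name or b.haplotype_id,
                        b.length,
                        0,
                        b.length,
                        "+",
                        b.chrom,
                        chrom_lengths[b.chrom],
                        b.ref_start,
                        b.ref_end,
                        b.length,
                        b.length,
                        b.mapq,
                    )
                )
                + "\n"
            )
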