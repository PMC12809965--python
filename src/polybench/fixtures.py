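"""Deterministic synthetic benchmark generator.

This module manufactures every input the rest of the package consumes —
reference FASTA, per-haplotype variant sets, diploid truth samples with
confident BEDs, assembly alignment blocks with presence/absence defects,
read placements, and corrupted polyploid callsets — together with a
bookkeeping ledger that predicts, exactly, what every downstream
evaluation must report.  The generator emulates the structure of a
polyploid benchmarking experiment (trio-style diploid truth samples merged
into tetraploid/hexaploid truth sets; callers that miss sites, call
spurious sites, and mis-assign allelic dosage) without simulating reads
at the base level.

Everything is driven by a single :class:`FixtureSpec`; the same spec and
seed always produce byte-identical artifacts.

Design notes on exactness: variant sites are sampled on the reference
with pairwise-disjoint *effective spans* — the union of the normalized
footprints of the site record and of every single-ALT sub-record — so no
representation shuffling (per-sample subsetting, normalization on load,
harmonization during merging) can ever fuse two sites or shift one into
its neighbour.  Spurious records are likewise normalized at generation
time and placed clear of all truth footprints, so they can never pair
with a truth record during matching.  These two guarantees make the
ledger's TP/FP/FN predictions exact rather than approximate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace as dc_replace
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ContractError
from .reference import DictReference
from .regions import AlignmentBlock, RegionSet, write_bed, write_paf
from .truth import MergedTruth, TruthSample, merge_truth
from .variants import (
    Genotype,
    VariantRecord,
    genotype_from_dosages,
    normalize,
    sort_records,
    write_vcf,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

_CLASS_DOSAGE = {
    "simplex": 1,
    "duplex": 2,
    "triplex": 3,
    "quadruplex": 4,
    "quintuplex": 5,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic benchmark.

    Rates are per-base probabilities on the reference; corruption rates
    are per-site probabilities on the merged truth.  Defaults describe a
    tetraploid experiment on a 1 Mb toy chromosome with human-like
    small-variant density (~1.2 variant sites per kb), which yields on
    the order of 1,100 truth sites — dense enough that count recovery is
    a meaningful test, small enough to run in seconds.
    """

    seed: int = 0
    n_chrom: int = 1
    chrom_len: int = 1_000_000
    n_haplotypes: int = 4
    snv_rate: float = 1.0e-3
    indel_rate: float = 2.0e-4
    indel_len_geom_p: float = 0.6
    max_indel_len: int = 10
    multi_allelic_prob: float = 0.02
    repeat_fraction: float = 0.0
    pav_events: int = 0
    pav_len_min: int = 500
    pav_len_max: int = 5000
    fn_rate: float = 0.02
    fp_rate: float = 0.03
    dosage_err_rate: float = 0.10
    spurious_indel_frac: float = 0.5
    spurious_class: str = "simplex"
    allow_dosage_to_zero: bool = False
    margin: int = 500
    read_length: int = 5000
    n_reads: int = 2000

    def __post_init__(self):
        for name in ("snv_rate", "indel_rate", "fn_rate", "fp_rate", "dosage_err_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ContractError(f"{name}={v} outside [0,1]")
        if self.n_haplotypes % 2 or self.n_haplotypes < 2:
            raise ContractError("n_haplotypes must be even and >= 2")
        if self.spurious_class not in _CLASS_DOSAGE:
            raise ContractError(f"unknown spurious_class {self.spurious_class!r}")

    @property
    def ploidy(self) -> int:
        return self.n_haplotypes

    @property
    def n_samples(self) -> int:
        return self.n_haplotypes // 2


@dataclass
class Site:
    """One truth variant site with per-haplotype allele assignment."""

    record: VariantRecord  # normalized skeleton, genotype=None
    hap_alleles: tuple[int, ...]  # allele index per haplotype (0 = REF)
    span: tuple[int, int]  # effective span (see module docstring)

    def dosage(self, alt_index: int) -> int:
        return self.hap_alleles.count(alt_index)

    def dosage_map(self) -> dict[str, int]:
        return {
            alt: self.dosage(i)
            for i, alt in enumerate(self.record.alts, start=1)
            if self.dosage(i) > 0
        }


@dataclass
class PavEvent:
    """One alignment defect: a duplicated or missing block segment."""

    haplotype: int
    chrom: str
    start: int
    end: int
    kind: str  # 'gap' (reference-only segment) or 'dup' (sample repeat)


@dataclass
class Bookkeeping:
    """Per-site ledger of injected corruption with exact count predictions."""

    n_truth: int
    ploidy: int
    dropped: list[str] = field(default_factory=list)
    shifted: list[dict] = field(default_factory=list)  # site/alt/old/new
    zeroed: list[str] = field(default_factory=list)
    spurious: list[dict] = field(default_factory=list)  # site/kind/class

    def predicted_counts(self, mode: str) -> dict[str, int]:
        n_drop = len(self.dropped)
        n_zero = len(self.zeroed)
        n_shift = len(self.shifted)
        n_sp = len(self.spurious)
        if mode == "detection":
            return {
                "TP": self.n_truth - n_drop - n_zero,
                "FP": n_sp,
                "FN": n_drop + n_zero,
            }
        if mode == "genotyping":
            return {
                "TP": self.n_truth - n_drop - n_zero - n_shift,
                "FP": n_sp + n_shift,
                "FN": n_drop + n_zero + n_shift,
            }
        raise ContractError(f"unknown mode {mode!r}")

    def to_json_dict(self) -> dict:
        return {
            "n_truth": self.n_truth,
            "ploidy": self.ploidy,
            "dropped": self.dropped,
            "shifted": self.shifted,
            "zeroed": self.zeroed,
            "spurious": self.spurious,
            "predicted": {m: self.predicted_counts(m) for m in ("detection", "genotyping")},
        }


@dataclass
class Fixture:
    spec: FixtureSpec
    reference: DictReference
    sites: list[Site]
    samples: list[TruthSample]
    confident: RegionSet
    blocks: list[AlignmentBlock]
    pav: list[PavEvent]
    expected_confidence: RegionSet
    repeat_tracts: RegionSet

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.reference.chrom_length(c) for c in self.reference.chrom_names()}

    def haplotype_sequence(self, hap: int) -> dict[str, str]:
        """Spell haplotype ``hap`` by applying its alleles to the reference."""
        out = {}
        for chrom in self.reference.chrom_names():
            seq = self.reference.sequence(chrom)
            pieces: list[str] = []
            cursor = 0
            for site in self.sites:
                if site.record.chrom != chrom:
                    continue
                allele_idx = site.hap_alleles[hap]
                if allele_idx == 0:
                    continue
                r = site.record
                pieces.append(seq[cursor : r.start0])
                pieces.append(r.alts[allele_idx - 1])
                cursor = r.end0
            pieces.append(seq[cursor:])
            out[chrom] = "".join(pieces)
        return out


# ---------------------------------------------------------------------------
# reference and site generation


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def gen_reference(spec: FixtureSpec) -> tuple[DictReference, RegionSet]:
    """Uniform-random ACGT reference; optional tandem-repeat tracts.

    Returns the reference and a RegionSet of inserted repeat tracts
    (empty when ``repeat_fraction`` is 0).  Repeat tracts exercise
    normalization shifting: indels landing in them are ambiguous until
    left-aligned.
    """
    seqs: dict[str, str] = {}
    tracts: dict[str, list[tuple[int, int]]] = {}
    for ci in range(spec.n_chrom):
        rng = np.random.default_rng([spec.seed, 11, ci])
        arr = _BASES[rng.integers(0, 4, size=spec.chrom_len)]
        chrom = _chrom_name(ci)
        if spec.repeat_fraction > 0:
            tract_len = 60
            n_tracts = max(1, int(spec.chrom_len * spec.repeat_fraction / tract_len))
            starts = rng.integers(0, spec.chrom_len - tract_len, size=n_tracts)
            for s in sorted(set(int(x) for x in starts)):
                unit_len = int(rng.integers(1, 5))
                unit = _BASES[rng.integers(0, 4, size=unit_len)]
                reps = np.tile(unit, tract_len // unit_len + 1)[:tract_len]
                arr[s : s + tract_len] = reps
                tracts.setdefault(chrom, []).append((s, s + tract_len))
        seqs[chrom] = arr.tobytes().decode()
    return DictReference(seqs), RegionSet(tracts)


def _carrier_count(rng: np.random.Generator, n_hap: int) -> int:
    """Neutral-ish dosage spectrum: P(d) proportional to 1/d."""
    weights = np.array([1.0 / d for d in range(1, n_hap + 1)])
    weights /= weights.sum()
    return int(rng.choice(np.arange(1, n_hap + 1), p=weights))


def _effective_span(record: VariantRecord, reference) -> tuple[int, int]:
    """Union of normalized footprints of the record and every ALT subset."""
    start, end = record.start0, record.end0
    for alt in record.alts:
        sub = normalize(
            VariantRecord(record.chrom, record.pos, record.ref, (alt,)), reference
        )
        start = min(start, sub.start0)
        end = max(end, sub.end0)
    return start, end


def gen_sites(spec: FixtureSpec, reference: DictReference) -> list[Site]:
    """Sample truth variant sites with disjoint effective spans."""
    sites: list[Site] = []
    total_rate = spec.snv_rate + spec.indel_rate
    for ci, chrom in enumerate(reference.chrom_names()):
        rng = np.random.default_rng([spec.seed, 23, ci])
        L = reference.chrom_length(chrom)
        lo = spec.margin
        hi = L - spec.margin - spec.max_indel_len - 2
        if hi <= lo:
            continue
        n_cand = rng.binomial(hi - lo, total_rate)
        positions = np.sort(rng.choice(np.arange(lo, hi), size=n_cand, replace=False))
        prev_span_end = -1
        for p in positions:
            p = int(p)
            is_indel = rng.random() < spec.indel_rate / total_rate
            ref_base = reference.fetch(chrom, p, p + 1)
            if is_indel:
                length = min(int(rng.geometric(spec.indel_len_geom_p)), spec.max_indel_len)
                if rng.random() < 0.5:  # insertion
                    ins = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
                    ref, alts = ref_base, (ref_base + ins,)
                else:  # deletion
                    ref = reference.fetch(chrom, p, p + 1 + length)
                    alts = (ref_base,)
            else:
                others = [b for b in "ACGT" if b != ref_base]
                alt = others[int(rng.integers(0, 3))]
                if rng.random() < spec.multi_allelic_prob:
                    second = [b for b in others if b != alt][int(rng.integers(0, 2))]
                    alts = tuple(sorted((alt, second)))
                else:
                    alts = (alt,)
                ref = ref_base
            try:
                record = normalize(VariantRecord(chrom, p + 1, ref, alts), reference)
            except ContractError:
                continue  # e.g. sampled alt equal to ref after context; skip
            span = _effective_span(record, reference)
            if span[0] <= prev_span_end or span[0] < spec.margin or span[1] > L - spec.margin:
                continue
            n_hap = spec.n_haplotypes
            d = _carrier_count(rng, n_hap)
            carriers = rng.choice(n_hap, size=d, replace=False)
            hap_alleles = [0] * n_hap
            if len(record.alts) == 2 and d >= 2:
                # split carriers across the two ALT alleles
                split = 1 + int(rng.integers(0, d - 1))
                for i, h in enumerate(carriers):
                    hap_alleles[int(h)] = 1 if i < split else 2
            else:
                record = dc_replace(record, alts=record.alts[:1])
                for h in carriers:
                    hap_alleles[int(h)] = 1
            sites.append(Site(record=record, hap_alleles=tuple(hap_alleles), span=span))
            prev_span_end = span[1]
    return sites


def _sample_records(
    sites: Sequence[Site], sample_index: int
) -> list[VariantRecord]:
    """Diploid truth records for sample k (haplotypes 2k and 2k+1)."""
    h0, h1 = 2 * sample_index, 2 * sample_index + 1
    records: list[VariantRecord] = []
    for site in sites:
        a0, a1 = site.hap_alleles[h0], site.hap_alleles[h1]
        if a0 == 0 and a1 == 0:
            continue
        carried = sorted({a for a in (a0, a1) if a > 0})
        alts = tuple(site.record.alts[i - 1] for i in carried)
        remap = {site_idx: local for local, site_idx in enumerate(carried, start=1)}
        gt = Genotype((remap.get(a0, 0), remap.get(a1, 0)))
        records.append(
            VariantRecord(
                chrom=site.record.chrom,
                pos=site.record.pos,
                ref=site.record.ref,
                alts=alts,
                genotype=gt,
            )
        )
    return sort_records(records)


def gen_alignment_blocks(
    spec: FixtureSpec, reference: DictReference
) -> tuple[list[AlignmentBlock], list[PavEvent], RegionSet]:
    """Per-haplotype alignment blocks with PAV-like defects.

    The default is one full-length block per haplotype per chromosome
    (confidence = whole chromosome).  Each PAV event either removes a
    segment from one haplotype's block (a reference-only segment: coverage
    gap) or adds a duplicated block over a segment (a sample-side repeat:
    coverage 2).  Events are pairwise disjoint, so the expected confidence
    region is exactly the chromosome minus the union of event intervals.
    """
    rng = np.random.default_rng([spec.seed, 37])
    chroms = reference.chrom_names()
    events: list[PavEvent] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    while len(events) < spec.pav_events and attempts < 100 * max(1, spec.pav_events):
        attempts += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        L = reference.chrom_length(chrom)
        length = int(rng.integers(spec.pav_len_min, spec.pav_len_max + 1))
        if L <= 2 * length:
            continue
        start = int(rng.integers(length, L - 2 * length))
        end = start + length
        if any(s < end and start < e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        events.append(
            PavEvent(
                haplotype=int(rng.integers(0, spec.n_haplotypes)),
                chrom=chrom,
                start=start,
                end=end,
                kind="gap" if rng.random() < 0.5 else "dup",
            )
        )

    blocks: list[AlignmentBlock] = []
    for h in range(spec.n_haplotypes):
        hap_id = f"hap{h}"
        for chrom in chroms:
            L = reference.chrom_length(chrom)
            segments = [(0, L)]
            for ev in events:
                if ev.haplotype != h or ev.chrom != chrom or ev.kind != "gap":
                    continue
                new_segments = []
                for s, e in segments:
                    if ev.start >= e or ev.end <= s:
                        new_segments.append((s, e))
                        continue
                    if s < ev.start:
                        new_segments.append((s, ev.start))
                    if ev.end < e:
                        new_segments.append((ev.end, e))
                segments = new_segments
            for i, (s, e) in enumerate(segments):
                blocks.append(
                    AlignmentBlock(
                        haplotype_id=hap_id,
                        chrom=chrom,
                        ref_start=s,
                        ref_end=e,
                        query_name=f"{hap_id}_{chrom}c{i}",
                        mapq=60,
                    )
                )
            for ev in events:
                if ev.haplotype == h and ev.chrom == chrom and ev.kind == "dup":
                    blocks.append(
                        AlignmentBlock(
                            haplotype_id=hap_id,
                            chrom=chrom,
                            ref_start=ev.start,
                            ref_end=ev.end,
                            query_name=f"{hap_id}_{chrom}dup",
                            mapq=60,
                        )
                    )

    whole = RegionSet({c: [(0, reference.chrom_length(c))] for c in chroms})
    holes = RegionSet({})
    if events:
        holes = RegionSet(
            {
                c: [(ev.start, ev.end) for ev in events if ev.chrom == c]
                for c in chroms
                if any(ev.chrom == c for ev in events)
            }
        )
    return blocks, events, whole.subtract(holes)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build the complete in-memory fixture for one spec."""
    reference, tracts = gen_reference(spec)
    sites = gen_sites(spec, reference)
    confident = RegionSet(
        {
            c: [(spec.margin, reference.chrom_length(c) - spec.margin)]
            for c in reference.chrom_names()
        }
    )
    samples = [
        TruthSample(
            sample_id=f"S{k}",
            confident=confident,
            ploidy=2,
            records=_sample_records(sites, k),
        )
        for k in range(spec.n_samples)
    ]
    blocks, pav, expected_conf = gen_alignment_blocks(spec, reference)
    return Fixture(
        spec=spec,
        reference=reference,
        sites=sites,
        samples=samples,
        confident=confident,
        blocks=blocks,
        pav=pav,
        expected_confidence=expected_conf,
        repeat_tracts=tracts,
    )


# ---------------------------------------------------------------------------
# callset corruption


def _round_half(x: float) -> float:
    """Round to the nearest 0.5 (exactly representable in float32 VCF INFO)."""
    return round(x * 2) / 2


def _annotations(rng: np.random.Generator) -> dict[str, float]:
    return {
        "QUAL": _round_half(float(rng.uniform(30, 2000))),
        "QD": _round_half(float(rng.uniform(2, 40))),
        "MQM": _round_half(float(rng.uniform(40, 60))),
        "DP": float(int(rng.integers(20, 120))),
    }


def corrupt_callset(
    truth: MergedTruth,
    reference,
    spec: FixtureSpec,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantRecord], Bookkeeping]:
    """Derive a caller-like query VCF from the merged truth.

    Each truth site is independently dropped (missed call) with
    ``fn_rate``, else dosage-shifted with ``dosage_err_rate`` (one ALT
    allele moves +-1 copy, staying in [1, ploidy-1] so the site is still
    detected; with ``allow_dosage_to_zero`` a biallelic simplex site may
    instead collapse to hom-ref, the diploid-model failure mode on
    polyploid data).  Spurious records are added at ``fp_rate`` x truth
    count, placed inside the confidence regions but clear of every truth
    footprint, with the configured type mix and genotype class.  The
    returned Bookkeeping predicts every evaluation count exactly.
    """
    if rng is None:
        rng = np.random.default_rng([spec.seed, 53])
    ploidy = truth.ploidy
    book = Bookkeeping(n_truth=len(truth.records), ploidy=ploidy)
    query: list[VariantRecord] = []

    for rec in truth.records:
        key = f"{rec.chrom}:{rec.pos}"
        if rng.random() < spec.fn_rate:
            book.dropped.append(key)
            continue
        gt = rec.genotype
        assert gt is not None
        new_rec = VariantRecord(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alts=rec.alts,
            genotype=gt,
            info=_annotations(rng),
        )
        if rng.random() < spec.dosage_err_rate:
            alt_indices = gt.alt_indices()
            idx = int(alt_indices[int(rng.integers(0, len(alt_indices)))])
            d = gt.dosage(idx)
            dosages = [gt.dosage(i) for i in range(1, len(rec.alts) + 1)]
            ref_dosage = ploidy - sum(dosages)
            if (
                spec.allow_dosage_to_zero
                and len(alt_indices) == 1
                and d == 1
                and rng.random() < 0.5
            ):
                hom_ref = Genotype(tuple([0] * ploidy))
                query.append(dc_replace(new_rec, genotype=hom_ref))
                book.zeroed.append(key)
                continue
            candidates = []
            if d - 1 >= 1:
                candidates.append(d - 1)
            if d + 1 <= ploidy - 1 and ref_dosage >= 1:
                candidates.append(d + 1)
            if candidates:
                new_d = int(candidates[int(rng.integers(0, len(candidates)))])
                dosages[idx - 1] = new_d
                shifted_gt = genotype_from_dosages(dosages, ploidy)
                query.append(dc_replace(new_rec, genotype=shifted_gt))
                book.shifted.append(
                    {"site": key, "alt": rec.alts[idx - 1], "old": d, "new": new_d}
                )
                continue
        query.append(new_rec)

    # spurious records: clear of every truth effective footprint
    n_spurious = int(round(spec.fp_rate * len(truth.records)))
    blocked: dict[str, list[tuple[int, int]]] = {}
    for rec in truth.records:
        blocked.setdefault(rec.chrom, []).append((rec.start0 - 1, rec.end0 + 1))
    blocked_rs = RegionSet({c: v for c, v in blocked.items()})
    conf = truth.regions
    chroms = conf.chroms()
    lengths = np.array(
        [sum(e - s for s, e in conf.intervals(c)) for c in chroms], dtype=float
    )
    if n_spurious and (not chroms or lengths.sum() == 0):
        raise ContractError("cannot place spurious records: empty confidence regions")
    probs = lengths / lengths.sum() if len(chroms) else None
    dosage_cls = _CLASS_DOSAGE[spec.spurious_class]
    if dosage_cls > ploidy - 1:
        raise ContractError(
            f"spurious_class {spec.spurious_class} impossible at ploidy {ploidy}"
        )
    added = 0
    attempts = 0
    new_blocked: list[tuple[str, int, int]] = []
    while added < n_spurious and attempts < 200 * max(1, n_spurious):
        attempts += 1
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        ivs = conf.intervals(chrom)
        weights = np.array([e - s for s, e in ivs], dtype=float)
        s, e = ivs[int(rng.choice(len(ivs), p=weights / weights.sum()))]
        if e - s < 20:
            continue
        p = int(rng.integers(s + 2, e - 12))
        ref_base = _fetch(reference, chrom, p, p + 1)
        if rng.random() < spec.spurious_indel_frac:
            if rng.random() < 0.5:
                ins = "ACGT"[int(rng.integers(0, 4))]
                ref, alt = ref_base, ref_base + ins
            else:
                ref, alt = _fetch(reference, chrom, p, p + 2), ref_base
        else:
            others = [b for b in "ACGT" if b != ref_base]
            ref, alt = ref_base, others[int(rng.integers(0, 3))]
        try:
            cand = normalize(
                VariantRecord(
                    chrom,
                    p + 1,
                    ref,
                    (alt,),
                    genotype=genotype_from_dosages([dosage_cls], ploidy),
                    info=_annotations(rng),
                ),
                reference,
            )
        except ContractError:
            continue
        lo, hi = cand.start0 - 1, cand.end0 + 1
        if blocked_rs.overlap_length(chrom, lo, hi) > 0:
            continue
        if any(c == chrom and s0 < hi and lo < e0 for c, s0, e0 in new_blocked):
            continue
        if not conf.contains_interval(chrom, cand.start0, cand.end0):
            continue
        new_blocked.append((chrom, lo, hi))
        query.append(cand)
        kind = (
            "SNV"
            if len(cand.ref) == len(cand.alts[0])
            else ("INS" if len(cand.alts[0]) > len(cand.ref) else "DEL")
        )
        book.spurious.append(
            {
                "site": f"{cand.chrom}:{cand.pos}",
                "kind": kind,
                "class": spec.spurious_class,
            }
        )
        added += 1
    if added < n_spurious:
        raise ContractError(
            f"placed only {added}/{n_spurious} spurious records; fixture too dense"
        )
    return sort_records(query), book


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    from .reference import as_reference

    return as_reference(reference).fetch(chrom, start, end)


# ---------------------------------------------------------------------------
# read placements


@dataclass
class PlacementLedger:
    read_id: str
    overlap: int
    read_length: int
    keep: bool  # under the strict >1/2 rule


def gen_read_placements(
    spec: FixtureSpec,
    reliable: RegionSet,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator | None = None,
):
    """Uniformly placed reads with exact per-read overlap bookkeeping."""
    from .filters import ReadPlacement

    if rng is None:
        rng = np.random.default_rng([spec.seed, 71])
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    reads, ledger = [], []
    for i in range(spec.n_reads):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        L = chrom_lengths[chrom]
        rl = min(spec.read_length, L)
        start = int(rng.integers(0, L - rl + 1))
        placement = ReadPlacement(
            read_id=f"read{i}",
            chrom=chrom,
            aligned_ref_intervals=((start, start + rl),),
            read_length=rl,
        )
        overlap = reliable.overlap_length(chrom, start, start + rl)
        reads.append(placement)
        ledger.append(
            PlacementLedger(
                read_id=placement.read_id,
                overlap=overlap,
                read_length=rl,
                keep=Fraction(overlap, rl) > Fraction(1, 2),
            )
        )
    return reads, ledger


# ---------------------------------------------------------------------------
# pipeline and on-disk artifacts


@dataclass
class PipelineResult:
    fixture: Fixture
    merged: MergedTruth
    query: list[VariantRecord]
    bookkeeping: Bookkeeping


def run_pipeline(spec: FixtureSpec) -> PipelineResult:
    """generate -> merge_truth -> corrupt: the full truth-to-query chain.

    With a single diploid sample (n_haplotypes=2) there is nothing to
    merge: the sample's normalized records inside its confident regions
    are the truth set directly.
    """
    fixture = generate_fixture(spec)
    if len(fixture.samples) >= 2:
        merged = merge_truth(fixture.samples, fixture.reference)
    else:
        from .regions import mask_vcf
        from .variants import check_sorted

        sample = fixture.samples[0]
        recs = [normalize(r, fixture.reference) for r in sample.records or []]
        recs = sort_records(recs)
        check_sorted(recs, "truth")
        merged = MergedTruth(
            records=list(mask_vcf(recs, sample.confident)),
            regions=sample.confident,
            ploidy=sample.ploidy,
        )
    query, book = corrupt_callset(merged, fixture.reference, spec)
    return PipelineResult(fixture=fixture, merged=merged, query=query, bookkeeping=book)


def _write_fasta(path: Path, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate(spec: FixtureSpec, outdir: str | Path) -> dict[str, str]:
    """Write the full fixture to disk; returns artifact name -> path.

    Artifacts: ref.fa, hapN.fa, sampleK.vcf/.bed, blocks.paf, truth.vcf,
    conf.bed, query.vcf, reads.tsv, ledger.json.  Same spec, same bytes.
    """
    from .filters import write_placements_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_pipeline(spec)
    fixture = result.fixture
    contigs = [(c, fixture.reference.chrom_length(c)) for c in fixture.reference.chrom_names()]
    paths: dict[str, str] = {}

    def reg(name: str, path: Path) -> Path:
        paths[name] = str(path)
        return path

    _write_fasta(reg("ref", outdir / "ref.fa"), {c: fixture.reference.sequence(c) for c, _ in contigs})
    for h in range(spec.n_haplotypes):
        _write_fasta(reg(f"hap{h}", outdir / f"hap{h}.fa"), fixture.haplotype_sequence(h))
    for k, sample in enumerate(fixture.samples):
        write_vcf(
            sample.records or [],
            str(reg(f"sample{k}_vcf", outdir / f"sample{k}.vcf")),
            ploidy=2,
            contigs=contigs,
            sample_name=sample.sample_id,
        )
        write_bed(sample.confident, str(reg(f"sample{k}_bed", outdir / f"sample{k}.bed")))
    write_paf(fixture.blocks, str(reg("paf", outdir / "blocks.paf")), dict(contigs))
    write_vcf(
        result.merged.records,
        str(reg("truth", outdir / "truth.vcf")),
        ploidy=result.merged.ploidy,
        contigs=contigs,
        sample_name="TRUTH",
    )
    write_bed(result.merged.regions, str(reg("conf", outdir / "conf.bed")))
    write_vcf(
        result.query,
        str(reg("query", outdir / "query.vcf")),
        ploidy=result.merged.ploidy,
        contigs=contigs,
        sample_name="QUERY",
    )
    reads, read_ledger = gen_read_placements(
        spec, fixture.expected_confidence, fixture.chrom_lengths()
    )
    write_placements_tsv(reads, str(reg("reads", outdir / "reads.tsv")))
    if not fixture.repeat_tracts.is_empty():
        write_bed(fixture.repeat_tracts, str(reg("repeats", outdir / "repeats.bed")))

    ledger = {
        "spec": asdict(spec),
        "n_sites": len(fixture.sites),
        "n_merged_truth": len(result.merged.records),
        "corruption": result.bookkeeping.to_json_dict(),
        "pav_events": [asdict(ev) for ev in fixture.pav],
        "reads": [asdict(r) for r in read_ledger],
    }
    with open(reg("ledger", outdir / "ledger.json"), "w") as fh:
        json.dump(ledger, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
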