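"""Synthetic polyploid truth-set construction.

A polyploid truth set is built by merging per-sample diploid truth VCFs:
the variant *sites* are unioned, the confident regions are intersected,
and at every site the output genotype is the dosage-preserving sum over
samples — a sample with no record at a site inside its confident regions
asserts hom-ref there and contributes dosage 0.  Merging two diploids
yields a tetraploid truth set; adding a third yields a hexaploid.

Because different samples may spell overlapping variants differently,
co-located records are first *harmonized*: REF alleles are right-padded
with reference bases to the longest footprint of the group and every ALT
is re-spelled against that unified REF, so dosages can be summed per
distinct ALT sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .errors import ConsistencyError, ContractError
from .reference import as_reference
from .regions import RegionSet, intersect_all, mask_vcf
from .variants import (
    Genotype,
    VariantRecord,
    check_sorted,
    genotype_from_dosages,
    normalize,
    read_vcf,
)

logger = logging.getLogger(__name__)


@dataclass
class TruthSample:
    """One input truth sample: diploid VCF + matching confident regions.

    ``records`` may be supplied directly (in-memory pipelines, fixtures);
    otherwise they are read from ``vcf`` on demand.
    """

    sample_id: str
    confident: RegionSet
    ploidy: int = 2
    vcf: str | None = None
    records: list[VariantRecord] | None = None

    def load_records(self) -> list[VariantRecord]:
        if self.records is not None:
            return self.records
        if self.vcf is None:
            raise ContractError(f"sample {self.sample_id}: neither records nor vcf given")
        return list(read_vcf(self.vcf, expected_ploidy=None))


@dataclass
class MergedTruth:
    """Merged polyploid truth: records at ploidy_out inside joint regions."""

    records: list[VariantRecord]
    regions: RegionSet
    ploidy: int
    n_dropped_hom_ref: int = 0


def harmonize_site(
    records: Sequence[VariantRecord], reference
) -> tuple[int, str, list[str]]:
    """Unify co-located records onto one padded REF.

    Returns ``(pos, unified_ref, respelled_alts_per_record)`` where
    ``respelled_alts_per_record[i][j]`` is record i's ALT j re-spelled
    against the unified REF.  Records must share a chromosome and have
    pairwise-connected overlapping footprints.
    """
    ref_acc = as_reference(reference)
    if not records:
        raise ContractError("harmonize_site requires at least one record")
    chroms = {r.chrom for r in records}
    if len(chroms) > 1:
        raise ContractError(f"records span multiple chromosomes: {sorted(chroms)}")
    chrom = records[0].chrom
    start = min(r.start0 for r in records)
    end = max(r.end0 for r in records)
    if len(records) > 1:
        # connectivity check: sorted by start, each must overlap the running span
        cur_end = None
        for r in sorted(records, key=lambda r: r.start0):
            if cur_end is not None and r.start0 >= cur_end:
                raise ContractError(
                    f"non-overlapping footprints in harmonize group at {chrom}:{r.pos}"
                )
            cur_end = max(cur_end or 0, r.end0)
    unified_ref = ref_acc.fetch(chrom, start, end)
    respelled: list[list[str]] = []
    for r in records:
        off = r.start0 - start
        if unified_ref[off : off + len(r.ref)] != r.ref:
            raise ConsistencyError(
                f"REF conflict during harmonization at {chrom}:{r.pos}"
            )
        respelled.append(
            [
                unified_ref[:off] + alt + unified_ref[off + len(r.ref) :]
                for alt in r.alts
            ]
        )
    return start + 1, unified_ref, respelled


def _group_overlapping(
    per_sample: list[list[VariantRecord]],
) -> list[list[tuple[int, VariantRecord]]]:
    """Group records (tagged with sample index) into overlap components."""
    tagged = [
        (rec, si) for si, recs in enumerate(per_sample) for rec in recs
    ]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start0, t[0].end0))
    groups: list[list[tuple[int, VariantRecord]]] = []
    cur: list[tuple[int, VariantRecord]] = []
    cur_chrom, cur_end = None, -1
    for rec, si in tagged:
        if cur and rec.chrom == cur_chrom and rec.start0 < cur_end:
            cur.append((si, rec))
            cur_end = max(cur_end, rec.end0)
        else:
            if cur:
                groups.append(cur)
            cur = [(si, rec)]
            cur_chrom, cur_end = rec.chrom, rec.end0
    if cur:
        groups.append(cur)
    return groups


def merge_truth(
    samples: Sequence[TruthSample],
    reference,
    normalize_on_load: bool = True,
) -> MergedTruth:
    """Union per-sample truth sites into one polyploid truth set.

    Output ploidy is the sum of input ploidies.  Confident regions are
    intersected; records whose footprint leaves the intersection are
    dropped before merging (absence inside the intersection then always
    asserts hom-ref).  At each harmonized site the merged genotype carries,
    for every distinct ALT spelling, the summed dosage over samples;
    ALTs are ordered lexicographically.  Sites that come out pure hom-ref
    are dropped and counted.
    """
    if len(samples) < 2:
        raise ContractError("merge_truth requires at least two samples")
    ref_acc = as_reference(reference)
    regions = intersect_all([s.confident for s in samples])
    ploidy_out = sum(s.ploidy for s in samples)

    per_sample: list[list[VariantRecord]] = []
    for s in samples:
        recs = s.load_records()
        check_sorted(recs, f"sample {s.sample_id}")
        if normalize_on_load:
            recs = [normalize(r, ref_acc) for r in recs]
            recs.sort(key=VariantRecord.sort_key)
        recs = list(mask_vcf(recs, regions))
        per_sample.append(recs)

    merged: list[VariantRecord] = []
    n_hom_ref = 0
    for group in _group_overlapping(per_sample):
        sample_idx = [si for si, _ in group]
        recs = [rec for _, rec in group]
        if len(set(sample_idx)) != len(sample_idx):
            dup = samples[
                next(si for si in sample_idx if sample_idx.count(si) > 1)
            ].sample_id
            first = recs[0]
            raise ConsistencyError(
                f"sample {dup} has conflicting overlapping records near "
                f"{first.chrom}:{first.pos}"
            )
        pos, unified_ref, respelled = harmonize_site(recs, ref_acc)

        # summed dosage per distinct ALT spelling (spellings equal to the
        # unified REF are hom-ref contributions and add nothing)
        dosage: dict[str, int] = {}
        for (si, rec), alts in zip(group, respelled):
            gt = rec.genotype
            if gt is None:
                continue  # missing genotype contributes hom-ref
            for alt_idx in gt.alt_indices():
                spelled = alts[alt_idx - 1]
                if spelled == unified_ref:
                    continue
                dosage[spelled] = dosage.get(spelled, 0) + gt.dosage(alt_idx)
        if not dosage:
            n_hom_ref += 1
            continue
        alts_sorted = sorted(dosage)
        record = VariantRecord(
            chrom=recs[0].chrom,
            pos=pos,
            ref=unified_ref,
            alts=tuple(alts_sorted),
            genotype=genotype_from_dosages(
                [dosage[a] for a in alts_sorted], ploidy_out
            ),
        )
        merged.append(normalize(record, ref_acc))

    merged.sort(key=VariantRecord.sort_key)
    if n_hom_ref:
        logger.info("merge_truth: dropped %d pure hom-ref union sites", n_hom_ref)
    return MergedTruth(
        records=merged, regions=regions, ploidy=ploidy_out, n_dropped_hom_ref=n_hom_ref
    )


def plan_coverage(
    n_samples: int,
    per_sample_depth: float,
    sample_ploidy: int = 2,
) -> dict[str, float]:
    """Coverage arithmetic for pooled-read polyploid designs.

    Pooling ``n_samples`` samples sequenced at ``per_sample_depth`` each
    gives ``total = n * depth`` and ``per-haplotype = total / ploidy_out``
    (e.g. two diploids at 30x pool to 60x total, 15x per haplotype).
    """
    if per_sample_depth <= 0:
        raise ContractError("depth must be positive")
    if n_samples < 1:
        raise ContractError("need at least one sample")
    ploidy_out = n_samples * sample_ploidy
    total = n_samples * per_sample_depth
    return {
        "n_samples": n_samples,
        "ploidy_out": ploidy_out,
        "total_depth": total,
        "per_haplotype_depth": total / ploidy_out,
    }


def coverage_grid(
    n_samples: int, total_depths: Sequence[float], sample_ploidy: int = 2
) -> list[dict[str, float]]:
    """One plan row per requested *total* coverage (e.g. 10/30/50/70/90x)."""
    return [
        plan_coverage(n_samples, d / n_samples, sample_ploidy) for d in total_depths
    ]
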