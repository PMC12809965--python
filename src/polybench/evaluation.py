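"""Detection- and genotyping-mode evaluation of polyploid callsets.

Two comparison semantics are computed from one site-level matching:

* **detection** — a truth/query pair is a true positive iff the two
  genotypes share at least one ALT allele (dosage >= 1 on both sides)
  after harmonization; the allelic copy number is ignored.
* **genotyping** — a pair is a true positive iff the full genotype
  multisets (allele composition *and* dosage) are identical.

A matched pair failing its mode's criterion counts as FP and FN
simultaneously (a wrong-allele or wrong-genotype site), unmatched truth
records are FN, and unmatched query records asserting any ALT are FP —
the accounting convention of haplotype-comparison benchmarking tools.
Matching itself is site-level: records whose normalized footprints overlap
(and whose REFs are consistent with the reference) are paired 1:1.
Detection >= genotyping therefore holds for precision and recall on any
input, and the gap isolates dosage/allele assignment errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, PloidyError
from .regions import RegionSet, mask_vcf
from .truth import harmonize_site
from .variants import (
    GenotypeClass,
    VariantRecord,
    check_sorted,
    classify_genotype,
    record_kind,
    sort_records,
)

MODES = ("detection", "genotyping")
ALL = "all"


@dataclass
class MatchResult:
    """1:1 site-level pairing of truth and query records."""

    pairs: list[tuple[VariantRecord, VariantRecord]]
    truth_only: list[VariantRecord]
    query_only: list[VariantRecord]


@dataclass
class Counts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def as_dict(self) -> dict[str, int]:
        return {"TP": self.tp, "FP": self.fp, "FN": self.fn}


@dataclass
class EvalReport:
    """Stratified counts and metrics plus the dosage confusion matrix.

    ``cells`` maps (mode, variant type, genotype class, stratum) to
    Counts; every axis includes an aggregate ``"all"`` label.
    ``fp_records`` keeps, per mode, the (record, type, query class) of
    each false-positive half for downstream diagnostics such as the
    simplex FP fraction.
    """

    cells: dict[tuple[str, str, str, str], Counts] = field(default_factory=dict)
    dosage_confusion: np.ndarray | None = None
    fp_records: dict[str, list[tuple[VariantRecord, str, str]]] = field(
        default_factory=lambda: {m: [] for m in MODES}
    )

    def counts(
        self, mode: str, vtype: str = ALL, gclass: str = ALL, stratum: str = ALL
    ) -> Counts:
        return self.cells.get((mode, vtype, gclass, stratum), Counts())

    def metrics_for(
        self, mode: str, vtype: str = ALL, gclass: str = ALL, stratum: str = ALL
    ) -> dict[str, float]:
        return metrics(self.counts(mode, vtype, gclass, stratum).as_dict())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (mode, vtype, gclass, stratum), c in sorted(self.cells.items()):
            m = metrics(c.as_dict())
            rows.append(
                {
                    "mode": mode,
                    "variant_type": vtype,
                    "genotype_class": gclass,
                    "stratum": stratum,
                    "TP": c.tp,
                    "FP": c.fp,
                    "FN": c.fn,
                    **m,
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        out = {"cells": [], "dosage_confusion": None}
        for row in self.to_frame().to_dict(orient="records"):
            out["cells"].append(row)
        if self.dosage_confusion is not None:
            out["dosage_confusion"] = self.dosage_confusion.tolist()
        return out


def metrics(counts: Mapping[str, int]) -> dict[str, float]:
    """Precision/recall/F1 with the 0-when-undefined convention."""
    tp, fp, fn = counts["TP"], counts["FP"], counts["FN"]
    if min(tp, fp, fn) < 0:
        raise ContractError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return {"precision": precision, "recall": recall, "F1": f1}


# ---------------------------------------------------------------------------
# matching


def match_sites(
    truth: Sequence[VariantRecord],
    query: Sequence[VariantRecord],
    regions: RegionSet | None = None,
    reference=None,
) -> MatchResult:
    """Pair truth and query records sharing a normalized locus.

    Records are paired 1:1 when their REF footprints overlap.  Ties (two
    query candidates for one truth record) are broken by nearest start,
    then lexicographically smallest ALT tuple; the loser stays unmatched.
    Inputs must be coordinate-sorted (use :func:`evaluate_callsets` for
    order-insensitive entry).
    """
    check_sorted(truth, "truth")
    check_sorted(query, "query")
    if regions is not None:
        truth = list(mask_vcf(truth, regions))
        query = list(mask_vcf(query, regions))

    by_chrom_q: dict[str, list[VariantRecord]] = {}
    for q in query:
        by_chrom_q.setdefault(q.chrom, []).append(q)

    pairs: list[tuple[VariantRecord, VariantRecord]] = []
    matched_q: set[int] = set()
    truth_only: list[VariantRecord] = []
    for chrom in sorted({t.chrom for t in truth}):
        t_recs = [t for t in truth if t.chrom == chrom]
        q_recs = by_chrom_q.get(chrom, [])
        j = 0
        for t in t_recs:
            while j < len(q_recs) and q_recs[j].end0 <= t.start0:
                j += 1
            candidates = []
            k = j
            while k < len(q_recs) and q_recs[k].start0 < t.end0:
                if id(q_recs[k]) not in matched_q:
                    candidates.append(q_recs[k])
                k += 1
            if not candidates:
                truth_only.append(t)
                continue
            best = min(
                candidates, key=lambda q: (abs(q.start0 - t.start0), q.alts)
            )
            matched_q.add(id(best))
            pairs.append((t, best))
    query_only = [q for q in query if id(q) not in matched_q]
    return MatchResult(pairs=pairs, truth_only=truth_only, query_only=query_only)


def _harmonized_dosages(
    t: VariantRecord, q: VariantRecord, reference
) -> tuple[dict[str, int], dict[str, int]]:
    """Dosage maps (ALT spelling -> copies) on a unified REF for a pair."""
    if (t.pos, t.ref) == (q.pos, q.ref):
        return t.dosage_map(), q.dosage_map()
    if reference is None:
        raise ContractError(
            "reference accessor required to harmonize records with different "
            f"footprints at {t.chrom}:{t.pos}"
        )
    _, unified_ref, (t_alts, q_alts) = harmonize_site([t, q], reference)
    out = []
    for rec, alts in ((t, t_alts), (q, q_alts)):
        dm: dict[str, int] = {}
        gt = rec.genotype
        if gt is not None:
            for idx in gt.alt_indices():
                if alts[idx - 1] != unified_ref:
                    dm[alts[idx - 1]] = dm.get(alts[idx - 1], 0) + gt.dosage(idx)
        out.append(dm)
    return out[0], out[1]


def _split_multiallelic(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    out = []
    for r in records:
        if len(r.alts) == 1:
            out.append(r)
            continue
        for idx, alt in enumerate(r.alts, start=1):
            gt = r.genotype
            new_gt = None
            if gt is not None:
                d = gt.dosage(idx)
                new_gt_alleles = [0] * (gt.ploidy - d) + [1] * d
                from .variants import Genotype

                new_gt = Genotype(tuple(new_gt_alleles))
            out.append(
                VariantRecord(
                    chrom=r.chrom,
                    pos=r.pos,
                    ref=r.ref,
                    alts=(alt,),
                    genotype=new_gt,
                    info=dict(r.info),
                )
            )
    return sort_records(out)


# ---------------------------------------------------------------------------
# evaluation


def _pair_outcome(
    t: VariantRecord, q: VariantRecord, mode: str, reference
) -> str:
    """'TP', 'FPFN' (wrong allele/genotype), or 'FN' (query no-call)."""
    if q.genotype is None:
        return "FN"  # no-call: conservative, truth counts as missed
    q_dm_raw = q.dosage_map()
    if not q_dm_raw:
        return "FN"  # hom-ref query asserts nothing
    t_dm, q_dm = _harmonized_dosages(t, q, reference)
    if mode == "detection":
        shared = set(t_dm) & set(q_dm)
        return "TP" if shared else "FPFN"
    if t.genotype is not None and q.genotype is not None:
        if t.genotype.ploidy != q.genotype.ploidy:
            raise PloidyError(
                f"genotyping mode: ploidy {t.genotype.ploidy} vs "
                f"{q.genotype.ploidy} at {t.chrom}:{t.pos}"
            )
    return "TP" if t_dm == q_dm else "FPFN"


def evaluate(
    match: MatchResult, mode: str, reference=None
) -> dict[str, int]:
    """TP/FP/FN under one mode; see module docstring for the convention."""
    if mode not in MODES:
        raise ContractError(f"unknown mode {mode!r}")
    tp = fp = fn = 0
    for t, q in match.pairs:
        outcome = _pair_outcome(t, q, mode, reference)
        if outcome == "TP":
            tp += 1
        elif outcome == "FPFN":
            fp += 1
            fn += 1
        else:
            fn += 1
    fn += len(match.truth_only)
    for q in match.query_only:
        if q.genotype is not None and q.dosage_map():
            fp += 1
    return {"TP": tp, "FP": fp, "FN": fn}


def dosage_confusion(
    match: MatchResult, ploidy: int, reference=None
) -> np.ndarray:
    """Confusion matrix over (truth dosage, called dosage) per truth ALT.

    Entry [d_t, d_c] counts truth ALT alleles with truth dosage d_t whose
    called dosage in the paired query genotype is d_c; unmatched truth
    sites and alleles absent from the query genotype land in column 0
    (the missed / hom-ref column).
    """
    mat = np.zeros((ploidy + 1, ploidy + 1), dtype=int)
    for t in match.truth_only:
        for _, d in sorted(t.dosage_map().items()):
            mat[d, 0] += 1
    for t, q in match.pairs:
        t_dm, q_dm = _harmonized_dosages(t, q, reference)
        for alt, d in sorted(t_dm.items()):
            mat[d, q_dm.get(alt, 0)] += 1
    return mat


def simplex_fp_fraction(report: EvalReport, vtype: str = "INS") -> float:
    """Share of genotyping-mode FP records of a type called as simplex.

    ``vtype`` may be a concrete kind (SNV/INS/DEL) or ``"indel"`` for
    INS+DEL combined.  Returns 0 when there are no such FPs.
    """
    wanted = {"INS", "DEL"} if vtype.lower() == "indel" else {vtype}
    fps = [
        (rec, kind, gclass)
        for rec, kind, gclass in report.fp_records["genotyping"]
        if kind in wanted
    ]
    if not fps:
        return 0.0
    n_simplex = sum(1 for _, _, gclass in fps if gclass == GenotypeClass.SIMPLEX.value)
    return n_simplex / len(fps)


# ---------------------------------------------------------------------------
# stratified report


def stratify(
    match: MatchResult,
    strata: Mapping[str, RegionSet] | None = None,
    by_type: bool = True,
    by_class: bool = True,
    reference=None,
    ploidy: int | None = None,
) -> EvalReport:
    """Build the full EvalReport from one matching.

    Each outcome record contributes to every applicable cell: the ``all``
    stratum plus each user stratum containing its footprint, its variant
    type (and ``all``), and its genotype class (and ``all``).  TP and FN
    outcomes are classed by the truth record; FP outcomes (wrong sites or
    spurious calls) are classed by the query record and genotype.
    """
    strata = dict(strata or {})
    if ALL in strata:
        raise ContractError("'all' is a reserved stratum label")

    report = EvalReport()

    def strata_for(rec: VariantRecord) -> list[str]:
        labels = [ALL]
        for label, rs in strata.items():
            if rs.contains_interval(rec.chrom, rec.start0, rec.end0):
                labels.append(label)
        return labels

    def add(mode: str, rec: VariantRecord, which: str, use_query_gt: bool):
        kind = record_kind(rec)
        gclass = classify_genotype(rec.genotype).value
        types = [ALL, kind] if by_type else [ALL]
        classes = [ALL, gclass] if by_class else [ALL]
        for stratum in strata_for(rec):
            for vt in types:
                for gc in classes:
                    cell = report.cells.setdefault(
                        (mode, vt, gc, stratum), Counts()
                    )
                    setattr(cell, which, getattr(cell, which) + 1)
        if which == "fp":
            report.fp_records[mode].append((rec, kind, gclass))

    for mode in MODES:
        for t, q in match.pairs:
            outcome = _pair_outcome(t, q, mode, reference)
            if outcome == "TP":
                add(mode, t, "tp", use_query_gt=False)
            elif outcome == "FPFN":
                add(mode, q, "fp", use_query_gt=True)
                add(mode, t, "fn", use_query_gt=False)
            else:
                add(mode, t, "fn", use_query_gt=False)
        for t in match.truth_only:
            add(mode, t, "fn", use_query_gt=False)
        for q in match.query_only:
            if q.genotype is not None and q.dosage_map():
                add(mode, q, "fp", use_query_gt=True)

    if ploidy is not None:
        report.dosage_confusion = dosage_confusion(match, ploidy, reference)
    return report


def evaluate_callsets(
    truth: Iterable[VariantRecord],
    query: Iterable[VariantRecord],
    regions: RegionSet | None = None,
    reference=None,
    strata: Mapping[str, RegionSet] | None = None,
    ploidy: int | None = None,
    split_multiallelic: bool = False,
    normalize_inputs: bool = False,
) -> EvalReport:
    """End-to-end comparison of a query callset against a truth set.

    Sorts inputs canonically (so the report is invariant to input record
    order), optionally normalizes them against the reference, masks both
    to the confidence regions, matches, and returns the stratified report
    including the dosage confusion matrix when ``ploidy`` is given.
    """
    from .variants import normalize as _normalize

    truth = list(truth)
    query = list(query)
    if normalize_inputs:
        if reference is None:
            raise ContractError("normalize_inputs requires a reference")
        truth = [_normalize(r, reference) for r in truth]
        query = [_normalize(r, reference) for r in query]
    truth = sort_records(truth)
    query = sort_records(query)
    if split_multiallelic:
        truth = _split_multiallelic(truth)
        query = _split_multiallelic(query)
    match = match_sites(truth, query, regions=regions, reference=reference)
    return stratify(
        match, strata=strata, reference=reference, ploidy=ploidy
    )
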