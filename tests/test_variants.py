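"""Domain types, classification, normalization, and VCF round-trips."""

import numpy as np
import pytest

from polybench.errors import ConsistencyError, ContractError, PloidyError
from polybench.reference import DictReference
from polybench.variants import (
    Genotype,
    GenotypeClass,
    VariantKind,
    VariantRecord,
    apply_to_sequence,
    classify_genotype,
    classify_variant,
    decompose_mnv,
    normalize,
    read_vcf,
    write_vcf,
)

from conftest import make_record, random_sequence


class TestGenotype:
    def test_multiset_semantics(self):
        gt = Genotype((1, 0, 0, 0))
        assert gt.alleles == (0, 0, 0, 1)  # canonical ascending order
        assert gt.ploidy == 4
        assert gt.dosage(0) == 3 and gt.dosage(1) == 1
        assert str(gt) == "0/0/0/1"

    def test_dosage_sums_to_ploidy(self):
        gt = Genotype((0, 1, 1, 2, 2, 2))
        assert sum(gt.dosage(a) for a in {0, 1, 2}) == gt.ploidy


class TestVariantRecordInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(ref=""),
            dict(alts=()),
            dict(alts=("",)),
            dict(alts=("A",)),  # ALT equals REF
            dict(alts=("T", "T")),  # duplicate ALT
            dict(alts=("T",), gt=(0, 2)),  # index out of range
        ],
    )
    def test_rejects_malformed(self, kwargs):
        base = dict(chrom="chr1", pos=5, ref="A", alts=("T",))
        base.update(kwargs)
        with pytest.raises(ContractError):
            make_record(**base)

    def test_footprint(self):
        rec = make_record(pos=10, ref="ATT", alts=("A",))
        assert (rec.start0, rec.end0) == (9, 12)


@pytest.mark.parametrize(
    "ref,alt,kind,indel_len",
    [
        ("A", "T", VariantKind.SNV, 0),
        ("AT", "A", VariantKind.DEL, 1),
        ("A", "ATTT", VariantKind.INS, 3),
        ("AT", "GC", VariantKind.MNV, 0),
        ("ATTTT", "A", VariantKind.DEL, 4),
    ],
)
def test_classify_variant(ref, alt, kind, indel_len):
    vc = classify_variant(ref, alt)
    assert vc.kind == kind and vc.indel_len == indel_len


def test_classify_variant_rejects_empty():
    with pytest.raises(ContractError):
        classify_variant("", "A")


@pytest.mark.parametrize(
    "alleles,expected",
    [
        ((0, 0), GenotypeClass.HOM_REF),
        ((0, 1), GenotypeClass.SIMPLEX),
        ((0, 0, 0, 1), GenotypeClass.SIMPLEX),  # AAAa
        ((0, 0, 0, 0, 0, 1), GenotypeClass.SIMPLEX),  # AAAAAa in a hexaploid
        ((0, 0, 1, 1), GenotypeClass.DUPLEX),
        ((0, 1, 1, 1), GenotypeClass.TRIPLEX),
        ((1, 1, 1, 1), GenotypeClass.QUADRUPLEX),
        ((0, 1, 1, 1, 1, 1), GenotypeClass.QUINTUPLEX),
        ((1, 1, 1, 1, 1, 1), GenotypeClass.SEXTUPLEX),
        ((0, 1, 1, 2), GenotypeClass.MULTI_ALLELIC),
    ],
)
def test_classify_genotype(alleles, expected):
    assert classify_genotype(Genotype(alleles)) == expected


def test_classify_genotype_missing():
    assert classify_genotype(None) == GenotypeClass.MISSING


@pytest.mark.parametrize("ploidy", [2, 4, 6])
def test_simplex_iff_total_alt_dosage_one(ploidy, rng):
    """simplex holds exactly when the summed ALT dosage is 1, any ploidy."""
    for _ in range(200):
        alleles = tuple(int(a) for a in rng.integers(0, 3, size=ploidy))
        gt = Genotype(alleles)
        total_alt = sum(gt.dosage(a) for a in gt.alt_indices())
        is_simplex = classify_genotype(gt) == GenotypeClass.SIMPLEX
        assert is_simplex == (total_alt == 1)


class TestNormalize:
    def test_snv_fixed_point(self, toy_reference):
        rec = make_record(pos=7, ref="A", alts=("T",))
        assert normalize(rec, toy_reference) is rec

    def test_trim_shared_leading_base(self, toy_reference):
        # chr1 starts ACTTTG; pos2-3 = CT -> CG spelled with shared anchor
        rec = make_record(pos=2, ref="CT", alts=("CG",))
        out = normalize(rec, toy_reference)
        assert (out.pos, out.ref, out.alts) == (3, "T", ("G",))

    def test_deletion_left_aligned_to_run_start(self, toy_reference):
        # deleting one T from the TTT run at pos 3-5: any spelling must
        # left-align to the anchored representation at pos 2 (CT -> C)
        rec = make_record(pos=4, ref="TT", alts=("T",))
        out = normalize(rec, toy_reference)
        assert (out.pos, out.ref, out.alts) == (2, "CT", ("C",))

    def test_ref_mismatch_raises(self, toy_reference):
        with pytest.raises(ConsistencyError):
            normalize(make_record(pos=1, ref="G", alts=("T",)), toy_reference)

    def test_equivalent_spellings_converge(self, toy_reference):
        # same one-T deletion spelled at three positions in the run
        spellings = [
            make_record(pos=2, ref="CT", alts=("C",)),
            make_record(pos=3, ref="TT", alts=("T",)),
            make_record(pos=4, ref="TT", alts=("T",)),
        ]
        normalized = {
            (r.pos, r.ref, r.alts)
            for r in (normalize(s, toy_reference) for s in spellings)
        }
        assert len(normalized) == 1

    def test_oracle_random_variants(self, rng):
        """Normalization preserves the spelled haplotype and is idempotent.

        Brute-force oracle: applying the original and the normalized
        record to the reference must give identical sequences.
        """
        n_trials = 1200
        for trial in range(n_trials):
            seq = random_sequence(rng, 1000)
            ref_acc = DictReference({"c": seq})
            pos0 = int(rng.integers(20, 960))
            kind = rng.integers(0, 3)
            if kind == 0:  # SNV
                ref = seq[pos0]
                alt = "ACGT"[int(rng.integers(0, 4))]
                if alt == ref:
                    continue
            elif kind == 1:  # deletion of 1-10 bp
                dlen = int(rng.integers(1, 11))
                ref, alt = seq[pos0 : pos0 + 1 + dlen], seq[pos0]
            else:  # insertion of 1-10 bp
                ins = random_sequence(rng, int(rng.integers(1, 11)))
                ref, alt = seq[pos0], seq[pos0] + ins
            # redundantly pad with reference context to de-normalize
            pad = int(rng.integers(0, 4))
            ref_p = seq[pos0 - pad : pos0] + ref + seq[pos0 + len(ref) : pos0 + len(ref) + pad]
            alt_p = seq[pos0 - pad : pos0] + alt + seq[pos0 + len(ref) : pos0 + len(ref) + pad]
            if ref_p == alt_p:
                continue
            rec = make_record(chrom="c", pos=pos0 - pad + 1, ref=ref_p, alts=(alt_p,))
            out = normalize(rec, ref_acc)
            assert apply_to_sequence(out, seq) == apply_to_sequence(rec, seq)
            again = normalize(out, ref_acc)
            assert (again.pos, again.ref, again.alts) == (out.pos, out.ref, out.alts)


def test_decompose_mnv():
    rec = make_record(pos=10, ref="ATG", alts=("GTC",))
    parts = decompose_mnv(rec)
    assert [(p.pos, p.ref, p.alts) for p in parts] == [(10, "A", ("G",)), (12, "G", ("C",))]


class TestVcfIO:
    CONTIGS = [("chr1", 1000)]

    def _roundtrip(self, tmp_path, records, ploidy):
        path = str(tmp_path / "x.vcf")
        write_vcf(records, path, ploidy=ploidy, contigs=self.CONTIGS)
        return list(read_vcf(path))

    def test_roundtrip_field_for_field(self, tmp_path):
        records = [
            make_record(pos=10, ref="A", alts=("T",), gt=(0, 0, 0, 1),
                        info={"QUAL": 50.0, "QD": 12.5, "DP": 30.0}),
            make_record(pos=20, ref="AT", alts=("A", "ATT"), gt=(0, 1, 2, 2)),
            make_record(pos=30, ref="C", alts=("G",), gt=None),
        ]
        back = self._roundtrip(tmp_path, records, ploidy=4)
        assert len(back) == len(records)
        for orig, rt in zip(records, back):
            assert (rt.chrom, rt.pos, rt.ref, rt.alts) == (
                orig.chrom, orig.pos, orig.ref, orig.alts)
            if orig.genotype is None:
                assert rt.genotype is None
            else:
                assert rt.genotype.alleles == orig.genotype.alleles
            for key, val in orig.info.items():
                assert rt.info[key] == pytest.approx(val, rel=1e-6)

    def test_empty_recordset_gives_header_only(self, tmp_path):
        assert self._roundtrip(tmp_path, [], ploidy=4) == []

    def test_multiallelic_line_format(self, tmp_path):
        path = str(tmp_path / "m.vcf")
        write_vcf(
            [make_record(pos=20, ref="A", alts=("C", "G"), gt=(0, 1, 2, 2))],
            path, ploidy=4, contigs=self.CONTIGS,
        )
        line = [l for l in open(path) if not l.startswith("#")][0]
        fields = line.split("\t")
        assert fields[4] == "C,G"
        assert fields[-1].strip() == "0/1/2/2"

    def test_expected_ploidy_mismatch_raises(self, tmp_path):
        path = str(tmp_path / "p.vcf")
        write_vcf([make_record(pos=10, ref="A", alts=("T",), gt=(0, 0, 0, 1))],
                  path, ploidy=4, contigs=self.CONTIGS)
        with pytest.raises(PloidyError):
            list(read_vcf(path, expected_ploidy=2))
        # matching ploidy streams fine
        assert len(list(read_vcf(path, expected_ploidy=4))) == 1

    def test_missing_genotype_convention(self, tmp_path):
        path = tmp_path / "miss.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n"
            "chr1\t100\t.\tA\tT\t.\t.\t.\tGT\t./.\n"
        )
        (rec,) = read_vcf(str(path))
        assert rec.genotype is None

    def test_phase_discarded(self, tmp_path):
        path = tmp_path / "ph.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n"
            "chr1\t100\t.\tA\tT\t.\t.\t.\tGT\t1|0\n"
        )
        (rec,) = read_vcf(str(path))
        assert rec.genotype.alleles == (0, 1)

    def test_symbolic_alts_skipped(self, tmp_path):
        path = tmp_path / "sym.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            '##ALT=<ID=DEL,Description="Deletion">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n"
            "chr1\t100\t.\tA\t<DEL>\t.\t.\t.\tGT\t0/1\n"
            "chr1\t200\t.\tA\tT\t.\t.\t.\tGT\t0/1\n"
        )
        records = list(read_vcf(str(path)))
        assert [r.pos for r in records] == [200]
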