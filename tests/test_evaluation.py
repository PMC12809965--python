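"""Detection vs genotyping accounting, stratification, dosage confusion."""

import numpy as np
import pytest

from polybench.errors import ContractError, OrderingError, PloidyError
from polybench.evaluation import (
    dosage_confusion,
    evaluate,
    evaluate_callsets,
    match_sites,
    metrics,
    simplex_fp_fraction,
    stratify,
)
from polybench.reference import DictReference
from polybench.regions import RegionSet
from polybench.variants import sort_records

from conftest import make_record, random_sequence


def snv(pos, gt, alt="T", ref="A", info=None):
    return make_record(pos=pos, ref=ref, alts=(alt,), gt=gt, info=info)


class TestMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"TP": 0, "FP": 0, "FN": 0}, (0.0, 0.0, 0.0)),
            ({"TP": 2, "FP": 1, "FN": 1}, (2 / 3, 2 / 3, 2 / 3)),
            ({"TP": 1, "FP": 1, "FN": 0}, (0.5, 1.0, 2 / 3)),
        ],
    )
    def test_formulas(self, counts, expected):
        m = metrics(counts)
        assert (m["precision"], m["recall"], m["F1"]) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ContractError):
            metrics({"TP": -1, "FP": 0, "FN": 0})


class TestMatchSites:
    def test_identical_sets_fully_paired(self):
        truth = [snv(100, (0, 0, 0, 1)), snv(200, (0, 1, 1, 1))]
        match = match_sites(truth, list(truth))
        assert len(match.pairs) == 2
        assert not match.truth_only and not match.query_only

    def test_unmatched_goes_to_truth_only(self):
        match = match_sites([snv(100, (0, 0, 0, 1))], [snv(500, (0, 0, 0, 1))])
        assert len(match.truth_only) == 1 and len(match.query_only) == 1

    def test_different_spellings_pair_after_normalization(self):
        # one-base deletion in a T-run spelled at two different anchors
        seq = "GACTTTTTAGC" + "G" * 50
        ref_acc = DictReference({"chr1": seq})
        truth = [make_record(pos=3, ref="CT", alts=("C",), gt=(0, 0, 0, 1))]
        query = [make_record(pos=5, ref="TT", alts=("T",), gt=(0, 0, 0, 1))]
        report = evaluate_callsets(
            truth, query, reference=ref_acc, normalize_inputs=True
        )
        assert report.counts("detection").as_dict() == {"TP": 1, "FP": 0, "FN": 0}
        assert report.counts("genotyping").as_dict() == {"TP": 1, "FP": 0, "FN": 0}

    def test_unsorted_raises(self):
        with pytest.raises(OrderingError):
            match_sites([snv(200, (0, 1)), snv(100, (0, 1))], [])


class TestEvaluateModes:
    def test_wrong_dosage_is_detection_tp_genotyping_fpfn(self):
        truth = [snv(100, (0, 0, 0, 1))]
        query = [snv(100, (0, 0, 1, 1))]
        match = match_sites(truth, query)
        assert evaluate(match, "detection") == {"TP": 1, "FP": 0, "FN": 0}
        assert evaluate(match, "genotyping") == {"TP": 0, "FP": 1, "FN": 1}

    def test_hand_counted_enumeration(self):
        """3 truth sites: one wrong dosage, one exact, one missed; plus a
        spurious query site."""
        truth = [snv(100, (0, 0, 0, 1)), snv(200, (0, 0, 1, 1)), snv(300, (0, 0, 0, 1))]
        query = [snv(100, (0, 0, 1, 1)), snv(200, (0, 0, 1, 1)), snv(400, (0, 0, 0, 1))]
        match = match_sites(truth, query)
        det = evaluate(match, "detection")
        gen = evaluate(match, "genotyping")
        assert det == {"TP": 2, "FP": 1, "FN": 1}
        assert gen == {"TP": 1, "FP": 2, "FN": 2}
        assert metrics(det)["precision"] == pytest.approx(2 / 3)
        assert metrics(gen)["recall"] == pytest.approx(1 / 3)

    def test_wrong_allele_is_fpfn_in_both_modes(self):
        truth = [snv(100, (0, 0, 0, 1), alt="T")]
        query = [snv(100, (0, 0, 0, 1), alt="G")]
        match = match_sites(truth, query)
        for mode in ("detection", "genotyping"):
            assert evaluate(match, mode) == {"TP": 0, "FP": 1, "FN": 1}

    def test_hom_ref_query_ignored(self):
        truth = [snv(100, (0, 0, 0, 1))]
        query = [snv(100, (0, 0, 0, 0)), snv(300, (0, 0, 0, 0))]
        match = match_sites(truth, query)
        for mode in ("detection", "genotyping"):
            assert evaluate(match, mode) == {"TP": 0, "FP": 0, "FN": 1}

    def test_missing_query_genotype_is_no_call(self):
        truth = [snv(100, (0, 0, 0, 1))]
        query = [snv(100, None)]
        match = match_sites(truth, query)
        assert evaluate(match, "detection") == {"TP": 0, "FP": 0, "FN": 1}

    def test_ploidy_mismatch_raises_in_genotyping(self):
        match = match_sites([snv(100, (0, 1))], [snv(100, (0, 0, 0, 1))])
        assert evaluate(match, "detection")["TP"] == 1
        with pytest.raises(PloidyError):
            evaluate(match, "genotyping")

    def test_truth_against_itself_is_perfect(self):
        truth = [
            snv(100, (0, 0, 0, 1)),
            make_record(pos=200, ref="A", alts=("T", "G"), gt=(0, 1, 1, 2)),
        ]
        match = match_sites(truth, list(truth))
        for mode in ("detection", "genotyping"):
            m = metrics(evaluate(match, mode))
            assert (m["precision"], m["recall"], m["F1"]) == (1.0, 1.0, 1.0)

    def test_conservation_tp_plus_fn(self, rng):
        truth = [snv(int(p), (0, 0, 0, 1)) for p in sorted(rng.choice(10_000, 50, replace=False) + 1)]
        keep = rng.random(50) > 0.3
        query = [t for t, k in zip(truth, keep) if k]
        match = match_sites(truth, query)
        for mode in ("detection", "genotyping"):
            counts = evaluate(match, mode)
            assert counts["TP"] + counts["FN"] == len(truth)


class TestDosageConfusion:
    def test_simplex_missed_lands_in_column_zero(self):
        truth = [snv(100, (0, 0, 0, 1))]
        mat = dosage_confusion(match_sites(truth, []), ploidy=4)
        assert mat[1, 0] == 1 and mat.sum() == 1

    def test_diagonal_for_exact_call(self):
        truth = [snv(100, (0, 0, 1, 1))]
        mat = dosage_confusion(match_sites(truth, list(truth)), ploidy=4)
        assert mat[2, 2] == 1 and mat.sum() == 1

    def test_row_sums_match_truth_class_counts(self, rng):
        truth, query = [], []
        truth_dosage_counts = np.zeros(5, dtype=int)
        pos = 100
        for _ in range(60):
            d_t = int(rng.integers(1, 4))
            d_c = int(rng.integers(0, 4))
            truth.append(snv(pos, (0,) * (4 - d_t) + (1,) * d_t))
            if d_c > 0:
                query.append(snv(pos, (0,) * (4 - d_c) + (1,) * d_c))
            truth_dosage_counts[d_t] += 1
            pos += 10
        mat = dosage_confusion(match_sites(truth, query), ploidy=4)
        assert np.array_equal(mat.sum(axis=1)[1:5], truth_dosage_counts[1:5])


class TestStratify:
    def test_single_all_covering_stratum_equals_unstratified(self):
        truth = [snv(100, (0, 0, 0, 1)), snv(200, (0, 0, 1, 1))]
        query = [snv(100, (0, 0, 1, 1)), snv(300, (0, 0, 0, 1))]
        match = match_sites(truth, query)
        everywhere = RegionSet({"chr1": [(0, 10_000)]})
        report = stratify(match, strata={"cover": everywhere})
        for mode in ("detection", "genotyping"):
            assert (
                report.counts(mode, stratum="cover").as_dict()
                == report.counts(mode).as_dict()
                == evaluate(match, mode)
            )

    def test_fps_outside_coding_give_coding_precision_one(self):
        coding = RegionSet({"chr1": [(0, 150)]})
        truth = [snv(100, (0, 0, 0, 1))]
        query = [snv(100, (0, 0, 0, 1)), snv(500, (0, 0, 0, 1))]  # FP at 500
        report = stratify(match_sites(truth, query), strata={"coding": coding})
        m = report.metrics_for("detection", stratum="coding")
        assert m["precision"] == 1.0
        assert report.counts("detection").fp == 1  # global still sees it

    def test_simplex_class_counts_truth_dosage_one(self):
        truth = [snv(100, (0, 0, 0, 1)), snv(200, (0, 0, 1, 1))]
        report = stratify(match_sites(truth, list(truth)))
        assert report.counts("genotyping", gclass="simplex").tp == 1
        assert report.counts("genotyping", gclass="duplex").tp == 1

    def test_fp_classed_by_query_genotype(self):
        truth = [snv(100, (0, 0, 0, 1))]
        query = [snv(100, (0, 0, 1, 1))]
        report = stratify(match_sites(truth, query))
        # genotyping: FP half classed duplex (query), FN half simplex (truth)
        assert report.counts("genotyping", gclass="duplex").fp == 1
        assert report.counts("genotyping", gclass="simplex").fn == 1


class TestSimplexFpFraction:
    def _report(self, fps):
        truth = []
        query = list(fps)
        return stratify(match_sites(truth, sort_records(query)))

    def test_all_simplex(self):
        fps = [make_record(pos=p, ref="A", alts=("AT",), gt=(0, 0, 0, 1)) for p in (10, 20)]
        assert simplex_fp_fraction(self._report(fps), "indel") == 1.0

    def test_three_of_four(self):
        fps = [make_record(pos=p, ref="A", alts=("AT",), gt=(0, 0, 0, 1)) for p in (10, 20, 30)]
        fps.append(make_record(pos=40, ref="A", alts=("AT",), gt=(0, 0, 1, 1)))
        assert simplex_fp_fraction(self._report(fps), "indel") == 0.75

    def test_zero_denominator(self):
        assert simplex_fp_fraction(self._report([]), "indel") == 0.0


class TestDominanceAndInvariance:
    def test_dominance_on_random_corruptions(self, rng):
        """detection P >= genotyping P and detection R >= genotyping R."""
        for trial in range(20):
            n = 80
            positions = sorted(int(p) * 10 + 1 for p in rng.choice(2000, n, replace=False))
            truth, query = [], []
            for p in positions:
                d = int(rng.integers(1, 4))
                truth.append(snv(p, (0,) * (4 - d) + (1,) * d))
                r = rng.random()
                if r < 0.1:
                    continue  # missed
                d_c = d if r > 0.3 else max(1, min(3, d + (1 if rng.random() < 0.5 else -1)))
                query.append(snv(p, (0,) * (4 - d_c) + (1,) * d_c))
            match = match_sites(truth, query)
            det = metrics(evaluate(match, "detection"))
            gen = metrics(evaluate(match, "genotyping"))
            assert det["precision"] >= gen["precision"]
            assert det["recall"] >= gen["recall"]

    def test_permutation_invariance(self, rng):
        truth = [snv(int(p) + 1, (0, 0, 0, 1)) for p in sorted(rng.choice(5000, 40, replace=False))]
        query = [snv(t.pos, (0, 0, 1, 1)) for t in truth[:30]]
        base = evaluate_callsets(truth, query)
        for _ in range(5):
            t2, q2 = list(truth), list(query)
            rng.shuffle(t2)
            rng.shuffle(q2)
            shuffled = evaluate_callsets(t2, q2)
            for mode in ("detection", "genotyping"):
                assert shuffled.counts(mode).as_dict() == base.counts(mode).as_dict()


def test_split_multiallelic_changes_site_granularity():
    truth = [make_record(pos=100, ref="A", alts=("C", "G"), gt=(0, 0, 1, 2))]
    query = [make_record(pos=100, ref="A", alts=("C",), gt=(0, 0, 0, 1))]
    joint = evaluate_callsets(truth, query)
    split = evaluate_callsets(truth, query, split_multiallelic=True)
    # joint: one site, shared allele C -> detection TP
    assert joint.counts("detection").as_dict() == {"TP": 1, "FP": 0, "FN": 0}
    # split: C-site TP at wrong dosage accounting per allele; G-site missed
    assert split.counts("detection").as_dict() == {"TP": 1, "FP": 0, "FN": 1}
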