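# polybench

Dosage-aware benchmarking of polyploid small-variant calls.

Calling SNVs and small indels in polyploids (autotetraploid potato,
hexaploid wheat, synthetic polyploids built from human trios) raises a
question that diploid benchmarking tools gloss over: a caller can flag the
right site yet assign the wrong **allelic dosage** — reporting `0/0/1/1`
where the truth is `0/0/0/1` (AAAa). polybench separates those failure
modes by scoring every callset under two semantics:

* **detection** — a truth site counts as found if the call shares at
  least one ALT allele with the truth genotype, at any copy number;
* **genotyping** — the call must reproduce the exact genotype multiset
  (allele composition *and* dosage) at the declared ploidy.

A matched site with the wrong allele or dosage counts as FP **and** FN
(the convention of haplotype-comparison evaluators), unmatched truth is
FN, and any unmatched call asserting an ALT is FP. Precision, recall and
F1 are reported per mode, stratified by variant type (SNV/INS/DEL),
truth genotype class (simplex `0/0/0/1`, duplex `0/0/1/1`, ...), and
user-supplied region strata, together with a dosage confusion matrix
over (truth dosage, called dosage). Detection metrics always dominate
genotyping metrics; the gap is exactly the dosage-assignment error.

The package also builds the inputs such a benchmark needs:

* **truth synthesis** — merge per-sample diploid truth VCFs (union of
  sites, summed dosages, harmonized allele spellings) restricted to the
  intersection of their confident BEDs, producing a tetraploid truth set
  from two diploids or a hexaploid from three;
* **confidence regions** — from per-haplotype assembly-to-reference
  alignments (PAF or BED), keep reference positions covered by exactly
  one alignment block per haplotype and intersect across haplotypes,
  generalizing diploid assembly-based benchmarking to any ploidy;
* **filters** — the per-type QD hard filter (drop SNVs and >1 bp indels
  with QD < 2, 1 bp indels with QD < 5), configurable YAML threshold
  policies for FreeBayes-style callsets, and the reliable-region read
  filter (keep a read iff strictly more than 50% of its bases fall in
  one-to-one homology regions, compared in exact rational arithmetic);
* **fixtures** — a deterministic generator of reference FASTA, diploid
  truth samples, alignment blocks with presence/absence defects, read
  placements, and corrupted callsets whose injected errors are bookkept
  so every evaluation count can be predicted exactly.

## Worked example

```bash
polybench simulate --seed 3 --ploidy 4 --chrom-len 60000 --pav-events 3 --out fx/
polybench evaluate --truth fx/truth.vcf --query fx/query.vcf \
    --regions fx/conf.bed --ref fx/ref.fa --ploidy 4 \
    --out report.tsv --json report.json
```

prints

```
detection: precision=0.9697 recall=0.9846 F1=0.9771
genotyping: precision=0.8333 recall=0.8462 F1=0.8397
```

Here the simulated caller missed 1 of 65 tetraploid truth sites, called 2
spurious sites, and mis-assigned dosage at 9 more. Detection ignores the
dosage errors (64 of 65 sites found; 2 of 66 calls wrong), while
genotyping charges each of the 9 dosage errors as one FP plus one FN —
the precision/recall gap between the two rows is exactly those sites.
`report.tsv` carries one row per (mode × type × class × stratum) cell;
`report.json` additionally contains the dosage confusion matrix, whose
off-diagonal mass here is the 9 injected dosage shifts.

The same pipeline is available as a library:

```python
from polybench import FixtureSpec, evaluate_callsets
from polybench.fixtures import run_pipeline

res = run_pipeline(FixtureSpec(seed=3, n_haplotypes=4))
report = evaluate_callsets(
    res.merged.records, res.query,
    regions=res.merged.regions,
    reference=res.fixture.reference,
    ploidy=res.merged.ploidy,
)
print(report.metrics_for("genotyping"))
```

## Command-line interface

| command | purpose |
| --- | --- |
| `polybench simulate` | generate a synthetic benchmark fixture |
| `polybench derive-regions` | confidence regions from PAF/BED alignments |
| `polybench merge-truth` | diploid truth VCFs → polyploid truth set |
| `polybench evaluate` | detection + genotyping report (TSV/JSON) |
| `polybench filter-vcf` | QD or FreeBayes-style hard filtering |
| `polybench filter-reads` | reliable-region read retention |

See `docs/methods.md` for the underlying models, conventions, and known
limitations.
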