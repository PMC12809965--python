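# Methods

This note documents the models, conventions, and numerical choices behind
polybench, and what the synthetic fixtures do and do not establish about
real data.

## Variant representation and normalization

All coordinates are 0-based half-open internally; the 1-based VCF
convention exists only at I/O boundaries (`VariantRecord.pos` keeps the
VCF value, `start0`/`end0` expose the footprint). Genotypes are unphased
multisets of allele indices: the package evaluates allelic dosage, not
phase, so `1|0` and `0/1` are the same object. Symbolic ALTs, breakends,
and spanning-deletion `*` alleles are skipped on read with a warning —
only small sequence-resolved variants are in scope.

Normalization trims shared trailing bases (extending left through the
reference when an allele would become empty, which is what left-aligns
indels), then shared leading bases, moving all alleles of a multiallelic
record together and keeping the single shared anchor base the VCF format
requires. The operation is idempotent, and its correctness criterion is
semantic, not syntactic: applying the normalized and the original record
to the reference must yield identical sequences (`apply_to_sequence` is
the oracle used throughout the test suite). Multi-nucleotide
substitutions can optionally be decomposed into SNVs (`decompose_mnv`);
this is off by default since callers differ in whether they emit MNVs
at all.

Genotype classes follow the polyploid nomenclature: simplex = exactly
one ALT copy (`0/0/0/1`, AAAa), duplex = one distinct ALT at dosage 2,
up to sextuplex at dosage 6 (hexaploid hom-alt), `multi_allelic` for two
or more distinct ALT alleles, plus `hom_ref` and `missing`. The sextuplex
label completes the scale so classification is total at ploidy 6.

## Confidence regions

Assembly-based benchmarking restricts evaluation to reference intervals
where the sample's haplotypes are unambiguously represented. For each
haplotype assembly, `unique_cover` keeps reference positions covered by
*exactly one* retained alignment block — zero coverage means the
haplotype is absent or unalignable there, coverage ≥ 2 means ambiguity
(e.g. a duplicated segment). Blocks below a length or MAPQ cutoff are
discarded first; the exposed defaults (50 kb, MAPQ 5) mirror common
practice for assembly-to-reference masking and are plain flags, since no
single canonical value exists. Intersecting the per-haplotype unique
covers yields the confidence mask for any haplotype count; diploid
benchmarking is the two-haplotype special case. Strand is ignored: only
the reference footprint matters for a mask.

Variant containment uses the full REF footprint: a record is inside the
mask iff `[pos−1, pos−1+len(ref))` lies within a single interval, so an
insertion is judged by its anchor base and a deletion can never be half
in, half out.

Interval algebra is implemented as sorted-interval sweeps rather than
delegated to an interval library, because `unique_cover`'s
coverage-exactly-one semantics is the core construction here and the
test suite checks all of it against an independent per-base boolean
array oracle; routing intersection/subtraction through a library would
collapse that dual-route check.

## Truth synthesis

A polyploid truth set at ploidy 2k is the union of k diploid truth sets:
confident regions are intersected, variant sites are unioned, and at
each site the output genotype carries the summed per-allele dosage. A
sample with no record at a site contributes hom-ref — valid precisely
because output is restricted to the intersection of confident regions,
inside which absence is an assertion of reference genotype (the
semantics high-confidence truth sets are built on).

Samples spell overlapping variants differently, so co-located records
are *harmonized* first: the unified REF spans the union of footprints
(right-padded with reference bases) and each ALT is re-spelled against
it; duplicate spellings collapse to one allele, spellings equal to the
unified REF are hom-ref contributions. ALTs are ordered
lexicographically so genotype indices are reproducible and the merge is
invariant to sample order. Sites that come out pure hom-ref (possible
when overlapping records cancel) are dropped and counted. Overlapping
records *within* one sample abort with a diagnostic: the per-haplotype
allele composition of such a site is ambiguous and silently guessing
would corrupt dosages.

The merge invariant checked in tests is sequence-level and per locus:
for every merged record, the multiset of chromosome sequences obtained
by applying each genotype allele (with multiplicity = dosage) equals the
multiset obtained from the input samples' own records at that locus.
Cross-site phase is deliberately not represented — merged genotypes are
unphased — so the oracle is per-locus rather than whole-haplotype.

`plan_coverage` is pure arithmetic for pooled-read designs (k samples at
d× pool to kd× total, kd/2k× per haplotype); no BAM manipulation is
performed or wrapped.

## Evaluation

Matching is site-level: truth and query records whose normalized REF
footprints overlap are paired 1:1 (nearest start wins ties, then
lexicographic ALT; losers stay unmatched). This replaces full
haplotype-replay comparison — a deliberate trade: it is deterministic
and oracle-testable, but clusters of nearby variants spelled as
different decompositions may score differently than a replay-based
evaluator would. Inputs should be normalized (the `evaluate_callsets`
entry point can do it) so equivalent spellings collide.

Per pair, alleles are compared after harmonization onto a unified REF.
Detection scores a TP iff the two genotypes share ≥ 1 ALT allele with
dosage ≥ 1 on both sides — a site called with only a *different* ALT
allele is not detected (the stricter reading of site-level
identification of a non-reference allele). Genotyping requires identical
dosage maps at equal ploidy. A pair failing its mode's criterion is
FP + FN simultaneously; query records asserting no ALT (hom-ref or
missing genotype) assert nothing and are ignored on the query side,
leaving the truth side FN. Consequences, asserted as test invariants:
genotyping TPs ⊆ detection TPs, detection precision ≥ genotyping
precision, detection recall ≥ genotyping recall, and detection
TP + FN = truth-site count.

Multiallelic records are compared jointly by default; a
`split_multiallelic` flag decomposes them into per-ALT records before
matching for callers/evaluators that account per allele.

The dosage confusion matrix counts, for each truth ALT allele, the pair
(truth dosage, called dosage), with column 0 holding missed sites and
alleles absent from the paired call — so row sums equal truth dosage
class counts by construction, and e.g. simplex→hom-ref failures
accumulate in cell (1, 0). `simplex_fp_fraction` reports the share of
genotyping-mode FP records of a given type whose *called* genotype is
simplex, the diagnostic for low-allele-fraction indel artifacts.

## Filters

The per-type QD rule is applied with strict inequalities exactly as
printed: QD < 2 drops SNVs, MNVs and indels longer than 1 bp; QD < 5
drops 1 bp indels; a multiallelic record uses the most stringent
threshold among its alleles. Records lacking QD are kept with a warning
(QD is only emitted for variant sites; failing closed would silently
drop valid records) — `missing_fails` reverses this per policy.

FreeBayes-style policies are ordered ≥-threshold rules over QUAL, MQM,
DP loaded from YAML. The shipped `minimal` (QUAL ≥ 20) and `strict`
(QUAL ≥ 20, MQM ≥ 40, DP ≥ 10) presets are labelled reconstructions of
commonly used site filters, not canonical values; the file is meant to
be edited. Strict's thresholds dominate minimal's, so strict survivors
are a subset of minimal survivors (tested).

The reliable-region read filter keeps a read iff strictly more than
`min_frac` (default 1/2) of its bases fall inside reliable regions.
Base accounting uses reference-projected aligned blocks (CIGAR M/=/X):
inserted and clipped read bases count toward read length but never
toward overlap — a deterministic choice where raw-base accounting would
be underdefined. The comparison is exact rational arithmetic
(`fractions.Fraction`), so a read at exactly 50% is dropped by the
strict rule rather than by a float rounding accident.

## Synthetic fixtures

The generator emulates the *structure* of a polyploid benchmarking
experiment, not sequencing physics. One `FixtureSpec` drives everything;
identical specs produce byte-identical artifacts (per-chromosome
sub-generators are derived deterministically from the seed, and VCF/BED/
PAF writers emit no timestamps).

Defaults, chosen once as the package's study conditions: 1 Mb uniform
ACGT chromosome, SNV rate 1.0 × 10⁻³ and indel rate 2.0 × 10⁻⁴ per base
(human-like small-variant density, ~1,100–1,250 sites per fixture),
geometric indel lengths (p = 0.6, capped at 10 bp), 2% multiallelic
SNVs, carrier counts with P(d) ∝ 1/d across haplotypes (a neutral-ish
dosage spectrum), fn_rate 0.02, fp_rate 0.03, dosage_err_rate 0.10 —
the dosage-error rate is set several-fold above the miss/spurious rates
because dosage mis-assignment, not outright missing or inventing sites,
is the dominant error mode in polyploid calling. Spurious calls default
to simplex genotypes (the characteristic low-allele-fraction artifact
class), with a 50/50 SNV/1-bp-indel mix.

Two construction guarantees make ledger predictions *exact* rather than
statistical:

1. **Disjoint effective spans.** A site's effective span is the union of
   the normalized footprints of its record and of every single-ALT
   sub-record. Sites are kept only if spans are pairwise disjoint within
   the margin-trimmed chromosome, so per-sample subsetting,
   normalization on load, and harmonization can never fuse two sites or
   shift one into its neighbour.
2. **Clear spurious placement.** Injected FP records are normalized at
   generation time and re-drawn unless their footprint (±1 base) avoids
   every truth footprint and every other spurious record, so they can
   never pair with a truth record during matching.

Corruption operates on the merged polyploid truth, because the error
taxonomy (missed site, spurious site, dosage shift) is defined at the
callset level being evaluated. A dosage shift moves one ALT allele ±1
copy staying within [1, ploidy−1], so detection still succeeds and the
detection/genotyping gap isolates dosage error; at ploidy 2 only
hom-alt sites admit a legal shift, and sites with no legal move are
left intact (the ledger records realized events only, which keeps
predictions exact at every ploidy). `allow_dosage_to_zero` additionally
lets biallelic simplex sites collapse to a hom-ref call, emulating the
diploid-model failure mode where single-copy alleles are read as noise;
those land in confusion cell (1, 0).

Alignment-block defects ("PAV events") are pairwise-disjoint intervals
that either cut a gap into one haplotype's block (a reference-only
segment) or add a duplicated block (a sample-side repeat), so the
expected confidence region is the chromosome minus the union of event
intervals in closed form — checked against the actual
`derive_confidence_regions` output. Read placements carry geometry only
(uniform starts, single aligned block, exact overlap bookkeeping); the
retained-read rule depends only on geometry, so base-level read
simulation is unnecessary for testing it.

**What passing fixtures do not show.** The generator draws i.i.d.
uniform sequence: no true repeat structure (unless `repeat_fraction`
adds simple tandem tracts), no mapping ambiguity, no clustered errors
near structural variants, no caller-specific biases beyond the
configured taxonomy, and no base-level error model. Exact count
recovery on fixtures validates the *accounting machinery* — matching,
harmonization, mode semantics, stratification — not any claim about how
a real caller performs on a real genome.

## Problem sizes and numerical choices

The default test and acceptance runs use 1 Mb fixtures (~1,100–1,250
truth sites) for pipeline checks, 100 kb chromosomes for the per-base
region oracle (1,000 random collections), 1 kb references for the
normalization oracle (1,000 random variants), and ≤ 10 kb toy genomes
for the merge spell-out oracle (100 genomes) — sizes at which every
oracle is exhaustive and the whole suite runs in well under a minute.
Metric conventions: precision/recall/F1 are 0 when their denominator is
0; VCF INFO floats survive the float32 round trip because generated
annotations are quantized to 0.5; fraction comparisons in the read
filter are exact rationals. Tie-breaks (matching) and orderings (ALT
lexicographic, canonical record sort) are all deterministic so reports
are permutation-invariant to input order.

## Known limitations

* Site-level matching is not haplotype replay: complex nearby-variant
  representation differences can score as FP+FN where a replay-based
  comparison would find equivalence.
* Confidence-region derivation consumes alignment intervals (PAF/BED);
  it does not run or replace an aligner, and it does not synthesize
  truth genotypes from assemblies — truth synthesis requires explicit
  per-sample VCFs.
* Detection-mode FP accounting is per site, not per allele (use
  `split_multiallelic` for per-allele granularity).
* k-mer-based validation of truth variants and structural-variant
  benchmarking are out of scope.
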