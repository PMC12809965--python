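# Post hoc hard-filter presets for FreeBayes callsets.
#
# These thresholds are reconstructions of commonly used FreeBayes site
# filters (site quality, mean ALT mapping quality, depth), not values
# fixed by any single publication; edit freely or supply your own file
# via `polybench filter-vcf --config`.  Every rule keeps a record iff
# annotation >= min (strict drop below).
minimal:
  QUAL:
    min: 20
strict:
  QUAL:
    min: 20
  MQM:
    min: 40
  DP:
    min: 10
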