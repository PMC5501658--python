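# Published dichotomization rules for the aggregated predictors.
# Numeric thresholds are strict ("exceeded" => strictly greater); COVEC
# "positive" means > 0 with 0 treated as neutral.  PolyPhen2 ships in two
# variants: variant A maps "possibly damaging" to neutral, variant B to
# harmful.
- name: cadd_phred
  kind: numeric_threshold
  threshold: 12.0
  direction: greater
- name: mtoolbox_ds
  kind: numeric_threshold
  threshold: 0.4311
  direction: greater
- name: covec_wmv
  kind: numeric_threshold
  threshold: 0.0
  direction: greater
- name: polyphen2
  kind: categorical_map
  mapping:
    benign: neutral
    possibly damaging: neutral
    probably damaging: harmful
- name: polyphen2_b
  kind: categorical_map
  mapping:
    benign: neutral
    possibly damaging: harmful
    probably damaging: harmful
- name: sift
  kind: categorical_map
  mapping:
    tolerated: neutral
    deleterious: harmful
- name: fathmm
  kind: categorical_map
  mapping:
    tolerated: neutral
    damaging: harmful
- name: provean
  kind: categorical_map
  mapping:
    neutral: neutral
    deleterious: harmful
- name: mutation_assessor
  kind: categorical_map
  mapping:
    neutral: neutral
    low: neutral
    medium: harmful
    high: harmful
- name: vest
  kind: significance_pair
  p_cutoff: 0.05
  fdr_cutoff: 0.2
  p_column: vest_pvalue
  fdr_column: vest_fdr
- name: chasm
  kind: significance_pair
  p_cutoff: 0.05
  fdr_cutoff: 0.2
  p_column: chasm_pvalue
  fdr_column: chasm_fdr
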