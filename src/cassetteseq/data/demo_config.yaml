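# Demo pipeline config: simulate a small two-gene locus set and analyse it.
sample_id: demo
params:
  read_length: 125
  min_overlap: 10
  fragment_lengths: [25, 50]
  retention_window: 100
  diagnostic_exon: 2
  seed: 7
simulate:
  enabled: true
  genes:
    - gene_id: demo_beta
      family: beta
      n_cassettes: 6
    - gene_id: demo_alpha
      family: alpha
      n_cassettes: 8
  mixture:
    canonical: 0.76
    type_i: 0.08
    type_ii: 0.08
    type_iii: 0.04
    between_retention: 0.04
  n_molecules_per_gene: 1500
  read_model:
    read_length: 125
    paired: true
    fragment_mean: 300.0
    fragment_sd: 30.0
    error_rate: 0.0
    n_reads: 6000
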