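# cassetteseq

Quantification and splice-classification of genes with **tandemly arrayed
5′ variable cassettes** from RNA-seq.

Some chelicerate cell-surface receptor genes (the shortened Dscam, or
*sDscam*, family of scorpions, spiders, ticks and horseshoe crabs) put
their diversity at the 5′ end: a cluster of near-identical cassette
repeats — 2 exons each in the α subfamily (one Ig domain per cassette), 4
exons in the β subfamily (two Ig domains) — feeds a shared set of 3′
constant exons. Each cassette has its own promoter, so one mRNA isoform is
born by promoter choice and finished by alternative splicing, much like
vertebrate clustered protocadherins. Quantifying such loci from short
reads is awkward for generic RNA-seq tooling: the duplicated cassettes are
nearly identical (multi-mapping), and the interesting biology lives in
exon–exon junctions between duplicated exons and in retained intronic
sequence at cassette boundaries.

`cassetteseq` implements the analysis end to end, for anyone studying
clustered multi-promoter loci with duplicated exon cassettes:

* **Junction library** — for every ordered variable-exon pair (donor,
  acceptor) a perfect-match reference of donor suffix + acceptor prefix,
  each flank `read_length − min_overlap` nt (115 nt for 125-nt reads under
  the 10-position rule, i.e. 230-nt references with the breakpoint at
  115), truncated at exon boundaries. Analogous exon–intron references
  detect retained introns.
* **Perfect-match junction counting** — a read supports a junction iff it
  (or its reverse complement) matches a reference exactly and spans the
  breakpoint with ≥ `min_overlap` bases on both sides; ambiguity across
  duplicate copies is resolved by unique-support rescue.
* **Classification** — canonical (within-cassette neighbours, and any
  cassette's last exon onto the first constant exon) versus non-canonical
  type I (within-cassette exon skipping), type II (cross-cassette
  junctions) and type III (within-cassette intron retention), plus
  Ig-domain accounting per isoform (exon 2 → one Ig; exons 3+4 → one Ig).
* **Fragment quantification** — reads are split into 25- and 50-nt
  fragments, mapped exactly, and multi-mapped fragments are re-allocated
  in tiers anchored on the parent full-length read; outputs are per-gene
  r.p.m. over constitutive exons, a per-cassette usage simplex from a
  diagnostic exon (exon 2), top-k isoform shares, and intron-retention
  rates (intron/exon coverage ratio over a 100-nt window).
* **Simulator** — segmental-duplication loci with tunable inter-copy
  divergence, promoter-weight and splicing-class-mixture transcript pools,
  and uniform-coverage (optionally paired, error-prone) reads with full
  ground truth, so every estimate is testable without any downloads.

## Worked example

```python
from cassetteseq.fixtures import fixture_loci
from cassetteseq.simulate import ClassMixture, ReadModel, simulate_transcripts, simulate_reads
from cassetteseq.pipeline import analyse

loci, genome = fixture_loci("beta")     # six beta genes, invented geometry
loci = loci[:2]
isoforms = []
for locus in loci:
    iso, truth = simulate_transcripts(locus, genome, ClassMixture(), 2000, seed=7)
    isoforms += iso
reads = simulate_reads(isoforms, ReadModel(n_reads=20_000), seed=7)
res = analyse(loci, genome, reads)
print({k: round(v, 3) for k, v in sorted(res.mixture.items())})
print("25/50 nt fragment correlation r =", round(res.correlations["pearson"], 4))
```

prints

```
{'between_retention': 0.032, 'canonical': 0.786, 'type_i': 0.083, 'type_ii': 0.074, 'type_iii': 0.025}
25/50 nt fragment correlation r = 0.9989
```

i.e. the molecule-level splicing-class mixture estimated from junction
evidence (the generator drew classes at 0.76/0.08/0.08/0.04/0.04 — the
estimate recovers the realised pool), and the consistency check between
the two fragment tilings. `res.usage`, `res.expression` and
`res.retention` hold the per-cassette usage simplex, r.p.m. table and
intron-retention table as DataFrames; `write_reports(res, outdir)` saves
them as TSV plus a `summary.json`.

The same pipeline runs from a shell:

```sh
cassetteseq run --config src/cassetteseq/data/demo_config.yaml --out demo_out --seed 7
```

with subcommands `simulate`, `build-junctions`, `map`, `classify`,
`quantify`, `report` for the individual stages.

## Packaged fixtures

`src/cassetteseq/data/` ships GFF3 gene models encoding the published
architecture of the *M. martensii* loci — six β-family genes with 13, 8,
13, 9, 10 and 2 cassettes and one α-family gene with 40 two-exon
cassettes — on **invented coordinates** (no public per-exon coordinates
exist); the matching synthetic genome is regenerated deterministically by
`cassetteseq.fixtures.fixture_genome`.

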