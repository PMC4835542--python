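# Methods

## The locus model

A `GeneLocus` is an ordered run of variable cassettes followed by the
constant (constitutive) exons, on one reference sequence. Coordinates are
0-based half-open internally; the GFF3 boundary converts from 1-based
inclusive. Cassette index 1 is the most 5′ cassette and the highest index
is adjacent to the first constant exon, matching how cassette proximity to
the constant region is discussed for these loci (the convention is not
fixed by any published coordinate set). Unit size is 2 for the α family
and 4 for β; cassettes with a different exon count are flagged as
warnings, not errors, because real loci mix duplication units. Validation
also scans codon-by-codon upstream of each cassette's annotated ATG
(window 300 nt, frame anchored at the ATG) for an in-frame stop codon —
the signature that each cassette opens its own reading frame under its
own promoter; absence is a warning ("generally located" is how the
biology is described, not an invariant). Minus-strand loci are supported
throughout; the simulator emits plus-strand only.

## Junction references and perfect-match counting

For a donor/acceptor exon pair the reference is donor suffix ++ acceptor
prefix with flank `min(read_length − min_overlap, exon_length)` per side:
125-nt reads and the 10-position rule give 230-nt references with the
breakpoint at offset 115. Candidate junctions are all ordered
variable-exon pairs plus each variable exon onto the first constant exon
(constant–constant junctions are out of scope: constant-side splicing is
taken as given). Exon–intron references are built the same way at each
variable exon's 3′ boundary, with the intron flank truncated at the next
annotated exon.

A read supports a reference iff it, or its reverse complement (library
strandedness is not assumed), equals a reference substring exactly and
covers ≥ `min_overlap` bases on each side of the breakpoint. Matching is
exact by design — no mismatches or indels — which keeps every count
reproducible against a brute-force scan (the test suite does exactly
that). Matching is seed-and-verify: every admissible start position of
every reference is indexed by a 16-mer; a candidate is verified by full
string comparison and the overlap rule.

Duplicate cassettes make junction evidence ambiguous: a read with a short
overlap into the acceptor often matches the "same" junction in several
copies. Two policies are implemented: `fractional` (1/k to each of k
matched references) and `rescue` (ambiguous reads are split in proportion
to each candidate's uniquely matching read count, falling back to 1/k
when no candidate has unique support). The pipeline uses rescue, which
empirically removes nearly all spurious cross-copy calls at 5%
divergence; a small residue remains when an entire ambiguity class has no
uniquely mapping read, so downstream consumers should treat junctions
with marginal weight accordingly. At divergence 0 every copy is
indistinguishable by construction and weight is shared evenly — the
honest answer.

## Splice classes and Ig accounting

Classes over junction keys: within-cassette neighbours are canonical;
within-cassette jumps are type I (skipping); a non-final exon spliced
straight onto the constant region skips the cassette tail and is also
type I; cross-cassette junctions are type II; any cassette's final exon
onto the first constant exon is canonical (downstream cassettes splice
into the constant region too, not only the cap-proximal one). Type III
(within-cassette intron retention) is never assigned from a key — only
from exon–intron boundary evidence at non-final exons. Boundary evidence
at cassette-final exons is between-cassette retention, reported
separately through the retention table rather than the class table.

Ig accounting, β family: each exon 2 contributes one complete Ig; each
adjacent (exon 3, exon 4) pair from one cassette contributes one; a lone
exon 3 or 4 leaves an incomplete domain. α family: each exon 2 is one Ig.
This exon→domain mapping is inferred from the three published worked
isoforms (2, 3 and 4 Ig) and is the only assignment consistent with all
three.

## Fragment quantification and allocation

Reads are tiled from their start into non-overlapping 25-nt and 50-nt
fragments (the trailing remainder is dropped; a 125-nt read yields five
25-nt and two 50-nt fragments). Fragments are mapped exactly against
per-exon targets plus the intron window downstream of each cassette-final
exon. Multi-mapped fragments are re-allocated in four tiers: (1) unique
fragment — full weight; (2) parent full-length read maps uniquely to one
of the fragment's candidates — full weight there; (3) split
proportionally to target weights estimated from all uniquely mapped
full-length reads; (4) uniform. Allocation conserves weight exactly
(Σ counts = mapped fragments) and tier occupancy is logged. The tier
scheme is this package's operationalisation of "allocate by referring to
the full-length mapping"; no published formula exists.

Tables: r.p.m. = constitutive-exon count / total mapped fragments × 10⁶
(the denominator is all fragments mapped anywhere in the analysis
reference — a deliberate, stated choice); usage = diagnostic-exon (exon
2, configurable) allocated counts renormalised per gene; top-k share with
stable tie-break; retention = mean per-base intron-window coverage
(W = 100 nt, truncated at the intron end) / mean adjacent-exon coverage,
clipped to [0, 1], flagged when the exon has no coverage. Coverage for
retention sums both fragment tilings. The 25- vs 50-nt count correlation
(Pearson and Spearman) is reported as the internal consistency check.

## Class-mixture estimation

Raw junction-read class fractions do not equal the molecule-level
mixture: a skip molecule still produces several canonical junction reads.
The estimator therefore (i) divides each junction's count by its
reference's valid-start window (the number of read start positions
satisfying the overlap rule), converting counts to molecule rates under
uniform coverage; (ii) reads each non-canonical class off the one
diagnostic event its molecules carry — exactly one skip junction (type
I), one cross-cassette junction (type II), one within-cassette
exon–intron boundary (type III), one cassette-final boundary
(between-cassette retention); and (iii) estimates the total molecule rate
from variable→constant junctions, of which every molecule has exactly
one. Canonical is the complement. This estimator is unbiased under the
generator's assumptions; its sampling error at 50,000 read pairs over six
genes is well inside ±0.03 per class.

## The simulator

`simulate_locus` copies a template unit (exons + within-cassette introns)
n times, mutating each copy at per-base divergence d (default 0.05 — no
published estimate exists, so this is an explicit assumption; d = 0
reproduces the identical-copy worst case). An in-frame TAA is planted
immediately upstream of each cassette's ATG. Default geometry: exons
130–220 nt, within-cassette introns 80–150 nt, inter-cassette intervals
150–300 nt, four constant exons of 150–400 nt.

`simulate_transcripts` draws each molecule's promoter cassette from a
promoter simplex (default geometric decay 0.85 toward the 5′ end, so the
cassette nearest the constant exons is used most — the proximity trend
seen in real tissue data), then a splicing class from a five-component
mixture: canonical, type I (skip one of exons 2..u), type II (donor exon
2..u spliced into exon 2..u of a uniformly chosen downstream cassette),
type III (one within-cassette intron retained verbatim), and
between-cassette retention (the full interval between a cassette and its
neighbour kept, both cassettes' exons present; a flag optionally splices
out the middle third of the interval, mimicking partially spliced
read-through forms). Type II and between-retention drawn for the last
cassette are resampled (no downstream cassette exists) and tallied.
Default mixture 0.76/0.08/0.08/0.04/0.04 puts non-canonical output at
24%, mid-range of the 10–40% reported for real loci. Ground truth records
every isoform structure with its molecule count, realised class counts,
per-cassette diagnostic-exon inclusion and retention fractions, and the
expected class of every junction.

`simulate_reads` samples a molecule proportionally to copy count × valid
start positions and a uniform start (uniform coverage; no GC or
positional bias, no empirical error profiles — substitution errors only),
emitting single or paired 125-nt reads whose ids encode the source
isoform. All stages draw from independent RNG streams derived from the
master seed by fixed labels, so each stage is independently reproducible
and identical seeds give byte-identical output.

What passing recovery tests shows — and does not: the simulator's reads
are uniform-coverage and (in the test conditions) error-free, its copies
diverge by i.i.d. substitutions, and its class mixture is homogeneous
across cassettes. Real libraries violate all of these (coverage bias,
indels, gene conversion between copies, tissue-specific splicing), so
recovery here demonstrates correctness of the accounting, not robustness
to every real-data artefact.

## Problem sizes and numerical choices

The end-to-end recovery test uses six β genes with 13/8/13/9/10/2
cassettes, 2,000 molecules per gene and 50,000 error-free read pairs
(seed fixed), a scale chosen so junction counts resolve every class while
the suite stays desk-sized. At this depth the per-cassette retention
estimate is noisy for weakly used cassettes — intron-window coverage
arrives in correlated fragment clusters from a handful of reads, so
per-cassette errors of ±0.05–0.1 occur at coverage below ~100 — and the
recovery test therefore checks retention pooled per gene
(coverage-weighted), where sampling error is a few thousandths; the
per-cassette estimator itself is validated separately on a targeted
high-retention cassette. Retention estimates are depth-stable (doubling
read count moves pooled rates < 0.02). Degenerate inputs: zero-variance
count vectors, all-zero usage, and zero exon coverage are flagged or
raised, never silently imputed; reads shorter than 2·min_overlap are
skipped and tallied.

## Known limitations

Exact matching means a single sequencing error destroys a junction match
(error rate enters recovery tests only through the fragment tables);
there is no spliced or gapped alignment, no base-quality model, no PCR
duplicate handling and no differential expression testing. Junction
ambiguity at divergence → 0 is fundamentally unresolvable read-by-read;
rescue allocation redistributes it but cannot recover per-copy truth.
Mates are treated independently for junction counting; pair-aware logic
could in principle rescue a few more ambiguous reads.
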