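"""Gene-locus data model for clustered-cassette genes.

A locus consists of an ordered run of tandemly arrayed 5' *variable
cassettes* — segmental-duplication units of 2 exons (alpha family, one Ig
domain per cassette) or 4 exons (beta family, two Ig domains) — followed by
the *constant* (constitutive) exons shared by every isoform. Each cassette
carries its own promoter immediately 5' of its first exon, so a transcript
is born by promoter choice and shaped by alternative splicing.

Coordinates are 0-based half-open internally; the GFF3 boundary converts
from/to 1-based inclusive. Cassette index 1 is the most 5' cassette; the
highest index sits adjacent to the first constant exon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "Exon",
    "Cassette",
    "GeneLocus",
    "ValidationRecord",
    "ValidationReport",
    "CONSTANT",
    "load_genome",
    "extract_sequence",
    "reverse_complement",
    "read_gene_model",
    "write_gene_model",
    "validate_locus",
    "isoform_space_size",
]

#: sentinel cassette_index for constitutive exons
CONSTANT = "constant"

GenomeLike = Union[str, Path, Mapping[str, str]]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Exon:
    """One exon of a locus.

    ``cassette_index`` is a 1-based cassette ordinal for variable exons or
    the string ``"constant"`` for constitutive exons. Variable exons are
    named ``e<exon_number>.<cassette_index>`` (the field's convention, e.g.
    ``e3.13`` = exon 3 of cassette 13).
    """

    cassette_index: Union[int, str]
    exon_number: int
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.cassette_index != CONSTANT and (
            not isinstance(self.cassette_index, int) or self.cassette_index < 1
        ):
            raise ValueError(f"bad cassette_index {self.cassette_index!r}")
        if self.exon_number < 1:
            raise ValueError("exon_number must be >= 1")

    @property
    def is_variable(self) -> bool:
        return self.cassette_index != CONSTANT

    @property
    def name(self) -> str:
        if self.is_variable:
            return f"e{self.exon_number}.{self.cassette_index}"
        return f"const{self.exon_number}"

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class Cassette:
    """A tandemly duplicated variable unit of 2 or 4 exons."""

    index: int
    exons: tuple[Exon, ...]
    unit_size: int

    def __post_init__(self) -> None:
        if self.unit_size not in (2, 4):
            raise ValueError("unit_size must be 2 or 4")
        if self.index < 1:
            raise ValueError("cassette index must be >= 1")

    @property
    def promoter_anchor(self) -> int:
        """Genomic position immediately 5' of exon 1 (strand-aware)."""
        first = self.exons[0].interval
        return first.start if first.strand == "+" else first.end

    @property
    def first_exon(self) -> Exon:
        return self.exons[0]

    @property
    def last_exon(self) -> Exon:
        return self.exons[-1]


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    family: str  # {"alpha", "beta"}
    cassettes: tuple[Cassette, ...]
    constant_exons: tuple[Exon, ...]
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.family not in ("alpha", "beta"):
            raise ValueError(f"family must be alpha|beta, got {self.family!r}")
        indices = [c.index for c in self.cassettes]
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError(
                f"{self.gene_id}: cassette indices must be 1..n with no gaps, "
                f"got {indices}"
            )

    @property
    def n_cassettes(self) -> int:
        return len(self.cassettes)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def variable_exons(self) -> tuple[Exon, ...]:
        """All variable exons in transcription order."""
        return tuple(e for c in self.cassettes for e in c.exons)

    def exon(self, name: str) -> Exon:
        try:
            return self._exon_index[name]
        except KeyError:
            raise KeyError(f"{self.gene_id}: no exon named {name!r}") from None

    @property
    def _exon_index(self) -> dict[str, Exon]:
        # cached lazily on the (frozen) instance
        idx = self.__dict__.get("_exon_index_cache")
        if idx is None:
            idx = {e.name: e for e in self.variable_exons + self.constant_exons}
            object.__setattr__(self, "_exon_index_cache", idx)
        return idx

    def cassette(self, index: int) -> Cassette:
        return self.cassettes[index - 1]


@dataclass(frozen=True)
class ValidationRecord:
    severity: str  # {"error", "warning", "info"}
    code: str
    message: str
    ref: str = ""


@dataclass
class ValidationReport:
    locus_id: str
    records: list[ValidationRecord] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(r.severity == "error" for r in self.records)

    def add(self, severity: str, code: str, message: str, ref: str = "") -> None:
        self.records.append(ValidationRecord(severity, code, message, ref))

    def by_severity(self, severity: str) -> list[ValidationRecord]:
        return [r for r in self.records if r.severity == severity]


# ---------------------------------------------------------------------------
# genome access


def load_genome(source: GenomeLike) -> dict[str, str]:
    """Load a genome as ``{chrom: sequence}`` from FASTA path or mapping."""
    if isinstance(source, Mapping):
        return {k: str(v).upper() for k, v in source.items()}
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(source), "fasta")
    }


def extract_sequence(interval: GenomicInterval, genome: GenomeLike) -> str:
    """Sequence of *interval* in transcription orientation.

    Minus-strand intervals are reverse-complemented.
    """
    seqs = load_genome(genome) if not isinstance(genome, dict) else genome
    if interval.chrom not in seqs:
        raise KeyError(f"chrom {interval.chrom!r} not in genome")
    chrom_seq = seqs[interval.chrom]
    if interval.end > len(chrom_seq):
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            f"exceeds chrom length {len(chrom_seq)}"
        )
    s = chrom_seq[interval.start : interval.end]
    return reverse_complement(s) if interval.strand == "-" else s


# ---------------------------------------------------------------------------
# GFF3 I/O
#
# Dialect: feature types gene and exon; gene attributes ID, family; exon
# attributes ID, Parent, cassette_index (integer or "constant"), exon_number.


def read_gene_model(
    gff3_source: Union[str, Path], fasta_source: GenomeLike | None = None
) -> list[GeneLocus]:
    """Read loci from a GFF3 gene model (and check chroms against a genome).

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention. When *fasta_source* is given, every
    referenced chrom must exist in it.
    """
    path = str(gff3_source)
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genome = load_genome(fasta_source) if fasta_source is not None else None

    loci: list[GeneLocus] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if genome is not None and gene.seqid not in genome:
            raise ValueError(
                f"gene {gene.id}: chrom {gene.seqid!r} missing from genome"
            )
        family = _require_attr(gene, "family")
        if family not in ("alpha", "beta"):
            raise ValueError(
                f"gene {gene.id} at {gene.seqid}:{gene.start}: malformed "
                f"family attribute {family!r}"
            )
        strand = gene.strand if gene.strand in ("+", "-") else "+"

        variable: dict[int, list[Exon]] = {}
        constant: list[Exon] = []
        for child in db.children(gene, featuretype="exon", order_by="start"):
            ci_raw = _require_attr(child, "cassette_index")
            en_raw = _require_attr(child, "exon_number")
            try:
                exon_number = int(en_raw)
                cassette_index: Union[int, str]
                cassette_index = CONSTANT if ci_raw == CONSTANT else int(ci_raw)
            except ValueError as exc:
                raise ValueError(
                    f"exon {child.id}: malformed attribute ({exc})"
                ) from None
            interval = GenomicInterval(
                child.seqid, child.start - 1, child.end, strand
            )
            exon = Exon(cassette_index, exon_number, interval)
            if exon.is_variable:
                variable.setdefault(int(cassette_index), []).append(exon)
            else:
                constant.append(exon)

        unit_size = 2 if family == "alpha" else 4
        cassettes = []
        for idx in sorted(variable):
            exons = _transcription_sort(variable[idx], strand)
            cassettes.append(Cassette(idx, tuple(exons), unit_size))
        constant = _transcription_sort(constant, strand)

        loci.append(
            GeneLocus(
                gene_id=gene.id,
                family=family,
                cassettes=tuple(cassettes),
                constant_exons=tuple(constant),
                interval=GenomicInterval(
                    gene.seqid, gene.start - 1, gene.end, strand
                ),
            )
        )
    loci.sort(key=lambda l: (l.interval.chrom, l.interval.start, l.gene_id))
    return loci


def _require_attr(feature: "gffutils.Feature", key: str) -> str:
    try:
        return feature.attributes[key][0]
    except (KeyError, IndexError):
        raise ValueError(
            f"feature {feature.id} at {feature.seqid}:{feature.start} is "
            f"missing required attribute {key!r}"
        ) from None


def _transcription_sort(exons: list[Exon], strand: str) -> list[Exon]:
    return sorted(
        exons, key=lambda e: e.interval.start, reverse=(strand == "-")
    )


def write_gene_model(loci: Iterable[GeneLocus], path: Union[str, Path]) -> None:
    """Write loci back to the GFF3 dialect read by :func:`read_gene_model`."""
    lines = ["##gff-version 3"]
    for locus in loci:
        iv = locus.interval
        lines.append(
            "\t".join(
                [
                    iv.chrom,
                    "cassetteseq",
                    "gene",
                    str(iv.start + 1),
                    str(iv.end),
                    ".",
                    iv.strand,
                    ".",
                    f"ID={locus.gene_id};family={locus.family}",
                ]
            )
        )
        for exon in locus.variable_exons + locus.constant_exons:
            e = exon.interval
            lines.append(
                "\t".join(
                    [
                        e.chrom,
                        "cassetteseq",
                        "exon",
                        str(e.start + 1),
                        str(e.end),
                        ".",
                        e.strand,
                        ".",
                        f"ID={locus.gene_id}.{exon.name};"
                        f"Parent={locus.gene_id};"
                        f"cassette_index={exon.cassette_index};"
                        f"exon_number={exon.exon_number}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# validation

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def validate_locus(
    locus: GeneLocus,
    genome: GenomeLike | None = None,
    *,
    stop_scan_window: int = 300,
) -> ValidationReport:
    """Structural and sequence checks on one locus.

    Checks: cassette exon counts vs unit size (warning on mismatch — real
    cassettes only *generally* carry the full unit), ordering/non-overlap
    (error), and — when a genome is supplied — an in-frame stop codon within
    ``stop_scan_window`` nt upstream of each cassette's annotated ATG, the
    signature that each cassette's reading frame opens fresh at its own
    promoter (absence is a warning).
    """
    report = ValidationReport(locus.gene_id)

    for cassette in locus.cassettes:
        if len(cassette.exons) != cassette.unit_size:
            report.add(
                "warning",
                "unit-size",
                f"cassette {cassette.index} has {len(cassette.exons)} exons, "
                f"expected {cassette.unit_size}",
                f"cassette:{cassette.index}",
            )
        numbers = [e.exon_number for e in cassette.exons]
        if numbers != sorted(numbers):
            report.add(
                "error",
                "exon-order",
                f"cassette {cassette.index} exon numbers out of order: {numbers}",
                f"cassette:{cassette.index}",
            )

    # ordering + overlap over the full exon chain in transcription direction
    chain = list(locus.variable_exons) + list(locus.constant_exons)
    for prev, cur in zip(chain, chain[1:]):
        if prev.interval.overlaps(cur.interval):
            report.add(
                "error",
                "overlap",
                f"exons {prev.name} and {cur.name} overlap",
                f"exon:{cur.name}",
            )
        elif not _precedes(prev.interval, cur.interval):
            report.add(
                "error",
                "order",
                f"exon {cur.name} does not follow {prev.name} in "
                "transcription direction",
                f"exon:{cur.name}",
            )

    if genome is not None:
        seqs = load_genome(genome)
        for cassette in locus.cassettes:
            _check_upstream_stop(cassette, seqs, stop_scan_window, report)

    return report


def _precedes(a: GenomicInterval, b: GenomicInterval) -> bool:
    if a.strand == "+":
        return a.end <= b.start
    return b.end <= a.start


def _check_upstream_stop(
    cassette: Cassette,
    genome: Mapping[str, str],
    window: int,
    report: ValidationReport,
) -> None:
    first = cassette.first_exon.interval
    chrom_seq = genome.get(first.chrom)
    if chrom_seq is None:
        report.add(
            "error",
            "missing-chrom",
            f"chrom {first.chrom!r} not in genome",
            f"cassette:{cassette.index}",
        )
        return
    # the annotated ATG sits at the 5' end of exon 1; scan codon-by-codon
    # upstream of it, in the same frame
    if first.strand == "+":
        upstream = chrom_seq[max(0, first.start - window) : first.start]
    else:
        upstream = reverse_complement(
            chrom_seq[first.end : min(len(chrom_seq), first.end + window)]
        )
    if len(upstream) < window:
        report.add(
            "warning",
            "scan-truncated",
            f"cassette {cassette.index}: upstream scan truncated to "
            f"{len(upstream)} nt",
            f"cassette:{cassette.index}",
        )
    found = False
    for pos in range(len(upstream) - 3, -1, -3):
        if upstream[pos : pos + 3] in STOP_CODONS:
            found = True
            break
    if found:
        report.add(
            "info",
            "upstream-stop",
            f"cassette {cassette.index}: in-frame stop found upstream of ATG",
            f"cassette:{cassette.index}",
        )
    else:
        report.add(
            "warning",
            "no-upstream-stop",
            f"cassette {cassette.index}: no in-frame stop within "
            f"{window} nt upstream of ATG",
            f"cassette:{cassette.index}",
        )


# ---------------------------------------------------------------------------
# combinatorics


def isoform_space_size(array_sizes: Sequence[int]) -> int:
    """Number of mutually exclusive exon combinations across tandem arrays.

    The product of per-array option counts, e.g. the four D. melanogaster
    Dscam1 arrays [12, 48, 33, 2] give 38,016 isoforms.
    """
    if len(array_sizes) == 0:
        raise ValueError("array_sizes must be non-empty")
    if any(s < 1 for s in array_sizes):
        raise ValueError("all array sizes must be >= 1")
    return math.prod(int(s) for s in array_sizes)
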