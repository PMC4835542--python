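"""Exon–exon junction reference library.

Junction-spanning reads are detected by perfect match against short
constructed references: the 3' flank of a donor exon concatenated with the
5' flank of an acceptor exon. For 125-nt reads and a 10-position overlap
rule each flank is 115 nt (read_length - min_overlap), so a full reference
is 230 nt with the breakpoint at offset 115; flanks truncate at exon
boundaries when an exon is shorter. Exon–intron references are built the
same way for the boundary between each variable exon and the sequence
immediately downstream of it, which is how retained introns are detected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

from .locus import Exon, GeneLocus, GenomicInterval, extract_sequence, load_genome

__all__ = [
    "JunctionKey",
    "JunctionRef",
    "ExonIntronRef",
    "enumerate_candidate_junctions",
    "build_junction_ref",
    "build_junction_library",
    "build_exon_intron_refs",
    "write_refs_fasta",
    "write_key_table",
]


@dataclass(frozen=True, order=True)
class JunctionKey:
    """Ordered (donor, acceptor) exon pair within one gene."""

    gene_id: str
    donor_exon: str
    acceptor_exon: str

    def __post_init__(self) -> None:
        if self.donor_exon == self.acceptor_exon:
            raise ValueError("donor and acceptor must differ")

    @property
    def label(self) -> str:
        return f"{self.gene_id}|{self.donor_exon}|{self.acceptor_exon}"


@dataclass(frozen=True)
class JunctionRef:
    """Constructed reference sequence around one junction breakpoint."""

    key: JunctionKey
    sequence: str
    breakpoint_offset: int
    left_flank: int
    right_flank: int

    def __post_init__(self) -> None:
        if self.left_flank + self.right_flank != len(self.sequence):
            raise ValueError("flanks must tile the sequence exactly")
        if self.breakpoint_offset != self.left_flank:
            raise ValueError("breakpoint_offset must equal left_flank")


@dataclass(frozen=True)
class ExonIntronRef:
    """Reference spanning a variable exon's 3' end into its downstream intron."""

    gene_id: str
    exon: str
    sequence: str
    breakpoint_offset: int
    left_flank: int
    right_flank: int
    side: str = "donor_into_intron"


def enumerate_candidate_junctions(locus: GeneLocus) -> list[JunctionKey]:
    """All candidate donor→acceptor pairs over the variable exons.

    Every ordered pair (donor 5' of acceptor in transcription direction)
    over variable exons, plus each variable exon as donor to the first
    constant exon. For V variable exons that is V(V-1)/2 + V keys, in
    deterministic (donor, acceptor) transcription order. Classification of
    the pairs into canonical / skip / cross-cassette happens downstream.
    """
    variable = locus.variable_exons
    keys = [
        JunctionKey(locus.gene_id, variable[i].name, variable[j].name)
        for i in range(len(variable))
        for j in range(i + 1, len(variable))
    ]
    if locus.constant_exons:
        first_const = locus.constant_exons[0].name
        keys.extend(
            JunctionKey(locus.gene_id, v.name, first_const) for v in variable
        )
    return keys


def flank_length(read_length: int, min_overlap: int, exon_length: int) -> int:
    """Flank size on one side: read_length - min_overlap, capped at the exon."""
    return min(read_length - min_overlap, exon_length)


def build_junction_ref(
    key: JunctionKey,
    locus: GeneLocus,
    genome,
    read_length: int = 125,
    min_overlap: int = 10,
) -> JunctionRef:
    """Build the perfect-match reference for one junction.

    donor-exon suffix ++ acceptor-exon prefix, in transcription
    orientation, with flank = min(read_length - min_overlap, exon length)
    on each side.
    """
    if not read_length > min_overlap >= 1:
        raise ValueError("require read_length > min_overlap >= 1")
    donor = locus.exon(key.donor_exon)
    acceptor = locus.exon(key.acceptor_exon)
    if donor.length == 0 or acceptor.length == 0:
        raise ValueError("zero-length exon")
    left = flank_length(read_length, min_overlap, donor.length)
    right = flank_length(read_length, min_overlap, acceptor.length)
    donor_seq = extract_sequence(donor.interval, genome)
    acceptor_seq = extract_sequence(acceptor.interval, genome)
    return JunctionRef(
        key=key,
        sequence=donor_seq[-left:] + acceptor_seq[:right],
        breakpoint_offset=left,
        left_flank=left,
        right_flank=right,
    )


def build_junction_library(
    locus: GeneLocus,
    genome,
    read_length: int = 125,
    min_overlap: int = 10,
) -> list[JunctionRef]:
    """Enumerate and build all junction references for one locus."""
    genome = load_genome(genome)
    return [
        build_junction_ref(key, locus, genome, read_length, min_overlap)
        for key in enumerate_candidate_junctions(locus)
    ]


def build_exon_intron_refs(
    locus: GeneLocus,
    genome,
    read_length: int = 125,
    min_overlap: int = 10,
) -> list[ExonIntronRef]:
    """One reference per variable exon into its downstream intronic sequence.

    The exon-side flank follows the junction rule; the intron-side flank is
    additionally truncated at the start of the next annotated exon (or the
    first constant exon).
    """
    if not read_length > min_overlap >= 1:
        raise ValueError("require read_length > min_overlap >= 1")
    genome = load_genome(genome)
    refs: list[ExonIntronRef] = []
    chain: list[Exon] = list(locus.variable_exons) + list(locus.constant_exons)
    for pos, exon in enumerate(chain):
        if not exon.is_variable:
            break
        nxt = chain[pos + 1] if pos + 1 < len(chain) else None
        iv = exon.interval
        if iv.strand == "+":
            intron_start = iv.end
            intron_end = nxt.interval.start if nxt else locus.interval.end
            gap = intron_end - intron_start
            if gap <= 0:
                continue
            right = min(read_length - min_overlap, gap)
            intron_iv = GenomicInterval(
                iv.chrom, intron_start, intron_start + right, "+"
            )
        else:
            intron_end = iv.start
            intron_start = nxt.interval.end if nxt else locus.interval.start
            gap = intron_end - intron_start
            if gap <= 0:
                continue
            right = min(read_length - min_overlap, gap)
            intron_iv = GenomicInterval(
                iv.chrom, intron_end - right, intron_end, "-"
            )
        left = flank_length(read_length, min_overlap, exon.length)
        exon_seq = extract_sequence(iv, genome)
        intron_seq = extract_sequence(intron_iv, genome)
        refs.append(
            ExonIntronRef(
                gene_id=locus.gene_id,
                exon=exon.name,
                sequence=exon_seq[-left:] + intron_seq,
                breakpoint_offset=left,
                left_flank=left,
                right_flank=right,
            )
        )
    return refs


def write_refs_fasta(
    refs: Iterable[Union[JunctionRef, ExonIntronRef]], path: Union[str, Path]
) -> None:
    """Export references as FASTA, headers ``gene|donor|acceptor|breakpoint``."""
    lines = []
    for ref in refs:
        if isinstance(ref, JunctionRef):
            header = f"{ref.key.label}|{ref.breakpoint_offset}"
        else:
            header = f"{ref.gene_id}|{ref.exon}|intron|{ref.breakpoint_offset}"
        lines.append(f">{header}")
        lines.append(ref.sequence)
    Path(path).write_text("\n".join(lines) + "\n")


def write_key_table(refs: Iterable[JunctionRef], path: Union[str, Path]) -> None:
    lines = ["gene_id\tdonor\tacceptor\tbreakpoint_offset\tlength"]
    for ref in refs:
        k = ref.key
        lines.append(
            f"{k.gene_id}\t{k.donor_exon}\t{k.acceptor_exon}\t"
            f"{ref.breakpoint_offset}\t{len(ref.sequence)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
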