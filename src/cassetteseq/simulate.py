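"""Synthetic clustered-cassette loci, transcript pools and RNA-seq reads.

The generator emulates the study system this package analyses: a gene
whose 5' end is a run of tandemly arrayed cassettes produced by segmental
duplication (a template unit copied n times and mutated at a per-base
divergence d — d = 0 gives identical copies, the hardest multi-mapping
case), each cassette preceded by its own promoter with an in-frame stop
codon planted immediately upstream of its ATG, followed by the constant
exons. Transcripts are drawn molecule by molecule: first a promoter
cassette from the promoter-weight simplex, then a splicing class from the
class mixture:

* canonical — the cassette's own exons spliced to the constant region;
* type I — one of exons 2..u skipped;
* type II — a donor exon spliced directly into a downstream cassette's
  exon, then on to the constant region;
* type III — one within-cassette intron retained verbatim;
* between-cassette retention — the full interval between a cassette and
  its downstream neighbour kept in the mature transcript (both cassettes'
  exons present), the read-through form seen at cassette boundaries.

Reads are uniform-coverage, optionally paired and error-prone, with ids
that encode the source isoform so every downstream estimate can be
checked against ground truth.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .classify import IsoformStructure, JunctionClass, classify_junction
from .junctions import JunctionKey
from .locus import (
    CONSTANT,
    Cassette,
    Exon,
    GeneLocus,
    GenomicInterval,
    extract_sequence,
    reverse_complement,
)
from .mapping import ReadRecord

__all__ = [
    "ClassMixture",
    "ReadModel",
    "GeneConfig",
    "SimConfig",
    "SimulatedIsoform",
    "TruthTable",
    "simulate_locus",
    "simulate_transcripts",
    "simulate_reads",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))


def _rng(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, stage label)."""
    return np.random.default_rng([int(seed), zlib.crc32(label.encode())])


@dataclass(frozen=True)
class ClassMixture:
    """Probability simplex over splicing classes of a molecule."""

    canonical: float = 0.76
    type_i: float = 0.08
    type_ii: float = 0.08
    type_iii: float = 0.04
    between_retention: float = 0.04

    def __post_init__(self) -> None:
        probs = self.as_tuple()
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"class mixture must be a simplex, got {probs}")

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.canonical,
            self.type_i,
            self.type_ii,
            self.type_iii,
            self.between_retention,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "canonical": self.canonical,
            "type_i": self.type_i,
            "type_ii": self.type_ii,
            "type_iii": self.type_iii,
            "between_retention": self.between_retention,
        }


CLASS_NAMES = ("canonical", "type_i", "type_ii", "type_iii", "between_retention")


@dataclass(frozen=True)
class ReadModel:
    read_length: int = 125
    paired: bool = True
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    error_rate: float = 0.0
    n_reads: int = 50000  # pairs when paired, reads otherwise

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.read_length < 1 or self.n_reads < 0:
            raise ValueError("bad read model")


@dataclass(frozen=True)
class GeneConfig:
    gene_id: str
    family: str = "beta"
    n_cassettes: int = 8
    exon_length_range: tuple[int, int] = (130, 220)
    intron_length_range: tuple[int, int] = (80, 150)
    intercassette_length_range: tuple[int, int] = (150, 300)
    divergence: float = 0.05
    promoter_decay: float = 0.85
    promoter_weights: tuple[float, ...] | None = None
    n_constant_exons: int = 4
    constant_exon_length_range: tuple[int, int] = (150, 400)

    def __post_init__(self) -> None:
        if self.family not in ("alpha", "beta"):
            raise ValueError("family must be alpha|beta")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if self.n_cassettes < 1:
            raise ValueError("need >= 1 cassette")
        if self.promoter_weights is not None:
            w = self.promoter_weights
            if len(w) != self.n_cassettes or any(x < 0 for x in w):
                raise ValueError("promoter_weights must match n_cassettes")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("promoter_weights must sum to 1")

    @property
    def unit_size(self) -> int:
        return 2 if self.family == "alpha" else 4

    def weights(self) -> np.ndarray:
        """Promoter simplex; default geometric decay toward the 5' end.

        The cassette adjacent to the constant exons (highest index) gets
        the largest weight, mirroring the proximity trend of real loci.
        """
        if self.promoter_weights is not None:
            return np.asarray(self.promoter_weights, dtype=float)
        n = self.n_cassettes
        w = self.promoter_decay ** np.arange(n - 1, -1, -1, dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class SimConfig:
    genes: tuple[GeneConfig, ...]
    mixture: ClassMixture = ClassMixture()
    read_model: ReadModel = ReadModel()
    n_molecules_per_gene: int = 2000
    partial_interval_splice: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("need at least one gene")


@dataclass(frozen=True)
class SimulatedIsoform:
    isoform_id: str
    structure: IsoformStructure
    sequence: str
    count: int
    promoter_cassette: int
    class_label: str


@dataclass
class TruthTable:
    """Ground truth of one simulated transcript pool."""

    gene_id: str
    isoforms: list[SimulatedIsoform]
    promoter_weights: dict[int, float]
    class_counts: dict[str, int]
    resampled_classes: int
    e2_inclusion: dict[int, int]  # cassette -> molecules containing exon 2
    retention: dict[int, tuple[int, int]]  # cassette -> (retained, containing)
    junction_classes: dict[JunctionKey, JunctionClass]

    @property
    def n_molecules(self) -> int:
        return sum(iso.count for iso in self.isoforms)

    def retention_rate(self, cassette_index: int) -> float:
        retained, containing = self.retention.get(cassette_index, (0, 0))
        return retained / containing if containing else 0.0


# ---------------------------------------------------------------------------
# locus simulation


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if not hit.any():
        return seq
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_locus(
    config: SimConfig, seed: int
) -> tuple[list[GeneLocus], dict[str, str]]:
    """Build loci and their genome; deterministic under (config, seed)."""
    rng = _rng(seed, "locus")
    loci: list[GeneLocus] = []
    genome: dict[str, str] = {}
    for gene_cfg in config.genes:
        locus, chrom_seq = _simulate_gene(gene_cfg, rng)
        loci.append(locus)
        genome[locus.interval.chrom] = chrom_seq
    return loci, genome


def _simulate_gene(
    cfg: GeneConfig, rng: np.random.Generator
) -> tuple[GeneLocus, str]:
    u = cfg.unit_size
    exon_lengths = [
        int(rng.integers(cfg.exon_length_range[0], cfg.exon_length_range[1] + 1))
        for _ in range(u)
    ]
    intron_lengths = [
        int(
            rng.integers(
                cfg.intron_length_range[0], cfg.intron_length_range[1] + 1
            )
        )
        for _ in range(u - 1)
    ]
    # template duplication unit: exon1, intron1, exon2, ... (exons+introns)
    template_parts = []
    for i in range(u):
        exon_seq = _random_seq(rng, exon_lengths[i])
        if i == 0:
            exon_seq = "ATG" + exon_seq[3:]
        template_parts.append(exon_seq)
        if i < u - 1:
            template_parts.append(_random_seq(rng, intron_lengths[i]))

    chrom = f"chr_{cfg.gene_id}"
    upstream_pad = 400
    parts: list[str] = [_random_seq(rng, upstream_pad)]
    pos = upstream_pad
    cassettes: list[Cassette] = []
    for idx in range(1, cfg.n_cassettes + 1):
        # in-frame stop immediately upstream of this cassette's ATG
        prev = parts[-1]
        parts[-1] = prev[:-3] + "TAA"
        exons = []
        for i in range(u):
            piece = _mutate(template_parts[2 * i], cfg.divergence, rng)
            if i == 0:
                piece = "ATG" + piece[3:]
            parts.append(piece)
            exons.append(
                Exon(
                    cassette_index=idx,
                    exon_number=i + 1,
                    interval=GenomicInterval(
                        chrom, pos, pos + len(piece), "+"
                    ),
                )
            )
            pos += len(piece)
            if i < u - 1:
                intron = _mutate(template_parts[2 * i + 1], cfg.divergence, rng)
                parts.append(intron)
                pos += len(intron)
        cassettes.append(Cassette(idx, tuple(exons), u))
        gap = int(
            rng.integers(
                cfg.intercassette_length_range[0],
                cfg.intercassette_length_range[1] + 1,
            )
        )
        parts.append(_random_seq(rng, gap))
        pos += gap

    constant_exons = []
    for i in range(cfg.n_constant_exons):
        length = int(
            rng.integers(
                cfg.constant_exon_length_range[0],
                cfg.constant_exon_length_range[1] + 1,
            )
        )
        seq = _random_seq(rng, length)
        parts.append(seq)
        constant_exons.append(
            Exon(
                cassette_index=CONSTANT,
                exon_number=i + 1,
                interval=GenomicInterval(chrom, pos, pos + length, "+"),
            )
        )
        pos += length
        if i < cfg.n_constant_exons - 1:
            gap = int(
                rng.integers(
                    cfg.intron_length_range[0], cfg.intron_length_range[1] + 1
                )
            )
            parts.append(_random_seq(rng, gap))
            pos += gap
    parts.append(_random_seq(rng, 100))
    pos += 100

    chrom_seq = "".join(parts)
    assert len(chrom_seq) == pos
    locus = GeneLocus(
        gene_id=cfg.gene_id,
        family=cfg.family,
        cassettes=tuple(cassettes),
        constant_exons=tuple(constant_exons),
        interval=GenomicInterval(chrom, 0, pos, "+"),
    )
    return locus, chrom_seq


# ---------------------------------------------------------------------------
# transcript simulation


def simulate_transcripts(
    locus: GeneLocus,
    genome: dict[str, str],
    mixture: ClassMixture,
    n_molecules: int,
    seed: int,
    promoter_weights: Sequence[float] | None = None,
    promoter_decay: float = 0.85,
    partial_interval_splice: bool = False,
) -> tuple[list[SimulatedIsoform], TruthTable]:
    """Draw a transcript pool under promoter choice x splicing class."""
    rng = _rng(seed, f"transcripts:{locus.gene_id}")
    n = locus.n_cassettes
    u = locus.cassettes[0].unit_size
    if promoter_weights is None:
        w = promoter_decay ** np.arange(n - 1, -1, -1, dtype=float)
        weights = w / w.sum()
    else:
        weights = np.asarray(promoter_weights, dtype=float)
        if weights.size != n or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("promoter_weights must be a length-n simplex")
    probs = np.asarray(mixture.as_tuple())

    structure_counter: Counter[tuple] = Counter()
    structure_meta: dict[tuple, tuple[int, str]] = {}
    resampled = 0
    for _ in range(n_molecules):
        cassette = int(rng.choice(n, p=weights)) + 1
        while True:
            cls = CLASS_NAMES[int(rng.choice(len(probs), p=probs))]
            if cls in ("type_ii", "between_retention") and cassette == n:
                resampled += 1  # no downstream cassette to splice into
                continue
            break
        parts = _draw_structure(locus, cassette, cls, u, n, rng)
        structure_counter[parts] += 1
        structure_meta.setdefault(parts, (cassette, cls))

    isoforms: list[SimulatedIsoform] = []
    for i, (parts, count) in enumerate(sorted(structure_counter.items())):
        cassette, cls = structure_meta[parts]
        structure = IsoformStructure(locus.gene_id, locus.family, parts)
        seq = _transcript_sequence(
            locus, genome, parts, partial_interval_splice
        )
        isoforms.append(
            SimulatedIsoform(
                isoform_id=f"{locus.gene_id}:iso{i:04d}",
                structure=structure,
                sequence=seq,
                count=count,
                promoter_cassette=cassette,
                class_label=cls,
            )
        )

    truth = _build_truth(locus, isoforms, weights, resampled)
    return isoforms, truth


def _draw_structure(
    locus: GeneLocus,
    cassette: int,
    cls: str,
    u: int,
    n: int,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    const_name = locus.constant_exons[0].name
    own = [f"e{i}.{cassette}" for i in range(1, u + 1)]
    if cls == "canonical":
        parts = own
    elif cls == "type_i":
        skip = int(rng.integers(2, u + 1))
        parts = [p for p in own if p != f"e{skip}.{cassette}"]
    elif cls == "type_ii":
        donor = int(rng.integers(2, u + 1))
        acceptor_cassette = cassette + 1 + int(rng.integers(0, n - cassette))
        acceptor = int(rng.integers(2, u + 1))
        parts = [f"e{i}.{cassette}" for i in range(1, donor + 1)]
        parts += [f"e{i}.{acceptor_cassette}" for i in range(acceptor, u + 1)]
    elif cls == "type_iii":
        kept = int(rng.integers(1, u))  # intron after exon `kept`
        parts = []
        for i in range(1, u + 1):
            parts.append(f"e{i}.{cassette}")
            if i == kept:
                parts.append(f"intron:e{i}.{cassette}")
    elif cls == "between_retention":
        parts = own + [f"intron:e{u}.{cassette}"]
        parts += [f"e{i}.{cassette + 1}" for i in range(1, u + 1)]
    else:  # pragma: no cover
        raise ValueError(cls)
    return tuple(parts + [const_name])


def _transcript_sequence(
    locus: GeneLocus,
    genome: dict[str, str],
    parts: tuple[str, ...],
    partial_interval_splice: bool,
) -> str:
    pieces = []
    for part in parts:
        if part.startswith("intron:"):
            seq = _downstream_intron_seq(locus, genome, part.split(":", 1)[1])
            if partial_interval_splice and len(seq) > 60:
                # splice out the middle third of the retained interval
                third = len(seq) // 3
                seq = seq[:third] + seq[2 * third :]
            pieces.append(seq)
        elif part.startswith("const"):
            for exon in locus.constant_exons:
                pieces.append(extract_sequence(exon.interval, genome))
        else:
            pieces.append(extract_sequence(locus.exon(part).interval, genome))
    return "".join(pieces)


def _downstream_intron_seq(
    locus: GeneLocus, genome: dict[str, str], exon_name: str
) -> str:
    chain = list(locus.variable_exons) + list(locus.constant_exons)
    names = [e.name for e in chain]
    i = names.index(exon_name)
    exon, nxt = chain[i], chain[i + 1]
    iv = exon.interval
    if iv.strand == "+":
        return genome[iv.chrom][iv.end : nxt.interval.start]
    return reverse_complement(genome[iv.chrom][nxt.interval.end : iv.start])


def _build_truth(
    locus: GeneLocus,
    isoforms: list[SimulatedIsoform],
    weights: np.ndarray,
    resampled: int,
) -> TruthTable:
    class_counts: Counter[str] = Counter()
    e2_inclusion: Counter[int] = Counter()
    retained: Counter[int] = Counter()
    containing: Counter[int] = Counter()
    junction_classes: dict[JunctionKey, JunctionClass] = {}
    u = locus.cassettes[0].unit_size
    for iso in isoforms:
        class_counts[iso.class_label] += iso.count
        parts = iso.structure.parts
        exon_parts = set(iso.structure.exon_parts)
        for cassette in locus.cassettes:
            if f"e2.{cassette.index}" in exon_parts:
                e2_inclusion[cassette.index] += iso.count
            if f"e{u}.{cassette.index}" in exon_parts:
                containing[cassette.index] += iso.count
            if f"intron:e{u}.{cassette.index}" in parts:
                retained[cassette.index] += iso.count
        for a, b in zip(parts, parts[1:]):
            if a.startswith("intron:") or b.startswith("intron:"):
                continue
            key = JunctionKey(locus.gene_id, a, b)
            if key not in junction_classes:
                junction_classes[key] = classify_junction(key, locus)
    return TruthTable(
        gene_id=locus.gene_id,
        isoforms=isoforms,
        promoter_weights={
            i + 1: float(weights[i]) for i in range(len(weights))
        },
        class_counts=dict(class_counts),
        resampled_classes=resampled,
        e2_inclusion=dict(e2_inclusion),
        retention={
            c.index: (retained[c.index], containing[c.index])
            for c in locus.cassettes
        },
        junction_classes=junction_classes,
    )


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    isoforms: Sequence[SimulatedIsoform],
    read_model: ReadModel,
    seed: int,
) -> list[ReadRecord]:
    """Uniform-coverage reads from a weighted isoform pool.

    Molecules are sampled proportionally to copy count times the number of
    valid start positions, so expected per-base start density is uniform
    across the pool. Read ids encode the source isoform for truth joins.
    Isoforms shorter than the span are skipped (tallied in the id space).
    """
    rng = _rng(seed, "reads")
    L = read_model.read_length
    lengths = np.array([len(iso.sequence) for iso in isoforms])
    counts = np.array([iso.count for iso in isoforms], dtype=float)
    cum_cache: dict[int, np.ndarray] = {}

    def draw(span: int) -> tuple[SimulatedIsoform | None, int]:
        cum = cum_cache.get(span)
        if cum is None:
            w = counts * np.maximum(0, lengths - span + 1)
            cum = np.cumsum(w)
            cum_cache[span] = cum
        total = cum[-1]
        if total <= 0:
            return None, 0
        idx = int(np.searchsorted(cum, rng.random() * total, side="right"))
        iso = isoforms[idx]
        start = int(rng.integers(0, len(iso.sequence) - span + 1))
        return iso, start

    reads: list[ReadRecord] = []
    if read_model.paired:
        sizes = np.maximum(
            np.round(
                rng.normal(
                    read_model.fragment_mean,
                    read_model.fragment_sd,
                    size=read_model.n_reads,
                )
            ).astype(int),
            L,
        )
        for i, fsize in enumerate(sizes):
            iso, start = draw(int(fsize))
            if iso is None:
                continue
            frag = iso.sequence[start : start + fsize]
            m1 = frag[:L]
            m2 = reverse_complement(frag[-L:])
            rid = f"{iso.isoform_id}#r{i}"
            reads.append(
                ReadRecord(rid, _with_errors(m1, read_model.error_rate, rng), 1)
            )
            reads.append(
                ReadRecord(rid, _with_errors(m2, read_model.error_rate, rng), 2)
            )
    else:
        for i in range(read_model.n_reads):
            iso, start = draw(L)
            if iso is None:
                continue
            seq = iso.sequence[start : start + L]
            reads.append(
                ReadRecord(
                    f"{iso.isoform_id}#r{i}",
                    _with_errors(seq, read_model.error_rate, rng),
                    None,
                )
            )
    return reads


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    return _mutate(seq, rate, rng)


def write_fastq(reads: Sequence[ReadRecord], path: str | Path) -> None:
    lines = []
    for r in reads:
        suffix = f"/{r.mate}" if r.mate else ""
        lines.append(f"@{r.read_id}{suffix}")
        lines.append(r.sequence)
        lines.append("+")
        lines.append("I" * len(r.sequence))
    Path(path).write_text("\n".join(lines) + "\n")
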