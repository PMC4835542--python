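"""Splice classification and Ig-domain accounting.

A junction between two variable exons is *canonical* when it joins
neighbouring exons within one cassette, or a cassette's last exon to the
first constant exon (any cassette may splice to the constant region, not
only the cap-proximal one). Non-canonical events fall into three types:

* type I  — within-cassette exon skipping (including a non-final exon
            spliced straight to the constant region, which skips the
            cassette's trailing exons);
* type II — a junction joining exons of two different cassettes;
* type III — retention of a within-cassette intron. Type III carries no
            exon–exon junction; it is assigned from exon–intron boundary
            evidence, never from a junction key.

Ig accounting: in the beta family exon 2 encodes one Ig domain and exons
3+4 of one cassette together encode a second; in the alpha family exon 2
encodes the cassette's single Ig. A lone exon 3 or exon 4 leaves an
incomplete Ig fold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .junctions import JunctionKey
from .locus import Exon, GeneLocus

__all__ = [
    "JunctionClass",
    "IsoformStructure",
    "IgCount",
    "classify_junction",
    "classify_junction_counts",
    "split_exon_intron_counts",
    "noncanonical_fraction",
    "ig_domain_count",
    "assemble_isoform_from_junction_chain",
]


class JunctionClass(Enum):
    CANONICAL = "canonical"
    TYPE_I_SKIP = "type_i_skip"
    TYPE_II_CROSS_CASSETTE = "type_ii_cross_cassette"
    TYPE_III_INTRON_RETENTION = "type_iii_intron_retention"


_INTRON_PART = re.compile(r"^intron:")


@dataclass(frozen=True)
class IsoformStructure:
    """Ordered exon (and retained-sequence) parts of one mRNA isoform.

    Parts are exon names (``e3.13``, ``const1``) or retained genomic
    sequence markers ``intron:<exon name>`` meaning the intronic sequence
    immediately downstream of that exon is kept in the mature transcript.
    """

    gene_id: str
    family: str
    parts: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError("empty isoform structure")

    @property
    def exon_parts(self) -> tuple[str, ...]:
        return tuple(p for p in self.parts if not _INTRON_PART.match(p))


@dataclass(frozen=True)
class IgCount:
    complete_ig: int
    has_incomplete: bool


def classify_junction(key: JunctionKey, locus: GeneLocus) -> JunctionClass:
    """Deterministic class label for one donor→acceptor junction key."""
    donor = locus.exon(key.donor_exon)
    acceptor = locus.exon(key.acceptor_exon)
    if not donor.is_variable:
        raise ValueError(f"donor {donor.name} is not a variable exon")
    d_cassette = locus.cassette(int(donor.cassette_index))
    if not acceptor.is_variable:
        # splicing into the constant region: canonical from any cassette's
        # last exon; from an earlier exon it skips the cassette's tail
        if donor.name == d_cassette.last_exon.name:
            return JunctionClass.CANONICAL
        return JunctionClass.TYPE_I_SKIP
    if donor.cassette_index != acceptor.cassette_index:
        return JunctionClass.TYPE_II_CROSS_CASSETTE
    if acceptor.exon_number == donor.exon_number + 1:
        return JunctionClass.CANONICAL
    if acceptor.exon_number <= donor.exon_number:
        raise ValueError(
            f"{key.label}: acceptor does not follow donor in its cassette"
        )
    return JunctionClass.TYPE_I_SKIP


def classify_junction_counts(
    junction_counts: Mapping[JunctionKey, float],
    loci: Iterable[GeneLocus],
) -> dict[str, dict[JunctionClass, float]]:
    """Aggregate junction read counts per gene and class."""
    by_gene = {l.gene_id: l for l in loci}
    out: dict[str, dict[JunctionClass, float]] = {}
    for key, count in junction_counts.items():
        locus = by_gene[key.gene_id]
        label = classify_junction(key, locus)
        gene = out.setdefault(key.gene_id, {})
        gene[label] = gene.get(label, 0.0) + count
    return out


def split_exon_intron_counts(
    exon_intron_counts: Mapping[str, float],
    loci: Iterable[GeneLocus],
) -> tuple[dict[str, float], dict[str, float]]:
    """Split exon–intron boundary counts into within- and between-cassette.

    Keys are ``gene|exon|intron`` reference ids. A boundary downstream of a
    non-final exon is within-cassette retention evidence (type III); one
    downstream of a cassette's final exon is between-cassette retention.
    Returns (within_counts, between_counts), both keyed by reference id.
    """
    by_gene = {l.gene_id: l for l in loci}
    within: dict[str, float] = {}
    between: dict[str, float] = {}
    for ref_id, count in exon_intron_counts.items():
        gene_id, exon_name, _ = ref_id.split("|")
        locus = by_gene[gene_id]
        exon = locus.exon(exon_name)
        cassette = locus.cassette(int(exon.cassette_index))
        if exon.name == cassette.last_exon.name:
            between[ref_id] = count
        else:
            within[ref_id] = count
    return within, between


def noncanonical_fraction(
    class_counts: Mapping[JunctionClass, float],
) -> dict[str, float]:
    """Non-canonical read fraction and per-class shares of one gene's counts."""
    total = float(sum(class_counts.values()))
    if total <= 0:
        raise ValueError("no classified junction events")
    shares = {
        cls.value: class_counts.get(cls, 0.0) / total for cls in JunctionClass
    }
    shares["noncanonical"] = 1.0 - shares[JunctionClass.CANONICAL.value]
    return shares


# ---------------------------------------------------------------------------
# Ig accounting

_EXON_NAME = re.compile(r"^e(\d+)\.(\d+)$")


def _parse_variable(name: str) -> tuple[int, int] | None:
    """(exon_number, cassette_index) for a variable exon name, else None."""
    m = _EXON_NAME.match(name)
    if m is None:
        return None
    return int(m.group(1)), int(m.group(2))


def ig_domain_count(structure: IsoformStructure) -> IgCount:
    """Complete Ig domains encoded by the variable region of an isoform.

    beta: each exon 2 contributes one Ig; each adjacent (exon 3, exon 4)
    pair from the same cassette contributes one Ig; a lone exon 3 or 4
    leaves an incomplete domain. alpha: each exon 2 is one Ig.
    """
    parsed = []
    for name in structure.exon_parts:
        pv = _parse_variable(name)
        if pv is None:
            if not name.startswith("const"):
                raise ValueError(f"unknown exon name {name!r}")
            continue
        parsed.append(pv)

    complete = 0
    incomplete = False
    if structure.family == "alpha":
        complete = sum(1 for n, _ in parsed if n == 2)
        if not complete:
            incomplete = True
        return IgCount(complete, incomplete)

    i = 0
    while i < len(parsed):
        n, c = parsed[i]
        if n == 1:
            i += 1
        elif n == 2:
            complete += 1
            i += 1
        elif n == 3:
            if i + 1 < len(parsed) and parsed[i + 1] == (4, c):
                complete += 1
                i += 2
            else:
                incomplete = True
                i += 1
        else:  # lone exon 4
            incomplete = True
            i += 1
    return IgCount(complete, incomplete)


# ---------------------------------------------------------------------------
# isoform assembly


def assemble_isoform_from_junction_chain(
    keys: Sequence[JunctionKey],
    locus: GeneLocus,
    start_cassette: int | None = None,
) -> IsoformStructure:
    """Reconstruct the unique isoform consistent with a chain of junctions.

    The structure starts at exon 1 of the 5'-most cassette involved (or of
    *start_cassette* for an empty chain, i.e. the canonical isoform), walks
    each junction in order filling in the canonical exons between acceptor
    and next donor, and ends at the first constant exon.
    """
    const_name = (
        locus.constant_exons[0].name if locus.constant_exons else None
    )

    def cassette_of(exon: Exon) -> int:
        return int(exon.cassette_index)

    if not keys:
        if start_cassette is None:
            raise ValueError("empty chain requires start_cassette")
        cassette = locus.cassette(start_cassette)
        parts = [e.name for e in cassette.exons]
        if const_name:
            parts.append(const_name)
        return IsoformStructure(locus.gene_id, locus.family, tuple(parts))

    ordered = sorted(
        keys,
        key=lambda k: _exon_order(locus, k.donor_exon),
    )
    first_donor = locus.exon(ordered[0].donor_exon)
    if not first_donor.is_variable:
        raise ValueError("chain must start at a variable-exon donor")
    cassette = locus.cassette(cassette_of(first_donor))
    parts: list[str] = [
        e.name
        for e in cassette.exons
        if e.exon_number <= first_donor.exon_number
    ]

    cursor = first_donor
    for i, key in enumerate(ordered):
        donor = locus.exon(key.donor_exon)
        if donor.name != cursor.name:
            raise ValueError(
                f"chain breaks at {key.label}: expected donor "
                f"{cursor.name}, got {donor.name}"
            )
        acceptor = locus.exon(key.acceptor_exon)
        if not acceptor.is_variable:
            if acceptor.name != const_name:
                raise ValueError(
                    f"{key.label}: constant acceptor must be {const_name}"
                )
            parts.append(acceptor.name)
            if i != len(ordered) - 1:
                raise ValueError("constant acceptor before end of chain")
            return IsoformStructure(locus.gene_id, locus.family, tuple(parts))
        a_cassette = locus.cassette(cassette_of(acceptor))
        if i + 1 < len(ordered):
            nxt_donor = locus.exon(ordered[i + 1].donor_exon)
            if (
                not nxt_donor.is_variable
                or cassette_of(nxt_donor) != a_cassette.index
                or nxt_donor.exon_number < acceptor.exon_number
            ):
                raise ValueError(
                    f"chain breaks after {key.label}: next donor "
                    f"{nxt_donor.name} is not downstream in cassette "
                    f"{a_cassette.index}"
                )
            parts.extend(
                e.name
                for e in a_cassette.exons
                if acceptor.exon_number <= e.exon_number <= nxt_donor.exon_number
            )
            cursor = nxt_donor
        else:
            # run to the end of the acceptor's cassette, then the constant
            parts.extend(
                e.name
                for e in a_cassette.exons
                if e.exon_number >= acceptor.exon_number
            )
            if const_name:
                parts.append(const_name)
    return IsoformStructure(locus.gene_id, locus.family, tuple(parts))


def _exon_order(locus: GeneLocus, name: str) -> int:
    chain = list(locus.variable_exons) + list(locus.constant_exons)
    for i, e in enumerate(chain):
        if e.name == name:
            return i
    raise KeyError(name)
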