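"""Perfect-match read mapping and multi-mapped fragment allocation.

Everything here is exact: a read or fragment either matches a reference
substring at full length (on either strand) or it does not. Junction
evidence only counts when the read spans the breakpoint with at least
``min_overlap`` matching bases on each side (the 10- or 25-position rule).

Reads are additionally split into 25- and 50-nt fragments for per-exon
quantification, because tandemly duplicated exons share long identical
stretches that full-length reads cannot resolve one by one. Fragments that
map to several duplicate copies are re-allocated in tiers, anchored on the
mapping of their parent full-length read.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from scipy import stats

from .junctions import ExonIntronRef, JunctionKey, JunctionRef
from .locus import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "ReadRecord",
    "FragmentRecord",
    "HitSet",
    "AllocatedCounts",
    "BreakpointMatcher",
    "match_junction_reads",
    "match_breakpoint_reads",
    "split_reads",
    "ExactIndex",
    "map_exact",
    "allocate_multimapped",
    "coverage_from_hits",
    "count_correlation",
]

VALID_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    mate: int | None = None  # 1, 2 or None for single-end

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read sequence")


@dataclass(frozen=True)
class FragmentRecord:
    parent_read_id: str
    offset: int
    length: int
    sequence: str

    @property
    def fragment_id(self) -> str:
        return f"{self.parent_read_id}:{self.offset}:{self.length}"


@dataclass(frozen=True)
class HitSet:
    """Exact full-length matches of one query against the target set."""

    query_id: str
    hits: tuple[tuple[str, int, str], ...]  # (target_id, position, strand)

    @property
    def multiplicity(self) -> int:
        return len(self.hits)

    @property
    def target_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t, _, _ in self.hits:
            seen.setdefault(t)
        return tuple(seen)


@dataclass
class AllocatedCounts:
    """Result of tiered multi-map allocation.

    ``per_target`` sums to the number of queries with at least one hit
    (weight is conserved exactly); ``tier_counts`` records how many queries
    were resolved at each tier; ``per_query`` holds each mapped query's
    target weights in input order.
    """

    per_target: dict[str, float] = field(default_factory=dict)
    tier_counts: dict[int, int] = field(default_factory=dict)
    per_query: list[tuple[str, dict[str, float]]] = field(default_factory=list)

    @property
    def total_allocated(self) -> float:
        return float(sum(self.per_target.values()))


# ---------------------------------------------------------------------------
# junction matching

RefLike = Union[JunctionRef, ExonIntronRef]


def _ref_id(ref: RefLike) -> str:
    if isinstance(ref, JunctionRef):
        return ref.key.label
    return f"{ref.gene_id}|{ref.exon}|intron"


class BreakpointMatcher:
    """Seed-and-verify perfect matcher for breakpoint-spanning reads.

    Indexes every position of every reference by a short prefix seed; a read
    is assigned to a reference when the read (or its reverse complement)
    equals the reference substring starting at an indexed position and the
    match covers >= min_overlap bases on both sides of the breakpoint.
    """

    def __init__(
        self,
        refs: Sequence[RefLike],
        min_overlap: int = 10,
        seed_length: int = 16,
    ) -> None:
        self.refs = list(refs)
        self.min_overlap = int(min_overlap)
        self.seed_length = int(seed_length)
        self._index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ri, ref in enumerate(self.refs):
            seq = ref.sequence
            bp = ref.breakpoint_offset
            k = self.seed_length
            # only starts that could ever satisfy the left-overlap rule
            for p in range(0, min(bp - self.min_overlap, len(seq) - k) + 1):
                if p < 0:
                    break
                self._index[seq[p : p + k]].append((ri, p))

    def matches(self, read_seq: str) -> set[int]:
        """Indices of refs matched by the read in either orientation."""
        out: set[int] = set()
        for seq in (read_seq, reverse_complement(read_seq)):
            if len(seq) < max(self.seed_length, 2 * self.min_overlap):
                continue
            for ri, p in self._index.get(seq[: self.seed_length], ()):
                ref = self.refs[ri]
                bp = ref.breakpoint_offset
                end = p + len(seq)
                if (
                    p <= bp - self.min_overlap
                    and end >= bp + self.min_overlap
                    and end <= len(ref.sequence)
                    and ref.sequence[p:end] == seq
                ):
                    out.add(ri)
        return out


def match_breakpoint_reads(
    reads: Iterable[ReadRecord],
    refs: Sequence[RefLike],
    min_overlap: int = 10,
    ambiguous: str = "fractional",
) -> tuple[dict[str, float], int]:
    """Count breakpoint-spanning perfect matches per reference.

    A read can match k > 1 distinct references when duplicate cassettes
    share their flanking sequence (always, at divergence 0; often for
    short overlaps at low divergence). Two policies:

    * ``fractional`` — each of the k references gets 1/k;
    * ``rescue`` — ambiguous reads are split proportionally to each
      candidate's uniquely matching read count (falling back to 1/k when
      no candidate has unique support), which stops junctions that exist
      only as near-copies of a true junction from absorbing weight.

    Returns (ref_id -> count, number of skipped short reads).
    """
    if ambiguous not in ("fractional", "rescue"):
        raise ValueError("ambiguous must be 'fractional' or 'rescue'")
    matcher = BreakpointMatcher(refs, min_overlap=min_overlap)
    skipped = 0
    match_sets: list[frozenset[int]] = []
    for read in reads:
        if len(read.sequence) < 2 * min_overlap:
            skipped += 1
            continue
        matched = matcher.matches(read.sequence)
        if matched:
            match_sets.append(frozenset(matched))
    counts: dict[str, float] = defaultdict(float)
    if ambiguous == "fractional":
        for matched in match_sets:
            w = 1.0 / len(matched)
            for ri in matched:
                counts[_ref_id(refs[ri])] += w
    else:
        unique: dict[int, float] = defaultdict(float)
        for matched in match_sets:
            if len(matched) == 1:
                unique[next(iter(matched))] += 1.0
        for matched in match_sets:
            support = [unique.get(ri, 0.0) for ri in matched]
            total = sum(support)
            if total > 0:
                for ri, s in zip(matched, support):
                    if s > 0:
                        counts[_ref_id(refs[ri])] += s / total
            else:
                for ri in matched:
                    counts[_ref_id(refs[ri])] += 1.0 / len(matched)
    if skipped:
        logger.info("match_breakpoint_reads: skipped %d short reads", skipped)
    return dict(counts), skipped


def match_junction_reads(
    reads: Iterable[ReadRecord],
    junction_refs: Sequence[JunctionRef],
    min_overlap: int = 10,
) -> dict[JunctionKey, float]:
    """Perfect-match junction read counts keyed by junction."""
    by_label = {ref.key.label: ref.key for ref in junction_refs}
    counts, _ = match_breakpoint_reads(reads, junction_refs, min_overlap)
    return {by_label[label]: c for label, c in counts.items()}


# ---------------------------------------------------------------------------
# fragmentation


def split_reads(
    reads: Iterable[ReadRecord],
    fragment_lengths: Sequence[int] = (25, 50),
) -> list[FragmentRecord]:
    """Tile each read from its start into non-overlapping fragments.

    One tiling per requested length; a trailing remainder shorter than the
    fragment length is dropped (a 125-nt read gives five 25-nt fragments
    and two 50-nt fragments).
    """
    if any(l <= 0 for l in fragment_lengths):
        raise ValueError("fragment lengths must be positive")
    fragments: list[FragmentRecord] = []
    for read in reads:
        seq = read.sequence
        rid = read.read_id if read.mate is None else f"{read.read_id}/{read.mate}"
        for flen in fragment_lengths:
            for off in range(0, len(seq) - flen + 1, flen):
                fragments.append(
                    FragmentRecord(rid, off, flen, seq[off : off + flen])
                )
    return fragments


# ---------------------------------------------------------------------------
# exact mapping


class ExactIndex:
    """Full-length exact substring lookup over a set of target sequences."""

    def __init__(self, targets: Mapping[str, str]) -> None:
        self.targets = dict(targets)
        self._by_length: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _index_for(self, length: int) -> dict[str, list[tuple[str, int]]]:
        idx = self._by_length.get(length)
        if idx is None:
            idx = defaultdict(list)
            for tid in sorted(self.targets):
                seq = self.targets[tid]
                for i in range(len(seq) - length + 1):
                    idx[seq[i : i + length]].append((tid, i))
            self._by_length[length] = idx
        return idx

    def lookup(self, query: str, allow_n: bool = False) -> HitSet:
        if not allow_n and "N" in query:
            return HitSet(query_id="", hits=())
        idx = self._index_for(len(query))
        hits = [(t, p, "+") for t, p in idx.get(query, ())]
        rc = reverse_complement(query)
        if rc != query:
            hits += [(t, p, "-") for t, p in idx.get(rc, ())]
        hits.sort()
        return HitSet(query_id="", hits=tuple(hits))


def map_exact(
    queries: Iterable[tuple[str, str]],
    targets: Mapping[str, str] | ExactIndex,
    allow_n: bool = False,
) -> list[HitSet]:
    """Map (query_id, sequence) pairs exactly onto the targets.

    Reports every full-query-length perfect match on either strand, ordered
    by (target_id, position). Queries containing N get zero hits unless
    *allow_n* is set.
    """
    index = targets if isinstance(targets, ExactIndex) else ExactIndex(targets)
    out = []
    for qid, seq in queries:
        hs = index.lookup(seq, allow_n=allow_n)
        out.append(HitSet(query_id=qid, hits=hs.hits))
    return out


# ---------------------------------------------------------------------------
# allocation


def _parent_of(query_id: str) -> str:
    # fragment ids are "<parent>:<offset>:<length>"
    return query_id.rsplit(":", 2)[0]


def allocate_multimapped(
    fragment_hits: Sequence[HitSet],
    fulllength_hits: Sequence[HitSet] = (),
    parent_of=_parent_of,
) -> AllocatedCounts:
    """Allocate fragment weight across duplicate targets, in four tiers.

    tier 1 — uniquely mapped fragment: full weight to its single target.
    tier 2 — multi-mapped fragment whose parent full-length read maps
             uniquely to one of the fragment's candidate targets: full
             weight there.
    tier 3 — split proportionally to target weights estimated from all
             uniquely mapped full-length reads.
    tier 4 — no information at all: uniform split over candidates.

    Total allocated weight equals the number of fragments with >= 1 hit.
    """
    unique_parent: dict[str, str] = {}
    fl_weights: dict[str, float] = defaultdict(float)
    for hs in fulllength_hits:
        if len(hs.target_ids) == 1:
            unique_parent[hs.query_id] = hs.target_ids[0]
            fl_weights[hs.target_ids[0]] += 1.0

    result = AllocatedCounts()
    per_target = defaultdict(float)
    tiers = defaultdict(int)
    for hs in fragment_hits:
        targets = hs.target_ids
        if not targets:
            continue
        weights: dict[str, float]
        if len(targets) == 1:
            tiers[1] += 1
            weights = {targets[0]: 1.0}
        else:
            anchor = unique_parent.get(parent_of(hs.query_id))
            if anchor is not None and anchor in targets:
                tiers[2] += 1
                weights = {anchor: 1.0}
            else:
                prior = [fl_weights.get(t, 0.0) for t in targets]
                total = sum(prior)
                if total > 0:
                    tiers[3] += 1
                    weights = {
                        t: w / total for t, w in zip(targets, prior) if w > 0
                    }
                else:
                    tiers[4] += 1
                    weights = {t: 1.0 / len(targets) for t in targets}
        for t, w in weights.items():
            per_target[t] += w
        result.per_query.append((hs.query_id, weights))

    result.per_target = dict(per_target)
    result.tier_counts = dict(sorted(tiers.items()))
    logger.info("allocation tier occupancy: %s", result.tier_counts)
    return result


def coverage_from_hits(
    fragment_hits: Sequence[HitSet],
    allocation: AllocatedCounts,
    target_lengths: Mapping[str, int],
    fragment_length_of=lambda qid: int(qid.rsplit(":", 1)[1]),
) -> dict[str, np.ndarray]:
    """Per-base coverage arrays from allocated fragment weights.

    Each fragment's per-target weight is spread over the bases it covers;
    when a fragment hits several positions within one target its weight
    there is split equally among those positions.
    """
    cov = {t: np.zeros(l, dtype=float) for t, l in target_lengths.items()}
    alloc_by_query: dict[str, dict[str, float]] = dict(allocation.per_query)
    for hs in fragment_hits:
        weights = alloc_by_query.get(hs.query_id)
        if not weights:
            continue
        flen = fragment_length_of(hs.query_id)
        pos_by_target: dict[str, list[int]] = defaultdict(list)
        for t, p, _ in hs.hits:
            pos_by_target[t].append(p)
        for t, w in weights.items():
            positions = pos_by_target.get(t)
            if not positions:
                continue
            share = w / len(positions)
            arr = cov[t]
            for p in positions:
                arr[p : p + flen] += share
    return cov


# ---------------------------------------------------------------------------
# QC


def count_correlation(
    counts_a: Sequence[float], counts_b: Sequence[float]
) -> dict[str, float]:
    """Pearson and Spearman correlation between two count vectors."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    if a.size < 3 or a.std() == 0 or b.std() == 0:
        raise ValueError("need >= 3 features with nonzero variance")
    pearson = float(stats.pearsonr(a, b).statistic)
    spearman = float(stats.spearmanr(a, b).statistic)
    return {"pearson": pearson, "spearman": spearman}
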