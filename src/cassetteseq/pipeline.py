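"""End-to-end analysis: junction counting, fragment quantification, reports.

``analyse`` runs the full desk pipeline on in-memory inputs (loci, genome,
reads) and returns every table the package produces; ``write_reports``
serialises them deterministically. The CLI wraps these two functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import (
    JunctionClass,
    classify_junction,
    classify_junction_counts,
    noncanonical_fraction,
    split_exon_intron_counts,
)
from .junctions import (
    build_exon_intron_refs,
    build_junction_library,
)
from .locus import GeneLocus, extract_sequence, reverse_complement
from .mapping import (
    ExactIndex,
    HitSet,
    ReadRecord,
    allocate_multimapped,
    count_correlation,
    coverage_from_hits,
    map_exact,
    match_breakpoint_reads,
    split_reads,
)
from .quantify import (
    cassette_usage,
    estimate_class_mixture,
    intron_retention_rate,
    top_k_share,
    transcript_rpm,
)

__all__ = ["PipelineResult", "analyse", "write_reports"]

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class PipelineResult:
    junction_table: pd.DataFrame
    class_counts: dict[str, dict[JunctionClass, float]]
    noncanonical: dict[str, dict[str, float]]
    mixture: dict[str, float]
    usage: pd.DataFrame
    expression: pd.DataFrame
    retention: pd.DataFrame
    correlations: dict[str, float]
    top10_usage: dict[str, float]
    top10_junction: dict[str, float]
    exon_counts: dict[int, dict[str, float]]
    tier_counts: dict[int, dict[int, int]]
    skipped_reads: int = 0
    extras: dict = field(default_factory=dict)


def _exon_targets(
    loci: Sequence[GeneLocus],
    genome: Mapping[str, str],
    intron_target_length: int,
) -> tuple[dict[str, str], set[str], set[str]]:
    """Target set for fragment mapping.

    One target per exon (``gene|exon``) plus one per cassette-final exon's
    downstream intron window (``gene|exon|intron``). Returns (targets,
    exon_target_ids, constant_target_ids).
    """
    targets: dict[str, str] = {}
    exon_ids: set[str] = set()
    const_ids: set[str] = set()
    for locus in loci:
        for exon in locus.variable_exons + locus.constant_exons:
            tid = f"{locus.gene_id}|{exon.name}"
            targets[tid] = extract_sequence(exon.interval, genome)
            exon_ids.add(tid)
            if not exon.is_variable:
                const_ids.add(tid)
        chain = list(locus.variable_exons) + list(locus.constant_exons)
        for pos, exon in enumerate(chain):
            if not exon.is_variable:
                break
            cassette = locus.cassette(int(exon.cassette_index))
            if exon.name != cassette.last_exon.name:
                continue
            nxt = chain[pos + 1]
            iv = exon.interval
            if iv.strand == "+":
                gap = nxt.interval.start - iv.end
                if gap <= 0:
                    continue
                seq = genome[iv.chrom][iv.end : iv.end + min(gap, intron_target_length)]
            else:
                gap = iv.start - nxt.interval.end
                if gap <= 0:
                    continue
                seq = reverse_complement(
                    genome[iv.chrom][iv.start - min(gap, intron_target_length) : iv.start]
                )
            targets[f"{locus.gene_id}|{exon.name}|intron"] = seq
    return targets, exon_ids, const_ids


def analyse(
    loci: Sequence[GeneLocus],
    genome: Mapping[str, str],
    reads: Sequence[ReadRecord],
    *,
    read_length: int = 125,
    min_overlap: int = 10,
    fragment_lengths: Sequence[int] = (25, 50),
    retention_window: int = 100,
    diagnostic_exon: int = 2,
    sample_id: str = "sample",
) -> PipelineResult:
    """Run the complete analysis on one sample."""
    junction_refs = []
    ei_refs = []
    for locus in loci:
        junction_refs.extend(
            build_junction_library(locus, genome, read_length, min_overlap)
        )
        ei_refs.extend(
            build_exon_intron_refs(locus, genome, read_length, min_overlap)
        )

    # --- junction evidence (full-length reads, perfect match) -------------
    all_refs = junction_refs + ei_refs
    raw_counts, skipped = match_breakpoint_reads(
        reads, all_refs, min_overlap, ambiguous="rescue"
    )
    key_by_label = {r.key.label: r.key for r in junction_refs}
    junction_counts = {
        key_by_label[lbl]: c
        for lbl, c in raw_counts.items()
        if lbl in key_by_label
    }
    ei_counts = {
        lbl: c for lbl, c in raw_counts.items() if lbl.endswith("|intron")
    }
    within_counts, between_counts = split_exon_intron_counts(ei_counts, loci)

    class_counts = classify_junction_counts(junction_counts, loci)
    for ref_id, c in within_counts.items():
        gene_id = ref_id.split("|")[0]
        gene = class_counts.setdefault(gene_id, {})
        gene[JunctionClass.TYPE_III_INTRON_RETENTION] = (
            gene.get(JunctionClass.TYPE_III_INTRON_RETENTION, 0.0) + c
        )
    noncanon = {}
    for gene_id, counts in class_counts.items():
        if sum(counts.values()) > 0:
            noncanon[gene_id] = noncanonical_fraction(counts)

    mixture = estimate_class_mixture(
        junction_counts,
        junction_refs,
        within_counts,
        between_counts,
        ei_refs,
        loci,
        read_length=read_length,
        min_overlap=min_overlap,
    )

    junction_rows = []
    by_gene = {l.gene_id: l for l in loci}
    for key in sorted(junction_counts, key=lambda k: k.label):
        junction_rows.append(
            {
                "gene_id": key.gene_id,
                "donor": key.donor_exon,
                "acceptor": key.acceptor_exon,
                "class": classify_junction(key, by_gene[key.gene_id]).value,
                "count": junction_counts[key],
            }
        )
    junction_table = pd.DataFrame(
        junction_rows, columns=["gene_id", "donor", "acceptor", "class", "count"]
    )

    # --- fragment quantification ------------------------------------------
    targets, exon_ids, const_ids = _exon_targets(
        loci, genome, intron_target_length=retention_window + 50
    )
    index = ExactIndex(targets)
    full_queries = [
        (
            r.read_id if r.mate is None else f"{r.read_id}/{r.mate}",
            r.sequence,
        )
        for r in reads
    ]
    full_hits = map_exact(full_queries, index)

    exon_counts: dict[int, dict[str, float]] = {}
    tier_counts: dict[int, dict[int, int]] = {}
    allocations = {}
    frag_hits_by_len = {}
    extras_alloc: dict[int, tuple[float, int]] = {}
    for flen in fragment_lengths:
        fragments = split_reads(reads, [flen])
        frag_hits = map_exact(
            ((f.fragment_id, f.sequence) for f in fragments), index
        )
        # re-attach query ids (map_exact preserves input order)
        frag_hits = [
            HitSet(query_id=f.fragment_id, hits=h.hits)
            for f, h in zip(fragments, frag_hits)
        ]
        alloc = allocate_multimapped(frag_hits, full_hits)
        allocations[flen] = alloc
        frag_hits_by_len[flen] = frag_hits
        extras_alloc[flen] = (
            alloc.total_allocated,
            sum(1 for h in frag_hits if h.hits),
        )
        exon_counts[flen] = {
            t: c for t, c in alloc.per_target.items() if t in exon_ids
        }
        tier_counts[flen] = alloc.tier_counts

    primary_len = fragment_lengths[0]
    alloc_primary = allocations[primary_len]

    # correlation between the two fragment tilings over all exon targets
    correlations: dict[str, float] = {}
    if len(fragment_lengths) >= 2:
        a_len, b_len = fragment_lengths[0], fragment_lengths[1]
        feats = sorted(exon_ids)
        va = [exon_counts[a_len].get(t, 0.0) for t in feats]
        vb = [exon_counts[b_len].get(t, 0.0) for t in feats]
        try:
            correlations = count_correlation(va, vb)
        except ValueError:
            correlations = {"pearson": float("nan"), "spearman": float("nan")}

    # expression (r.p.m. over constitutive exons, primary tiling)
    const_per_gene: dict[str, float] = {l.gene_id: 0.0 for l in loci}
    for tid, c in alloc_primary.per_target.items():
        if tid in const_ids:
            const_per_gene[tid.split("|")[0]] += c
    expression = transcript_rpm(
        const_per_gene, alloc_primary.total_allocated, sample_id
    )

    usage = cassette_usage(
        exon_counts[primary_len], loci, diagnostic_exon, sample_id
    )

    # retention from combined per-base coverage of both tilings
    target_lengths = {t: len(s) for t, s in targets.items()}
    combined_cov: dict[str, np.ndarray] = {
        t: np.zeros(l) for t, l in target_lengths.items()
    }
    for flen in fragment_lengths:
        cov = coverage_from_hits(
            frag_hits_by_len[flen], allocations[flen], target_lengths
        )
        for t, arr in cov.items():
            combined_cov[t] += arr
    exon_cov = {t: a for t, a in combined_cov.items() if t in exon_ids}
    intron_cov = {
        t: a for t, a in combined_cov.items() if t.endswith("|intron")
    }
    retention = intron_retention_rate(
        exon_cov, intron_cov, loci, window=retention_window, sample_id=sample_id
    )

    # top-10 shares, both units the field argues about
    top10_usage = {}
    top10_junction = {}
    for locus in loci:
        gene_usage = usage[usage.gene_id == locus.gene_id]
        vals = gene_usage.diagnostic_count.to_numpy()
        if vals.sum() > 0:
            top10_usage[locus.gene_id] = top_k_share(vals, 10)
        jc = [
            c
            for k, c in junction_counts.items()
            if k.gene_id == locus.gene_id
        ]
        if jc and sum(jc) > 0:
            top10_junction[locus.gene_id] = top_k_share(jc, 10)

    return PipelineResult(
        junction_table=junction_table,
        class_counts=class_counts,
        noncanonical=noncanon,
        mixture=mixture,
        usage=usage,
        expression=expression,
        retention=retention,
        correlations=correlations,
        top10_usage=top10_usage,
        top10_junction=top10_junction,
        exon_counts=exon_counts,
        tier_counts=tier_counts,
        skipped_reads=skipped,
        extras={"allocation": extras_alloc},
    )


def write_reports(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write junctions/usage/expression/retention TSVs and summary.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "junctions": outdir / "junctions.tsv",
        "usage": outdir / "usage.tsv",
        "expression": outdir / "expression.tsv",
        "retention": outdir / "retention.tsv",
        "summary": outdir / "summary.json",
    }
    result.junction_table.to_csv(paths["junctions"], sep="\t", index=False)
    result.usage.to_csv(paths["usage"], sep="\t", index=False)
    result.expression.to_csv(paths["expression"], sep="\t", index=False)
    result.retention.to_csv(paths["retention"], sep="\t", index=False)

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "mixture_estimate": result.mixture,
        "noncanonical": result.noncanonical,
        "class_counts": {
            g: {cls.value: c for cls, c in counts.items()}
            for g, counts in sorted(result.class_counts.items())
        },
        "correlations": result.correlations,
        "top10_usage_share": result.top10_usage,
        "top10_junction_share": result.top10_junction,
        "tier_counts": {
            str(k): v for k, v in sorted(result.tier_counts.items())
        },
        "skipped_reads": result.skipped_reads,
        "usage_vectors": {
            gene: df.sort_values("cassette_index").usage.round(6).tolist()
            for gene, df in result.usage.groupby("gene_id")
        },
    }
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))
    return paths
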