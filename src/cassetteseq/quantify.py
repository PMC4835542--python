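"""Expression tables: r.p.m., cassette usage, top-k share, intron retention,
and class-mixture estimation from junction evidence.

Quantities mirror how clustered-cassette loci are read out in practice:

* per-gene expression as reads per million mapped (r.p.m.) over the
  constitutive exons, the only features shared by every isoform;
* per-cassette usage from a *diagnostic exon* (exon 2 by default): the
  allocated diagnostic-exon counts renormalised to a simplex per gene;
* intron retention as the ratio of mean per-base coverage over the first
  W nt of the intron downstream of a cassette's final exon to the mean
  coverage of that exon, clipped to [0, 1];
* the splicing-class mixture, estimated by normalising each junction's
  read count by its reference's valid-start window and reading each
  non-canonical class off its unique diagnostic event (see
  :func:`estimate_class_mixture`).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import JunctionClass, classify_junction
from .junctions import ExonIntronRef, JunctionKey, JunctionRef
from .locus import GeneLocus

__all__ = [
    "transcript_rpm",
    "cassette_usage",
    "top_k_share",
    "intron_retention_rate",
    "valid_start_window",
    "estimate_class_mixture",
]


def transcript_rpm(
    constitutive_counts: Mapping[str, float],
    total_mapped: float,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Per-gene r.p.m. from allocated constitutive-exon counts.

    rpm = constitutive_read_count / total_mapped * 1e6, where total_mapped
    is the number of fragments mapped anywhere in the analysis reference.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    rows = [
        {
            "gene_id": gene,
            "sample_id": sample_id,
            "constitutive_read_count": float(count),
            "total_mapped": float(total_mapped),
            "rpm": float(count) / float(total_mapped) * 1e6,
        }
        for gene, count in sorted(constitutive_counts.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "sample_id",
            "constitutive_read_count",
            "total_mapped",
            "rpm",
        ],
    )


def cassette_usage(
    exon_counts: Mapping[str, float],
    loci: Iterable[GeneLocus],
    diagnostic_exon_number: int = 2,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Per-cassette usage simplex from diagnostic-exon allocated counts.

    *exon_counts* is keyed ``gene|exon_name``. Per (gene, sample) the
    diagnostic-exon counts are renormalised to sum to one; a gene whose
    counts are all zero gets NaN usage and ``flagged=True``.
    """
    rows = []
    for locus in loci:
        counts = []
        for cassette in locus.cassettes:
            key = f"{locus.gene_id}|e{diagnostic_exon_number}.{cassette.index}"
            counts.append(float(exon_counts.get(key, 0.0)))
        total = sum(counts)
        for cassette, count in zip(locus.cassettes, counts):
            rows.append(
                {
                    "gene_id": locus.gene_id,
                    "sample_id": sample_id,
                    "cassette_index": cassette.index,
                    "diagnostic_count": count,
                    "usage": count / total if total > 0 else np.nan,
                    "flagged": total <= 0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "sample_id",
            "cassette_index",
            "diagnostic_count",
            "usage",
            "flagged",
        ],
    )


def top_k_share(values: Sequence[float], k: int) -> float:
    """Share of the k largest usage values (ties broken by input order)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    v = np.asarray(values, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("values sum to zero")
    order = np.argsort(-v, kind="stable")
    return float(v[order[: min(k, v.size)]].sum() / total)


def intron_retention_rate(
    exon_coverage: Mapping[str, np.ndarray],
    intron_coverage: Mapping[str, np.ndarray],
    loci: Iterable[GeneLocus],
    window: int = 100,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Retention of sequence downstream of each cassette's final exon.

    Coverage maps are keyed ``gene|exon`` and ``gene|exon|intron``. The
    rate is mean per-base coverage over the first *window* nt of the
    intron (truncated at the intron end) divided by mean coverage of the
    adjacent exon, clipped to [0, 1]; zero exon coverage flags the row.
    """
    rows = []
    for locus in loci:
        for cassette in locus.cassettes:
            exon = cassette.last_exon
            exon_key = f"{locus.gene_id}|{exon.name}"
            intron_key = f"{locus.gene_id}|{exon.name}|intron"
            if exon_key not in exon_coverage or intron_key not in intron_coverage:
                continue
            exon_cov = float(np.mean(exon_coverage[exon_key]))
            icov = intron_coverage[intron_key][:window]
            intron_cov = float(np.mean(icov)) if icov.size else 0.0
            rate = (
                min(1.0, intron_cov / exon_cov) if exon_cov > 0 else np.nan
            )
            rows.append(
                {
                    "gene_id": locus.gene_id,
                    "cassette_index": cassette.index,
                    "sample_id": sample_id,
                    "exon_coverage": exon_cov,
                    "intron_coverage": intron_cov,
                    "retention_rate": rate,
                    "flagged": exon_cov <= 0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "cassette_index",
            "sample_id",
            "exon_coverage",
            "intron_coverage",
            "retention_rate",
            "flagged",
        ],
    )


# ---------------------------------------------------------------------------
# class-mixture estimation


def valid_start_window(
    ref: JunctionRef | ExonIntronRef, read_length: int, min_overlap: int
) -> int:
    """Number of read start positions that satisfy the overlap rule.

    A read of length L starting at p on the reference spans the breakpoint
    with >= min_overlap on each side iff
    max(0, bp + m - L) <= p <= min(bp - m, len - L).
    """
    bp = ref.breakpoint_offset
    lo = max(0, bp + min_overlap - read_length)
    hi = min(bp - min_overlap, len(ref.sequence) - read_length)
    return max(0, hi - lo + 1)


def estimate_class_mixture(
    junction_counts: Mapping[JunctionKey, float],
    junction_refs: Sequence[JunctionRef],
    within_intron_counts: Mapping[str, float],
    between_intron_counts: Mapping[str, float],
    exon_intron_refs: Sequence[ExonIntronRef],
    loci: Iterable[GeneLocus],
    read_length: int = 125,
    min_overlap: int = 10,
) -> dict[str, float]:
    """Estimate the molecule-level splicing-class mixture from read counts.

    Raw junction-read class fractions do not equal the molecule mixture: a
    skip molecule, say, still produces several canonical junction reads.
    Instead each count is first converted to a molecule *rate* by dividing
    by its reference's valid-start window (read starts supporting the
    event are uniform along molecules). Then:

    * every molecule splices exactly one variable exon to the first
      constant exon, so the summed rate over variable→constant junctions
      estimates the total molecule rate;
    * a type I molecule carries exactly one skip junction, a type II
      molecule exactly one cross-cassette junction, and a type III
      molecule exactly one within-cassette exon–intron boundary, so each
      class rate is the summed rate of its diagnostic events;
    * between-cassette retention is read the same way off boundaries at
      cassette-final exons;
    * canonical is the complement.
    """
    by_gene = {l.gene_id: l for l in loci}
    win = {
        r.key.label: valid_start_window(r, read_length, min_overlap)
        for r in junction_refs
    }
    key_by_label = {r.key.label: r.key for r in junction_refs}

    total_rate = 0.0
    rate_i = 0.0
    rate_ii = 0.0
    for key, count in junction_counts.items():
        w = win.get(key.label, 0)
        if w <= 0:
            continue
        rate = count / w
        locus = by_gene[key.gene_id]
        label = classify_junction(key, locus)
        acceptor = locus.exon(key.acceptor_exon)
        if not acceptor.is_variable:
            total_rate += rate
        if label is JunctionClass.TYPE_I_SKIP:
            rate_i += rate
        elif label is JunctionClass.TYPE_II_CROSS_CASSETTE:
            rate_ii += rate

    ei_win = {
        f"{r.gene_id}|{r.exon}|intron": valid_start_window(
            r, read_length, min_overlap
        )
        for r in exon_intron_refs
    }
    rate_iii = sum(
        c / ei_win[k] for k, c in within_intron_counts.items() if ei_win.get(k)
    )
    rate_between = sum(
        c / ei_win[k] for k, c in between_intron_counts.items() if ei_win.get(k)
    )

    if total_rate <= 0:
        raise ValueError("no variable-to-constant junction evidence")
    est = {
        "type_i": rate_i / total_rate,
        "type_ii": rate_ii / total_rate,
        "type_iii": rate_iii / total_rate,
        "between_retention": rate_between / total_rate,
    }
    est["canonical"] = 1.0 - sum(est.values())
    return est
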