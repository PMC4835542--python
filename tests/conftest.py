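"""Shared fixtures: hand-built micro-loci and small simulated data sets."""

from __future__ import annotations

import pytest

from cassetteseq.locus import CONSTANT, Cassette, Exon, GeneLocus, GenomicInterval
from cassetteseq.simulate import (
    ClassMixture,
    GeneConfig,
    ReadModel,
    SimConfig,
    simulate_locus,
    simulate_reads,
    simulate_transcripts,
)


def build_locus(
    gene_id: str,
    family: str,
    n_cassettes: int,
    exon_len: int = 120,
    intron_len: int = 40,
    gap_len: int = 80,
    n_constant: int = 2,
    const_len: int = 200,
    chrom: str | None = None,
    pad: int = 50,
) -> tuple[GeneLocus, int]:
    """Deterministic exon layout on one chrom; returns (locus, chrom length)."""
    unit = 2 if family == "alpha" else 4
    chrom = chrom or f"chr_{gene_id}"
    pos = pad
    cassettes = []
    for idx in range(1, n_cassettes + 1):
        exons = []
        for e in range(1, unit + 1):
            exons.append(
                Exon(idx, e, GenomicInterval(chrom, pos, pos + exon_len, "+"))
            )
            pos += exon_len
            if e < unit:
                pos += intron_len
        cassettes.append(Cassette(idx, tuple(exons), unit))
        pos += gap_len
    constant = []
    for i in range(1, n_constant + 1):
        constant.append(
            Exon(CONSTANT, i, GenomicInterval(chrom, pos, pos + const_len, "+"))
        )
        pos += const_len + intron_len
    locus = GeneLocus(
        gene_id=gene_id,
        family=family,
        cassettes=tuple(cassettes),
        constant_exons=tuple(constant),
        interval=GenomicInterval(chrom, 0, pos + pad, "+"),
    )
    return locus, pos + pad


def random_genome_for(locus: GeneLocus, length: int, seed: int = 0) -> dict:
    import numpy as np

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return {
        locus.interval.chrom: "".join(bases[rng.integers(0, 4, size=length)])
    }


@pytest.fixture(scope="session")
def micro_locus():
    """Tiny 2-cassette beta locus with a random genome."""
    locus, length = build_locus("mini", "beta", 2)
    return locus, random_genome_for(locus, length, seed=11)


@pytest.fixture(scope="session")
def sim_small():
    """Two simulated genes (beta + alpha) with transcripts, truth and reads."""
    cfg = SimConfig(
        genes=(
            GeneConfig(gene_id="g1", family="beta", n_cassettes=4),
            GeneConfig(gene_id="g2", family="alpha", n_cassettes=5),
        ),
        mixture=ClassMixture(),
        read_model=ReadModel(n_reads=4000),
        n_molecules_per_gene=1500,
    )
    loci, genome = simulate_locus(cfg, 42)
    isoforms = []
    truths = {}
    for locus in loci:
        iso, truth = simulate_transcripts(
            locus, genome, cfg.mixture, cfg.n_molecules_per_gene, 42
        )
        isoforms.extend(iso)
        truths[locus.gene_id] = truth
    reads = simulate_reads(isoforms, cfg.read_model, 42)
    return {
        "config": cfg,
        "loci": loci,
        "genome": genome,
        "isoforms": isoforms,
        "truths": truths,
        "reads": reads,
    }
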