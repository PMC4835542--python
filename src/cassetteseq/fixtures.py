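"""Packaged gene-model fixtures.

The GFF3 fixtures encode the cassette counts and ordering of the
M. martensii sDscam loci — six beta-family genes with 13, 8, 13, 9, 10
and 2 tandem cassettes, and one alpha-family gene with 40 two-exon
cassettes — on invented coordinates: no public per-exon coordinates exist
for these loci, so the geometry (exon/intron lengths, spacing) is
synthetic, generated deterministically by the package's own locus
simulator. The matching genome is likewise synthetic and is regenerated
on demand by :func:`fixture_genome` rather than shipped.
"""

from __future__ import annotations

from importlib.resources import files

from .locus import GeneLocus
from .simulate import GeneConfig, SimConfig, simulate_locus

__all__ = [
    "BETA_CASSETTE_COUNTS",
    "ALPHA_CASSETTE_COUNT",
    "FIXTURE_SEED",
    "fixture_path",
    "fixture_config",
    "fixture_loci",
    "fixture_genome",
]

#: per-gene cassette counts of the six beta-family loci
BETA_CASSETTE_COUNTS = (13, 8, 13, 9, 10, 2)
#: tandem copies in the single alpha-family locus
ALPHA_CASSETTE_COUNT = 40
#: seed fixing the invented fixture geometry
FIXTURE_SEED = 101


def fixture_path(name: str):
    """Path to the packaged GFF3 fixture (``beta`` or ``alpha``)."""
    if name not in ("beta", "alpha"):
        raise ValueError("fixture name must be 'beta' or 'alpha'")
    return files("cassetteseq.data").joinpath(f"mmartensii_sdscam_{name}.gff3")


def fixture_config(name: str) -> SimConfig:
    if name == "beta":
        genes = tuple(
            GeneConfig(
                gene_id=f"sdscam_beta{i + 1}",
                family="beta",
                n_cassettes=n,
            )
            for i, n in enumerate(BETA_CASSETTE_COUNTS)
        )
    elif name == "alpha":
        genes = (
            GeneConfig(
                gene_id="sdscam_alpha",
                family="alpha",
                n_cassettes=ALPHA_CASSETTE_COUNT,
            ),
        )
    else:
        raise ValueError("fixture name must be 'beta' or 'alpha'")
    return SimConfig(genes=genes)


def fixture_loci(name: str) -> tuple[list[GeneLocus], dict[str, str]]:
    """Regenerate the fixture loci and their synthetic genome."""
    return simulate_locus(fixture_config(name), FIXTURE_SEED)


def fixture_genome(name: str) -> dict[str, str]:
    """The synthetic genome matching the packaged GFF3 coordinates."""
    return fixture_loci(name)[1]
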