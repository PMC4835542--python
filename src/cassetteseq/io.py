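"""Small format helpers: FASTQ/FASTA reading for the CLI layer."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .mapping import ReadRecord
from .simulate import SimulatedIsoform

__all__ = ["read_fastq", "write_transcripts_fasta"]


def read_fastq(path: str | Path, mate: int | None = None) -> list[ReadRecord]:
    """Read a FASTQ (optionally gzipped) into ReadRecords.

    When *mate* is not given it is inferred from a ``/1`` or ``/2`` id
    suffix, which is also stripped from the read id.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    reads: list[ReadRecord] = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            rid, m = rec.id, mate
            if rid.endswith(("/1", "/2")):
                if m is None:
                    m = int(rid[-1])
                rid = rid[:-2]
            reads.append(ReadRecord(rid, str(rec.seq).upper(), m))
    return reads


def write_transcripts_fasta(
    isoforms: Iterable[SimulatedIsoform], path: str | Path
) -> None:
    lines = []
    for iso in isoforms:
        lines.append(
            f">{iso.isoform_id} count={iso.count} class={iso.class_label} "
            f"promoter_cassette={iso.promoter_cassette}"
        )
        lines.append(iso.sequence)
    Path(path).write_text("\n".join(lines) + "\n")
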