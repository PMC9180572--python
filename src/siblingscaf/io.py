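"""FASTA/FASTQ reading and writing (thin wrappers over Bio.SeqIO).

Sequences travel through the toolkit as plain ``{name: sequence}`` dicts;
these helpers are the only place file formats are touched.
"""

from __future__ import annotations

import os
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA (or FASTQ, by extension) into an ordered name->sequence dict."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
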