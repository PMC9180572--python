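"""Annotation features and GFF3 serialization.

Coordinates are 0-based half-open internally; GFF3 I/O converts to the
1-based closed convention of the format. The UMF-eligible type list is the
set of feature types counted as uniquely mappable features during contig
triage: gene, mRNA, exon, CDS, transcript, lnc_RNA, primary_transcript,
miRNA, tRNA and pseudogene annotations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

UMF_TYPES = frozenset(
    {
        "gene",
        "mRNA",
        "exon",
        "CDS",
        "transcript",
        "lnc_RNA",
        "primary_transcript",
        "miRNA",
        "tRNA",
        "pseudogene",
    }
)


@dataclass(frozen=True)
class AnnotationFeature:
    """A reference annotation feature (0-based half-open internally)."""

    id: str
    type: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    parent: str | None = None
    attributes: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.id}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def write_gff3(features: list[AnnotationFeature], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.id}"]
            if f.parent:
                attrs.append(f"Parent={f.parent}")
            attrs.extend(f"{k}={v}" for k, v in f.attributes.items())
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        "siblingscaf",
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | os.PathLike) -> list[AnnotationFeature]:
    out: list[AnnotationFeature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            fid = attrs.pop("ID", f"{cols[0]}:{cols[3]}-{cols[4]}")
            parent = attrs.pop("Parent", None)
            out.append(
                AnnotationFeature(
                    id=fid,
                    type=cols[2],
                    chrom=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6] if cols[6] in "+-" else "+",
                    parent=parent,
                    attributes=attrs,
                )
            )
    return out
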