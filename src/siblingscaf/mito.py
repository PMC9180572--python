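"""Mitogenome recovery from tandem-copy contigs.

Long-read assemblers often emit the circular mitochondrial genome as a
nuclear-style contig containing several near-identical head-to-tail copies
of the circle. This module finds that contig by similarity to a related
species' reference mitogenome, detects the tandem period by self-matching,
extracts a single circular unit, rotates it to a canonical origin, and
compares gene content between two mitogenomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anchors import align_identity, best_infix_hit, index_anchors, minimizer_positions
from .annotations import AnnotationFeature
from .util import revcomp


@dataclass
class MitoUnit:
    sequence: str
    source_contig: str
    copy_count: int
    rotation_offset: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)


def find_mito_contig(
    contigs: dict[str, str],
    ref_mito: str,
    min_similarity: float = 80.0,
    k_anchor: int = 15,
    window: int = 10,
) -> tuple[str, float] | None:
    """Contig with the best alignment of the reference mitogenome, or None.

    Candidates are ranked by shared minimizers with the reference unit
    (max_occ is raised so tandem copies are not masked), then the top
    candidates are scored by infix alignment identity of the full
    reference unit; the best above ``min_similarity`` wins.
    """
    index = index_anchors(contigs, k_anchor=k_anchor, window=window, max_occ=100)
    _, qh, _ = minimizer_positions(ref_mito, k_anchor, window)
    if qh.size == 0:
        return None
    _, sids, _, _ = index.lookup(qh)
    if sids.size == 0:
        return None
    uniq, counts = np.unique(sids, return_counts=True)
    ranked = sorted(zip(counts.tolist(), uniq.tolist()), reverse=True)[:3]
    best: tuple[float, str] | None = None
    for _, sid in ranked:
        name = index.names[sid]
        ident = max(
            align_identity(ref_mito, contigs[name], mode="HW"),
            align_identity(revcomp(ref_mito), contigs[name], mode="HW"),
        )
        if best is None or ident > best[0]:
            best = (ident, name)
    if best is None or best[0] < min_similarity:
        return None
    return best[1], best[0]


def extract_unit(
    contig: str,
    source_name: str = "",
    min_unit: int = 1_000,
    identity_floor: float = 95.0,
    k_anchor: int = 15,
    window: int = 10,
) -> MitoUnit:
    """Detect the tandem period of a contig and return one full unit.

    The period is the smallest offset p >= min_unit at which the contig
    matches itself above the identity floor over the overlap; candidates
    come from self-minimizer matches. When no period is found (a
    single-copy contig), the whole contig is returned with copy count 1.
    """
    n = len(contig)
    pos, h, strand = minimizer_positions(contig, k_anchor, window)
    candidates: list[int] = []
    if pos.size:
        order = np.argsort(h, kind="stable")
        hs, ps, ss = h[order], pos[order], strand[order]
        # offsets between same-strand occurrences of identical minimizers
        bounds = np.nonzero(np.diff(hs) != 0)[0] + 1
        offs: list[int] = []
        for grp in np.split(np.arange(hs.size), bounds):
            if grp.size < 2 or grp.size > 20:
                continue
            p_grp = np.sort(ps[grp[ss[grp] == ss[grp[0]]]])
            offs.extend(np.diff(p_grp).tolist())
        offs = [o for o in offs if o >= min_unit]
        if offs:
            uniq, counts = np.unique(offs, return_counts=True)
            # cluster nearby offsets, most-supported first, smallest period wins
            ranked = sorted(zip(uniq.tolist(), counts.tolist()),
                            key=lambda t: (-t[1], t[0]))
            seen: list[int] = []
            for off, _ in ranked[:10]:
                if all(abs(off - s) > 50 for s in seen):
                    seen.append(off)
            candidates = sorted(seen)
    for p in candidates:
        if p >= n:
            continue
        ident = align_identity(contig[: n - p], contig[p:], mode="NW")
        if ident >= identity_floor:
            return MitoUnit(
                sequence=contig[:p],
                source_contig=source_name,
                copy_count=n // p,
            )
    return MitoUnit(sequence=contig, source_contig=source_name, copy_count=1)


def rotate_canonical(unit: MitoUnit, anchor: str, identity_floor: float = 60.0) -> MitoUnit:
    """Rotate (and strand-flip if needed) the unit so ``anchor`` starts at 0.

    The anchor — typically the first annotated gene of a reference
    mitogenome — is located on the doubled unit so matches across the
    origin are found; the better strand wins.
    """
    best = None  # (identity, strand, start)
    for strand, seq in (("+", unit.sequence), ("-", revcomp(unit.sequence))):
        hit = best_infix_hit(anchor, seq + seq)
        if hit is None:
            continue
        start, _, ident = hit
        start %= len(unit.sequence)
        if best is None or ident > best[0]:
            best = (ident, strand, start)
    if best is None or best[0] < identity_floor:
        raise ValueError("anchor not found on the unit above the identity floor")
    _, strand, start = best
    seq = unit.sequence if strand == "+" else revcomp(unit.sequence)
    rotated = seq[start:] + seq[:start]
    return MitoUnit(
        sequence=rotated,
        source_contig=unit.source_contig,
        copy_count=unit.copy_count,
        rotation_offset=start,
    )


@dataclass
class GeneSimilarity:
    gene: str
    identity: float | None  # None when the gene is not locatable on unit B


def gene_similarity(
    unit_a: str,
    annot_a: list[AnnotationFeature],
    unit_b: str,
    identity_floor: float = 50.0,
) -> list[GeneSimilarity]:
    """Percent identity of each annotated gene of unit A against unit B.

    Genes are located on the doubled unit B (circularity) on both strands;
    genes below the identity floor are reported missing rather than fatal.
    """
    doubled = unit_b + unit_b
    doubled_rc = revcomp(unit_b) + revcomp(unit_b)
    out = []
    for f in annot_a:
        if f.end > len(unit_a):
            raise ValueError(f"gene {f.id} outside unit A")
        g = unit_a[f.start : f.end]
        if f.strand == "-":
            g = revcomp(g)
        best = 0.0
        for target in (doubled, doubled_rc):
            hit = best_infix_hit(g, target)
            if hit is not None:
                best = max(best, hit[2])
        out.append(
            GeneSimilarity(gene=f.id, identity=round(best, 2) if best >= identity_floor else None)
        )
    return out
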