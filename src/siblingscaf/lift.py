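"""Annotation liftover onto contigs by minimizer seeding and colinear chaining.

Each reference feature's subsequence is seeded against a contig minimizer
index; anchor matches on a contig are clustered by position, chained into
the longest colinear run per cluster, and scored with a global edlib
alignment of the chain-spanned query region against the target span. Chains
passing the identity and coverage thresholds (defaults 50%/50%) become
accepted lifts; all accepted copies of a feature are reported with a copy
index. A contig's UMF count is the number of *distinct* source features
with at least one accepted lift on it — copies of one feature count once.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .anchors import AnchorIndex, chain_matches, align_identity, index_anchors, minimizer_positions
from .annotations import UMF_TYPES, AnnotationFeature
from .util import revcomp, round_half_up

__all__ = [
    "LiftParams",
    "LiftedFeature",
    "index_anchors",
    "lift_features",
    "count_umfs",
    "retention_report",
    "location_retention",
]


@dataclass(frozen=True)
class LiftParams:
    k_anchor: int = 15
    window: int = 10
    max_occ: int = 10
    min_identity: float = 50.0
    min_coverage: float = 50.0
    min_anchors: int = 2


@dataclass
class LiftedFeature:
    """A reference feature mapped onto a contig (0-based half-open)."""

    source_id: str
    type: str
    contig: str
    start: int
    end: int
    strand: str
    copy_index: int
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 100 and 0 <= self.coverage <= 100):
            raise ValueError("identity and coverage must be percentages")


def _cluster_by_target(tpos: np.ndarray, gap: int) -> list[np.ndarray]:
    """Split sorted anchor matches into clusters separated by > gap on the target."""
    order = np.argsort(tpos, kind="stable")
    sorted_t = tpos[order]
    breaks = np.nonzero(np.diff(sorted_t) > gap)[0] + 1
    return [order[idx] for idx in np.split(np.arange(order.size), breaks)]


def lift_features(
    reference: dict[str, str],
    annotation: list[AnnotationFeature],
    contigs: dict[str, str],
    params: LiftParams = LiftParams(),
    index: AnchorIndex | None = None,
) -> list[LiftedFeature]:
    """Map UMF-eligible annotation features onto contigs.

    Only features whose type is UMF-eligible are lifted. Multiple accepted
    copies per feature are reported, ordered by score; ties between
    equal-score chains break on (contig id, position) for determinism.
    """
    for f in annotation:
        if f.chrom not in reference:
            raise ValueError(f"feature {f.id}: unknown chromosome {f.chrom}")
        if f.end > len(reference[f.chrom]):
            raise ValueError(f"feature {f.id} exceeds its chromosome bounds")
    if index is None:
        index = index_anchors(
            contigs, k_anchor=params.k_anchor, window=params.window,
            max_occ=params.max_occ,
        )
    lifted: list[LiftedFeature] = []
    for feat in annotation:
        if feat.type not in UMF_TYPES:
            continue
        qseq = reference[feat.chrom][feat.start : feat.end]
        if len(qseq) < params.k_anchor:
            continue
        qpos, qhash, qstrand = minimizer_positions(qseq, params.k_anchor, params.window)
        if qpos.size == 0:
            continue
        q_rows, sids, tpos, tstrand = index.lookup(qhash)
        if q_rows.size == 0:
            continue
        candidates = []  # (score, contig, chain)
        same = qstrand[q_rows] == tstrand
        for sid in np.unique(sids):
            m = sids == sid
            contig_name = index.names[sid]
            gap = 2 * max(len(qseq), 1000)
            for cluster in _cluster_by_target(tpos[m], gap):
                if cluster.size < params.min_anchors:
                    continue
                sel = np.nonzero(m)[0][cluster]
                chains = chain_matches(
                    qpos[q_rows[sel]], tpos[sel], same[sel], params.k_anchor,
                    contig_name,
                )
                for ch in chains:
                    if ch.n_anchors >= params.min_anchors:
                        candidates.append(ch)
        accepted = []
        lq = len(qseq)
        for ch in candidates:
            # extend the chained target span by the unchained query overhangs,
            # so a feature wholly contained in a contig is scored end to end
            if ch.strand == "+":
                ext_start = ch.t_start - ch.q_start
                ext_end = ch.t_end + (lq - ch.q_end)
            else:
                ext_start = ch.t_start - (lq - ch.q_end)
                ext_end = ch.t_end + ch.q_start
            clip_left = max(0, -ext_start)
            clip_right = max(0, ext_end - len(contigs[ch.target]))
            t_start = ext_start + clip_left
            t_end = ext_end - clip_right
            if t_end <= t_start:
                continue
            # clipped target flanks trim the corresponding query ends
            if ch.strand == "+":
                q_lo, q_hi = clip_left, lq - clip_right
            else:
                q_lo, q_hi = clip_right, lq - clip_left
            sub_q = qseq[q_lo:q_hi]
            if ch.strand == "-":
                sub_q = revcomp(sub_q)
            tseq = contigs[ch.target][t_start:t_end]
            identity = align_identity(sub_q, tseq, mode="NW")
            coverage = min(100.0, 100.0 * (q_hi - q_lo) / lq)
            if identity >= params.min_identity and coverage >= params.min_coverage:
                strand = feat.strand if ch.strand == "+" else ("-" if feat.strand == "+" else "+")
                accepted.append(
                    (
                        -ch.n_anchors,
                        ch.target,
                        t_start,
                        LiftedFeature(
                            source_id=feat.id,
                            type=feat.type,
                            contig=ch.target,
                            start=t_start,
                            end=t_end,
                            strand=strand,
                            copy_index=0,
                            identity=round(identity, 2),
                            coverage=round(coverage, 2),
                        ),
                    )
                )
        accepted.sort(key=lambda x: (x[0], x[1], x[2]))
        for ci, (_, _, _, lf) in enumerate(accepted):
            lf.copy_index = ci
            lifted.append(lf)
    return lifted


def count_umfs(lifted: list[LiftedFeature]) -> dict[str, int]:
    """Per contig, the number of distinct source features with an accepted lift."""
    per_contig: dict[str, set[str]] = {}
    for lf in lifted:
        per_contig.setdefault(lf.contig, set()).add(lf.source_id)
    return {contig: len(ids) for contig, ids in per_contig.items()}


@dataclass
class RetentionRow:
    type: str
    total: int
    lifted: int
    retained_pct: float


def retention_report(
    annotation: list[AnnotationFeature], lifted: list[LiftedFeature]
) -> list[RetentionRow]:
    """Per feature type: total, number with >=1 accepted lift, % retained.

    Types with zero annotated features are omitted. Percentages are rounded
    half-up to 2 decimals, matching how annotation-comparison tables print.
    """
    lifted_ids = {lf.source_id for lf in lifted}
    rows = []
    for ftype in sorted({f.type for f in annotation}):
        members = [f for f in annotation if f.type == ftype]
        n_lifted = sum(1 for f in members if f.id in lifted_ids)
        rows.append(
            RetentionRow(
                type=ftype,
                total=len(members),
                lifted=n_lifted,
                retained_pct=retention_pct(len(members), n_lifted),
            )
        )
    return rows


def retention_pct(total: int, lifted: int) -> float:
    """100 x lifted / total, rounded half-up to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * lifted / total, 2)


def location_retention(
    lifted: list[LiftedFeature],
    placements: dict[str, str],
    annotation: list[AnnotationFeature],
) -> tuple[dict[str, float], float]:
    """Fraction of lifted genes whose contig's assigned group matches their
    source chromosome.

    ``placements`` maps contig id -> assigned reference chromosome (or
    "unplaced"). Genes on unplaced contigs go to an "unplaced" bucket and
    are excluded from per-group denominators and the overall fraction.
    Returns (per-group fraction incl. the unplaced share of all genes,
    overall fraction over placed genes).
    """
    source_chrom = {f.id: f.chrom for f in annotation if f.type == "gene"}
    per_group_total: dict[str, int] = {}
    per_group_match: dict[str, int] = {}
    n_unplaced = 0
    seen: set[tuple[str, str]] = set()
    for lf in lifted:
        if lf.type != "gene" or lf.source_id not in source_chrom:
            continue
        key = (lf.source_id, lf.contig)
        if key in seen:
            continue
        seen.add(key)
        group = placements.get(lf.contig, "unplaced")
        if group == "unplaced":
            n_unplaced += 1
            continue
        per_group_total[group] = per_group_total.get(group, 0) + 1
        if source_chrom[lf.source_id] == group:
            per_group_match[group] = per_group_match.get(group, 0) + 1
    fractions = {
        g: per_group_match.get(g, 0) / t for g, t in sorted(per_group_total.items())
    }
    total = sum(per_group_total.values())
    overall = sum(per_group_match.values()) / total if total else 0.0
    if n_unplaced:
        fractions["unplaced"] = n_unplaced / (total + n_unplaced)
    return fractions, overall


def write_lifted_gff3(lifted: list[LiftedFeature], path: str | os.PathLike) -> None:
    """Emit lifted features as GFF3 with copy_num and identity attributes."""
    from .annotations import write_gff3

    feats = [
        AnnotationFeature(
            id=f"{lf.source_id}_{lf.copy_index}",
            type=lf.type,
            chrom=lf.contig,
            start=lf.start,
            end=lf.end,
            strand=lf.strand,
            attributes={
                "source_id": lf.source_id,
                "copy_num": str(lf.copy_index),
                "identity": f"{lf.identity:.2f}",
                "coverage": f"{lf.coverage:.2f}",
            },
        )
        for lf in lifted
    ]
    write_gff3(feats, path)
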