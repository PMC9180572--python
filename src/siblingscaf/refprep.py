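"""Reference preparation: fill N-gaps with spanning donor sequence.

Before a diverged genome's contigs are ordered against a reference, runs of
N in the reference are patched with sequence from donor reads or contigs of
the *query* species: for each gap, the two reference flanks are matched
against candidate donors; a donor whose two flank hits are colinear on one
strand, each at identity >= ``min_identity`` (default 80%, deliberately
permissive because the donors come from a diverged sibling), and separated
by at most ``max_span``, supplies its intervening sequence verbatim as the
patch. Non-gap bases are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import re

from .anchors import best_infix_hit, index_anchors, minimizer_positions
from .util import revcomp

_N_RUN = re.compile(r"N+")


@dataclass
class GapRecord:
    """One N-run in the reference (0-based half-open) and its fill outcome."""

    chrom: str
    start: int
    end: int
    status: str = "unfilled"  # or "filled"
    patch_length: int = 0
    donor: str | None = None


@dataclass(frozen=True)
class FillParams:
    flank: int = 500
    min_identity: float = 80.0
    max_span: int = 100_000
    k_anchor: int = 15
    window: int = 10
    max_donor_candidates: int = 25


def find_gaps(ref: dict[str, str], min_n: int = 1) -> list[GapRecord]:
    """Maximal runs of >= min_n N per chromosome, sorted by position."""
    out = []
    for chrom, seq in ref.items():
        for m in _N_RUN.finditer(seq):
            if m.end() - m.start() >= min_n:
                out.append(GapRecord(chrom=chrom, start=m.start(), end=m.end()))
    return out


def _candidate_donors(flank_l: str, flank_r: str, index, params) -> list[int]:
    """Donor seq ids sharing minimizers with both flanks, best-shared first."""
    votes: dict[int, int] = {}
    for flank in (flank_l, flank_r):
        _, qh, _ = minimizer_positions(flank, params.k_anchor, params.window)
        if qh.size == 0:
            return []
        _, sids, _, _ = index.lookup(qh)
        uniq, counts = np.unique(sids, return_counts=True)
        stage = dict(zip(uniq.tolist(), counts.tolist()))
        if not votes:
            votes = stage
        else:
            votes = {
                sid: min(c, stage[sid]) for sid, c in votes.items() if sid in stage
            }
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    return [sid for sid, _ in ranked[: params.max_donor_candidates]]


def fill_gaps(
    ref: dict[str, str],
    donors: dict[str, str],
    params: FillParams = FillParams(),
) -> tuple[dict[str, str], list[GapRecord]]:
    """Fill N-gaps of ``ref`` with donor sequence spanning both flanks.

    Candidate donors are shortlisted by shared minimizers with the flanks,
    then both flanks are located in each candidate (on both strands) by
    infix alignment. The best-scoring donor (highest summed flank identity,
    then longest donor, then lexicographic id) wins; its sequence between
    the flank hits replaces the N-run verbatim — no error polishing.
    Unfillable gaps are reported unfilled, never fatal.
    """
    gaps = find_gaps(ref)
    if not gaps:
        return dict(ref), []
    index = index_anchors(donors, k_anchor=params.k_anchor, window=params.window,
                          max_occ=4 * params.max_donor_candidates)
    donor_names = index.names
    filled = dict(ref)
    # process per chromosome right-to-left so earlier gap coordinates stay valid
    for gap in sorted(gaps, key=lambda g: (g.chrom, -g.start)):
        seq = filled[gap.chrom]
        fl_start = max(0, gap.start - params.flank)
        fr_end = min(len(seq), gap.end + params.flank)
        flank_l = seq[fl_start : gap.start]
        flank_r = seq[gap.end : fr_end]
        if not flank_l or not flank_r:
            continue
        best = None  # (score, -donor_len, donor_name, patch)
        for sid in _candidate_donors(flank_l, flank_r, index, params):
            dname = donor_names[sid]
            for dseq in (donors[dname], revcomp(donors[dname])):
                hit_l = best_infix_hit(flank_l, dseq)
                hit_r = best_infix_hit(flank_r, dseq)
                if hit_l is None or hit_r is None:
                    continue
                ls, le, lid = hit_l
                rs, re_, rid = hit_r
                if lid < params.min_identity or rid < params.min_identity:
                    continue
                if not (le <= rs and rs - le <= params.max_span):
                    continue
                patch = dseq[le:rs]
                if "N" in patch:
                    continue
                # higher summed flank identity wins; ties: longer donor,
                # then lexicographically smaller donor id
                key = (lid + rid, len(dseq))
                if (
                    best is None
                    or key > best[0]
                    or (key == best[0] and dname < best[1])
                ):
                    best = (key, dname, patch)
        if best is not None:
            _, dname, patch = best
            filled[gap.chrom] = seq[: gap.start] + patch + seq[gap.end :]
            gap.status = "filled"
            gap.patch_length = len(patch)
            gap.donor = dname
    return filled, sorted(gaps, key=lambda g: (g.chrom, g.start))
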