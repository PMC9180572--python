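"""Minimizer anchor indexing, colinear chaining, and pairwise alignment scoring.

This is the single alignment engine used across the toolkit: annotation
liftover, contig placement, gap-flank matching and mitogenome discovery all
seed with minimizers from the same index and score candidate regions with
edlib alignments. Minimizers follow the standard (k, w) scheme: within every
window of w consecutive k-mers the one with the smallest mixed hash of its
canonical encoding is kept. Anchors whose hash occurs more than ``max_occ``
times in the indexed sequences are dropped as repetitive, which is what keeps
satellite arrays from attracting spurious chains.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_U64_MAX = np.uint64(0xFFFFFFFFFFFFFFFF)


def encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes 0..3; non-ACGT becomes 255."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical 2-bit k-mer codes for every position of ``seq``.

    Returns (canonical codes, strand flags, validity mask); strand is True
    where the forward k-mer is the canonical one. Positions whose window
    contains a non-ACGT base are invalid. Requires k <= 31 (2 bits/base in
    a uint64) and odd k so no k-mer equals its own reverse complement.
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd for unambiguous canonicalization, got {k}")
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    b = encode_bases(seq)
    n = b.size - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return empty, np.empty(0, dtype=bool), np.empty(0, dtype=bool)
    bad = (b == 255).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[k:] - cum[:-k]) == 0
    bm = np.where(b == 255, 0, b).astype(np.uint64)
    rbm = np.uint64(3) - bm
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        fwd = (fwd << two) | bm[j : j + n]
    for j in range(k - 1, -1, -1):
        rev = (rev << two) | rbm[j : j + n]
    strand = fwd <= rev
    canon = np.where(strand, fwd, rev)
    return canon, strand, valid


def mix_hash(codes: np.ndarray) -> np.ndarray:
    """64-bit finalizer-style mix so minimizer choice is not composition-biased."""
    h = codes.copy()
    with np.errstate(over="ignore"):
        h ^= h >> np.uint64(33)
        h *= np.uint64(0xFF51AFD7ED558CCD)
        h ^= h >> np.uint64(33)
        h *= np.uint64(0xC4CEB9FE1A85EC53)
        h ^= h >> np.uint64(33)
    return h


def _trailing_min(x: np.ndarray, w: int) -> np.ndarray:
    """out[s] = min(x[s:s+w]) for s in 0..len(x)-w."""
    out = x[: x.size - w + 1].copy()
    for shift in range(1, w):
        np.minimum(out, x[shift : shift + out.size], out=out)
    return out


def minimizer_positions(seq: str, k: int, window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positions, hashes and strands of the (k, w)-minimizers of ``seq``.

    A position is selected if its k-mer hash is the minimum of at least one
    window covering it (ties select all tied positions — the robust
    minimizer convention), and its k-mer window is N-free.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    canon, strand, valid = kmer_codes(seq, k)
    if canon.size == 0:
        e = np.empty(0, dtype=np.int64)
        return e, np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    h = mix_hash(canon)
    h[~valid] = _U64_MAX
    if h.size < window:
        sel = (h == h.min()) & valid
        pos = np.nonzero(sel)[0]
        return pos, h[pos], strand[pos]
    winmin = _trailing_min(h, window)
    # covmax[i] = max over windows covering i of that window's minimum;
    # i is a minimizer iff h[i] equals it.
    covmax = np.zeros(h.size, dtype=np.uint64)
    m = winmin.size
    for s_off in range(window):
        seg = covmax[s_off : s_off + m]
        np.maximum(seg, winmin, out=seg)
    sel = (h == covmax) & valid
    pos = np.nonzero(sel)[0]
    return pos, h[pos], strand[pos]


@dataclass
class AnchorIndex:
    """Minimizer index over a set of named sequences.

    Parallel arrays sorted by hash allow vectorized binary-search lookup.
    """

    k: int
    window: int
    max_occ: int
    names: list[str]
    lengths: dict[str, int]
    hashes: np.ndarray = field(repr=False)
    seq_ids: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)
    strands: np.ndarray = field(repr=False)

    def lookup(
        self, query_hashes: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Match query minimizer hashes against the index.

        Returns (query_row, seq_id, target_pos, target_strand) with one row
        per (query hash, indexed occurrence) pair.
        """
        left = np.searchsorted(self.hashes, query_hashes, side="left")
        right = np.searchsorted(self.hashes, query_hashes, side="right")
        counts = right - left
        q_rows = np.repeat(np.arange(query_hashes.size), counts)
        if q_rows.size == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e.copy(), e.copy(), np.empty(0, dtype=bool)
        offsets = np.concatenate([np.arange(c) for c in counts if c > 0])
        idx = np.repeat(left, counts) + offsets
        return q_rows, self.seq_ids[idx], self.positions[idx], self.strands[idx]


def index_anchors(
    seqs: dict[str, str], k_anchor: int = 15, window: int = 10, max_occ: int = 10
) -> AnchorIndex:
    """Build a minimizer index, dropping anchors above the frequency ceiling."""
    if not 11 <= k_anchor <= 31:
        raise ValueError(f"k_anchor must be in [11, 31], got {k_anchor}")
    all_h, all_sid, all_pos, all_str = [], [], [], []
    names = list(seqs)
    for sid, name in enumerate(names):
        pos, h, strand = minimizer_positions(seqs[name], k_anchor, window)
        all_h.append(h)
        all_sid.append(np.full(pos.size, sid, dtype=np.int64))
        all_pos.append(pos)
        all_str.append(strand)
    h = np.concatenate(all_h) if all_h else np.empty(0, dtype=np.uint64)
    sid = np.concatenate(all_sid) if all_sid else np.empty(0, dtype=np.int64)
    pos = np.concatenate(all_pos) if all_pos else np.empty(0, dtype=np.int64)
    strand = np.concatenate(all_str) if all_str else np.empty(0, dtype=bool)
    order = np.argsort(h, kind="stable")
    h, sid, pos, strand = h[order], sid[order], pos[order], strand[order]
    if h.size:
        uniq, inv, counts = np.unique(h, return_inverse=True, return_counts=True)
        keep = counts[inv] <= max_occ
        h, sid, pos, strand = h[keep], sid[keep], pos[keep], strand[keep]
    return AnchorIndex(
        k=k_anchor,
        window=window,
        max_occ=max_occ,
        names=names,
        lengths={n: len(s) for n, s in seqs.items()},
        hashes=h,
        seq_ids=sid,
        positions=pos,
        strands=strand,
    )


@dataclass
class Chain:
    """A colinear run of anchor matches between a query and one target."""

    target: str
    strand: str  # '+' if query and target agree
    q_start: int
    q_end: int  # half-open, includes the k of the last anchor
    t_start: int
    t_end: int
    n_anchors: int


def _lis_indices(keys: np.ndarray) -> np.ndarray:
    """Indices of a longest strictly increasing subsequence (O(n log n))."""
    import bisect

    tails: list[int] = []  # value at the end of an LIS of each length
    tails_idx: list[int] = []
    prev = np.full(keys.size, -1, dtype=np.int64)
    for i, v in enumerate(keys):
        j = bisect.bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    cur = tails_idx[-1] if tails_idx else -1
    while cur != -1:
        out.append(cur)
        cur = prev[cur]
    return np.array(out[::-1], dtype=np.int64)


def chain_matches(
    qpos: np.ndarray, tpos: np.ndarray, same_strand: np.ndarray, k: int, target: str
) -> list[Chain]:
    """Chain anchor matches against one target into per-strand colinear runs.

    For each relative strand, anchors are sorted by query position and the
    longest colinear run (strictly increasing, or decreasing for '-',
    target positions) is kept. Returns the best chain per strand (at most
    two), sorted by anchor count descending then strand.
    """
    chains: list[Chain] = []
    for strand_flag, sym in ((True, "+"), (False, "-")):
        m = same_strand == strand_flag
        if not m.any():
            continue
        q, t = qpos[m], tpos[m]
        order = np.lexsort((t if strand_flag else -t, q))
        q, t = q[order], t[order]
        keys = t if strand_flag else -t
        lis = _lis_indices(keys)
        if lis.size == 0:
            continue
        qs, ts = q[lis], t[lis]
        chains.append(
            Chain(
                target=target,
                strand=sym,
                q_start=int(qs.min()),
                q_end=int(qs.max()) + k,
                t_start=int(ts.min()),
                t_end=int(ts.max()) + k,
                n_anchors=int(lis.size),
            )
        )
    chains.sort(key=lambda c: (-c.n_anchors, c.strand))
    return chains


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def align_identity(query: str, target: str, mode: str = "NW") -> float:
    """Percent identity of an edlib alignment (matches / alignment columns).

    mode 'NW' is global; 'HW' aligns the whole query to the best infix of
    the target. Returns 0.0 for empty input.
    """
    if not query or not target:
        return 0.0
    res = edlib.align(query, target, mode=mode, task="path")
    cols = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    if cols == 0:
        return 0.0
    return 100.0 * (cols - res["editDistance"]) / cols


def best_infix_hit(query: str, target: str) -> tuple[int, int, float] | None:
    """Best infix alignment of ``query`` within ``target``.

    Returns (start, end, identity%) with end exclusive, or None when either
    side is empty.
    """
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="HW", task="path")
    if not res["locations"]:
        return None
    start, end = res["locations"][0]
    cols = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    ident = 100.0 * (cols - res["editDistance"]) / cols if cols else 0.0
    return int(start), int(end) + 1, ident
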