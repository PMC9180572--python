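"""Satellite and interspersed repeat annotation.

Monomer hits are found by a seed-and-extend scan: exact k-mer seed matches
between the query (a satellite monomer or a library element) and the target
vote for candidate alignment start positions on each strand; vote clusters
are verified with an infix edlib alignment and kept only when both percent
identity and query coverage are *strictly greater* than their thresholds
(default 70/70). Overlapping hits are resolved to a non-overlapping tiling
greedily, best score first.

Satellite hits on one target are merged into arrays when consecutive hits
are separated by at most ``max_gap_frac`` monomer lengths; an array must
contain at least ``min_monomers`` (default 5) hits — shorter tandem runs
are not called arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anchors import _CIGAR_RE, kmer_codes
from .util import revcomp, round_half_up

import edlib


@dataclass
class MonomerHit:
    target: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float

    @property
    def score(self) -> float:
        return self.identity * (self.end - self.start)


@dataclass
class RepeatArray:
    target: str
    start: int
    end: int
    n_monomers: int
    mean_identity: float
    strand: str  # consensus strand of member hits


@dataclass
class RepeatElement:
    family: str
    class_label: str
    target: str
    start: int
    end: int
    strand: str
    identity: float


@dataclass
class RepeatAnnotation:
    elements: list[RepeatElement] = field(default_factory=list)

    def per_class(self) -> dict[str, tuple[int, int]]:
        """class -> (count, total bp)."""
        out: dict[str, list[int]] = {}
        for e in self.elements:
            c = out.setdefault(e.class_label, [0, 0])
            c[0] += 1
            c[1] += e.end - e.start
        return {k: (v[0], v[1]) for k, v in sorted(out.items())}

    def per_family(self) -> dict[str, tuple[int, int]]:
        """family -> (count, total bp)."""
        out: dict[str, list[int]] = {}
        for e in self.elements:
            c = out.setdefault(e.family, [0, 0])
            c[0] += 1
            c[1] += e.end - e.start
        return {k: (v[0], v[1]) for k, v in sorted(out.items())}


def _seed_votes(target_seq: str, query: str, k_seed: int) -> dict[str, dict[int, int]]:
    """Vote for candidate query-alignment start positions per strand."""
    tq, ts, tv = kmer_codes(target_seq, k_seed)
    qq, qs, qv = kmer_codes(query, k_seed)
    votes: dict[str, dict[int, int]] = {"+": {}, "-": {}}
    if tq.size == 0 or qq.size == 0:
        return votes
    order = np.argsort(qq[qv], kind="stable")
    q_codes = qq[qv][order]
    q_pos = np.arange(qq.size)[qv][order]
    q_str = qs[qv][order]
    t_idx = np.nonzero(tv)[0]
    left = np.searchsorted(q_codes, tq[t_idx], side="left")
    right = np.searchsorted(q_codes, tq[t_idx], side="right")
    counts = right - left
    has = counts > 0
    t_rows = np.repeat(t_idx[has], counts[has])
    offs = np.concatenate([np.arange(c) for c in counts[has]]) if has.any() else np.empty(0, int)
    qi = np.repeat(left[has], counts[has]) + offs
    if t_rows.size == 0:
        return votes
    same = ts[t_rows] == q_str[qi]
    m = len(query)
    s_fwd = t_rows[same] - q_pos[qi[same]]
    s_rev = t_rows[~same] - (m - (q_pos[qi[~same]] + k_seed))
    for strand, starts in (("+", s_fwd), ("-", s_rev)):
        if starts.size:
            uniq, cnt = np.unique(starts, return_counts=True)
            votes[strand] = dict(zip(uniq.tolist(), cnt.tolist()))
    return votes


def _cluster_starts(votes: dict[int, int], min_sep: int) -> list[int]:
    """Collapse nearby vote positions, keeping the best-voted representative."""
    if not votes:
        return []
    starts = sorted(votes)
    clusters: list[list[int]] = [[starts[0]]]
    for s in starts[1:]:
        if s - clusters[-1][-1] <= min_sep:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    return [max(cl, key=lambda s: (votes[s], -s)) for cl in clusters]


def _verify_hit(
    target_seq: str, query: str, start: int, strand: str, pad: int
) -> tuple[int, int, float, float] | None:
    """Align the (oriented) query around a candidate start; return hit coords,
    identity and target-span query coverage."""
    m = len(query)
    lo = max(0, start - pad)
    hi = min(len(target_seq), start + m + pad)
    window = target_seq[lo:hi]
    if not window:
        return None
    q = query if strand == "+" else revcomp(query)
    res = edlib.align(q, window, mode="HW", task="path")
    if not res["locations"]:
        return None
    ws, we = res["locations"][0]
    cols = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    if cols == 0:
        return None
    identity = 100.0 * (cols - res["editDistance"]) / cols
    hit_start, hit_end = lo + ws, lo + we + 1
    coverage = min(100.0, 100.0 * (hit_end - hit_start) / m)
    return hit_start, hit_end, identity, coverage


def _greedy_tile(hits: list[MonomerHit], max_overlap: int) -> list[MonomerHit]:
    """Best-score-first selection of hits overlapping by at most max_overlap."""
    chosen: list[MonomerHit] = []
    occupied: list[tuple[int, int]] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.start, h.strand)):
        if all(
            min(h.end, e) - max(h.start, s) <= max_overlap for s, e in occupied
        ):
            chosen.append(h)
            occupied.append((h.start, h.end))
    chosen.sort(key=lambda h: h.start)
    return chosen


def find_monomer_hits(
    targets: dict[str, str],
    monomer: str,
    min_identity: float = 70.0,
    min_coverage: float = 70.0,
    k_seed: int = 11,
    min_votes: int = 2,
) -> list[MonomerHit]:
    """Locate monomer copies in the targets on both strands.

    Thresholds are strict: a hit at exactly ``min_identity`` or
    ``min_coverage`` is rejected.
    """
    if set(monomer) - set("ACGT"):
        raise ValueError("monomer must contain only ACGT")
    if len(monomer) < 20:
        raise ValueError("monomer must be at least 20 bp")
    m = len(monomer)
    out: list[MonomerHit] = []
    for name, seq in targets.items():
        votes = _seed_votes(seq, monomer, k_seed)
        raw: list[MonomerHit] = []
        for strand in "+-":
            strand_votes = {
                s: v for s, v in votes[strand].items() if v >= min_votes
            }
            for cand in _cluster_starts(strand_votes, min_sep=max(5, m // 8)):
                v = _verify_hit(seq, monomer, cand, strand, pad=max(10, m // 8))
                if v is None:
                    continue
                hs, he, ident, cov = v
                if ident > min_identity and cov > min_coverage:
                    raw.append(MonomerHit(name, hs, he, strand, ident, cov))
        out.extend(_greedy_tile(raw, max_overlap=max(2, m // 10)))
    out.sort(key=lambda h: (h.target, h.start))
    return out


def merge_arrays(
    hits: list[MonomerHit],
    monomer_len: int,
    min_monomers: int = 5,
    max_gap_frac: float = 0.5,
) -> list[RepeatArray]:
    """Chain consecutive same-target hits into arrays of >= min_monomers."""
    max_gap = max_gap_frac * monomer_len
    arrays: list[RepeatArray] = []
    chain: list[MonomerHit] = []

    def flush() -> None:
        if len(chain) >= min_monomers:
            n_plus = sum(1 for h in chain if h.strand == "+")
            arrays.append(
                RepeatArray(
                    target=chain[0].target,
                    start=chain[0].start,
                    end=chain[-1].end,
                    n_monomers=len(chain),
                    mean_identity=sum(h.identity for h in chain) / len(chain),
                    strand="+" if 2 * n_plus >= len(chain) else "-",
                )
            )

    for h in sorted(hits, key=lambda h: (h.target, h.start)):
        if chain and (h.target != chain[-1].target or h.start - chain[-1].end > max_gap):
            flush()
            chain = []
        chain.append(h)
    flush()
    return arrays


@dataclass
class ArraySummary:
    n_arrays: int
    total_bp: int
    genome_fraction_pct: float  # 1-decimal percent of genome bp
    max_array_bp: int
    histogram: dict[int, int]  # bin start (bp) -> array count
    bin_bp: int


def array_summary(
    arrays: list[RepeatArray], genome: dict[str, str], bin_bp: int = 5_000
) -> ArraySummary:
    """Array-length histogram, total bp and genome fraction."""
    total = sum(a.end - a.start for a in arrays)
    genome_bp = sum(len(s) for s in genome.values())
    hist: dict[int, int] = {}
    for a in arrays:
        b = ((a.end - a.start) // bin_bp) * bin_bp
        hist[b] = hist.get(b, 0) + 1
    return ArraySummary(
        n_arrays=len(arrays),
        total_bp=total,
        genome_fraction_pct=round_half_up(100.0 * total / genome_bp, 1)
        if genome_bp
        else 0.0,
        max_array_bp=max((a.end - a.start for a in arrays), default=0),
        histogram=dict(sorted(hist.items())),
        bin_bp=bin_bp,
    )


def annotate_library(
    genome: dict[str, str],
    library: dict[str, str],
    min_identity: float = 70.0,
    min_coverage: float = 70.0,
) -> RepeatAnnotation:
    """Annotate interspersed repeats from a ``name#class``-labelled library.

    Runs the same seed-and-extend engine per library element and aggregates
    per class/family counts and bp.
    """
    families: list[tuple[str, str, str]] = []
    seen = set()
    for label, seq in library.items():
        name, _, class_label = label.partition("#")
        if name in seen:
            raise ValueError(f"duplicate library name {name!r}")
        seen.add(name)
        families.append((name, class_label or "Unknown", seq))
    ann = RepeatAnnotation()
    for name, class_label, seq in families:
        hits = find_monomer_hits(
            genome, seq, min_identity=min_identity, min_coverage=min_coverage
        )
        ann.elements.extend(
            RepeatElement(name, class_label, h.target, h.start, h.end, h.strand,
                          h.identity)
            for h in hits
        )
    ann.elements.sort(key=lambda e: (e.target, e.start, e.family))
    return ann


def find_low_complexity(
    seqs: dict[str, str], window: int = 64, max_entropy: float = 1.0
) -> list[RepeatElement]:
    """Flag low-complexity regions by windowed base entropy (< bits/base).

    A reporting aid outside the alignment path; merged overlapping windows
    are emitted as class ``Low_complexity`` elements.
    """
    out: list[RepeatElement] = []
    for name, seq in seqs.items():
        b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        counts = {base: np.cumsum(b == base) for base in (65, 67, 71, 84)}
        n = b.size
        if n < window:
            continue
        ent = np.zeros(n - window + 1)
        for base, cum in counts.items():
            c = (cum[window - 1 :] - np.concatenate([[0], cum[: n - window]])).astype(float)
            p = c / window
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(p > 0, -p * np.log2(p), 0.0)
            ent += term
        low = ent < max_entropy
        for s, e in _runs(low):
            out.append(
                RepeatElement(
                    "low_complexity", "Low_complexity", name, int(s),
                    int(e + window - 1), "+", 100.0,
                )
            )
    return out


def _runs(mask: np.ndarray):
    """(start, end) half-open runs of True."""
    if mask.size == 0:
        return
    diff = np.diff(mask.astype(np.int8))
    starts = np.nonzero(diff == 1)[0] + 1
    ends = np.nonzero(diff == -1)[0] + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [mask.size]])
    yield from zip(starts, ends)


def compare_repeats(
    annot_a: RepeatAnnotation, annot_b: RepeatAnnotation
) -> dict[str, dict[str, tuple[int, int]]]:
    """Signed A-B differences in (count, bp) per class and per family.

    Categories absent on one side count as zero.
    """
    out: dict[str, dict[str, tuple[int, int]]] = {}
    for level in ("class", "family"):
        a = annot_a.per_class() if level == "class" else annot_a.per_family()
        b = annot_b.per_class() if level == "class" else annot_b.per_family()
        keys = sorted(set(a) | set(b))
        out[level] = {
            k: (
                a.get(k, (0, 0))[0] - b.get(k, (0, 0))[0],
                a.get(k, (0, 0))[1] - b.get(k, (0, 0))[1],
            )
            for k in keys
        }
    return out


def density_tracks(
    intervals: list[tuple[str, int, int]],
    seq_lengths: dict[str, int],
    bin_bp: int,
) -> dict[str, np.ndarray]:
    """Per-bin interval counts (assignment by midpoint) for plotting tracks."""
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    tracks = {
        name: np.zeros(max(1, -(-length // bin_bp)), dtype=np.int64)
        for name, length in seq_lengths.items()
    }
    for name, start, end in intervals:
        mid = (start + end) // 2
        tracks[name][min(mid // bin_bp, tracks[name].size - 1)] += 1
    return tracks
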