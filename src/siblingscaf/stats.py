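"""Assembly and read-set contiguity statistics, plus coverage arithmetic."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .util import round_half_up


@dataclass
class ContiguityStats:
    n_seqs: int
    total_bp: int
    min_bp: int
    max_bp: int
    n50: int
    n90: int
    l50: int
    l90: int
    gc_pct: float | None = None


def _nx(lengths_desc: np.ndarray, cum: np.ndarray, frac: float) -> tuple[int, int]:
    """(Nx, Lx): length of the sequence where cumulative sum first reaches
    frac*total, and its 1-based rank in the descending order."""
    target = frac * cum[-1]
    idx = int(np.searchsorted(cum, target, side="left"))
    return int(lengths_desc[idx]), idx + 1


def contiguity_stats(
    lengths: Sequence[int] | None = None,
    sequences: dict[str, str] | None = None,
) -> ContiguityStats:
    """N50/N90, L50/L90, extremes and (when sequences are given) GC%.

    N50 is the length of the sequence at which the cumulative sum of
    descending lengths first reaches half the total (not interpolated);
    L50 is that sequence's rank. GC% excludes N from the denominator and
    is rounded half-up to 2 decimals.
    """
    if lengths is None:
        if not sequences:
            raise ValueError("need lengths or sequences")
        lengths = [len(s) for s in sequences.values()]
    lengths = np.asarray(list(lengths), dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("need at least one sequence")
    if (lengths <= 0).any():
        raise ValueError("sequence lengths must be positive")
    desc = np.sort(lengths)[::-1]
    cum = np.cumsum(desc)
    n50, l50 = _nx(desc, cum, 0.5)
    n90, l90 = _nx(desc, cum, 0.9)
    gc = None
    if sequences:
        at = gc_count = 0
        for s in sequences.values():
            gc_count += s.count("G") + s.count("C")
            at += s.count("A") + s.count("T")
        if at + gc_count:
            gc = round_half_up(100.0 * gc_count / (at + gc_count), 2)
    return ContiguityStats(
        n_seqs=int(lengths.size),
        total_bp=int(cum[-1]),
        min_bp=int(desc[-1]),
        max_bp=int(desc[0]),
        n50=n50,
        n90=n90,
        l50=l50,
        l90=l90,
        gc_pct=gc,
    )


def split_at_n(seqs: dict[str, str], min_n: int = 1) -> dict[str, str]:
    """Split scaffolds at N-runs into contigs (for contig-level statistics)."""
    import re

    out: dict[str, str] = {}
    pat = re.compile(f"N{{{min_n},}}")
    for name, seq in seqs.items():
        parts = [p for p in pat.split(seq) if p]
        if len(parts) == 1:
            out[name] = parts[0]
        else:
            for i, p in enumerate(parts, start=1):
                out[f"{name}.ctg{i}"] = p
    return out


def coverage_depth(total_bases: int, genome_size: int) -> float:
    """Fold coverage = total bases / genome size, rounded half-up to 1 decimal."""
    if genome_size <= 0:
        raise ValueError(f"genome_size must be > 0, got {genome_size}")
    return round_half_up(total_bases / genome_size, 1)
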