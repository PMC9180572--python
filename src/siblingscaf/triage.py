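"""Contig triage: keep contigs carrying substantial unique genetic information.

A contig is retained iff its UMF count is strictly greater than ``min_umf``
(default 10, so a contig with exactly 10 is discarded). The module also
quantifies how much of the total UMF signal the retained set keeps, and the
satellite burden of each contig — discarded contigs in a satellite-rich
genome are expected to be predominantly satellite DNA.
"""

from __future__ import annotations

from dataclasses import dataclass

from .util import round_half_up


@dataclass
class TriageResult:
    retained: list[str]
    discarded: list[str]
    umf_counts: dict[str, int]
    min_umf: int


def filter_contigs(
    contigs: dict[str, str], umf_counts: dict[str, int], min_umf: int = 10
) -> TriageResult:
    """Partition contigs into retained (UMF count > min_umf) and discarded.

    Contigs absent from ``umf_counts`` count as 0.
    """
    if min_umf < 0:
        raise ValueError(f"min_umf must be >= 0, got {min_umf}")
    counts = {name: umf_counts.get(name, 0) for name in contigs}
    retained = [n for n in contigs if counts[n] > min_umf]
    discarded = [n for n in contigs if counts[n] <= min_umf]
    return TriageResult(retained=retained, discarded=discarded,
                        umf_counts=counts, min_umf=min_umf)


def umf_retention(result: TriageResult, umf_counts: dict[str, int]) -> float:
    """Percent of all UMF placements that sit on retained contigs (2 decimals).

    By convention 100.00 when no UMFs were counted at all.
    """
    total = sum(umf_counts.values())
    if total == 0:
        return 100.00
    kept = sum(umf_counts.get(n, 0) for n in result.retained)
    return round_half_up(100.0 * kept / total, 2)


@dataclass
class SatelliteBurden:
    fractions: dict[str, float]  # contig -> satellite bp / contig bp
    n_over_half: int  # contigs where satellite exceeds 50% of length
    n_with_array: int  # contigs carrying at least one array


def satellite_burden(
    contigs: dict[str, str],
    arrays: list[tuple[str, int, int]],
    burden_threshold: float = 0.5,
) -> SatelliteBurden:
    """Per-contig satellite fraction from annotated arrays.

    ``arrays`` holds (contig, start, end) intervals; overlapping intervals
    on one contig are merged first so fractions cannot exceed 1.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for name, start, end in arrays:
        if name not in contigs:
            raise ValueError(f"array on unknown contig {name!r}")
        if not (0 <= start <= end <= len(contigs[name])):
            raise ValueError(
                f"array [{start},{end}) outside contig {name} "
                f"(length {len(contigs[name])})"
            )
        by_contig.setdefault(name, []).append((start, end))
    fractions = {}
    for name, seq in contigs.items():
        ivs = sorted(by_contig.get(name, []))
        merged_bp = 0
        cur_s = cur_e = None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    merged_bp += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            merged_bp += cur_e - cur_s
        fractions[name] = merged_bp / len(seq) if seq else 0.0
    return SatelliteBurden(
        fractions=fractions,
        n_over_half=sum(1 for v in fractions.values() if v > burden_threshold),
        n_with_array=sum(1 for n in contigs if by_contig.get(n)),
    )
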