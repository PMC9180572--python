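"""Small shared helpers: presentation rounding and sequence primitives."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, as tables are typically printed.

    Python's built-in round() uses banker's rounding, which would turn
    201.55 into 201.5 instead of 201.6.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]
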