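"""Small shared helpers: rounding and nucleotide utilities."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

NUCLEOTIDES = "ACGT"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, matching how summary tables are printed.

    Python's built-in round() uses banker's rounding, which disagrees with
    printed percentages on exact .5 ties (e.g. 9.55 -> 9.5 instead of 9.6).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
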