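"""Small shared helpers: coordinate conventions and table display rounding."""

from __future__ import annotations

import math

_COMPLEMENT = str.maketrans("ACGTRYMKSWN*acgtrymkswn", "TGCAYRKMSWN*tgcayrkmswn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware, keeps pads)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round1(x: float) -> float:
    """Round to one decimal, ties to even (the convention of per-gene table cells)."""
    return round(x, 1)


def trunc1(x: float) -> float:
    """Floor to one decimal (the convention of percentage and subtotal rows).

    A tiny epsilon guards against 47.399999... artifacts of binary floats.
    """
    return math.floor(x * 10 + 1e-9) / 10


def as_interval(start: int, end: int) -> tuple[int, int]:
    if not (0 <= start <= end):
        raise ValueError(f"invalid interval [{start}, {end})")
    return (start, end)
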