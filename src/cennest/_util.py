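"""Small shared helpers: interval arithmetic, rounding, sequence ops."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used for printed summary values.

    ``round()`` rounds half to even (8.25 -> 8.2); printed rates such as
    8.25% -> 8.3% need half-up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, as a sorted list of disjoint intervals."""
    out: list[list[int]] = []
    for s, e in sorted((s, e) for s, e in ivs if e > s):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def union_length(ivs: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(ivs))


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def covered_fraction(target: tuple[int, int], ivs: Sequence[tuple[int, int]]) -> float:
    """Fraction of the half-open interval `target` covered by the union of `ivs`."""
    s, e = target
    if e <= s:
        return 1.0
    clipped = [(max(s, a), min(e, b)) for a, b in ivs if b > s and a < e]
    return union_length(clipped) / (e - s)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))
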