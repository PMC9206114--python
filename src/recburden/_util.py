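"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero to ``ndigits`` decimals (report convention).

    Python's builtin rounds half to even; reported cohort proportions follow
    the conventional half-up rule (e.g. 10.75 -> 10.8).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream seed (< 2**31) from one master seed.

    Counter-based: inserting a stage never shifts another stage's stream.
    """
    h = np.uint64(seed & 0x7FFFFFFF)
    for ch in stage:
        h = np.uint64((int(h) * 1000003 + ord(ch)) & 0xFFFFFFFFFFFF)
    return int(h % np.uint64(2**31 - 1))
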