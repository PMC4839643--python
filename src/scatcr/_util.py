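"""Small shared helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero).

    Report tables round this way; Python's builtin ``round`` is
    banker's rounding and disagrees on exact .5 ties.
    """
    x = float(x)
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    v = float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
    return v if ndigits > 0 else v


def int_half_up(x: float) -> int:
    return int(round_half_up(x, 0))
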