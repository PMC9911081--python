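"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero toward +inf.

    Used wherever a count is derived from a fraction (e.g. the number of
    trans-spliced genes from a target fraction) so that results are
    deterministic and independent of banker's rounding.
    """
    return math.floor(x + 0.5)


def percent(part: float, whole: float, decimals: int = 1) -> float:
    """100 * part / whole, rounded half-up to `decimals` places."""
    if whole == 0:
        raise ValueError("percent() with zero denominator")
    scale = 10**decimals
    return math.floor(100.0 * part / whole * scale + 0.5) / scale
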