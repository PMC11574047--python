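"""Small arithmetic helpers used in reports and summaries."""

from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), unlike banker's rounding."""
    factor = 10.0**ndigits
    scaled = x * factor
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return rounded / factor if ndigits else float(rounded)


def percent_change(before: float, after: float, ndigits: int | None = 0) -> float:
    """Percent change from *before* to *after*, positive for a reduction."""
    if before == 0:
        raise ValueError("percent change undefined for a zero baseline")
    pct = 100.0 * (before - after) / before
    return pct if ndigits is None else round_half_up(pct, ndigits)


def log2_threshold_to_fold(delta_log2: float, ndigits: int = 1) -> float:
    """Linear fold change corresponding to a log2 threshold."""
    return round_half_up(2.0**delta_log2, ndigits)
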