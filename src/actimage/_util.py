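"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (report-table convention).

    Python's built-in ``round`` uses banker's rounding; report tables in this
    field conventionally print 0.125 as 0.13, not 0.12.
    """
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
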