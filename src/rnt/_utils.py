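"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math

from scipy import stats


def z_quantile(alpha: float) -> float:
    """Standard-normal quantile z_{1-alpha/2} for a two-sided level-alpha CI."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(stats.norm.ppf(1.0 - alpha / 2.0))


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero, the convention of clinical reporting.

    Python's built-in ``round`` uses banker's rounding (0.145 -> 0.14); printed
    trial summaries round 0.145 -> 0.15, so comparisons against published
    values use this helper.
    """
    if math.isinf(x) or math.isnan(x):
        return x
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale
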