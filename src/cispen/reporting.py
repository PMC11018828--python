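"""Small helpers for reporting cohort counts and rates."""
from __future__ import annotations

from .exceptions import ConfigurationError


def percent(numerator: int | float, denominator: int | float, digits: int = 1) -> float:
    """Percentage rounded to ``digits`` decimals, e.g. percent(257, 1230) -> 20.9."""
    if denominator == 0:
        raise ConfigurationError("denominator must be non-zero")
    return round(100.0 * numerator / denominator, digits)
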