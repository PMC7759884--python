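"""Display rounding conventions shared across report surfaces.

Percentages are shown to 1 decimal, or 2 decimals below 1%; sizes in
Mb/Gb to 2 decimals.
"""

from __future__ import annotations


def round_percent(value: float) -> float:
    """Round a percentage: 1 decimal, 2 decimals when below 1%."""
    return round(value, 2 if abs(value) < 1.0 else 1)


def round_size(value: float) -> float:
    """Round an Mb/Gb quantity to 2 decimals."""
    return round(value, 2)


def share_percent(count: int | float, total: int | float) -> float:
    """count/total as a display-rounded percentage."""
    if total == 0:
        return 0.0
    return round_percent(100.0 * count / total)
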