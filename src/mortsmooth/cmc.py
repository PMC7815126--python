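"""Century-month-code helpers (months since January 1900, January 1900 = 1)."""

from __future__ import annotations

__all__ = ["cmc", "cmc_year", "cmc_month"]


def cmc(year: int, month: int) -> int:
    """CMC index of a calendar month; cmc(1900, 1) == 1."""
    if not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")
    return 12 * (year - 1900) + month


def cmc_year(code: int) -> int:
    return 1900 + (code - 1) // 12


def cmc_month(code: int) -> int:
    return (code - 1) % 12 + 1
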