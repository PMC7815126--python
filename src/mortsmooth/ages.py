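"""Age-band schemes and monthly hazard schedules.

Both mortality indicators are block probabilities over a fixed span of
months of age: 0-59 months for under-five mortality (six bands of widths
1, 11, 12, 12, 12, 12) and 60-179 months for ages 5-14 (ten one-year
bands). A schedule assigns a constant monthly probability of dying to
each band; a block probability is the life-table combination

    q_block = 1 - prod_a (1 - q_a) ** width_a .
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "HazardSchedule",
    "U5_SCHEME",
    "OLDER_SCHEME",
    "scheme_for",
    "block_q_from_monthly",
    "hazards_from_block_q",
]

AGE_GROUPS = ("u5", "5to14")


@dataclass(frozen=True)
class HazardSchedule:
    """Ordered age bands ``[start, end)`` in months, with optional monthly q."""

    age_bands: tuple[tuple[int, int], ...]
    monthly_q: tuple[float, ...] | None = None

    def __post_init__(self):
        starts = [b[0] for b in self.age_bands]
        ends = [b[1] for b in self.age_bands]
        if any(e <= s for s, e in self.age_bands):
            raise ValueError("empty age band")
        if any(starts[i + 1] != ends[i] for i in range(len(starts) - 1)):
            raise ValueError("age bands must be contiguous")
        if self.monthly_q is not None:
            if len(self.monthly_q) != len(self.age_bands):
                raise ValueError("monthly_q length must match age_bands")
            if any(not (0.0 <= q < 1.0) for q in self.monthly_q):
                raise ValueError("monthly_q must lie in [0, 1)")

    @property
    def n_bands(self) -> int:
        return len(self.age_bands)

    @property
    def widths(self) -> np.ndarray:
        return np.array([e - s for s, e in self.age_bands])

    @property
    def start(self) -> int:
        return self.age_bands[0][0]

    @property
    def end(self) -> int:
        return self.age_bands[-1][1]

    def band_of(self, age_months: np.ndarray) -> np.ndarray:
        """Band index of each age in completed months; -1 outside support."""
        age = np.asarray(age_months)
        edges = np.array([b[0] for b in self.age_bands] + [self.end])
        idx = np.searchsorted(edges, age, side="right") - 1
        idx[(age < self.start) | (age >= self.end)] = -1
        return idx


U5_SCHEME = HazardSchedule(((0, 1), (1, 12), (12, 24), (24, 36), (36, 48), (48, 60)))
OLDER_SCHEME = HazardSchedule(tuple((60 + 12 * k, 72 + 12 * k) for k in range(10)))


def scheme_for(age_group: str) -> HazardSchedule:
    if age_group == "u5":
        return U5_SCHEME
    if age_group == "5to14":
        return OLDER_SCHEME
    raise ValueError(f"unknown age group {age_group!r}")


def block_q_from_monthly(monthly_q, widths) -> float:
    """Life-table combination of per-band monthly probabilities."""
    monthly_q = np.asarray(monthly_q, dtype=float)
    widths = np.asarray(widths, dtype=float)
    return 1.0 - float(np.exp(np.sum(widths * np.log1p(-monthly_q))))


def hazards_from_block_q(
    block_q: float, scheme: HazardSchedule, multipliers=None
) -> HazardSchedule:
    """Invert the life-table product: monthly q per band from a block q.

    Band levels are proportional to ``multipliers`` on the log-hazard
    scale (hazard = -log(1 - q)), so the product over all months
    reproduces ``block_q`` exactly:

        q_a = 1 - exp(-c * m_a),   c = -log(1 - block_q) / sum_a w_a m_a.
    """
    if not (0.0 < block_q < 1.0):
        raise ValueError("block_q must lie in (0, 1)")
    widths = scheme.widths.astype(float)
    if multipliers is None:
        multipliers = np.ones(scheme.n_bands)
    m = np.asarray(multipliers, dtype=float)
    if m.shape != (scheme.n_bands,) or np.any(m <= 0):
        raise ValueError("multipliers must be positive, one per band")
    c = -np.log1p(-block_q) / float(widths @ m)
    monthly = -np.expm1(-c * m)
    return replace(scheme, monthly_q=tuple(monthly))
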