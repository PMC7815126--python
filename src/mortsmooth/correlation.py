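"""Between-age-group correlation with propagated posterior uncertainty.

For every posterior draw, the Pearson correlation between the two age
groups' probabilities is computed across the retained (area, period)
cells; the spread of these draw-wise correlations yields a credible
interval that reflects the uncertainty of the sub-national estimates
themselves. Correlations are reported pooled over all retained periods
and stratified by period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smoothing import PosteriorDraws

log = logging.getLogger(__name__)

__all__ = ["CorrelationReport", "pearson_with_ci", "correlation_report"]


@dataclass(frozen=True)
class CorrelationReport:
    scope: str  # "pooled" or "per-period"
    period_label: str  # "ALL" for pooled scope
    r_point: float
    ci_low: float
    ci_high: float
    n_points: int

    @property
    def crosses_zero(self) -> bool:
        return self.ci_low <= 0.0 <= self.ci_high


def _drawwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r across cells (axis 1) for each draw (axis 0)."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def pearson_with_ci(
    q_draws_a: np.ndarray,
    q_draws_b: np.ndarray,
    scope: str = "pooled",
    period_label: str = "ALL",
    ci: float = 0.95,
) -> CorrelationReport | None:
    """Draw-wise Pearson correlation over (S, cells) probability arrays.

    The point estimate is the median of the draw-wise correlations and
    the interval their central ``ci`` percentiles. Returns None (with a
    logged reason) when fewer than 3 cells are available.
    """
    a = np.atleast_2d(np.asarray(q_draws_a, dtype=float))
    b = np.atleast_2d(np.asarray(q_draws_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("draw arrays must share shape (draws, cells)")
    if a.shape[1] < 3:
        log.info("scope %s/%s skipped: only %d cells", scope, period_label, a.shape[1])
        return None
    r = _drawwise_pearson(a, b)
    r = r[np.isfinite(r)]
    if len(r) == 0:
        raise ValueError("all draw-wise correlations are degenerate")
    tail = (1.0 - ci) / 2.0
    lo, mid, hi = np.quantile(r, [tail, 0.5, 1.0 - tail])
    return CorrelationReport(scope, period_label, float(mid), float(lo), float(hi),
                             n_points=a.shape[1])


def correlation_report(
    draws_u5: PosteriorDraws,
    draws_514: PosteriorDraws,
    retained_labels: list[str] | None = None,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Pooled and per-period correlation between the two age groups.

    The fits must share areas; cells are matched on period labels (the
    two age groups cover different retrospective spans, so indices need
    not align). ``retained_labels`` — e.g. the periods kept by the
    precision screen of the 5-14 fit — restricts the cells entering both
    scopes; by default every period present in both fits is used.
    """
    if draws_u5.areas != draws_514.areas:
        raise ValueError("fits must share areas")
    common = [lab for lab in draws_514.period_labels if lab in draws_u5.period_labels]
    if retained_labels is not None:
        common = [lab for lab in common if lab in set(map(str, retained_labels))]
    if not common:
        raise ValueError("no shared periods between the two fits")
    S = min(draws_u5.n_draws, draws_514.n_draws)
    qa = draws_u5.q_draws[:S]
    qb = draws_514.q_draws[:S]
    ia = {lab: i for i, lab in enumerate(draws_u5.period_labels)}
    ib = {lab: i for i, lab in enumerate(draws_514.period_labels)}
    rows = []
    pooled_a = np.concatenate([qa[:, :, ia[lab]] for lab in common], axis=1)
    pooled_b = np.concatenate([qb[:, :, ib[lab]] for lab in common], axis=1)
    rep = pearson_with_ci(pooled_a, pooled_b, "pooled", "ALL", ci)
    if rep is not None:
        rows.append(rep)
    for lab in common:
        rep = pearson_with_ci(
            qa[:, :, ia[lab]], qb[:, :, ib[lab]], "per-period", lab, ci
        )
        if rep is not None:
            rows.append(rep)
    return pd.DataFrame(
        [
            dict(scope=r.scope, period_label=r.period_label, r_point=r.r_point,
                 ci_low=r.ci_low, ci_high=r.ci_high, n_points=r.n_points,
                 crosses_zero=r.crosses_zero)
            for r in rows
        ]
    )
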