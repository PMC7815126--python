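"""Posterior coefficient-of-variation screening.

Each (area, period) estimate gets a CV in percent — 100 times the
posterior standard deviation of q divided by its posterior mean — and is
classified against a threshold (default 20%: a CV at or above the
threshold marks the estimate as not sufficiently precise). A period is
retained when at least a given share of its areas (default 75%) are
precise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .smoothing import PosteriorDraws

__all__ = ["cv_percent", "posterior_cv", "classify_and_retain", "precision_report"]


def cv_percent(mean: float, sd: float) -> float:
    """100 x sd / mean; the CV of a distribution, in percent."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    return 100.0 * sd / mean


def posterior_cv(q_draws: np.ndarray) -> float:
    """Posterior CV (%) of one cell's probability draws. Scale-invariant."""
    q = np.asarray(q_draws, dtype=float)
    if q.size < 2:
        raise ValueError("need at least 2 draws")
    return cv_percent(float(q.mean()), float(q.std(ddof=1)))


def classify_and_retain(
    cv_table: pd.DataFrame, threshold: float = 20.0, retention_share: float = 0.75
) -> pd.DataFrame:
    """Classify cells as precise and flag retained periods.

    ``cv_table`` needs columns (admin1, period, cv_percent); a cell is
    precise iff its CV is strictly below the threshold, and a period is
    retained iff the share of precise areas is at least
    ``retention_share``.
    """
    out = cv_table.copy()
    out["precise"] = out["cv_percent"] < threshold
    shares = out.groupby("period")["precise"].mean().rename("share_precise")
    out = out.merge(shares, on="period")
    out["retained"] = out["share_precise"] >= retention_share
    return out


def precision_report(
    draws: PosteriorDraws, threshold: float = 20.0, retention_share: float = 0.75
) -> pd.DataFrame:
    """CV screening of a fitted surface, one row per (area, period)."""
    q = draws.q_draws
    rows = [
        dict(
            admin1=str(area),
            period=t,
            period_label=draws.period_labels[t],
            cv_percent=posterior_cv(q[:, i, t]),
        )
        for i, area in enumerate(draws.areas)
        for t in range(draws.T)
    ]
    return classify_and_retain(pd.DataFrame(rows), threshold, retention_share)
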