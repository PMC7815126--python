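"""Variance decomposition of the fitted logit surface.

The five model components are summarised by their posterior-mean effect
vectors; the empirical variance of each vector over its own index set
(periods for the temporal terms, areas for the spatial terms, the full
area x period grid for the interaction) is expressed as a percentage of
the five-component total. Intrinsic precision hyperparameters are not
marginal variances, so shares are computed from the effects themselves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .smoothing import PosteriorDraws

__all__ = ["SHARE_COLUMNS", "component_variance_shares", "shares_table"]

SHARE_COLUMNS = {
    "gamma": "rw2",
    "phi": "icar",
    "delta": "rw2_x_icar",
    "alpha": "time_iid",
    "theta": "space_iid",
}


def _empirical_variance(values: np.ndarray) -> float:
    flat = np.asarray(values, dtype=float).ravel()
    if flat.size < 2:
        return 0.0
    return float(flat.var(ddof=1))


def component_variance_shares(draws: PosteriorDraws) -> dict[str, float]:
    """Percent of total variance per component; values sum to 100."""
    means = {
        "alpha": draws.alpha.mean(axis=0),
        "gamma": draws.gamma.mean(axis=0),
        "theta": draws.theta.mean(axis=0),
        "phi": draws.phi.mean(axis=0),
        "delta": draws.delta.mean(axis=0),
    }
    variances = {c: _empirical_variance(v) for c, v in means.items()}
    total = sum(variances.values())
    if total == 0:
        raise ValueError("all components are degenerate; no variance to decompose")
    return {SHARE_COLUMNS[c]: 100.0 * variances[c] / total for c in SHARE_COLUMNS}


def shares_table(draws: PosteriorDraws, label: str = "run") -> pd.DataFrame:
    """One-row table mirroring the shares layout: label, age group, 5 shares."""
    shares = component_variance_shares(draws)
    row = {"label": label, "age_group": draws.age_group, **shares}
    return pd.DataFrame([row])
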