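"""Multi-survey pooling and HIV bias adjustment.

Survey-specific direct estimates of one (area, period, age group) cell
are combined on the logit scale by inverse-variance weighting — the
fixed-effect meta-analysis estimator. Externally supplied HIV correction
factors are then applied multiplicatively, on the probability scale, to
pooled under-five estimates only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "pool_surveys",
    "pool_table",
    "HivAdjustmentTable",
    "apply_hiv_adjustment",
]


def pool_surveys(logit_q: np.ndarray, var_logit_q: np.ndarray) -> tuple[float, float]:
    """Inverse-variance pooled (logit_q, var) of one cell's survey estimates."""
    x = np.asarray(logit_q, dtype=float)
    v = np.asarray(var_logit_q, dtype=float)
    if len(x) == 0:
        raise ValueError("no estimates to pool")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    w = 1.0 / v
    return float((w @ x) / w.sum()), float(1.0 / w.sum())


def pool_table(estimates: pd.DataFrame) -> pd.DataFrame:
    """Pool a direct-estimate table over surveys, cell by cell.

    Cells where every contributing survey is missing are returned with
    status="missing" so the smoothing stage can still lay out the full
    area x period grid.
    """
    rows = []
    for (area, period, group), cell in estimates.groupby(
        ["admin1", "period", "age_group"], observed=True
    ):
        ok = cell[cell["status"] == "ok"]
        label = cell["period_label"].iloc[0]
        if len(ok) == 0:
            rows.append(
                dict(admin1=area, period=period, period_label=label, age_group=group,
                     q=np.nan, logit_q=np.nan, var_logit_q=np.nan,
                     n_surveys=0, hiv_adjusted=False, status="missing")
            )
            continue
        x, v = pool_surveys(ok["logit_q"].to_numpy(), ok["var_logit_q"].to_numpy())
        rows.append(
            dict(admin1=area, period=period, period_label=label, age_group=group,
                 q=1.0 / (1.0 + np.exp(-x)), logit_q=x, var_logit_q=v,
                 n_surveys=len(ok), hiv_adjusted=False, status="ok")
        )
    return pd.DataFrame(rows).sort_values(["age_group", "period", "admin1"],
                                          key=lambda s: s.astype(str),
                                          ignore_index=True)


class HivAdjustmentTable:
    """Multiplicative under-five correction factors keyed by area or country.

    The table holds rows (area_or_country, period_label, factor). Lookup
    tries the Admin-1 label first, then the country label; a cell whose
    country appears in the table but whose period has no factor is an
    error, while a country absent from the table passes through.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"area_or_country", "period_label", "factor"}
        if not required.issubset(table.columns):
            raise ValueError(f"HIV table needs columns {sorted(required)}")
        if (table["factor"] <= 0).any():
            raise ValueError("factors must be positive")
        self._factors = {
            (str(r.area_or_country), str(r.period_label)): float(r.factor)
            for r in table.itertuples()
        }
        self._keys = {str(k) for k in table["area_or_country"]}

    @classmethod
    def read_csv(cls, path) -> "HivAdjustmentTable":
        return cls(pd.read_csv(path, dtype={"area_or_country": str, "period_label": str}))

    def lookup(self, admin1, period_label, country=None) -> float | None:
        for key in (str(admin1), None if country is None else str(country)):
            if key is None:
                continue
            if (key, str(period_label)) in self._factors:
                return self._factors[(key, str(period_label))]
            if key in self._keys:
                raise KeyError(
                    f"HIV table covers {key!r} but has no factor for period {period_label!r}"
                )
        return None


def apply_hiv_adjustment(
    pooled: pd.DataFrame, table: HivAdjustmentTable | None, country: str | None = None
) -> pd.DataFrame:
    """Apply HIV correction factors to pooled under-five estimates.

    q is multiplied by the factor on the probability scale and
    re-logit-transformed; the logit-scale variance is carried over
    unchanged. Estimates for ages 5-14 are returned untouched.
    """
    out = pooled.copy()
    if table is None:
        return out
    mask = (out["age_group"] == "u5") & (out["status"] == "ok")
    for idx in out.index[mask]:
        factor = table.lookup(out.at[idx, "admin1"], out.at[idx, "period_label"], country)
        if factor is None:
            continue
        q = out.at[idx, "q"] * factor
        if not 0.0 < q < 1.0:
            raise ValueError(f"adjusted q={q} outside (0, 1)")
        out.at[idx, "q"] = q
        out.at[idx, "logit_q"] = np.log(q) - np.log1p(-q)
        out.at[idx, "hiv_adjusted"] = True
    return out
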