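"""Design-based direct estimation of block mortality probabilities.

Full birth histories are expanded to person-months, monthly probabilities
of dying are fitted per age band by weighted logistic regression (the
band-indicator model is saturated, so the fit has a closed form), the
covariance of the band logits is the Taylor-linearization estimator with
clusters as primary sampling units nested in strata, and bands are
combined into a block probability with a delta-method variance on the
logit scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ages import HazardSchedule, scheme_for
from .cmc import cmc_year
from .synthetic import validate_records

log = logging.getLogger(__name__)

__all__ = [
    "PeriodGrid",
    "BandFit",
    "DirectEstimate",
    "build_period_grid",
    "expand_person_months",
    "fit_band_logits",
    "combine_bands_to_q",
    "estimate_direct",
    "write_estimates",
    "read_estimates",
]

PERIOD_MONTHS = 48
#: retrospective truncation per survey, in periods
MAX_PERIODS = {"u5": 6, "5to14": 3}


@dataclass(frozen=True)
class PeriodGrid:
    """Contiguous 4-year calendar periods anchored at the most recent survey."""

    breaks: tuple[int, ...]  # T+1 CMC boundaries, [start, end) per period
    labels: tuple[str, ...]
    age_group: str

    def __post_init__(self):
        widths = np.diff(self.breaks)
        if np.any(widths != PERIOD_MONTHS):
            raise ValueError("periods must be exactly 48 months")

    @property
    def T(self) -> int:
        return len(self.labels)

    @property
    def start(self) -> int:
        return self.breaks[0]

    @property
    def end(self) -> int:
        return self.breaks[-1]

    def period_of(self, code) -> np.ndarray:
        """Period index of each CMC; -1 outside the grid."""
        code = np.asarray(code)
        idx = np.searchsorted(self.breaks, code, side="right") - 1
        idx = np.where((code < self.start) | (code >= self.end), -1, idx)
        return idx


def _label(start_cmc: int, end_cmc: int) -> str:
    return f"{cmc_year(start_cmc)}-{cmc_year(end_cmc - 1)}"


def build_period_grid(
    survey_end_cmcs: Sequence[int], age_group: str
) -> PeriodGrid:
    """Anchor 48-month periods at the most recent survey's fieldwork end.

    The last period closes with the most recent fieldwork month; earlier
    periods step backwards in 48-month blocks far enough to cover every
    survey's truncated retrospective window (24 years for under-five,
    12 years for ages 5-14).
    """
    if len(survey_end_cmcs) == 0:
        raise ValueError("at least one survey is required")
    trunc = MAX_PERIODS[age_group] * PERIOD_MONTHS
    anchor = max(survey_end_cmcs) + 1  # exclusive end of the last period
    earliest = min(survey_end_cmcs) + 1 - trunc
    n_periods = int(np.ceil((anchor - earliest) / PERIOD_MONTHS))
    breaks = tuple(anchor - PERIOD_MONTHS * k for k in range(n_periods, -1, -1))
    labels = tuple(_label(breaks[i], breaks[i + 1]) for i in range(n_periods))
    return PeriodGrid(breaks, labels, age_group)


def survey_period_overlap(grid: PeriodGrid, survey_end_cmc: int) -> np.ndarray:
    """Months of overlap between each period and the survey's truncated window."""
    trunc = MAX_PERIODS[grid.age_group] * PERIOD_MONTHS
    w0, w1 = survey_end_cmc + 1 - trunc, survey_end_cmc + 1
    starts = np.asarray(grid.breaks[:-1])
    ends = np.asarray(grid.breaks[1:])
    return np.maximum(0, np.minimum(ends, w1) - np.maximum(starts, w0))


def expand_person_months(
    records: pd.DataFrame, grid: PeriodGrid, scheme: HazardSchedule
) -> pd.DataFrame:
    """Expand birth histories into aggregated person-month exposure.

    Returns one row per (child, age band, period) with the number of
    months of exposure and a 0/1 event flag. The death month counts as a
    full exposed month with event=1; the interview month is excluded for
    surviving children. Months outside the grid's calendar support or the
    scheme's age support contribute nothing.
    """
    validate_records(records)
    birth = records["birth_cmc"].to_numpy(dtype=int)
    interview = records["interview_cmc"].to_numpy(dtype=int)
    died = records["died"].to_numpy(dtype=bool)
    aod = records["age_at_death_months"].fillna(0).to_numpy(dtype=int)
    # observed months of age: [0, n_obs)
    n_obs = np.where(died, aod + 1, interview - birth)

    chunks = []
    for band, (a0, a1) in enumerate(scheme.age_bands):
        for t in range(grid.T):
            p0, p1 = grid.breaks[t], grid.breaks[t + 1]
            lo = np.maximum(a0, p0 - birth)
            hi = np.minimum.reduce([np.full_like(birth, a1), n_obs, p1 - birth])
            months = np.maximum(0, hi - lo)
            keep = months > 0
            if not keep.any():
                continue
            event = (died & (aod >= lo) & (aod < hi))[keep].astype(int)
            sub = records.loc[
                keep, ["survey_id", "stratum", "cluster", "woman_id", "admin1", "weight"]
            ].copy()
            sub["period"] = t
            sub["age_band"] = band
            sub["months"] = months[keep]
            sub["event"] = event
            chunks.append(sub)
    if not chunks:
        return pd.DataFrame(
            columns=[
                "survey_id", "stratum", "cluster", "woman_id", "admin1",
                "weight", "period", "age_band", "months", "event",
            ]
        )
    return pd.concat(chunks, ignore_index=True)


@dataclass(frozen=True)
class BandFit:
    """Weighted-logistic band fit with design-based covariance."""

    beta: np.ndarray  # (A,) logit monthly probability per band; nan if non-estimable
    cov: np.ndarray  # (A, A) Taylor-linearization covariance; nan rows if non-estimable
    estimable: np.ndarray  # (A,) bool
    n_events: float
    n_personmonths: float


def fit_band_logits(pm: pd.DataFrame, scheme: HazardSchedule) -> BandFit:
    """Fit per-band monthly logits on one cell's person-months.

    The model has one indicator per age band and no intercept, so the
    weighted MLE is the weighted log-odds of death within each band. The
    covariance is the stratified-cluster sandwich estimator: cluster
    totals of the weighted score, centred within stratum with an
    n_h/(n_h-1) factor (grand-mean centring for lonely PSUs).
    """
    if len(pm) == 0:
        raise ValueError("cell has no person-months")
    A = scheme.n_bands
    w_exp = pm["weight"].to_numpy() * pm["months"].to_numpy()
    w_evt = pm["weight"].to_numpy() * pm["event"].to_numpy()
    band = pm["age_band"].to_numpy()
    W = np.bincount(band, weights=w_exp, minlength=A)
    D = np.bincount(band, weights=w_evt, minlength=A)
    estimable = (W > 0) & (D > 0) & (D < W)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(estimable, np.log(D) - np.log(W - D), np.nan)
        p = np.where(W > 0, D / W, 0.0)

    # cluster totals of the score  U_ac = sum_k w_k (y_k - p_a m_k)
    resid = w_evt - p[band] * w_exp
    scores = (
        pd.DataFrame(
            {
                "stratum": pm["stratum"].to_numpy(),
                "cluster": pm["cluster"].to_numpy(),
                "band": band,
                "resid": resid,
            }
        )
        .groupby(["stratum", "cluster", "band"], observed=True)["resid"]
        .sum()
        .unstack("band", fill_value=0.0)
        .reindex(columns=range(A), fill_value=0.0)
    )
    u = scores.to_numpy()
    strata = scores.index.get_level_values("stratum").to_numpy()
    g = np.zeros((A, A))
    grand_mean = u.mean(axis=0)
    for h in np.unique(strata):
        uh = u[strata == h]
        nh = uh.shape[0]
        if nh >= 2:
            centred = uh - uh.mean(axis=0)
            g += (nh / (nh - 1)) * centred.T @ centred
        else:
            centred = uh - grand_mean
            g += centred.T @ centred
    binfo = W * p * (1.0 - p)
    cov = np.full((A, A), np.nan)
    ok = estimable
    if ok.any():
        binv = 1.0 / binfo[ok]
        cov_ok = (binv[:, None] * g[np.ix_(ok, ok)]) * binv[None, :]
        cov[np.ix_(ok, ok)] = cov_ok
    return BandFit(beta, cov, estimable, float(D.sum()), float(W.sum()))


@dataclass(frozen=True)
class DirectEstimate:
    """One (area, period, survey, age group) block-probability estimate."""

    admin1: object
    period: int
    survey_id: str
    age_group: str
    q: float = np.nan
    logit_q: float = np.nan
    var_logit_q: float = np.nan
    status: str = "ok"


def combine_bands_to_q(
    fit: BandFit,
    scheme: HazardSchedule,
    admin1=None,
    period: int = -1,
    survey_id: str = "",
    age_group: str = "",
) -> DirectEstimate:
    """Life-table combination of band logits with delta-method variance.

    q = 1 - prod_a (1 - expit(beta_a)) ** width_a; the gradient of
    logit(q) in beta_a is width_a * p_a / q, so
    var(logit q) = g' Sigma g with the design-based band covariance.
    """
    meta = dict(admin1=admin1, period=period, survey_id=survey_id, age_group=age_group)
    if not fit.estimable.all():
        return DirectEstimate(status="missing", **meta)
    p = 1.0 / (1.0 + np.exp(-fit.beta))
    widths = scheme.widths.astype(float)
    q = 1.0 - float(np.exp(np.sum(widths * np.log1p(-p))))
    grad = widths * p / q
    var = float(grad @ fit.cov @ grad)
    if not np.isfinite(var) or var <= 0:
        return DirectEstimate(status="missing", **meta)
    logit_q = float(np.log(q) - np.log1p(-q))
    return DirectEstimate(q=q, logit_q=logit_q, var_logit_q=var, **meta)


def estimate_direct(
    records: pd.DataFrame,
    grid: PeriodGrid,
    age_group: str,
    min_exposure_months: int = 12,
) -> pd.DataFrame:
    """All survey-area-period direct estimates for one age group.

    A survey informs a period only when its truncated retrospective
    window overlaps it by strictly more than ``min_exposure_months``
    calendar months. Cells with no estimable fit are reported with
    status="missing".
    """
    scheme = scheme_for(age_group)
    pm = expand_person_months(records, grid, scheme)
    areas = sorted(records["admin1"].unique(), key=str)
    survey_ends = records.groupby("survey_id")["interview_cmc"].max()

    groups = {k: v for k, v in pm.groupby(["survey_id", "period", "admin1"], observed=True)}
    rows = []
    for survey_id, end in survey_ends.items():
        overlap = survey_period_overlap(grid, int(end))
        for t in range(grid.T):
            if overlap[t] <= min_exposure_months:
                continue
            for area in areas:
                cell = groups.get((survey_id, t, area))
                if cell is None or len(cell) == 0:
                    est = DirectEstimate(
                        admin1=area, period=t, survey_id=survey_id,
                        age_group=age_group, status="missing",
                    )
                else:
                    fit = fit_band_logits(cell, scheme)
                    est = combine_bands_to_q(
                        fit, scheme, admin1=area, period=t,
                        survey_id=survey_id, age_group=age_group,
                    )
                rows.append(est)
    df = pd.DataFrame([vars(e) for e in rows])
    if len(df):
        df["period_label"] = [grid.labels[t] for t in df["period"]]
    else:
        df["period_label"] = []
    cols = ["admin1", "period", "period_label", "survey_id", "age_group",
            "q", "logit_q", "var_logit_q", "status"]
    return df[cols]


def write_estimates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_estimates(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"admin1": str, "survey_id": str})
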