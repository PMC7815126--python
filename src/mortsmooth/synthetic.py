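"""Synthetic survey worlds with known truth.

Generates (i) latent space-time mortality surfaces with the additive
structure used by the smoothing model, (ii) monthly hazards per area,
period and age band consistent with those surfaces, and (iii) stratified
two-stage cluster samples of women whose full birth histories are
simulated month by month. Everything downstream of the raw survey files
can therefore be tested against known generating values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ages import OLDER_SCHEME, U5_SCHEME, HazardSchedule, hazards_from_block_q
from .graphs import AdjacencyGraph, generate_adjacency  # noqa: F401  (re-export)
from .structure import (
    build_icar_precision,
    build_interaction_precision,
    build_rw2_precision,
    sample_intrinsic,
)

log = logging.getLogger(__name__)

__all__ = [
    "SurfaceHypers",
    "TrueSurface",
    "Stratum",
    "SamplingDesign",
    "sample_true_surface",
    "correlated_surface",
    "default_design",
    "simulate_survey",
    "validate_records",
    "write_records",
    "read_records",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = [
    "survey_id",
    "stratum",
    "cluster",
    "woman_id",
    "weight",
    "interview_cmc",
    "birth_cmc",
    "died",
    "age_at_death_months",
    "admin1",
]


@dataclass(frozen=True)
class SurfaceHypers:
    """Variances of the five latent components (logit scale)."""

    sigma2_alpha: float = 0.0
    sigma2_gamma: float = 0.0
    sigma2_theta: float = 0.0
    sigma2_phi: float = 0.0
    sigma2_delta: float = 0.0

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TrueSurface:
    """Latent logit mortality surface lambda = mu + alpha + gamma + theta + phi + delta."""

    areas: tuple
    mu: float
    alpha: np.ndarray  # (T,) iid temporal
    gamma: np.ndarray  # (T,) RW2 temporal
    theta: np.ndarray  # (n,) iid spatial
    phi: np.ndarray  # (n,) ICAR spatial
    delta: np.ndarray  # (n, T) RW2 x ICAR interaction

    @property
    def n(self) -> int:
        return len(self.areas)

    @property
    def T(self) -> int:
        return len(self.alpha)

    @property
    def lam(self) -> np.ndarray:
        """(n, T) surface assembled from the components."""
        return (
            self.mu
            + self.alpha[None, :]
            + self.gamma[None, :]
            + self.theta[:, None]
            + self.phi[:, None]
            + self.delta
        )

    @property
    def q(self) -> np.ndarray:
        """(n, T) block probabilities, inverse-logit of the surface."""
        return 1.0 / (1.0 + np.exp(-self.lam))


def sample_true_surface(
    graph: AdjacencyGraph,
    T: int,
    hyper: SurfaceHypers,
    mu: float,
    seed: int | np.random.Generator,
) -> TrueSurface:
    """Draw a surface from its generative priors with constraints applied.

    alpha and theta are iid normal; gamma is an intrinsic RW2 draw, phi an
    intrinsic ICAR draw, delta an intrinsic RW2 x ICAR draw — each sampled
    in the row space of its structure matrix, so the sum-to-zero
    constraints (per connected component for phi; row and column sums for
    delta) hold exactly. A zero variance yields an all-zero component.
    """
    if T < 3:
        raise ValueError("T must be >= 3")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = graph.n
    if not graph.is_connected():
        log.warning(
            "adjacency graph has %d components; intrinsic constraints applied per component",
            graph.n_components,
        )
    q_space = build_icar_precision(graph)
    q_time = build_rw2_precision(T)
    q_inter, _ = build_interaction_precision(q_time, q_space)

    alpha = rng.standard_normal(T) * np.sqrt(hyper.sigma2_alpha)
    theta = rng.standard_normal(n) * np.sqrt(hyper.sigma2_theta)
    gamma = sample_intrinsic(q_time, hyper.sigma2_gamma, rng)
    phi = sample_intrinsic(q_space, hyper.sigma2_phi, rng)
    delta_vec = sample_intrinsic(q_inter, hyper.sigma2_delta, rng)
    delta = delta_vec.reshape(T, n).T  # vec is period-major
    return TrueSurface(tuple(graph.nodes), float(mu), alpha, gamma, theta, phi, delta)


def correlated_surface(
    base: TrueSurface,
    graph: AdjacencyGraph,
    hyper: SurfaceHypers,
    mu: float,
    rho: float,
    seed: int | np.random.Generator,
) -> TrueSurface:
    """Draw a second surface whose centred part correlates with ``base``.

    Each component is ``rho * base_component + sqrt(1-rho^2) * fresh``,
    which preserves the marginal priors (all components are Gaussian and
    the constraints are linear). ``rho=0`` gives an independent surface,
    ``rho=1`` a copy with the new level ``mu``.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    fresh = sample_true_surface(graph, base.T, hyper, 0.0, seed)
    s = np.sqrt(1.0 - rho**2)
    return TrueSurface(
        base.areas,
        float(mu),
        rho * base.alpha + s * fresh.alpha,
        rho * base.gamma + s * fresh.gamma,
        rho * base.theta + s * fresh.theta,
        rho * base.phi + s * fresh.phi,
        rho * base.delta + s * fresh.delta,
    )


# ---------------------------------------------------------------------------
# sampling design


@dataclass(frozen=True)
class Stratum:
    """One sampling stratum: an (admin1, urban/rural) cell with its frame."""

    admin1: object
    name: str
    cluster_sizes: tuple[int, ...]  # women per enumeration area


@dataclass(frozen=True)
class SamplingDesign:
    strata: tuple[Stratum, ...]
    clusters_per_stratum: int
    women_per_cluster: int

    def __post_init__(self):
        if self.clusters_per_stratum < 1 or self.women_per_cluster < 1:
            raise ValueError("counts must be positive")
        for st in self.strata:
            if len(st.cluster_sizes) < self.clusters_per_stratum:
                raise ValueError(f"stratum {st.name}: frame smaller than sample")
            if min(st.cluster_sizes) < self.women_per_cluster:
                raise ValueError(f"stratum {st.name}: cluster smaller than take")

    @property
    def total_women(self) -> int:
        return sum(sum(st.cluster_sizes) for st in self.strata)


def default_design(
    areas: Sequence,
    clusters_per_stratum: int = 8,
    women_per_cluster: int = 20,
    n_clusters_frame: int = 40,
    cluster_size_range: tuple[int, int] = (100, 400),
    urban_rural: bool = True,
    seed: int | np.random.Generator = 0,
) -> SamplingDesign:
    """A simple frame: per area, one or two strata of random-size clusters."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    strata = []
    suffixes = ("urban", "rural") if urban_rural else ("all",)
    lo, hi = cluster_size_range
    for area in areas:
        for sfx in suffixes:
            sizes = tuple(int(s) for s in rng.integers(lo, hi + 1, size=n_clusters_frame))
            strata.append(Stratum(area, f"{area}_{sfx}", sizes))
    return SamplingDesign(tuple(strata), clusters_per_stratum, women_per_cluster)


def _pps_systematic(sizes: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Systematic PPS sample of k clusters; inclusion prob = k*size/total."""
    total = sizes.sum()
    step = total / k
    if sizes.max() > step:
        raise ValueError("a cluster exceeds the sampling interval; PPS inclusion > 1")
    targets = rng.uniform(0.0, step) + step * np.arange(k)
    return np.searchsorted(np.cumsum(sizes), targets, side="right")


# ---------------------------------------------------------------------------
# survey simulation


def _monthly_hazard_table(
    surfaces: Mapping[str, TrueSurface],
    multipliers: Mapping[str, Sequence[float]] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """(n, T, 180) monthly death probability by area, period, age in months."""
    schemes: dict[str, HazardSchedule] = {"u5": U5_SCHEME, "5to14": OLDER_SCHEME}
    any_surf = next(iter(surfaces.values()))
    n, T = any_surf.n, any_surf.T
    table = np.zeros((n, T, 180))
    for group, surf in surfaces.items():
        scheme = schemes[group]
        mult = None if multipliers is None else multipliers.get(group)
        q = surf.q
        for i in range(n):
            for t in range(T):
                sched = hazards_from_block_q(float(q[i, t]), scheme, mult)
                for (a0, a1), m in zip(sched.age_bands, sched.monthly_q):
                    table[i, t, a0:a1] = m
    areas = np.asarray(any_surf.areas, dtype=object)
    return table, areas


def simulate_survey(
    surfaces: Mapping[str, TrueSurface],
    design: SamplingDesign,
    period_breaks: Sequence[int],
    interview_cmc: int,
    fertility: float,
    seed: int | np.random.Generator,
    survey_id: str = "svy",
    multipliers: Mapping[str, Sequence[float]] | None = None,
    lookback_months: int = 324,
) -> pd.DataFrame:
    """Simulate one survey's full-birth-history file.

    Women are sampled in two stages (PPS systematic selection of clusters
    within strata, then a fixed take of women per cluster); births follow
    a homogeneous Poisson process over ``lookback_months`` before the
    interview; each child's survival is simulated month by month from the
    hazards implied by the surfaces. Calendar months outside
    ``period_breaks`` are clamped to the nearest period.

    The default lookback of 324 months (27 years) is the minimum needed
    for births to cover every age band of the 5-14 scheme across the full
    12-year retrospective window used by the estimation stage.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    breaks = np.asarray(period_breaks, dtype=int)
    any_surf = next(iter(surfaces.values()))
    if len(breaks) != any_surf.T + 1:
        raise ValueError("period_breaks must have length T + 1")
    if interview_cmc < breaks[0]:
        raise ValueError("fieldwork predates the surface's period support")

    hazards, areas = _monthly_hazard_table(surfaces, multipliers)
    area_index = {a: i for i, a in enumerate(areas)}

    # stage 1+2: sampled women with design labels and weights
    w_stratum, w_cluster, w_area, w_weight = [], [], [], []
    for st in design.strata:
        sizes = np.asarray(st.cluster_sizes, dtype=float)
        chosen = _pps_systematic(sizes, design.clusters_per_stratum, rng)
        weight = sizes.sum() / (design.clusters_per_stratum * design.women_per_cluster)
        for c in chosen:
            for _ in range(design.women_per_cluster):
                w_stratum.append(st.name)
                w_cluster.append(f"{st.name}_c{c + 1}")
                w_area.append(st.admin1)
                w_weight.append(weight)
    n_women = len(w_weight)

    # births: Poisson count per woman, months uniform over the lookback window
    n_births = rng.poisson(fertility * lookback_months, size=n_women)
    woman_of_child = np.repeat(np.arange(n_women), n_births)
    birth_cmc = interview_cmc - 1 - rng.integers(0, lookback_months, size=len(woman_of_child))
    child_area_idx = np.array(
        [area_index[w_area[w]] for w in woman_of_child], dtype=int
    ) if len(woman_of_child) else np.zeros(0, dtype=int)

    # month-by-month survival
    alive = np.ones(len(birth_cmc), dtype=bool)
    age_at_death = np.full(len(birth_cmc), -1, dtype=int)
    max_age = interview_cmc - birth_cmc  # months observed: [0, max_age)
    for m in range(180):
        at_risk = alive & (m < max_age)
        if not at_risk.any():
            break
        cal = birth_cmc[at_risk] + m
        t = np.clip(np.searchsorted(breaks, cal, side="right") - 1, 0, len(breaks) - 2)
        p = hazards[child_area_idx[at_risk], t, m]
        dead = rng.random(at_risk.sum()) < p
        idx = np.flatnonzero(at_risk)[dead]
        alive[idx] = False
        age_at_death[idx] = m

    died = ~alive
    df = pd.DataFrame(
        {
            "survey_id": survey_id,
            "stratum": np.array(w_stratum, dtype=object)[woman_of_child],
            "cluster": np.array(w_cluster, dtype=object)[woman_of_child],
            "woman_id": np.array(
                [f"{w_stratum[w]}_w{w}" for w in woman_of_child], dtype=object
            ),
            "weight": np.array(w_weight)[woman_of_child],
            "interview_cmc": interview_cmc,
            "birth_cmc": birth_cmc,
            "died": died,
            "age_at_death_months": pd.array(
                np.where(died, age_at_death, 0), dtype="Int64"
            ),
            "admin1": np.array([w_area[w] for w in woman_of_child], dtype=object),
        }
    )
    df.loc[~died, "age_at_death_months"] = pd.NA
    return df[RECORD_COLUMNS]


def validate_records(df: pd.DataFrame) -> None:
    """Raise if any full-birth-history row violates the schema invariants."""
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if (df["weight"] <= 0).any():
        raise ValueError("weights must be strictly positive")
    if (df["birth_cmc"] > df["interview_cmc"]).any():
        raise ValueError("birth after interview")
    dead = df[df["died"].astype(bool)]
    if dead["age_at_death_months"].isna().any():
        raise ValueError("died=True requires age_at_death_months")
    if (dead["age_at_death_months"] < 0).any():
        raise ValueError("negative age at death")
    if (dead["birth_cmc"] + dead["age_at_death_months"] > dead["interview_cmc"]).any():
        raise ValueError("death after interview")


def write_records(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["died"] = out["died"].astype(bool).astype(int)
    out.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "survey_id": str,
            "stratum": str,
            "cluster": str,
            "woman_id": str,
            "admin1": str,
        },
    )
    df["died"] = df["died"].astype(bool)
    df["age_at_death_months"] = pd.array(df["age_at_death_months"], dtype="Int64")
    validate_records(df)
    return df
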