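"""Bayesian space-time smoothing of pooled logit estimates.

The observation model treats each pooled cell as a Gaussian measurement
of a latent logit surface with known variance; the surface decomposes
additively into an overall level (flat prior), iid and RW2 temporal
terms, iid and ICAR spatial terms, and an RW2 x ICAR (type-IV)
interaction, with Gamma hyperpriors on the precisions.

Everything is conditionally Gaussian, so inference is by a blocked Gibbs
sampler: the full latent vector is drawn jointly from its Gaussian full
conditional (exact, via dense Cholesky — Admin-1 problems are small) and
the precisions from their conjugate Gamma full conditionals. Intrinsic
components are parametrized on bases of their constraint subspaces, so
sum-to-zero constraints hold exactly in every draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, helmert, solve_triangular

from .graphs import AdjacencyGraph
from .structure import (
    build_icar_precision,
    build_interaction_precision,
    build_rw2_precision,
    scaled_structure,
)

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "PosteriorDraws",
    "fit_smoothing_model",
    "posterior_summaries",
    "write_draws",
    "read_draws",
]

COMPONENTS = ("alpha", "gamma", "theta", "phi", "delta")


@dataclass(frozen=True)
class ModelSpec:
    """Sampler and prior configuration.

    ``a`` and ``b`` are the Gamma(shape, rate) hyperprior parameters on
    every precision (variances are configurable per component via
    ``fixed_sigma2``, which pins a component's variance instead of
    sampling it; a fixed value of 0 removes the component).
    """

    a: float = 0.5
    b: float = 0.00149
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    scale_structure: bool = False
    fixed_sigma2: dict = field(default_factory=dict)
    rhat_threshold: float = 1.05

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("hyperprior parameters must be positive")
        if self.draws < 1 or self.chains < 1 or self.warmup < 0:
            raise ValueError("invalid sampler settings")
        for k in self.fixed_sigma2:
            if k not in COMPONENTS:
                raise ValueError(f"unknown component {k!r}")


@dataclass
class PosteriorDraws:
    """Joint posterior samples of the latent surface and hyperparameters."""

    areas: tuple
    period_labels: tuple
    age_group: str
    mu: np.ndarray  # (S,)
    alpha: np.ndarray  # (S, T)
    gamma: np.ndarray  # (S, T)
    theta: np.ndarray  # (S, n)
    phi: np.ndarray  # (S, n)
    delta: np.ndarray  # (S, n, T)
    sigma2: dict  # component -> (S,)
    n_chains: int = 1
    diagnostics: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.areas)

    @property
    def T(self) -> int:
        return len(self.period_labels)

    @property
    def n_draws(self) -> int:
        return len(self.mu)

    @property
    def lambda_draws(self) -> np.ndarray:
        """(S, n, T) latent logits, assembled from the component draws."""
        return (
            self.mu[:, None, None]
            + self.alpha[:, None, :]
            + self.gamma[:, None, :]
            + self.theta[:, :, None]
            + self.phi[:, :, None]
            + self.delta
        )

    @property
    def q_draws(self) -> np.ndarray:
        """(S, n, T) block probabilities, inverse-logit of the latent logits."""
        return 1.0 / (1.0 + np.exp(-self.lambda_draws))


def _sum_zero_basis(m: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace of R^m, as columns."""
    return helmert(m, full=False).T


def _row_space_basis(q: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Orthonormal basis (columns) of the row space of a PSD structure matrix."""
    w, v = np.linalg.eigh(q)
    return v[:, w > rtol * w.max()]


def _phi_parametrization(graph: AdjacencyGraph, scale: bool):
    """Basis and effective structure matrix for the ICAR component.

    Sum-to-zero is imposed per connected component; degree-0 islands stay
    free but are penalized as iid, so their conditional prior is
    N(0, sigma2_phi).
    """
    q = build_icar_precision(graph)
    if scale:
        q = scaled_structure(q)
    n = graph.n
    idx = {v: i for i, v in enumerate(graph.nodes)}
    cols = []
    q_eff = q.copy()
    for comp in graph.components:
        members = sorted(idx[v] for v in comp)
        if len(members) == 1:
            q_eff[members[0], members[0]] += 1.0
            col = np.zeros(n)
            col[members[0]] = 1.0
            cols.append(col)
        else:
            h = _sum_zero_basis(len(members))
            for j in range(h.shape[1]):
                col = np.zeros(n)
                col[members] = h[:, j]
                cols.append(col)
    return np.column_stack(cols), q_eff, q


def _numeric_rank(k: np.ndarray, rtol: float = 1e-9) -> int:
    w = np.linalg.eigvalsh(k)
    top = w.max() if len(w) else 0.0
    if top <= 0:
        return 0
    return int((w > rtol * top).sum())


class _ModelAssembly:
    """Design matrix, constraint bases and structure forms for one fit."""

    def __init__(self, graph: AdjacencyGraph, T: int, spec: ModelSpec):
        n = graph.n
        if T < 3:
            raise ValueError("need at least 3 periods for the RW2 prior")
        self.n, self.T = n, T
        r_time = build_rw2_precision(T)
        if spec.scale_structure:
            r_time = scaled_structure(r_time)
        b_phi, q_phi_eff, q_space = _phi_parametrization(graph, spec.scale_structure)
        q_inter, _ = build_interaction_precision(r_time, q_space)
        b_gamma = _sum_zero_basis(T)
        # delta lives on the row space of its structure matrix: this yields a
        # proper prior with exactly (T-2)(n-c) free dimensions and implies the
        # row/column sum-to-zero constraints (the constraint vectors lie in
        # the null space)
        b_delta = np.kron(_row_space_basis(r_time), _row_space_basis(q_space))

        self.active = [c for c in COMPONENTS if spec.fixed_sigma2.get(c, None) != 0]
        blocks: dict[str, np.ndarray] = {}
        forms: dict[str, np.ndarray] = {}
        ones_n = np.ones((n, 1))
        ones_T = np.ones((T, 1))
        maps = {
            "alpha": (np.kron(np.eye(T), ones_n), np.eye(T)),
            "gamma": (np.kron(b_gamma, ones_n), b_gamma.T @ r_time @ b_gamma),
            "theta": (np.kron(ones_T, np.eye(n)), np.eye(n)),
            "phi": (np.kron(ones_T, b_phi), b_phi.T @ q_phi_eff @ b_phi),
            "delta": (b_delta, b_delta.T @ q_inter @ b_delta),
        }
        cols = [np.ones((n * T, 1))]
        self.slices: dict[str, slice] = {}
        pos = 1
        for c in self.active:
            fmap, k = maps[c]
            blocks[c] = fmap
            forms[c] = k
            self.slices[c] = slice(pos, pos + fmap.shape[1])
            pos += fmap.shape[1]
            cols.append(fmap)
        self.f = np.hstack(cols)  # lambda vec (period-major) = f @ z
        self.dim = pos
        self.forms = forms
        self.ranks = {c: _numeric_rank(forms[c]) for c in self.active}
        self.bases = {"gamma": b_gamma, "phi": b_phi, "delta": b_delta}

    def prior_precision(self, tau: dict) -> np.ndarray:
        q = np.zeros((self.dim, self.dim))
        for c in self.active:
            s = self.slices[c]
            q[s, s] = tau[c] * self.forms[c]
        return q

    def unpack(self, z: np.ndarray) -> dict:
        out = {"mu": float(z[0])}
        zero_t, zero_n = np.zeros(self.T), np.zeros(self.n)
        get = lambda c: z[self.slices[c]] if c in self.slices else None
        out["alpha"] = get("alpha") if "alpha" in self.slices else zero_t
        u = get("gamma")
        out["gamma"] = self.bases["gamma"] @ u if u is not None else zero_t
        out["theta"] = get("theta") if "theta" in self.slices else zero_n
        u = get("phi")
        out["phi"] = self.bases["phi"] @ u if u is not None else zero_n
        u = get("delta")
        dv = self.bases["delta"] @ u if u is not None else np.zeros(self.n * self.T)
        out["delta"] = dv.reshape(self.T, self.n).T
        return out


def _split_rhat(x: np.ndarray) -> float:
    """Split-R̂ of one scalar; x has shape (chains, draws_per_chain)."""
    c, d = x.shape
    half = d // 2
    if half < 2:
        return np.nan
    segs = x[:, : 2 * half].reshape(c * 2, half)
    w = segs.var(axis=1, ddof=1).mean()
    if w <= 1e-300:
        return 1.0
    b = half * segs.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def fit_smoothing_model(
    pooled: pd.DataFrame,
    graph: AdjacencyGraph,
    spec: ModelSpec,
    age_group: str | None = None,
) -> PosteriorDraws:
    """Sample the posterior of the latent surface given pooled estimates.

    ``pooled`` must carry columns (admin1, period, period_label, logit_q,
    var_logit_q, status); rows with status != "ok" contribute no
    likelihood term but their cells still receive draws through the
    space-time structure. Reproducible given ``spec.seed``.
    """
    df = pooled
    if age_group is not None and "age_group" in df.columns:
        df = df[df["age_group"] == age_group]
    if len(df) == 0:
        raise ValueError("no cells for the requested age group")
    areas = tuple(graph.nodes)
    if set(map(str, df["admin1"])) - set(map(str, areas)):
        raise ValueError("estimate table contains areas absent from the graph")
    T = int(df["period"].max()) + 1
    labels = [""] * T
    for _, r in df.iterrows():
        labels[int(r["period"])] = str(r["period_label"])

    asm = _ModelAssembly(graph, T, spec)
    area_idx = {str(a): i for i, a in enumerate(areas)}
    ok = df[df["status"] == "ok"]
    if len(ok) == 0:
        raise ValueError("all cells are missing; nothing to fit")
    if (ok["var_logit_q"] <= 0).any():
        raise ValueError("design variances must be positive")
    if ok["period"].nunique() < 2:
        # flat mu + unpenalized RW2 linear trend need two observed periods
        raise ValueError("need observed cells in at least 2 distinct periods")
    cell = ok["period"].astype(int).to_numpy() * graph.n + np.array(
        [area_idx[str(a)] for a in ok["admin1"]]
    )
    y = ok["logit_q"].to_numpy(dtype=float)
    v = ok["var_logit_q"].to_numpy(dtype=float)

    f_obs = asm.f[cell]
    ft_vinv_f = (f_obs / v[:, None]).T @ f_obs
    ft_vinv_y = f_obs.T @ (y / v)

    a_hyp, b_hyp = spec.a, spec.b
    n_keep = spec.draws
    total = spec.warmup + n_keep
    rng_master = np.random.default_rng(spec.seed)
    chain_seeds = rng_master.spawn(spec.chains)

    store = {
        "mu": np.empty((spec.chains, n_keep)),
        "alpha": np.empty((spec.chains, n_keep, T)),
        "gamma": np.empty((spec.chains, n_keep, T)),
        "theta": np.empty((spec.chains, n_keep, graph.n)),
        "phi": np.empty((spec.chains, n_keep, graph.n)),
        "delta": np.empty((spec.chains, n_keep, graph.n, T)),
    }
    sig_store = {c: np.empty((spec.chains, n_keep)) for c in COMPONENTS}

    for ch, rng in enumerate(chain_seeds):
        tau = {}
        for c in COMPONENTS:
            if c in spec.fixed_sigma2:
                s2 = spec.fixed_sigma2[c]
                tau[c] = np.inf if s2 == 0 else 1.0 / s2
            else:
                tau[c] = 100.0 * np.exp(rng.normal(scale=0.5))  # dispersed start
        for it in range(total):
            prec = asm.prior_precision({c: tau[c] for c in asm.active}) + ft_vinv_f
            try:
                cf = cho_factor(prec)
            except np.linalg.LinAlgError:
                prec = prec + 1e-8 * np.mean(np.diag(prec)) * np.eye(asm.dim)
                cf = cho_factor(prec)
            mean = cho_solve(cf, ft_vinv_y)
            eps = rng.standard_normal(asm.dim)
            z = mean + solve_triangular(cf[0], eps, lower=cf[1])
            comps = asm.unpack(z)
            for c in asm.active:
                if c in spec.fixed_sigma2:
                    continue
                u = z[asm.slices[c]]
                quad = max(float(u @ asm.forms[c] @ u), 0.0)
                tau[c] = rng.gamma(a_hyp + asm.ranks[c] / 2.0,
                                   1.0 / (b_hyp + quad / 2.0))
            if it >= spec.warmup:
                k = it - spec.warmup
                store["mu"][ch, k] = comps["mu"]
                for name in ("alpha", "gamma", "theta", "phi", "delta"):
                    store[name][ch, k] = comps[name]
                for c in COMPONENTS:
                    sig_store[c][ch, k] = (
                        spec.fixed_sigma2[c] if c in spec.fixed_sigma2
                        else 1.0 / tau[c]
                    )

    # convergence: split-Rhat over every lambda scalar and mu
    lam = (
        store["mu"][:, :, None, None]
        + store["alpha"][:, :, None, :]
        + store["gamma"][:, :, None, :]
        + store["theta"][:, :, :, None]
        + store["phi"][:, :, :, None]
        + store["delta"]
    )
    rhats = [_split_rhat(store["mu"])]
    for i in range(graph.n):
        for t in range(T):
            rhats.append(_split_rhat(lam[:, :, i, t]))
    max_rhat = float(np.nanmax(rhats))
    converged = max_rhat <= spec.rhat_threshold
    if not converged:
        log.warning("max split-Rhat %.3f exceeds %.2f", max_rhat, spec.rhat_threshold)

    flat = lambda arr: arr.reshape((spec.chains * n_keep,) + arr.shape[2:])
    return PosteriorDraws(
        areas=areas,
        period_labels=tuple(labels),
        age_group=age_group or (str(df["age_group"].iloc[0]) if "age_group" in df else ""),
        mu=flat(store["mu"]),
        alpha=flat(store["alpha"]),
        gamma=flat(store["gamma"]),
        theta=flat(store["theta"]),
        phi=flat(store["phi"]),
        delta=flat(store["delta"]),
        sigma2={c: flat(sig_store[c]) for c in COMPONENTS},
        n_chains=spec.chains,
        diagnostics={"max_rhat": max_rhat, "converged": converged},
    )


def posterior_summaries(
    draws: PosteriorDraws, quantiles=(0.025, 0.5, 0.975)
) -> pd.DataFrame:
    """Posterior mean, median and quantiles of q per (area, period)."""
    if draws.n_draws < 2:
        raise ValueError("need at least 2 draws")
    q = draws.q_draws
    rows = []
    qs = np.sort(np.asarray(quantiles, dtype=float))
    for i, area in enumerate(draws.areas):
        for t, label in enumerate(draws.period_labels):
            cell = q[:, i, t]
            row = dict(
                admin1=area, period=t, period_label=label,
                age_group=draws.age_group,
                mean=float(cell.mean()), median=float(np.median(cell)),
            )
            for p, val in zip(qs, np.quantile(cell, qs)):
                row[f"q{p:g}"] = float(val)
            rows.append(row)
    return pd.DataFrame(rows)


def write_draws(draws: PosteriorDraws, path) -> None:
    """Long-format CSV (draw, area, period, component, value)."""
    frames = []
    S = draws.n_draws
    d = np.arange(S)

    def block(component, values, area=None, period=None):
        frames.append(
            pd.DataFrame(
                {"draw": d, "area": "" if area is None else str(area),
                 "period": -1 if period is None else period,
                 "component": component, "value": values}
            )
        )

    block("mu", draws.mu)
    for c in COMPONENTS:
        block(f"sigma2_{c}", draws.sigma2[c])
    for t in range(draws.T):
        block("alpha", draws.alpha[:, t], period=t)
        block("gamma", draws.gamma[:, t], period=t)
    for i, area in enumerate(draws.areas):
        block("theta", draws.theta[:, i], area=area)
        block("phi", draws.phi[:, i], area=area)
        for t in range(draws.T):
            block("delta", draws.delta[:, i, t], area=area, period=t)
    meta = pd.DataFrame(
        {"draw": -1, "area": [str(a) for a in draws.areas], "period": -1,
         "component": "_area", "value": np.arange(draws.n)}
    )
    meta2 = pd.DataFrame(
        {"draw": -1, "area": list(draws.period_labels), "period": np.arange(draws.T),
         "component": "_period_label", "value": np.arange(draws.T)}
    )
    meta3 = pd.DataFrame(
        {"draw": -1, "area": [draws.age_group], "period": -1,
         "component": "_age_group", "value": [draws.n_chains]}
    )
    pd.concat(frames + [meta, meta2, meta3], ignore_index=True).to_csv(path, index=False)


def read_draws(path) -> PosteriorDraws:
    df = pd.read_csv(path, dtype={"area": str}, keep_default_na=False)
    areas = tuple(df[df["component"] == "_area"].sort_values("value")["area"])
    plabels = tuple(df[df["component"] == "_period_label"].sort_values("period")["area"])
    meta3 = df[df["component"] == "_age_group"].iloc[0]
    age_group, n_chains = str(meta3["area"]), int(meta3["value"])
    body = df[~df["component"].str.startswith("_")]
    S = int(body["draw"].max()) + 1
    n, T = len(areas), len(plabels)
    mu = np.empty(S)
    alpha, gamma = np.empty((S, T)), np.empty((S, T))
    theta, phi = np.empty((S, n)), np.empty((S, n))
    delta = np.empty((S, n, T))
    sigma2 = {}
    aidx = {a: i for i, a in enumerate(areas)}
    for comp, sub in body.groupby("component"):
        if comp == "mu":
            mu[sub["draw"].to_numpy()] = sub["value"].to_numpy()
        elif comp.startswith("sigma2_"):
            arr = np.empty(S)
            arr[sub["draw"].to_numpy()] = sub["value"].to_numpy()
            sigma2[comp.removeprefix("sigma2_")] = arr
        elif comp in ("alpha", "gamma"):
            tgt = alpha if comp == "alpha" else gamma
            tgt[sub["draw"].to_numpy(), sub["period"].to_numpy()] = sub["value"].to_numpy()
        elif comp in ("theta", "phi"):
            tgt = theta if comp == "theta" else phi
            ai = sub["area"].map(aidx).to_numpy()
            tgt[sub["draw"].to_numpy(), ai] = sub["value"].to_numpy()
        elif comp == "delta":
            ai = sub["area"].map(aidx).to_numpy()
            delta[sub["draw"].to_numpy(), ai, sub["period"].to_numpy()] = (
                sub["value"].to_numpy()
            )
    return PosteriorDraws(
        areas=areas, period_labels=plabels, age_group=age_group,
        mu=mu, alpha=alpha, gamma=gamma, theta=theta, phi=phi, delta=delta,
        sigma2=sigma2, n_chains=n_chains,
    )
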