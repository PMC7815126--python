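"""Intrinsic Gaussian Markov random field structure matrices.

ICAR (graph Laplacian), second-order random walk, and their Kronecker
product for the space-time interaction. All matrices are dense — Admin-1
problems have at most a few dozen areas and a handful of periods.
"""

from __future__ import annotations

import numpy as np

from .graphs import AdjacencyGraph

__all__ = [
    "build_icar_precision",
    "build_rw2_precision",
    "build_interaction_precision",
    "scaled_structure",
    "sample_intrinsic",
]


def build_icar_precision(graph: AdjacencyGraph) -> np.ndarray:
    """ICAR structure matrix Q = D - A in the graph's node order.

    Rows sum to zero; rank is n minus the number of connected components.
    """
    if graph.n < 2:
        raise ValueError("graph must have at least 2 nodes")
    a = graph.adjacency_matrix()
    return np.diag(a.sum(axis=1)) - a


def build_rw2_precision(T: int) -> np.ndarray:
    """Random-walk-2 structure matrix D2'D2 for a series of length T.

    D2 is the (T-2) x T second-difference operator. The null space is
    spanned by constant and linear sequences, so the rank is T - 2.
    """
    if T < 3:
        raise ValueError("RW2 needs T >= 3")
    d2 = np.zeros((T - 2, T))
    for i in range(T - 2):
        d2[i, i : i + 3] = (1.0, -2.0, 1.0)
    return d2.T @ d2


def build_interaction_precision(
    q_time: np.ndarray, q_space: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Type-IV interaction structure: Kronecker product Q_time x Q_space.

    Operates on vec(delta) stacked period-major: the spatial field of
    period 1 first, then period 2, etc. Returns ``(Q, C)`` where the rows
    of C are the identifiability constraints C @ vec(delta) = 0 — each
    area's time series and each period's spatial field sums to zero.
    """
    T = q_time.shape[0]
    n = q_space.shape[0]
    q = np.kron(q_time, q_space)
    constraints = []
    for i in range(n):  # area i's series over periods
        c = np.zeros(n * T)
        c[i::n] = 1.0
        constraints.append(c)
    for t in range(T):  # period t's spatial field
        c = np.zeros(n * T)
        c[t * n : (t + 1) * n] = 1.0
        constraints.append(c)
    return q, np.array(constraints)


def scaled_structure(q: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Rescale an intrinsic structure matrix to unit generalized variance.

    Divides Q by the geometric mean of the marginal variances of its
    generalized inverse, so a precision hyperparameter is comparable
    across components.
    """
    w, v = np.linalg.eigh(q)
    pos = w > rtol * w.max()
    diag_cov = (v[:, pos] ** 2 / w[pos]).sum(axis=1)
    gv = np.exp(np.mean(np.log(diag_cov)))
    return q * gv


def sample_intrinsic(
    q: np.ndarray, sigma2: float, rng: np.random.Generator, rtol: float = 1e-9
) -> np.ndarray:
    """Draw from the intrinsic Gaussian with precision Q/sigma2.

    The draw lives in the row space of Q (orthogonal to the null space),
    which realises the usual sum-to-zero style constraints exactly.
    """
    if sigma2 < 0:
        raise ValueError("variance must be >= 0")
    if sigma2 == 0:
        return np.zeros(q.shape[0])
    w, v = np.linalg.eigh(q)
    pos = w > rtol * w.max()
    z = rng.standard_normal(int(pos.sum()))
    return v[:, pos] @ (z * np.sqrt(sigma2 / w[pos]))
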