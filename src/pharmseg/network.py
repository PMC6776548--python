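"""Weighted cell-line similarity network from multi-metric drug response.

Every pair of cell lines (i, j) is compared through a quasi-Gaussian
similarity w = exp(-d) with

    d(X_i, X_j) = (dX' pinv(Sigma_ij) dX) ** beta,      dX = X_i - X_j,

where Sigma_ij is a rank-one, 4x4 covariance-like matrix built from the
pairwise difference and the mean signed difference of each vertex to the
rest of the (complete) graph:

    t(a)      = dX(a) + g_i(a) + g_j(a)
    g_i(a)    = mean over k != i of (X_i(a) - X_k(a))
    Sigma_ij  = t t' / 9.

Because Sigma_ij = t t' / 9 has rank <= 1, its Moore-Penrose pseudo-inverse
has the closed form 9 t t' / ||t||^4, giving

    d = (9 (t . dX)^2 / ||t||^4) ** beta            (t != 0)

and d = 0 when t = 0 (the pseudo-inverse of the zero matrix is zero).  A
generic SVD-based pseudo-inverse path is retained for cross-checking.

The similarity lies in (0, 1], equals 1 exactly when the two profiles are
identical, and shrinks as profiles diverge relative to the network-wide
statistics folded into t.  Note that t is orientation-dependent (swapping i
and j does not simply flip its sign), so the adjacency matrix is computed
once per unordered pair with the (min, max) orientation and mirrored,
making W exactly symmetric.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_prep import Cohort

#: below this Euclidean norm, t is treated as exactly zero (rank-0 Sigma).
T_NORM_TOL = 1e-12
#: cap on d before exp(-d) so similarities never underflow out of (0, 1].
MAX_DISTANCE = 700.0
DEFAULT_BETA = 0.5


@dataclass
class PairwiseDifferences:
    """Signed difference tensor and per-vertex neighbourhood means.

    ``delta[i, j, a] = X_i(a) - X_j(a)`` (antisymmetric, zero diagonal);
    ``ngbd_mean[i, a]`` averages ``delta[i, k, a]`` over the complete-graph
    neighbourhood k != i.  With signed differences this equals
    ``N/(N-1) * (X_i(a) - mean(X(a)))``, a centrality statistic.
    """

    delta: np.ndarray  # (N, N, 4)
    ngbd_mean: np.ndarray  # (N, 4)

    @property
    def n(self) -> int:
        return self.delta.shape[0]


@dataclass
class SigmaMatrix:
    sigma: np.ndarray  # (4, 4), rank <= 1, PSD
    t_vector: np.ndarray  # (4,)


@dataclass
class WeightedAdjacency:
    """Symmetric N x N similarity matrix with w in (0, 1] off-diagonal.

    The diagonal is held at 0 by convention; it does not enter the graph
    Laplacian used for bisection.
    """

    w: np.ndarray
    beta: float = DEFAULT_BETA

    @property
    def n(self) -> int:
        return self.w.shape[0]


def pairwise_differences(cohort: Cohort, absolute: bool = False) -> PairwiseDifferences:
    """All signed DRP differences plus complete-graph neighbourhood means.

    ``absolute=True`` averages |delta| instead of signed delta in the
    neighbourhood means (an alternative reading, not the default).
    """
    if not cohort.standardized:
        raise ValueError("cohort must be standardized before building the network")
    if cohort.n < 2:
        raise ValueError("need at least 2 cell lines")
    x = cohort.drp
    delta = x[:, None, :] - x[None, :, :]
    base = np.abs(delta) if absolute else delta
    ngbd_mean = base.sum(axis=1) / (cohort.n - 1)
    return PairwiseDifferences(delta=delta, ngbd_mean=ngbd_mean)


def sigma(i: int, j: int, diffs: PairwiseDifferences) -> SigmaMatrix:
    """The rank-one covariance-like matrix Sigma_ij = t t' / 9 for pair (i, j)."""
    if i == j:
        raise ValueError("sigma is defined for distinct vertices only")
    t = diffs.delta[i, j] + diffs.ngbd_mean[i] + diffs.ngbd_mean[j]
    return SigmaMatrix(sigma=np.outer(t, t) / 9.0, t_vector=t)


def distance(
    i: int,
    j: int,
    diffs: PairwiseDifferences,
    beta: float = DEFAULT_BETA,
    method: str = "closed_form",
) -> float:
    """Sigma-weighted distance d(i, j) = (dX' pinv(Sigma) dX) ** beta.

    ``method='closed_form'`` uses the rank-one pseudo-inverse identity;
    ``method='pinv'`` goes through a generic SVD pseudo-inverse (slow, kept
    as an independent numerical route for testing).
    """
    if i == j:
        raise ValueError("distance is defined for distinct vertices only")
    if beta <= 0:
        raise ValueError("beta must be positive")
    dx = diffs.delta[i, j]
    t = diffs.delta[i, j] + diffs.ngbd_mean[i] + diffs.ngbd_mean[j]
    if method == "closed_form":
        nt2 = float(t @ t)
        if nt2 < T_NORM_TOL**2:
            return 0.0
        q = 9.0 * float(t @ dx) ** 2 / nt2**2
    elif method == "pinv":
        s = np.outer(t, t) / 9.0
        q = float(dx @ np.linalg.pinv(s) @ dx)
        q = max(q, 0.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    if q == 0.0:
        return 0.0
    return float(min(q**beta, MAX_DISTANCE))


def adjacency(
    cohort: Cohort, beta: float = DEFAULT_BETA, absolute: bool = False
) -> WeightedAdjacency:
    """Dense similarity matrix W with w_ij = exp(-d(i, j)), diagonal 0.

    Each unordered pair is evaluated once with orientation (min, max) and
    mirrored, so W is exactly symmetric.
    """
    diffs = pairwise_differences(cohort, absolute=absolute)
    n = diffs.n
    t = diffs.delta + diffs.ngbd_mean[:, None, :] + diffs.ngbd_mean[None, :, :]
    nt2 = np.einsum("ija,ija->ij", t, t)
    tdx = np.einsum("ija,ija->ij", t, diffs.delta)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = 9.0 * tdx**2 / nt2**2
    q[nt2 < T_NORM_TOL**2] = 0.0
    d = np.zeros_like(q)
    pos = q > 0.0
    d[pos] = np.minimum(q[pos] ** beta, MAX_DISTANCE)
    w = np.exp(-d)
    # keep only the (i < j) orientation and mirror it
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = w[iu]
    out = out + out.T
    return WeightedAdjacency(w=out, beta=beta)


def write_adjacency(adj: WeightedAdjacency, cell_line_ids: list[str], path) -> None:
    """Optional inspection export of W as a square delimited matrix."""
    import pandas as pd

    pd.DataFrame(adj.w, index=cell_line_ids, columns=cell_line_ids).to_csv(
        path, sep="\t", index_label="CELL_LINE_ID"
    )
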