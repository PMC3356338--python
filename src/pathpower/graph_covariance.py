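"""Network-consistent covariance construction (Gaussian graphical models).

For a multivariate normal vector the precision matrix ``K = sigma^{-1}``
encodes conditional independence: the partial correlation between genes *i*
and *j* given the rest is ``rho_ij|rest = -k_ij / sqrt(k_ii k_jj)``, so
``k_ij = 0`` exactly when *i* and *j* are conditionally independent.  A
distribution is *Markov* with respect to an undirected network when every
missing edge corresponds to such a zero.  This module builds covariance
matrices whose precision respects a given :class:`~pathpower.network.GeneNetwork`,
verifies that consistency, and samples expression data from the model.

Two constructions are offered:

``ipf_covariance``
    Pairwise iterative proportional scaling.  Starting from the identity
    precision, each sweep updates the 2x2 precision block of every edge so the
    implied marginal covariance of that gene pair matches the target block
    ``[[1, rho], [rho, 1]]`` (plus rank-one vertex updates enforcing unit
    variances).  Off-edge precision entries are never touched, so conditional
    independence holds *exactly* by construction; the sweeps converge to the
    unique Gaussian graphical model matching all edge marginals.

``projection_covariance``
    Alternating projection between the linear subspace of precision matrices
    with zeros on non-edges and the positive-definite cone (eigenvalue floor),
    with a unit-diagonal rescaling.  Only consistency is promised; edge
    correlation magnitudes are whatever the random starting point yields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import GeneNetwork

__all__ = [
    "CovarianceModel",
    "ConsistencyReport",
    "NotPositiveDefiniteError",
    "CovarianceInfeasibleError",
    "ConvergenceError",
    "partial_correlations",
    "ipf_covariance",
    "projection_covariance",
    "check_consistency",
    "sample_mvn",
]


class NotPositiveDefiniteError(ValueError):
    """Input matrix is not symmetric positive definite."""


class CovarianceInfeasibleError(ValueError):
    """No positive-definite covariance satisfies the requested constraints."""


class ConvergenceError(RuntimeError):
    """Iteration budget exhausted before reaching the tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last residual {residual:.3e})")
        self.residual = residual


@dataclass
class CovarianceModel:
    """A covariance matrix together with its precision and its network.

    Invariants: ``sigma`` symmetric positive definite with
    ``precision @ sigma = I``; for every non-adjacent gene pair the partial
    correlation vanishes (within the construction tolerance).
    """

    sigma: np.ndarray
    precision: np.ndarray
    graph: GeneNetwork
    target_edge_correlation: float | None = None

    @property
    def p(self) -> int:
        return self.sigma.shape[0]


@dataclass
class ConsistencyReport:
    max_offgraph_partial: float
    min_eigenvalue: float
    mean_edge_correlation: float
    passed: bool


def _require_spd(sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(sigma, sigma.T, atol=1e-10, rtol=0):
        raise NotPositiveDefiniteError("matrix is not symmetric within 1e-10")
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals[0] <= 0:
        raise NotPositiveDefiniteError(
            f"matrix is not positive definite: smallest eigenvalue {eigvals[0]:.6e}"
        )
    return sigma


def partial_correlations(sigma: np.ndarray) -> np.ndarray:
    """Matrix of partial correlations given all remaining variables.

    ``rho_ij|rest = -k_ij / sqrt(k_ii k_jj)`` with ``K = sigma^{-1}``;
    the diagonal is set to 1.
    """
    sigma = _require_spd(sigma)
    k = np.linalg.inv(sigma)
    d = np.sqrt(np.diag(k))
    rho = -k / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return (rho + rho.T) / 2.0


def _offgraph_mask(graph: GeneNetwork) -> np.ndarray:
    """Boolean p x p mask selecting non-adjacent off-diagonal pairs."""
    p = graph.n_nodes
    mask = ~np.eye(p, dtype=bool)
    for i, j in graph.edge_indices():
        mask[i, j] = mask[j, i] = False
    return mask


def ipf_covariance(
    graph: GeneNetwork,
    target_edge_correlation: float,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> CovarianceModel:
    """Covariance with unit diagonal, ``rho`` on every edge, GGM-consistent.

    Pairwise iterative proportional scaling over edges plus rank-one vertex
    updates.  Sweeps stop once the constraint residual
    ``max(|sigma_ij - rho| over edges, |sigma_ii - 1|)`` drops below ``tol``,
    which realises the advertised postcondition directly.

    Raises
    ------
    CovarianceInfeasibleError
        If the constraints admit no positive-definite completion (the
        precision leaves the PD cone during fitting).
    ConvergenceError
        If ``max_iter`` sweeps do not reach ``tol``.
    """
    r = float(target_edge_correlation)
    if not -1.0 < r < 1.0:
        raise ValueError("target edge correlation must lie in (-1, 1)")
    p = graph.n_nodes
    if p == 0:
        raise ValueError("graph has no nodes")
    edges = graph.edge_indices()
    if not edges:
        eye = np.eye(p)
        return CovarianceModel(eye.copy(), eye.copy(), graph, r)

    target_inv = np.linalg.inv(np.array([[1.0, r], [r, 1.0]]))
    K = np.eye(p)
    sigma = np.eye(p)
    eye2 = np.eye(2)
    residual = np.inf
    for _ in range(max_iter):
        for i, j in edges:
            idx = (i, j)
            s_block = sigma[np.ix_(idx, idx)]
            try:
                delta = target_inv - np.linalg.inv(s_block)
            except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
                raise CovarianceInfeasibleError(
                    f"singular marginal block on edge {idx}"
                ) from exc
            K[np.ix_(idx, idx)] += delta
            # rank-2 downdate of sigma (Woodbury, no inversion of delta)
            su = sigma[:, idx]
            middle = delta @ np.linalg.inv(eye2 + s_block @ delta)
            sigma -= su @ middle @ su.T
        # rank-1 vertex updates pin the diagonal (covers isolated vertices too)
        diag = np.diag(sigma).copy()
        for i in range(p):
            d = 1.0 - 1.0 / diag[i]
            if abs(d) < 1e-15:
                continue
            K[i, i] += d
            col = sigma[:, i]
            sigma -= np.outer(col, col) * (d / (1.0 + d * diag[i]))
            diag = np.diag(sigma).copy()
        # re-synchronise sigma with K (controls Woodbury drift) and check PD
        try:
            np.linalg.cholesky(K)
        except np.linalg.LinAlgError as exc:
            raise CovarianceInfeasibleError(
                f"precision left the positive-definite cone; target correlation "
                f"{r} is infeasible for this graph"
            ) from exc
        sigma = np.linalg.inv(K)
        sigma = (sigma + sigma.T) / 2.0
        edge_res = max(abs(sigma[i, j] - r) for i, j in edges)
        diag_res = float(np.max(np.abs(np.diag(sigma) - 1.0)))
        residual = max(edge_res, diag_res)
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"IPF did not converge in {max_iter} sweeps", residual
        )
    K = (K + K.T) / 2.0
    return CovarianceModel(sigma, K, graph, r)


def projection_covariance(
    graph: GeneNetwork,
    seed: int,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> CovarianceModel:
    """GGM-consistent covariance from a seeded random start.

    Alternates (i) zeroing non-edge precision entries with (ii) projection
    back into the PD cone by flooring eigenvalues at 1e-6, then rescales the
    covariance to unit diagonal (which preserves the precision zero pattern).
    Edge correlation strengths are not controlled.
    """
    p = graph.n_nodes
    if p == 0:
        raise ValueError("graph has no nodes")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((p, max(p, 2)))
    sigma = a @ a.T / a.shape[1] + 0.5 * np.eye(p)
    d = np.sqrt(np.diag(sigma))
    sigma = sigma / np.outer(d, d)

    offgraph = _offgraph_mask(graph)
    residual = np.inf
    for _ in range(max_iter):
        k = np.linalg.inv(sigma)
        k = (k + k.T) / 2.0
        k[offgraph] = 0.0
        eigvals, eigvecs = np.linalg.eigh(k)
        if eigvals[0] < 1e-6:
            eigvals = np.clip(eigvals, 1e-6, None)
            k = (eigvecs * eigvals) @ eigvecs.T
            k = (k + k.T) / 2.0
        sigma = np.linalg.inv(k)
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
        sigma = (sigma + sigma.T) / 2.0
        partial = partial_correlations(sigma)
        residual = float(np.max(np.abs(partial[offgraph]))) if offgraph.any() else 0.0
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"projection did not converge in {max_iter} iterations", residual
        )
    precision = np.linalg.inv(sigma)
    precision = (precision + precision.T) / 2.0
    return CovarianceModel(sigma, precision, graph, None)


def check_consistency(model: CovarianceModel, tol: float = 1e-8
                      ) -> ConsistencyReport:
    """Verify that a model's covariance is Markov w.r.t. its graph.

    Always returns a report; ``passed`` is True when the largest off-graph
    partial correlation is below ``tol`` and the covariance is PD.
    """
    eigvals = np.linalg.eigvalsh(model.sigma)
    min_eig = float(eigvals[0])
    partial = (
        partial_correlations(model.sigma) if min_eig > 0
        else np.full_like(model.sigma, np.nan)
    )
    offgraph = _offgraph_mask(model.graph)
    max_off = float(np.max(np.abs(partial[offgraph]))) if offgraph.any() else 0.0
    edges = model.graph.edge_indices()
    mean_edge = (
        float(np.mean([model.sigma[i, j] for i, j in edges])) if edges else float("nan")
    )
    passed = bool(min_eig > 0 and max_off < tol)
    return ConsistencyReport(max_off, min_eig, mean_edge, passed)


def sample_mvn(
    mean: np.ndarray, model: CovarianceModel, n: int, seed: int
) -> np.ndarray:
    """Draw ``n`` iid p-variate normal samples; returns a p x n matrix."""
    mean = np.asarray(mean, dtype=float)
    p = model.p
    if mean.shape != (p,):
        raise ValueError(f"mean has shape {mean.shape}, expected ({p},)")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(model.sigma)
    return mean[:, None] + chol @ rng.standard_normal((p, n))
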