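"""Crosstalk susceptibility matrices.

The susceptibility chi_ij = d_j * d[m_i]/d[b_j] measures the linear
response of the steady-state free level of RNA i to a small change in the
transcription rate of RNA j.  Linearizing the titration fixed point gives
the closed form

    chi = (I - W)^-1 diag(m/m*),

where W couples RNA pairs through their shared miRNA regulators:

    W_ij = (m_i^2 / m*_i) * sum_{a in (i and j)} (mu_a^2 / mu*_a)
           / (m0_ja * mu0_ia).

W is sparse (supported on co-regulated pairs) while chi is generically
dense: crosstalk propagates along chains of miRNA-mediated interactions,
so RNAs need not share a regulator to influence each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

from .network_model import InteractionNetwork, KineticParameters
from .steady_state import SteadyState, solve_steady_state

__all__ = [
    "SusceptibilityResult",
    "StabilityError",
    "build_W",
    "compute_susceptibility",
    "susceptibility_matrix",
    "finite_difference_susceptibility",
    "finite_difference_matrix",
]


class StabilityError(RuntimeError):
    """The linear-response expansion is invalid (spectral radius of W >= 1)."""


@dataclass(frozen=True)
class SusceptibilityResult:
    chi: np.ndarray  # dense N x N susceptibility matrix
    W: sparse.spmatrix  # sparse N x N coupling matrix
    chi_self: np.ndarray  # diagonal chi_ii
    spectral_radius: float | None = None  # power-iteration estimate, if requested


def build_W(
    network: InteractionNetwork,
    params: KineticParameters,
    state: SteadyState,
) -> sparse.csr_matrix:
    """Sparse coupling matrix over pairs of co-regulated RNAs.

    Computed as diag(m^2/m*) . A . D . B^T with A_ia = 1/mu0_ia,
    B_ja = 1/m0_ja on the edges and D = diag(mu_a^2/mu*_a); the diagonal
    (i = j) is included.
    """
    if not state.converged:
        raise ValueError("build_W requires a converged steady state")
    shape = (network.n_rna, network.n_mirna)
    ij = (network.edge_rna, network.edge_mirna)
    A = sparse.csr_matrix((1.0 / params.mu0_edge, ij), shape=shape)
    B = sparse.csr_matrix((1.0 / params.m0_edge, ij), shape=shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_mu = np.where(state.mu_star > 0, state.mu**2 / state.mu_star, 0.0)
    W = A @ sparse.diags(d_mu) @ B.T
    prefactor = state.m**2 / state.m_star
    return sparse.diags(prefactor) @ W.tocsr()


def compute_susceptibility(
    W: sparse.spmatrix,
    state: SteadyState,
    *,
    validate: bool = False,
) -> SusceptibilityResult:
    """Solve (I - W) chi = diag(m/m*) for the full susceptibility matrix.

    Uses a sparse LU factorization and N dense right-hand sides rather
    than an explicit inverse.  Negative entries or a failed factorization
    signal a spectral radius >= 1, i.e. a violated steady-state expansion,
    and raise :class:`StabilityError`.
    """
    n = W.shape[0]
    rhs = np.diag(state.m / state.m_star)
    A = (sparse.identity(n, format="csc") - W.tocsc()).tocsc()
    try:
        lu = spla.splu(A)
        chi = lu.solve(rhs)
    except RuntimeError as exc:
        raise StabilityError(f"(I - W) is numerically singular: {exc}") from None
    if not np.all(np.isfinite(chi)):
        raise StabilityError("susceptibility solve produced non-finite entries")
    tiny = -1e-10 * max(chi.max(), 1.0)
    if chi.min() < tiny:
        raise StabilityError(
            "negative susceptibilities indicate spectral radius of W >= 1 "
            f"(min entry {chi.min():.3e})"
        )
    chi = np.clip(chi, 0.0, None)
    rho_W = _power_iteration_radius(W) if validate else None
    if rho_W is not None and rho_W >= 1.0:
        raise StabilityError(f"spectral radius of W is {rho_W:.6f} >= 1")
    return SusceptibilityResult(chi=chi, W=W, chi_self=np.diag(chi).copy(), spectral_radius=rho_W)


def _power_iteration_radius(W: sparse.spmatrix, n_iter: int = 200, seed: int = 0) -> float:
    """Power-iteration estimate of the spectral radius of the non-negative W."""
    n = W.shape[0]
    rng = np.random.default_rng(seed)
    v = rng.random(n) + 1e-12
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(n_iter):
        w = W @ v
        nrm = np.linalg.norm(w)
        if nrm == 0.0:
            return 0.0
        lam = nrm
        v = w / nrm
    return float(lam)


def susceptibility_matrix(
    network: InteractionNetwork,
    params: KineticParameters,
    *,
    tol: float = 1e-12,
    validate: bool = False,
) -> tuple[SusceptibilityResult, SteadyState]:
    """Convenience wrapper: solve the steady state, then chi."""
    state = solve_steady_state(network, params, tol=tol)
    W = build_W(network, params, state)
    return compute_susceptibility(W, state, validate=validate), state


def finite_difference_matrix(
    network: InteractionNetwork,
    params: KineticParameters,
    rel_step: float = 1e-4,
    solver_tol: float = 1e-14,
) -> np.ndarray:
    """Full susceptibility matrix by central differences on each b_j.

    Independent of the linear-response formula: each column j is
    d_j * (m(b_j(1+eps)) - m(b_j(1-eps))) / (2 b_j eps) with both states
    re-solved at tightened tolerance.
    """
    n = network.n_rna
    chi = np.empty((n, n))
    for j in range(n):
        chi[:, j] = _fd_column(network, params, j, rel_step, solver_tol)
    return chi


def _fd_column(network, params, j, rel_step, solver_tol):
    b = params.b
    bj = b[j]
    if bj <= 0:
        raise ValueError("finite differences need a strictly positive b_j")
    up = b.copy()
    up[j] = bj * (1.0 + rel_step)
    down = b.copy()
    down[j] = bj * (1.0 - rel_step)
    m_up = solve_steady_state(network, params.with_rates(up, params.beta), tol=solver_tol).m
    m_dn = solve_steady_state(network, params.with_rates(down, params.beta), tol=solver_tol).m
    return params.d * (m_up - m_dn) / (2.0 * bj * rel_step)


def finite_difference_susceptibility(
    network: InteractionNetwork,
    params: KineticParameters,
    i: int,
    j: int,
    eps: float = 1e-4,
    solver_tol: float = 1e-14,
) -> float:
    """Single-entry central-difference estimate of chi_ij."""
    return float(_fd_column(network, params, j, eps, solver_tol)[i])
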