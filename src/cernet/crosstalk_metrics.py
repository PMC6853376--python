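"""Scalar descriptors of system-level crosstalk patterns.

All pairwise statistics run over *ordered* pairs of distinct RNA species
(the susceptibility is directional); self terms are reported separately.
Selectivities are inverse-participation-ratio statistics: g_i close to 1
means RNA i is influenced by few partners, g_i close to 1/(N-1) means
influence is spread evenly.  The locality kernel K_ij aggregates inverse
binding thresholds over shared regulators; its Pearson correlation with
chi quantifies how well local interaction parameters predict emergent
crosstalk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .network_model import InteractionNetwork, KineticParameters
from .steady_state import SteadyState

__all__ = [
    "CrosstalkSummary",
    "UndefinedMetricError",
    "intensity_stats",
    "selectivity",
    "locality_matrix",
    "locality_correlation",
    "asymmetry_index",
    "expression_cv",
    "sextile_persistence",
    "susceptible_region",
    "offdiag_values",
]


class UndefinedMetricError(ValueError):
    """A metric has no defined value for this input (e.g. all-zero chi)."""


@dataclass(frozen=True)
class CrosstalkSummary:
    """Scalar metrics of one susceptibility matrix / steady state."""

    mean_chi: float
    max_chi: float
    mean_self: float
    max_self: float
    s_in: float | None
    s_out: float | None
    rho: float | None
    cv_expression: float
    asymmetry: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "mean_chi": self.mean_chi,
            "max_chi": self.max_chi,
            "mean_self": self.mean_self,
            "max_self": self.max_self,
            "s_in": self.s_in,
            "s_out": self.s_out,
            "rho": self.rho,
            "cv_expression": self.cv_expression,
            "asymmetry": self.asymmetry,
        }


def offdiag_values(mat: np.ndarray) -> np.ndarray:
    """Flatten the off-diagonal entries in a fixed (row-major) pair order."""
    n = mat.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return mat[mask]


def intensity_stats(chi: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, max) of chi over ordered distinct pairs, and over the diagonal."""
    if chi.shape[0] < 2:
        raise ValueError("intensity statistics need at least two RNA species")
    off = offdiag_values(chi)
    diag = np.diag(chi)
    return float(off.mean()), float(off.max()), float(diag.mean()), float(diag.max())


def selectivity(chi: np.ndarray):
    """Inverse-participation selectivities (S_in, S_out, g, h).

    g_i = sum_{j != i} chi_ij^2 / (sum_{j != i} chi_ij)^2, over rows;
    h_j is the analogous column statistic.  Rows/columns whose
    off-diagonal sum is zero are undefined (NaN in g/h) and excluded from
    the S averages; if every row is undefined the metric itself is.
    """
    n = chi.shape[0]
    if n < 2:
        raise ValueError("selectivity needs at least two RNA species")
    off = chi * ~np.eye(n, dtype=bool)
    row_sum = off.sum(axis=1)
    col_sum = off.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(row_sum > 0, (off**2).sum(axis=1) / row_sum**2, np.nan)
        h = np.where(col_sum > 0, (off**2).sum(axis=0) / col_sum**2, np.nan)
    if np.all(np.isnan(g)) or np.all(np.isnan(h)):
        raise UndefinedMetricError("selectivity undefined: all off-diagonal sums are zero")
    return float(np.nanmean(g)), float(np.nanmean(h)), g, h


def locality_matrix(network: InteractionNetwork, params: KineticParameters) -> np.ndarray:
    """Kernel K_ij = (1/M) sum over shared miRNAs of 1/(mu0_ia * mu0_ja).

    Symmetric; zero exactly when i and j share no regulator.
    """
    shape = (network.n_rna, network.n_mirna)
    A = sparse.csr_matrix(
        (1.0 / params.mu0_edge, (network.edge_rna, network.edge_mirna)), shape=shape
    )
    return np.asarray((A @ A.T).todense()) / network.n_mirna


def locality_correlation(chi: np.ndarray, K: np.ndarray) -> float:
    """Pearson correlation of chi and K over ordered distinct pairs.

    Zeros are included.  Although the kernel-based construction makes the
    correlation positive in practice, the true Pearson value in [-1, 1]
    is returned.
    """
    x = offdiag_values(chi)
    y = offdiag_values(K)
    if x.size < 2:
        raise ValueError("need at least two ordered distinct pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedMetricError("locality correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def asymmetry_index(chi: np.ndarray, floor: float | None = None) -> float:
    """Mean relative difference |chi_ij - chi_ji| / (chi_ij + chi_ji).

    Averaged over unordered pairs whose susceptibility sum exceeds
    ``floor`` (default 1e-8 times the maximum off-diagonal entry, which
    drops numerically-zero pairs).  Lies in [0, 1]: 0 for a symmetric
    pattern, 1 when every pair is one-directional.
    """
    n = chi.shape[0]
    if n < 2:
        raise ValueError("asymmetry needs at least two RNA species")
    iu, ju = np.triu_indices(n, k=1)
    s = chi[iu, ju] + chi[ju, iu]
    if floor is None:
        off_max = offdiag_values(chi).max()
        floor = 1e-8 * off_max if off_max > 0 else 0.0
    if floor < 0:
        raise ValueError("floor must be non-negative")
    keep = s > floor
    if not np.any(keep):
        raise UndefinedMetricError("asymmetry undefined: no pair above the floor")
    num = np.abs(chi[iu, ju] - chi[ju, iu])[keep]
    return float(np.mean(num / s[keep]))


def expression_cv(state: SteadyState) -> float:
    """Coefficient of variation of steady-state free RNA levels."""
    if len(state.m) < 2:
        raise ValueError("expression CV needs at least two RNA species")
    return float(np.std(state.m) / np.mean(state.m))


def sextile_persistence(
    chi_mean_low: np.ndarray,
    chi_mean_high: np.ndarray,
    n_bins: int = 6,
    n_permutations: int = 1000,
    seed: int = 0,
):
    """Conservation of intensity ranking between two heterogeneity levels.

    Both inputs are realization-averaged susceptibilities over the same
    ordered pair set (flat arrays, or square matrices whose off-diagonals
    are taken in fixed order).  Pairs are ranked in each condition and cut
    into ``n_bins`` equal-size bins (strongest first; ties broken by pair
    index); returned are the per-bin fractions of pairs staying in their
    bin, the overall fraction, and a seeded rank-permutation chance
    baseline (which approaches 1/n_bins).
    """
    lo = np.asarray(chi_mean_low, float)
    hi = np.asarray(chi_mean_high, float)
    if lo.ndim == 2:
        lo = offdiag_values(lo)
    if hi.ndim == 2:
        hi = offdiag_values(hi)
    if lo.shape != hi.shape:
        raise ValueError("the two conditions cover different pair sets")
    n_pairs = lo.size
    if n_pairs < n_bins:
        raise ValueError(f"need at least {n_bins} pairs for {n_bins} bins")

    def bin_labels(values: np.ndarray) -> np.ndarray:
        order = np.lexsort((np.arange(n_pairs), -values))  # strongest first, stable
        labels = np.empty(n_pairs, dtype=np.intp)
        for k, chunk in enumerate(np.array_split(np.arange(n_pairs), n_bins)):
            labels[order[chunk]] = k
        return labels

    lab_lo = bin_labels(lo)
    lab_hi = bin_labels(hi)
    fractions = np.array(
        [np.mean(lab_hi[lab_lo == k] == k) for k in range(n_bins)]
    )
    overall = float(np.mean(lab_lo == lab_hi))

    rng = np.random.default_rng(seed)
    chance = np.empty(n_permutations)
    for p in range(n_permutations):
        chance[p] = np.mean(lab_lo == lab_hi[rng.permutation(n_pairs)])
    return fractions, overall, float(chance.mean())


def susceptible_region(
    beta_grid: np.ndarray,
    mean_chi: np.ndarray,
    frac: float = 0.05,
) -> tuple[float, float]:
    """Extent of the regime where mean crosstalk is appreciable.

    Returns the smallest and largest grid beta_mean whose mean chi is at
    least ``frac`` of the curve's peak.
    """
    beta_grid = np.asarray(beta_grid, float)
    mean_chi = np.asarray(mean_chi, float)
    if beta_grid.size < 3:
        raise ValueError("need at least 3 grid points")
    peak = mean_chi.max()
    if peak <= 0:
        raise UndefinedMetricError("susceptible region undefined: mean chi is zero everywhere")
    keep = beta_grid[mean_chi >= frac * peak]
    return float(keep.min()), float(keep.max())


def summarize(
    chi: np.ndarray,
    state: SteadyState,
    K: np.ndarray | None = None,
) -> CrosstalkSummary:
    """All scalar metrics of one realization, tolerating undefined cases."""
    mean_chi, max_chi, mean_self, max_self = intensity_stats(chi)
    try:
        s_in, s_out, _, _ = selectivity(chi)
    except UndefinedMetricError:
        s_in = s_out = None
    try:
        rho = locality_correlation(chi, K) if K is not None else None
    except UndefinedMetricError:
        rho = None
    try:
        asym = asymmetry_index(chi)
    except UndefinedMetricError:
        asym = None
    return CrosstalkSummary(
        mean_chi=mean_chi,
        max_chi=max_chi,
        mean_self=mean_self,
        max_self=max_self,
        s_in=s_in,
        s_out=s_out,
        rho=rho,
        cv_expression=expression_cv(state),
        asymmetry=asym,
    )
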