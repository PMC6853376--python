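"""Bipartite miRNA-RNA networks and their kinetic parameterization.

The model couples ``N`` RNA species to ``M`` miRNA species through a
bipartite interaction graph.  Each edge ``(i, a)`` carries one of four
binding-mode labels derived from CLASH-style interactome reconstructions
(perfect seed k-mers, non-canonical seed pairings, 9-nt non-seed stems,
and diffuse non-seed contacts).  Binding modes set the per-edge repression
threshold ``mu0_ia`` (the free-miRNA level at which repression of RNA *i*
by miRNA *a* crosses over), and the sequestration threshold ``m0_ia``
follows from the stoichiometricity tie

    mu0_ia / m0_ia = lam * d / delta,

with ``lam = sigma / (sigma + kappa)`` the fraction of complex decay that
consumes the miRNA.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BindingMode",
    "InteractionNetwork",
    "KineticParameters",
    "BHScenario",
    "assign_binding_strengths",
    "compute_m0",
    "derive_rate_constants",
    "build_parameters",
    "read_edge_list",
    "write_edge_list",
]


class BindingMode(enum.Enum):
    """The four CLASH interaction classes, strongest binding first."""

    KMER = "kmer"
    SEED_NC = "seed-nc"
    NOSEED_9NT = "noseed-9nt"
    NOSEED = "noseed"

    @classmethod
    def from_label(cls, label: str) -> "BindingMode":
        for mode in cls:
            if mode.value == label:
                return mode
        valid = ", ".join(m.value for m in cls)
        raise ValueError(f"unknown binding mode {label!r}; expected one of {valid}")


# Strongest -> weakest ranking used to resolve duplicate (rna, mirna) pairs.
MODE_STRENGTH_ORDER = (
    BindingMode.KMER,
    BindingMode.SEED_NC,
    BindingMode.NOSEED_9NT,
    BindingMode.NOSEED,
)
_MODE_RANK = {m: r for r, m in enumerate(MODE_STRENGTH_ORDER)}


@dataclass(frozen=True)
class InteractionNetwork:
    """Bipartite miRNA-RNA interaction graph.

    Edges are stored as three parallel arrays (RNA index, miRNA index,
    binding mode) with at most one edge per (RNA, miRNA) pair.
    """

    rna_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    edge_rna: np.ndarray  # int array, indices into rna_ids
    edge_mirna: np.ndarray  # int array, indices into mirna_ids
    edge_mode: tuple[BindingMode, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "edge_rna", np.asarray(self.edge_rna, dtype=np.intp))
        object.__setattr__(self, "edge_mirna", np.asarray(self.edge_mirna, dtype=np.intp))
        object.__setattr__(self, "edge_mode", tuple(self.edge_mode))
        self.validate()

    def validate(self) -> None:
        n, m = self.n_rna, self.n_mirna
        if n < 1 or m < 1:
            raise ValueError("network needs at least one RNA and one miRNA species")
        if len(set(self.rna_ids)) != n or len(set(self.mirna_ids)) != m:
            raise ValueError("node identifiers must be unique on each side")
        if not (len(self.edge_rna) == len(self.edge_mirna) == len(self.edge_mode)):
            raise ValueError("edge arrays have inconsistent lengths")
        if self.n_edges:
            if self.edge_rna.min() < 0 or self.edge_rna.max() >= n:
                raise ValueError("RNA edge index out of range")
            if self.edge_mirna.min() < 0 or self.edge_mirna.max() >= m:
                raise ValueError("miRNA edge index out of range")
        pairs = set(zip(self.edge_rna.tolist(), self.edge_mirna.tolist()))
        if len(pairs) != self.n_edges:
            raise ValueError("duplicate (rna, mirna) pairs are not allowed")

    @property
    def n_rna(self) -> int:
        return len(self.rna_ids)

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_rna)

    def rna_degrees(self) -> np.ndarray:
        return np.bincount(self.edge_rna, minlength=self.n_rna)

    def mirna_degrees(self) -> np.ndarray:
        return np.bincount(self.edge_mirna, minlength=self.n_mirna)

    def mode_counts(self) -> dict[BindingMode, int]:
        counts = dict.fromkeys(BindingMode, 0)
        for mode in self.edge_mode:
            counts[mode] += 1
        return counts

    def edges(self) -> list[tuple[int, int, BindingMode]]:
        return list(zip(self.edge_rna.tolist(), self.edge_mirna.tolist(), self.edge_mode))


@dataclass(frozen=True)
class BHScenario:
    """Binding-heterogeneity scenario: binding mode -> multiplier of mu0_base.

    ``low`` treats every edge identically (mu0 = 2*mu0_base); ``medium``
    singles out k-mer pairings as stronger (mu0 = mu0_base) with all other
    modes at 2*mu0_base; ``high`` places the four classes on a two-fold
    geometric ladder, strongest (k-mer) to weakest.
    """

    level: str
    multiplier_map: dict[BindingMode, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [m for m in BindingMode if m not in self.multiplier_map]
        if missing:
            raise ValueError(f"multiplier_map is missing modes: {missing}")
        if any(v <= 0 for v in self.multiplier_map.values()):
            raise ValueError("multipliers must be strictly positive")

    @classmethod
    def low(cls) -> "BHScenario":
        return cls("low", {m: 2.0 for m in BindingMode})

    @classmethod
    def medium(cls) -> "BHScenario":
        mult = {m: 2.0 for m in BindingMode}
        mult[BindingMode.KMER] = 1.0
        return cls("medium", mult)

    @classmethod
    def high(cls, order: tuple[BindingMode, ...] = MODE_STRENGTH_ORDER) -> "BHScenario":
        if set(order) != set(BindingMode):
            raise ValueError("order must be a permutation of the four binding modes")
        return cls("high", {mode: float(2**r) for r, mode in enumerate(order)})

    @classmethod
    def from_level(cls, level: str) -> "BHScenario":
        try:
            return {"low": cls.low, "medium": cls.medium, "high": cls.high}[level]()
        except KeyError:
            raise ValueError(f"unknown BH level {level!r}; expected low/medium/high") from None


@dataclass(frozen=True)
class KineticParameters:
    """Kinetic parameterization of a network.

    Rates are per hour, abundances in molecules per cell.  ``lam`` is the
    stoichiometricity ratio sigma/(sigma+kappa); ``complex_decay_total`` is
    sigma+kappa, a nuisance scale that only affects complex abundances and
    transient dynamics, never the free-species steady state (the
    association rate is tied to mu0 with zero unbinding).
    """

    d: float  # RNA degradation rate [1/h]
    delta: float  # miRNA degradation rate [1/h]
    lam: float  # stoichiometricity ratio, in (0, 1]
    mu0_base: float  # reference repression threshold [molecules]
    b: np.ndarray  # RNA transcription rates [molecules/h], length N
    beta: np.ndarray  # miRNA transcription rates [molecules/h], length M
    mu0_edge: np.ndarray  # per-edge repression thresholds [molecules]
    m0_edge: np.ndarray  # per-edge sequestration thresholds [molecules]
    complex_decay_total: float = 1.0  # sigma + kappa [1/h]

    def __post_init__(self) -> None:
        for name in ("b", "beta", "mu0_edge", "m0_edge"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if min(self.d, self.delta, self.mu0_base, self.complex_decay_total) <= 0:
            raise ValueError("rates and thresholds must be strictly positive")
        if not 0 < self.lam <= 1:
            raise ValueError("stoichiometricity ratio lam must lie in (0, 1]")
        if np.any(self.b < 0) or np.any(self.beta < 0):
            raise ValueError("transcription rates must be non-negative")
        if np.any(self.mu0_edge <= 0) or np.any(self.m0_edge <= 0):
            raise ValueError("edge thresholds must be strictly positive")
        expected = self.mu0_edge * self.delta / (self.lam * self.d)
        if not np.allclose(self.m0_edge, expected, rtol=1e-12, atol=0):
            raise ValueError("m0_edge violates the stoichiometric tie mu0*delta/(lam*d)")

    def with_rates(self, b: np.ndarray, beta: np.ndarray) -> "KineticParameters":
        """Return a copy with new transcription-rate vectors."""
        return replace(self, b=np.asarray(b, float), beta=np.asarray(beta, float))


def assign_binding_strengths(
    network: InteractionNetwork,
    scenario: BHScenario,
    mu0_base: float,
) -> np.ndarray:
    """Per-edge repression thresholds mu0_ia = mu0_base * multiplier(mode).

    Deterministic and independent of edge order; the network is not
    modified.
    """
    if mu0_base <= 0:
        raise ValueError("mu0_base must be strictly positive")
    out = np.empty(network.n_edges, dtype=float)
    for e, mode in enumerate(network.edge_mode):
        try:
            mult = scenario.multiplier_map[mode]
        except KeyError:
            raise ValueError(
                f"edge ({network.rna_ids[network.edge_rna[e]]}, "
                f"{network.mirna_ids[network.edge_mirna[e]]}) carries "
                f"unknown binding mode {mode!r}"
            ) from None
        out[e] = mu0_base * mult
    return out


def compute_m0(mu0, *, d: float, delta: float, lam: float):
    """Sequestration threshold m0 from the stoichiometric tie.

    m0 = mu0 * delta / (lam * d); the ratio mu0/m0 = lam*d/delta is
    independent of mu0.
    """
    mu0 = np.asarray(mu0, dtype=float)
    if np.any(mu0 <= 0) or d <= 0 or delta <= 0 or not 0 < lam <= 1:
        raise ValueError("compute_m0 requires positive inputs and lam in (0, 1]")
    out = mu0 * delta / (lam * d)
    return float(out) if out.ndim == 0 else out


def derive_rate_constants(mu0, *, d: float, lam: float, complex_decay_total: float = 1.0):
    """Microscopic rate constants (k_on, k_off, sigma, kappa) realizing mu0.

    Unbinding is taken negligible (k_off = 0), so mu0 = d / k_on fixes the
    association rate, and ``complex_decay_total`` is split between the
    stoichiometric (sigma) and catalytic (kappa) decay channels according
    to lam.
    """
    mu0 = np.asarray(mu0, dtype=float)
    if np.any(mu0 <= 0) or d <= 0 or complex_decay_total <= 0 or not 0 < lam <= 1:
        raise ValueError("derive_rate_constants requires positive inputs")
    k_on = d / mu0
    k_on = float(k_on) if k_on.ndim == 0 else k_on
    sigma = lam * complex_decay_total
    kappa = (1.0 - lam) * complex_decay_total
    return k_on, 0.0, sigma, kappa


def build_parameters(
    network: InteractionNetwork,
    scenario: BHScenario,
    b: np.ndarray,
    beta: np.ndarray,
    *,
    d: float = 0.08,
    delta: float = 0.027,
    lam: float = 0.2,
    mu0_base: float = 4.0,
    complex_decay_total: float = 1.0,
) -> KineticParameters:
    """Assemble a complete :class:`KineticParameters` for a network.

    Defaults are the empirically motivated global rates: RNA degradation
    0.08/h, miRNA degradation 0.027/h, stoichiometricity 0.2, reference
    threshold 4 molecules.
    """
    b = np.asarray(b, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if b.shape != (network.n_rna,) or beta.shape != (network.n_mirna,):
        raise ValueError("transcription-rate vectors must match network node counts")
    mu0_edge = assign_binding_strengths(network, scenario, mu0_base)
    m0_edge = compute_m0(mu0_edge, d=d, delta=delta, lam=lam)
    return KineticParameters(
        d=d,
        delta=delta,
        lam=lam,
        mu0_base=mu0_base,
        b=b,
        beta=beta,
        mu0_edge=mu0_edge,
        m0_edge=m0_edge,
        complex_decay_total=complex_decay_total,
    )


# ---------------------------------------------------------------------------
# Edge-list I/O
#
# TSV dialect: header `rna_id<TAB>mirna_id<TAB>binding_mode`, one edge per
# row, `#` starts a comment line.  Modes are spelled kmer / seed-nc /
# noseed-9nt / noseed.
# ---------------------------------------------------------------------------


def read_edge_list(path) -> tuple[InteractionNetwork, dict]:
    """Parse a TSV edge list into a network.

    Duplicate (rna, mirna) rows are collapsed keeping the strongest mode;
    nodes without any edge are dropped.  Returns the network plus a report
    dict with counts of collapsed rows and dropped nodes.
    """
    rows: list[tuple[str, str, BindingMode]] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
            if not header_seen:
                header_seen = True
                if parts == ["rna_id", "mirna_id", "binding_mode"]:
                    continue
                raise ValueError(f"{path}:1: missing header 'rna_id\\tmirna_id\\tbinding_mode'")
            try:
                mode = BindingMode.from_label(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            rows.append((parts[0], parts[1], mode))
    # collapse duplicates keeping the strongest (lowest-rank) mode
    best: dict[tuple[str, str], BindingMode] = {}
    n_dup = 0
    for rna, mirna, mode in rows:
        key = (rna, mirna)
        if key in best:
            n_dup += 1
            if _MODE_RANK[mode] < _MODE_RANK[best[key]]:
                best[key] = mode
        else:
            best[key] = mode
    if n_dup:
        logger.info("collapsed %d duplicate (rna, mirna) rows in %s", n_dup, path)
    rna_ids = sorted({k[0] for k in best})
    mirna_ids = sorted({k[1] for k in best})
    rna_index = {r: i for i, r in enumerate(rna_ids)}
    mirna_index = {m: a for a, m in enumerate(mirna_ids)}
    items = sorted(best.items())
    network = InteractionNetwork(
        rna_ids=tuple(rna_ids),
        mirna_ids=tuple(mirna_ids),
        edge_rna=np.array([rna_index[k[0]] for k, _ in items], dtype=np.intp),
        edge_mirna=np.array([mirna_index[k[1]] for k, _ in items], dtype=np.intp),
        edge_mode=tuple(mode for _, mode in items),
    )
    report = {"n_rows": len(rows), "n_duplicates_collapsed": n_dup, "n_edges": network.n_edges}
    return network, report


def write_edge_list(network: InteractionNetwork, path, *, comment: str | None = None) -> None:
    """Write a network in the TSV edge-list dialect."""
    frame = pd.DataFrame(
        {
            "rna_id": [network.rna_ids[i] for i in network.edge_rna],
            "mirna_id": [network.mirna_ids[a] for a in network.edge_mirna],
            "binding_mode": [m.value for m in network.edge_mode],
        }
    )
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        frame.to_csv(fh, sep="\t", index=False)
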