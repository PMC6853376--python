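"""Topology null models for bipartite interaction networks.

Two randomization protocols isolate what the wiring contributes to
emergent crosstalk: a uniform rewiring that keeps only node and edge
counts (destroying degree sequences and all correlations), and a
degree-preserving double-edge-swap protocol that keeps both degree
sequences exactly while shuffling which RNA each miRNA slot points at.
Both keep the multiset of binding modes.
"""

from __future__ import annotations

import warnings

import numpy as np

from .network_model import InteractionNetwork

__all__ = ["rewire_uniform", "rewire_degree_preserving"]


def rewire_uniform(network: InteractionNetwork, seed=0) -> InteractionNetwork:
    """Place every edge uniformly at random among free (rna, mirna) pairs.

    Node sets, edge count and the binding-mode multiset are preserved
    (each mode travels with its edge slot); degree sequences generally are
    not.  Nodes isolated by the rewiring are retained — they simply
    decouple in the model.
    """
    n, m, ne = network.n_rna, network.n_mirna, network.n_edges
    rng = np.random.default_rng(seed)
    flat = rng.choice(n * m, size=ne, replace=False)
    return InteractionNetwork(
        rna_ids=network.rna_ids,
        mirna_ids=network.mirna_ids,
        edge_rna=(flat // m).astype(np.intp),
        edge_mirna=(flat % m).astype(np.intp),
        edge_mode=network.edge_mode,
    )


def rewire_degree_preserving(
    network: InteractionNetwork,
    n_accepted_swaps: int | None = None,
    seed=0,
    attempt_factor: int = 10,
) -> InteractionNetwork:
    """Randomize wiring by double edge swaps, preserving all degrees.

    A swap picks two edges (i1, a1) and (i2, a2) and rewires them to
    (i2, a1) and (i1, a2); it is rejected if it would duplicate an
    existing pair or is a no-op.  Each rewired edge keeps the binding
    mode of the edge that contributed its miRNA endpoint (modes stay
    attached to miRNA slots).  Runs until ``n_accepted_swaps`` (default
    10x the edge count) are accepted or an attempt budget of
    ``attempt_factor * n_accepted_swaps`` is exhausted, in which case a
    warning reports the accepted count.
    """
    ne = network.n_edges
    if ne < 2:
        warnings.warn("fewer than 2 edges: no swap possible, returning network unchanged")
        return network
    if n_accepted_swaps is None:
        n_accepted_swaps = 10 * ne
    rng = np.random.default_rng(seed)
    edge_rna = network.edge_rna.copy()
    edge_mirna = network.edge_mirna.copy()
    pairs = set(zip(edge_rna.tolist(), edge_mirna.tolist()))

    accepted = 0
    budget = attempt_factor * n_accepted_swaps
    for _ in range(budget):
        if accepted >= n_accepted_swaps:
            break
        e1, e2 = rng.choice(ne, size=2, replace=False)
        i1, a1 = int(edge_rna[e1]), int(edge_mirna[e1])
        i2, a2 = int(edge_rna[e2]), int(edge_mirna[e2])
        if i1 == i2 or a1 == a2:
            continue
        if (i2, a1) in pairs or (i1, a2) in pairs:
            continue
        pairs.discard((i1, a1))
        pairs.discard((i2, a2))
        pairs.add((i2, a1))
        pairs.add((i1, a2))
        # swap RNA endpoints; (miRNA, mode) stay attached to the edge slot
        edge_rna[e1], edge_rna[e2] = i2, i1
        accepted += 1
    if accepted < n_accepted_swaps:
        warnings.warn(
            f"accepted only {accepted}/{n_accepted_swaps} degree-preserving swaps "
            f"within the attempt budget"
        )
    return InteractionNetwork(
        rna_ids=network.rna_ids,
        mirna_ids=network.mirna_ids,
        edge_rna=edge_rna,
        edge_mirna=edge_mirna,
        edge_mode=network.edge_mode,
    )
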