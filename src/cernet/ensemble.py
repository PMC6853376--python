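"""Ensemble orchestration: sweeps over miRNA availability and heterogeneity.

Each condition (beta_mean, cv_tr, BH scenario, network) is evaluated over
``n_reps`` independent draws of the lognormal transcription-rate vectors;
scalar crosstalk metrics are aggregated into per-condition means and
standard errors.  Replicate seeds are derived from the base seed with a
counter-based spawn key (condition index, replicate index) and recorded
in the output, so every table is reproducible from its manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .network_model import (
    BHScenario,
    BindingMode,
    InteractionNetwork,
    build_parameters,
    read_edge_list,
)
from .steady_state import SteadyStateError, solve_steady_state
from .susceptibility import build_W, compute_susceptibility
from .crosstalk_metrics import locality_matrix, summarize, susceptible_region
from .synthetic_data import EnsembleConfig, sample_transcription_rates, replicate_rng

logger = logging.getLogger(__name__)

__all__ = [
    "run_condition",
    "sweep_beta",
    "load_interactome",
    "subnetwork_by_modes",
    "export_results",
]

METRIC_COLUMNS = [
    "mean_chi",
    "max_chi",
    "mean_self",
    "max_self",
    "s_in",
    "s_out",
    "rho",
    "cv_expression",
    "asymmetry",
]


def realization(
    network: InteractionNetwork,
    bh: BHScenario,
    b: np.ndarray,
    beta: np.ndarray,
    *,
    kinetics: dict | None = None,
):
    """Solve one parameter draw end to end: steady state, chi, metrics."""
    params = build_parameters(network, bh, b, beta, **(kinetics or {}))
    state = solve_steady_state(network, params)
    W = build_W(network, params, state)
    result = compute_susceptibility(W, state)
    K = locality_matrix(network, params)
    return summarize(result.chi, state, K), result, state


def run_condition(
    network: InteractionNetwork,
    config: EnsembleConfig,
    bh: BHScenario,
    *,
    condition_index: int = 0,
    kinetics: dict | None = None,
    collect_chi: bool = False,
) -> pd.DataFrame:
    """Replicate ensemble at fixed (beta_mean, cv_tr, BH).

    Returns a tidy frame with one row per replicate plus ``mean`` and
    ``sem`` rows (SEM rows are NaN when ``n_reps == 1``).  Failed
    replicates are logged and excluded from the aggregates; their count is
    carried in the ``n_failed`` column of the aggregate rows.  With
    ``collect_chi`` the per-pair average of chi across successful
    replicates is attached as ``frame.attrs['chi_mean']``.
    """
    rows = []
    chi_sum = None
    n_failed = 0
    for r in range(config.n_reps):
        rng = replicate_rng(config.seed, condition_index, r)
        seed_b, seed_beta = rng.spawn(2) if hasattr(rng, "spawn") else (rng, rng)
        b = sample_transcription_rates(network.n_rna, config.b_mean, config.cv_tr, seed_b)
        beta = sample_transcription_rates(network.n_mirna, config.beta_mean, config.cv_tr, seed_beta)
        try:
            summary, result, _state = realization(network, bh, b, beta, kinetics=kinetics)
        except SteadyStateError as exc:
            logger.warning("replicate %d failed: %s", r, exc)
            n_failed += 1
            continue
        row = {"replicate": r, "seed": f"{config.seed}:{condition_index}:{r}"}
        row.update(summary.as_dict())
        rows.append(row)
        if collect_chi:
            chi_sum = result.chi if chi_sum is None else chi_sum + result.chi
    if not rows:
        raise SteadyStateError("every replicate of the condition failed")

    frame = pd.DataFrame(rows)
    agg_rows = []
    values = frame[METRIC_COLUMNS].astype(float)
    mean_row = {"replicate": "mean", "seed": "", "n_failed": n_failed}
    mean_row.update(values.mean().to_dict())
    agg_rows.append(mean_row)
    sem_row = {"replicate": "sem", "seed": "", "n_failed": n_failed}
    if len(rows) > 1:
        sem_row.update((values.std(ddof=1) / np.sqrt(len(rows))).to_dict())
    else:
        sem_row.update({c: np.nan for c in METRIC_COLUMNS})
    agg_rows.append(sem_row)
    out = pd.concat([frame, pd.DataFrame(agg_rows)], ignore_index=True)
    out.insert(0, "beta_mean", config.beta_mean)
    out.insert(1, "cv_tr", config.cv_tr)
    out.insert(2, "bh", bh.level)
    if collect_chi and chi_sum is not None:
        out.attrs["chi_mean"] = chi_sum / len(rows)
    return out


def default_beta_grid(n_points: int = 25, low: float = 0.1, high: float = 1e4) -> np.ndarray:
    """Log-spaced miRNA transcription-rate grid spanning unrepressed to fully repressed."""
    return np.geomspace(low, high, n_points)


def sweep_beta(
    network: InteractionNetwork,
    config: EnsembleConfig,
    bh: BHScenario,
    beta_grid: np.ndarray | None = None,
    *,
    kinetics: dict | None = None,
) -> pd.DataFrame:
    """One condition per grid point; susceptible region from the mean curve.

    The returned frame stacks per-replicate and aggregate rows for every
    beta_mean; ``frame.attrs['susceptible_region']`` holds the (low,
    high) grid bounds where mean chi is at least 5% of its peak.
    """
    if beta_grid is None:
        beta_grid = default_beta_grid()
    beta_grid = np.asarray(beta_grid, float)
    if np.any(beta_grid <= 0):
        raise ValueError("beta grid values must be positive")
    tables = []
    for k, beta_mean in enumerate(beta_grid):
        cond = EnsembleConfig(
            b_mean=config.b_mean,
            beta_mean=float(beta_mean),
            cv_tr=config.cv_tr,
            n_reps=config.n_reps,
            seed=config.seed,
        )
        tables.append(run_condition(network, cond, bh, condition_index=k, kinetics=kinetics))
    frame = pd.concat(tables, ignore_index=True)
    means = frame[frame["replicate"] == "mean"]
    try:
        region = susceptible_region(means["beta_mean"].to_numpy(), means["mean_chi"].to_numpy())
    except Exception:  # all-zero curve on e.g. an edge-free network
        region = None
    frame.attrs["susceptible_region"] = region
    return frame


def load_interactome(path) -> InteractionNetwork:
    """Read a TSV edge list, collapsing duplicates and pruning isolated nodes.

    The TSV dialect never represents edge-free nodes, so pruning is
    implicit; duplicate rows keep the strongest binding mode and are
    logged.
    """
    network, report = read_edge_list(path)
    if report["n_duplicates_collapsed"]:
        logger.info(
            "%s: collapsed %d duplicate rows (%d edges kept)",
            path,
            report["n_duplicates_collapsed"],
            report["n_edges"],
        )
    return network


def subnetwork_by_modes(
    network: InteractionNetwork,
    modes: set[BindingMode],
    largest_component: bool = False,
) -> InteractionNetwork:
    """Restrict to edges of the given binding modes, pruning isolated nodes.

    With ``largest_component`` the result is further cut to the largest
    connected component of the induced bipartite graph.
    """
    if not modes:
        raise ValueError("mode set must be non-empty")
    keep = np.array([m in modes for m in network.edge_mode], dtype=bool)
    if not keep.any():
        raise ValueError("no edges with the requested binding modes")
    er = network.edge_rna[keep]
    ea = network.edge_mirna[keep]
    em = tuple(m for m, k in zip(network.edge_mode, keep) if k)

    if largest_component:
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from((("r", int(i)), ("m", int(a))) for i, a in zip(er, ea))
        comp = max(nx.connected_components(g), key=len)
        in_comp = np.array(
            [(("r", int(i)) in comp) and (("m", int(a)) in comp) for i, a in zip(er, ea)],
            dtype=bool,
        )
        er, ea = er[in_comp], ea[in_comp]
        em = tuple(m for m, k in zip(em, in_comp) if k)
        if len(er) == 0:
            raise ValueError("largest component is empty")

    rna_keep = sorted(set(er.tolist()))
    mirna_keep = sorted(set(ea.tolist()))
    rna_map = {old: new for new, old in enumerate(rna_keep)}
    mirna_map = {old: new for new, old in enumerate(mirna_keep)}
    return InteractionNetwork(
        rna_ids=tuple(network.rna_ids[i] for i in rna_keep),
        mirna_ids=tuple(network.mirna_ids[a] for a in mirna_keep),
        edge_rna=np.array([rna_map[i] for i in er.tolist()], dtype=np.intp),
        edge_mirna=np.array([mirna_map[a] for a in ea.tolist()], dtype=np.intp),
        edge_mode=em,
    )


def export_results(tables: dict[str, pd.DataFrame], out_dir, manifest: dict | None = None) -> list[Path]:
    """Write tidy CSVs plus a JSON run manifest; deterministic naming."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        path = out_dir / f"{name}.csv"
        tables[name].to_csv(path, index=False)
        written.append(path)
    manifest = dict(manifest or {})
    manifest.setdefault("tables", sorted(tables))
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    written.append(manifest_path)
    return written
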