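"""Communication measures on binary directed connectomes.

Per-node incoming/outgoing efficiency under two communication models:
shortest paths (hop counts, efficiency = mean inverse distance) and
unbiased random walks (mean first passage times via the fundamental matrix
of the walk's Markov chain, diffusion efficiency = mean inverse MFPT),
plus core-vs-periphery comparisons of the four resulting profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .connectome import ConnectomeError
from .core import CorePartition
from .stats import TestResult, ks_perm_test

__all__ = [
    "EfficiencyProfile",
    "shortest_path_lengths",
    "node_efficiency",
    "mean_first_passage_times",
    "diffusion_efficiency",
    "efficiency_profile",
    "compare_core_periphery_efficiency",
]


@dataclass
class EfficiencyProfile:
    ids: list[str]
    table: pd.DataFrame          # columns eff_out_sp, eff_in_sp, eff_out_diff, eff_in_diff
    D: np.ndarray                # shortest-path length matrix
    H: np.ndarray                # mean-first-passage-time matrix
    pi: np.ndarray               # stationary distribution


def _as_bool_adj(graph: np.ndarray) -> np.ndarray:
    adj = np.asarray(graph)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    adj = adj.astype(bool)
    np.fill_diagonal(adj, False)
    return adj


def shortest_path_lengths(graph: np.ndarray) -> np.ndarray:
    """Directed hop-count distance matrix (np.inf where unreachable)."""
    adj = _as_bool_adj(graph)
    D = shortest_path(csr_matrix(adj.astype(np.int8)), method="D", unweighted=True)
    np.fill_diagonal(D, 0.0)
    return D


def node_efficiency(graph: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(eff_out_sp, eff_in_sp): mean inverse shortest-path length per node."""
    D = shortest_path_lengths(graph)
    n = D.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    eff_out = inv.sum(axis=1) / (n - 1)
    eff_in = inv.sum(axis=0) / (n - 1)
    return eff_out, eff_in


def _check_strongly_connected(adj: np.ndarray) -> None:
    n_comp, labels = connected_components(
        csr_matrix(adj.astype(np.int8)), directed=True, connection="strong"
    )
    if n_comp > 1:
        groups = [np.nonzero(labels == k)[0].tolist() for k in range(n_comp)]
        raise ConnectomeError(
            f"graph is not strongly connected ({n_comp} components): {groups}"
        )


def mean_first_passage_times(graph: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MFPT matrix H and stationary distribution pi of the unbiased walk.

    P is the row-normalized adjacency; pi its stationary distribution; with
    Z = inv(I - P + 1 pi^T) the fundamental matrix,
    H(i, j) = (Z(j, j) - Z(i, j)) / pi(j), and H(i, i) = 0.
    """
    adj = _as_bool_adj(graph)
    _check_strongly_connected(adj)
    A = adj.astype(float)
    P = A / A.sum(axis=1, keepdims=True)
    n = P.shape[0]
    evals, evecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, k])
    pi = pi / pi.sum()
    if (pi <= 0).any():
        raise ConnectomeError("stationary distribution has nonpositive entries")
    Z = np.linalg.inv(np.eye(n) - P + np.outer(np.ones(n), pi))
    H = (np.diag(Z)[None, :] - Z) / pi[None, :]
    np.fill_diagonal(H, 0.0)
    return H, pi


def diffusion_efficiency(graph: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(eff_out_diff, eff_in_diff): mean inverse MFPT per node."""
    H, _ = mean_first_passage_times(graph)
    n = H.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / H
    np.fill_diagonal(inv, 0.0)
    eff_out = inv.sum(axis=1) / (n - 1)
    eff_in = inv.sum(axis=0) / (n - 1)
    return eff_out, eff_in


def efficiency_profile(graph: np.ndarray, ids: list[str]) -> EfficiencyProfile:
    """All four per-node efficiency measures for a directed binary graph."""
    adj = _as_bool_adj(graph)
    D = shortest_path_lengths(adj)
    eff_out_sp, eff_in_sp = node_efficiency(adj)
    H, pi = mean_first_passage_times(adj)
    eff_out_diff, eff_in_diff = diffusion_efficiency(adj)
    table = pd.DataFrame(
        {
            "eff_out_sp": eff_out_sp,
            "eff_in_sp": eff_in_sp,
            "eff_out_diff": eff_out_diff,
            "eff_in_diff": eff_in_diff,
        },
        index=ids,
    )
    return EfficiencyProfile(ids=list(ids), table=table, D=D, H=H, pi=pi)


def compare_core_periphery_efficiency(
    partition: CorePartition,
    profile: EfficiencyProfile,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, TestResult]:
    """KS permutation tests of each efficiency measure, core vs periphery."""
    if not partition.core or not partition.periphery:
        raise ConnectomeError("both core and periphery must be nonempty")
    analyzed = partition.core | partition.periphery
    if set(profile.ids) != set(analyzed):
        raise ConnectomeError("profile and partition cover different area sets")
    results = {}
    for k, measure in enumerate(
        ["eff_in_sp", "eff_out_sp", "eff_in_diff", "eff_out_diff"]
    ):
        vals = profile.table[measure]
        core_vals = vals.loc[sorted(partition.core)].to_numpy()
        peri_vals = vals.loc[sorted(partition.periphery)].to_numpy()
        results[measure] = ks_perm_test(core_vals, peri_vals, n_perm=n_perm, seed=seed + k)
    return results
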