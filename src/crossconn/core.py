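"""Core-periphery detection via maximal cliques.

The structural core of a connectome is the union of the largest maximal
cliques of its undirected projection; significance of the observed largest
clique size is assessed against degree-matched surrogate networks built by
directed double-edge swaps.  Cliques are enumerated by Bron-Kerbosch with
pivoting, iterating the outer loop in degeneracy order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import PRESENT, UNKNOWN, Connectome, ConnectomeError
from .stats import TestResult, energy_test, ks_perm_test, perm_pvalue

__all__ = [
    "CorePartition",
    "undirected_projection",
    "maximal_cliques",
    "core_from_cliques",
    "degree_matched_null_sizes",
    "core_significance",
    "detect_core",
    "compare_core_periphery_attribute",
    "core_cyto_robustness",
]


@dataclass
class CorePartition:
    cliques: list[frozenset[str]]          # all maximum-size maximal cliques
    max_clique_size: int
    core: frozenset[str]
    periphery: frozenset[str]
    edge_rule: str
    null_max_sizes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    p_value: float | None = None


def undirected_projection(c: Connectome, edge_rule: str = "mutual") -> tuple[np.ndarray, list[str]]:
    """Project a directed tri-state connectome onto an undirected graph.

    ``mutual``: edge iff both directions are present; ``any``: edge iff at
    least one direction is present.  Requires an edge-complete square
    connectome (no unknown statuses off the diagonal).
    """
    if not c.is_square:
        raise ConnectomeError("projection requires a square connectome")
    status = c.status
    n = status.shape[0]
    off = ~np.eye(n, dtype=bool)
    if (status[off] == UNKNOWN).any():
        raise ConnectomeError(
            "unknown statuses present; apply edge_complete_subgraph first"
        )
    present = status == PRESENT
    if edge_rule == "mutual":
        adj = present & present.T
    elif edge_rule == "any":
        adj = present | present.T
    else:
        raise ValueError(f"unknown edge rule {edge_rule!r}")
    adj = adj & off
    return adj, c.ids


def _degeneracy_order(neighbors: list[set[int]]) -> list[int]:
    n = len(neighbors)
    deg = [len(nb) for nb in neighbors]
    buckets: list[set[int]] = [set() for _ in range(n)]
    for v, d in enumerate(deg):
        buckets[d].add(v)
    order, removed = [], [False] * n
    d = 0
    for _ in range(n):
        while not buckets[d]:
            d += 1
        v = buckets[d].pop()
        order.append(v)
        removed[v] = True
        for u in neighbors[v]:
            if not removed[u]:
                buckets[deg[u]].discard(u)
                deg[u] -= 1
                buckets[deg[u]].add(u)
                if deg[u] < d:
                    d = deg[u]
    return order


def maximal_cliques(adj: np.ndarray) -> list[frozenset[int]]:
    """All maximal cliques of a simple undirected graph (boolean adjacency).

    Bron-Kerbosch with pivoting; the outermost level iterates vertices in
    degeneracy order, which bounds the recursion on sparse graphs.
    """
    adj = np.asarray(adj, dtype=bool)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T) or adj.diagonal().any():
        raise ValueError("adjacency must be symmetric with an empty diagonal")
    n = adj.shape[0]
    neighbors = [set(np.nonzero(adj[v])[0].tolist()) for v in range(n)]
    out: list[frozenset[int]] = []

    def expand(r: set[int], p: set[int], x: set[int]) -> None:
        if not p and not x:
            out.append(frozenset(r))
            return
        pivot = max(p | x, key=lambda u: len(p & neighbors[u]))
        for v in list(p - neighbors[pivot]):
            expand(r | {v}, p & neighbors[v], x & neighbors[v])
            p.discard(v)
            x.add(v)

    order = _degeneracy_order(neighbors)
    pos = {v: i for i, v in enumerate(order)}
    for v in order:
        later = {u for u in neighbors[v] if pos[u] > pos[v]}
        earlier = {u for u in neighbors[v] if pos[u] < pos[v]}
        expand({v}, later, earlier)
    return out


def core_from_cliques(
    cliques: list[frozenset], all_areas: list[str], edge_rule: str = "mutual"
) -> CorePartition:
    """Keep the maximum-size cliques; core = their union, rest = periphery."""
    if not cliques:
        raise ConnectomeError("no cliques supplied")
    kmax = max(len(c) for c in cliques)
    largest = [frozenset(c) for c in cliques if len(c) == kmax]
    core = frozenset().union(*largest)
    periphery = frozenset(all_areas) - core
    return CorePartition(
        cliques=largest,
        max_clique_size=kmax,
        core=core,
        periphery=periphery,
        edge_rule=edge_rule,
    )


def _double_edge_swap(
    edges: list[tuple[int, int]], edge_set: set[tuple[int, int]],
    n_swaps: int, rng: np.random.Generator, max_attempts: int,
) -> None:
    """In-place Maslov-Sneppen swaps preserving in- and out-degrees."""
    m = len(edges)
    accepted = attempts = 0
    while accepted < n_swaps:
        if attempts >= max_attempts:
            raise ConnectomeError(
                "degree-preserving swap failed: no valid swap found "
                f"in {max_attempts} attempts"
            )
        attempts += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b or b == d or a == c:
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.discard((a, b))
        edge_set.discard((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[i] = (a, d)
        edges[j] = (c, b)
        accepted += 1


def degree_matched_null_sizes(
    c: Connectome,
    edge_rule: str = "mutual",
    n_null: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> np.ndarray:
    """Largest-clique sizes of degree-matched surrogate networks.

    Each surrogate rewires the directed present-edge graph with
    ``swaps_per_edge * |E|`` accepted double-edge swaps (self-loops and
    duplicate edges rejected), preserving every node's in- and out-degree,
    then is projected with ``edge_rule`` and its maximum clique size
    recorded.
    """
    adj, ids = undirected_projection(c, "any")  # validates edge-completeness
    status = c.status
    base_edges = [tuple(e) for e in np.argwhere(status == PRESENT) if e[0] != e[1]]
    n = len(ids)
    rng = np.random.default_rng(seed)
    sizes = np.empty(n_null, dtype=int)
    n_swaps = swaps_per_edge * len(base_edges)
    max_attempts = 100 * len(base_edges) + n_swaps * 20
    for b in range(n_null):
        edges = list(base_edges)
        edge_set = set(edges)
        _double_edge_swap(edges, edge_set, n_swaps, rng, max_attempts)
        surr = np.zeros((n, n), dtype=bool)
        rows = np.array([e[0] for e in edges])
        cols = np.array([e[1] for e in edges])
        surr[rows, cols] = True
        if edge_rule == "mutual":
            und = surr & surr.T
        else:
            und = surr | surr.T
        np.fill_diagonal(und, False)
        cl = maximal_cliques(und)
        sizes[b] = max((len(q) for q in cl), default=1)
    return sizes


def core_significance(observed_size: int, null_sizes: np.ndarray) -> float:
    """Add-one p-value: fraction of surrogate clique sizes >= observed."""
    null_sizes = np.asarray(null_sizes)
    if null_sizes.size == 0:
        raise ConnectomeError("null_sizes is empty")
    return perm_pvalue(null_sizes.astype(float), float(observed_size))


def detect_core(
    c: Connectome,
    edge_rule: str = "mutual",
    n_null: int = 1000,
    seed: int = 0,
) -> CorePartition:
    """Full core-periphery pipeline: project, enumerate, test significance."""
    adj, ids = undirected_projection(c, edge_rule)
    cliques_idx = maximal_cliques(adj)
    cliques = [frozenset(ids[v] for v in q) for q in cliques_idx]
    part = core_from_cliques(cliques, ids, edge_rule)
    if n_null:
        nulls = degree_matched_null_sizes(c, edge_rule, n_null=n_null, seed=seed)
        part.null_max_sizes = nulls
        part.p_value = core_significance(part.max_clique_size, nulls)
    return part


def compare_core_periphery_attribute(
    partition: CorePartition,
    attribute: dict[str, float],
    test: str = "energy",
    n_perm: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Two-sample test of an attribute between core and periphery areas.

    The permutation null shuffles the core/periphery labels over areas,
    which is exactly the pooled re-splitting done by the underlying tests.
    """
    if not partition.core or not partition.periphery:
        raise ConnectomeError("both core and periphery must be nonempty")
    missing = sorted((partition.core | partition.periphery) - set(attribute))
    if missing:
        raise ConnectomeError(f"attribute missing for areas: {missing}")
    core_vals = np.array([attribute[a] for a in sorted(partition.core)])
    peri_vals = np.array([attribute[a] for a in sorted(partition.periphery)])
    if test == "energy":
        return energy_test(core_vals, peri_vals, n_perm=n_perm, seed=seed)
    if test == "ks":
        return ks_perm_test(core_vals, peri_vals, n_perm=n_perm, seed=seed)
    raise ValueError(f"unknown test {test!r}")


def core_cyto_robustness(
    c: Connectome,
    partition: CorePartition,
    fractions: np.ndarray,
    n_rep: int = 100,
    mode: str = "clamped",
    seed: int = 0,
    n_null: int = 100,
):
    """Core-vs-periphery energy statistic under ordinal type reassignment.

    Reuses the reassignment scheme of the wiring robustness analysis with a
    fixed partition: per fraction and repetition the cytoarchitectonic
    energy statistic between core and periphery is recomputed; a
    label-permutation null (shuffled cyto values) is appended as
    fraction = NaN rows.
    """
    import pandas as pd

    from .stats import energy_statistic
    from .wiring import _reassign_types

    cyto = np.array([a.cyto for a in c.areas])
    if c.areas[0].cyto_kind != "type" or not np.allclose(cyto * 2, np.round(cyto * 2)):
        raise ConnectomeError("type reassignment requires an ordinal cyto scale")
    ids = c.ids
    in_core = np.array([a in partition.core for a in ids])
    analyzed = np.array([a in (partition.core | partition.periphery) for a in ids])
    rng = np.random.default_rng(seed)
    lo, hi = cyto.min(), cyto.max()

    def _stat(values: np.ndarray) -> float:
        return energy_statistic(values[in_core & analyzed], values[~in_core & analyzed])

    baseline = _stat(cyto)
    rows = []
    for f in np.asarray(fractions, dtype=float):
        for rep in range(n_rep if f > 0 else 1):
            stat = baseline if f == 0 else _stat(_reassign_types(cyto, f, mode, rng, lo, hi))
            rows.append({"fraction": f, "rep": rep, "energy": stat, "null": False})
    for rep in range(n_null):
        rows.append(
            {"fraction": np.nan, "rep": rep, "energy": _stat(rng.permutation(cyto)),
             "null": True}
        )
    out = pd.DataFrame(rows)
    out.attrs["baseline_energy"] = baseline
    out.attrs["mode"] = mode
    return out
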