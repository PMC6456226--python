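"""Connectome data model and I/O.

A connectome here is a directed graph over named cortical areas whose edges
carry a tri-state status (present / absent / unknown), together with an
inter-areal distance matrix and per-area attributes (cytoarchitectonic
measure, spatial coordinates, rostrocaudal position).  Unknown statuses are
kept explicit throughout and are never coerced to "absent".

CSV conventions: comma-separated UTF-8; the adjacency file has area ids as
both header row and first column; cells are ``1`` (present), ``0`` (absent)
or ``NA`` (unknown).  The area-attribute file has columns
``id,name,cyto,x,y,z`` plus optional ``rostrocaudal`` and ``cyto_kind``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PRESENT",
    "ABSENT",
    "UNKNOWN",
    "Area",
    "Connectome",
    "ConnectomeError",
    "load_connectome",
    "write_connectome",
    "rescale01",
    "cyto_dissimilarity",
    "build_pair_table",
    "edge_complete_subgraph",
]

PRESENT: int = 1
ABSENT: int = 0
UNKNOWN: int = -1


class ConnectomeError(ValueError):
    """Raised on invalid connectome inputs or degenerate operations."""


@dataclass
class Area:
    """One cortical area with its cytoarchitectonic and spatial attributes.

    ``cyto`` is either an ordinal cortical type (e.g. 1..5, half-steps
    allowed) or a neuronal density (neurons per mm^3); ``cyto_kind``
    distinguishes the two scales so they are never mixed in a difference.
    """

    id: str
    cyto: float
    name: str = ""
    coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rostrocaudal: float | None = None
    cyto_kind: str = "type"  # "type" (ordinal) or "density"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ConnectomeError(f"area {self.id!r}: coords must be a 3-vector")
        if not np.isfinite(self.cyto) or self.cyto <= 0:
            raise ConnectomeError(f"area {self.id!r}: cyto must be finite and positive")
        if self.rostrocaudal is not None and not 0.0 <= self.rostrocaudal <= 1.0:
            raise ConnectomeError(
                f"area {self.id!r}: rostrocaudal must lie in [0,1] once normalized"
            )


@dataclass
class Connectome:
    """Directed tri-state connectome over a list of areas.

    ``status`` is an ``(n_sources, n_areas)`` integer matrix with entries in
    {PRESENT, ABSENT, UNKNOWN}; rows index ``areas[i]`` for ``i`` in
    ``source_index`` (all areas for a square matrix, the injected subset for
    rectangular injection-based matrices).  ``distance`` matches ``status``
    in shape.  The diagonal (self-connections) is ignored by every analysis.
    """

    areas: list[Area]
    status: np.ndarray
    distance: np.ndarray
    species: str
    distance_kind: str = "euclidean"  # geodesic | euclidean | border
    source_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        self.distance = np.asarray(self.distance, dtype=float)
        n = len(self.areas)
        if self.source_index is None:
            self.source_index = np.arange(self.status.shape[0])
        self.source_index = np.asarray(self.source_index, dtype=int)
        if self.status.shape != (len(self.source_index), n):
            raise ConnectomeError(
                f"status shape {self.status.shape} does not match "
                f"{len(self.source_index)} sources x {n} areas"
            )
        if self.distance.shape != self.status.shape:
            raise ConnectomeError("distance and status shapes differ")
        bad = ~np.isin(self.status, (PRESENT, ABSENT, UNKNOWN))
        if bad.any():
            raise ConnectomeError("status entries must be in {1, 0, -1}")
        known = self.distance[self.status != UNKNOWN]
        if known.size and (known < 0).any():
            raise ConnectomeError("distances must be nonnegative")

    # -- convenience -------------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.areas]

    @property
    def source_ids(self) -> list[str]:
        return [self.areas[i].id for i in self.source_index]

    @property
    def is_square(self) -> bool:
        return self.status.shape[0] == self.status.shape[1] and np.array_equal(
            self.source_index, np.arange(len(self.areas))
        )

    def area(self, area_id: str) -> Area:
        for a in self.areas:
            if a.id == area_id:
                return a
        raise KeyError(area_id)


def rescale01(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Affinely map a vector onto [0,1]: min -> 0, max -> 1, order preserved."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ConnectomeError("rescale01 needs at least two values")
    if not np.isfinite(v).all():
        raise ConnectomeError("rescale01: non-finite values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ConnectomeError("rescale01: constant vector (degenerate rescale)")
    return (v - lo) / (hi - lo)


def cyto_dissimilarity(a: Area, b: Area) -> float:
    """Absolute difference of the cytoarchitectonic measure of two areas."""
    if a.cyto_kind != b.cyto_kind:
        raise ConnectomeError(
            f"cannot compare cyto scales {a.cyto_kind!r} vs {b.cyto_kind!r}"
        )
    return abs(a.cyto - b.cyto)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_cell(raw: str, row: str, col: str) -> int:
    s = str(raw).strip()
    if s in {"NA", "", "nan"}:
        return UNKNOWN
    if s in {"1", "1.0"}:
        return PRESENT
    if s in {"0", "0.0"}:
        return ABSENT
    raise ConnectomeError(f"invalid adjacency cell {raw!r} at ({row}, {col})")


def load_connectome(
    adjacency_path: str | Path,
    areas_path: str | Path,
    species: str,
    distance_path: str | Path | None = None,
    distance_kind: str | None = None,
) -> Connectome:
    """Load a connectome from an adjacency CSV and an area-attribute CSV.

    Distances come from ``distance_path`` if given (same layout as the
    adjacency file), otherwise they are Euclidean distances between the area
    coordinates.  Area id sets of the two files must match exactly; unknown
    cells (``NA``) stay unknown.
    """
    adj = pd.read_csv(adjacency_path, index_col=0, dtype=str, keep_default_na=False)
    adj.index = adj.index.astype(str).str.strip()
    adj.columns = adj.columns.astype(str).str.strip()

    attrs = pd.read_csv(areas_path, dtype={"id": str})
    attrs["id"] = attrs["id"].str.strip()
    attr_ids = list(attrs["id"])

    col_ids = list(adj.columns)
    row_ids = list(adj.index)
    extra_adj = sorted((set(col_ids) | set(row_ids)) - set(attr_ids))
    extra_attr = sorted(set(attr_ids) - (set(col_ids) | set(row_ids)))
    if extra_adj or extra_attr:
        raise ConnectomeError(
            "area id mismatch between adjacency and attribute files: "
            f"adjacency-only={extra_adj}, attributes-only={extra_attr}"
        )
    if not set(row_ids) <= set(col_ids):
        raise ConnectomeError("adjacency rows must be a subset of its columns")

    areas = []
    for rec in attrs.to_dict("records"):
        coords = np.array(
            [rec.get("x", 0.0), rec.get("y", 0.0), rec.get("z", 0.0)], dtype=float
        )
        rc = rec.get("rostrocaudal")
        rc = None if rc is None or (isinstance(rc, float) and np.isnan(rc)) else float(rc)
        areas.append(
            Area(
                id=rec["id"],
                cyto=float(rec["cyto"]),
                name=str(rec.get("name", "") or ""),
                coords=coords,
                rostrocaudal=rc,
                cyto_kind=str(rec.get("cyto_kind", "type") or "type"),
            )
        )
    # order areas by adjacency columns
    by_id = {a.id: a for a in areas}
    areas = [by_id[i] for i in col_ids]
    idx_of = {i: k for k, i in enumerate(col_ids)}
    source_index = np.array([idx_of[r] for r in row_ids], dtype=int)

    status = np.empty((len(row_ids), len(col_ids)), dtype=np.int8)
    for i, r in enumerate(row_ids):
        for j, c in enumerate(col_ids):
            status[i, j] = _parse_cell(adj.iat[i, j], r, c)

    if distance_path is not None:
        dmat = pd.read_csv(distance_path, index_col=0)
        dmat.index = dmat.index.astype(str).str.strip()
        dmat.columns = dmat.columns.astype(str).str.strip()
        distance = dmat.loc[row_ids, col_ids].to_numpy(dtype=float)
        kind = distance_kind or "geodesic"
    else:
        coords = np.stack([a.coords for a in areas])
        full = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        distance = full[source_index, :]
        kind = distance_kind or "euclidean"

    return Connectome(
        areas=areas,
        status=status,
        distance=distance,
        species=species,
        distance_kind=kind,
        source_index=source_index,
    )


def write_connectome(c: Connectome, adjacency_path: str | Path, areas_path: str | Path,
                     distance_path: str | Path | None = None) -> None:
    """Write a connectome back to the CSV dialect accepted by ``load_connectome``."""
    cells = np.where(c.status == UNKNOWN, "NA", c.status.astype(str))
    adj = pd.DataFrame(cells, index=c.source_ids, columns=c.ids)
    adj.to_csv(adjacency_path)
    rows = []
    for a in c.areas:
        rows.append(
            {
                "id": a.id,
                "name": a.name,
                "cyto": a.cyto,
                "x": a.coords[0],
                "y": a.coords[1],
                "z": a.coords[2],
                "rostrocaudal": a.rostrocaudal,
                "cyto_kind": a.cyto_kind,
            }
        )
    pd.DataFrame(rows).to_csv(areas_path, index=False)
    if distance_path is not None:
        pd.DataFrame(c.distance, index=c.source_ids, columns=c.ids).to_csv(distance_path)


# ---------------------------------------------------------------------------
# Pair table
# ---------------------------------------------------------------------------

def build_pair_table(c: Connectome) -> pd.DataFrame:
    """Long-format table of ordered area pairs with known connection status.

    One row per ordered (source, target) pair with status in
    {present, absent}; the distance and cytoarchitectonic-dissimilarity
    regressors are linearly rescaled to [0,1] over exactly the included
    pairs (i.e. within this connectome/species only).  Columns:
    ``source, target, d01, c01, status`` with status coded 1/0.
    """
    srcs, tgts, dist, dissim, stat = [], [], [], [], []
    cyto = np.array([a.cyto for a in c.areas])
    for i_row, i in enumerate(c.source_index):
        for j in range(len(c.areas)):
            if i == j:
                continue
            s = c.status[i_row, j]
            if s == UNKNOWN:
                continue
            srcs.append(c.areas[i].id)
            tgts.append(c.areas[j].id)
            dist.append(c.distance[i_row, j])
            dissim.append(abs(cyto[i] - cyto[j]))
            stat.append(int(s))
    if not srcs:
        raise ConnectomeError("no pairs with known status")
    table = pd.DataFrame(
        {
            "source": srcs,
            "target": tgts,
            "d01": rescale01(dist),
            "c01": rescale01(dissim),
            "status": np.array(stat, dtype=int),
        }
    )
    table.attrs["species"] = c.species
    return table


def edge_complete_subgraph(c: Connectome) -> Connectome:
    """Restrict to areas whose pairwise statuses are all known.

    For rectangular injection-based matrices this starts from the injected
    (row) areas; any area still involved in unknown pairs is then removed
    greedily (most unknowns first) until the block is edge-complete.
    """
    n = len(c.areas)
    # square status over candidate set = row areas; missing rows are unknown
    full = np.full((n, n), UNKNOWN, dtype=np.int8)
    full_d = np.zeros((n, n))
    for i_row, i in enumerate(c.source_index):
        full[i, :] = c.status[i_row, :]
        full_d[i, :] = c.distance[i_row, :]
    keep = sorted(int(i) for i in c.source_index)
    keep_set = set(keep)
    while True:
        counts = {}
        for i in keep:
            row = sum(
                1 for j in keep if j != i and (full[i, j] == UNKNOWN or full[j, i] == UNKNOWN)
            )
            counts[i] = row
        worst = max(keep, key=lambda i: counts[i])
        if counts[worst] == 0:
            break
        keep.remove(worst)
        keep_set.discard(worst)
        if len(keep) < 3:
            raise ConnectomeError("edge-complete subgraph has fewer than 3 areas")
    keep = sorted(keep)
    sub_areas = [c.areas[i] for i in keep]
    idx = np.array(keep, dtype=int)
    return Connectome(
        areas=[dataclasses.replace(a, coords=a.coords.copy()) for a in sub_areas],
        status=full[np.ix_(idx, idx)].copy(),
        distance=full_d[np.ix_(idx, idx)].copy(),
        species=c.species,
        distance_kind=c.distance_kind,
        source_index=np.arange(len(keep)),
    )
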