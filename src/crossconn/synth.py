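"""Synthetic cortex generator with retained ground truth.

Produces spatially embedded areas carrying a smooth cytoarchitectonic
gradient, a directed tri-state connectome sampled from a logistic model in
rescaled distance and cytoarchitectonic dissimilarity, a laminar-origin
table whose NSG% is a monotone noisy function of the signed
cytoarchitectonic difference, and (optionally) a planted reciprocal clique
acting as a known network core.  Every stage is deterministic given the
spec seed, and the realized per-pair connection probabilities are kept so
downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import copy
import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .connectome import (
    ABSENT,
    PRESENT,
    Area,
    Connectome,
    ConnectomeError,
    rescale01,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticCortex",
    "generate_areas",
    "generate_connectome",
    "generate_laminar",
    "plant_core",
    "generate_cortex",
]


@dataclass
class SyntheticSpec:
    """Full generative parameterization of a synthetic cortex."""

    n_areas: int = 60
    layout: str = "uniform2d"  # grid2d | uniform2d | line
    gradient_origin: tuple[float, float] = (0.0, 0.0)
    gradient_noise_sd: float = 0.0
    cyto_scale: str = "continuous"  # "continuous" or "ordinal:<k>"
    beta0: float = 0.0
    beta_d: float = -3.0
    beta_c: float = -2.0
    nsg_slope: float = 30.0
    nsg_noise_sd: float = 5.0
    planted_core_size: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_areas < 4:
            raise ValueError("n_areas must be >= 4")
        if self.gradient_noise_sd < 0 or self.nsg_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.layout not in {"grid2d", "uniform2d", "line"}:
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.cyto_scale != "continuous" and not self.cyto_scale.startswith("ordinal:"):
            raise ValueError(f"unknown cyto_scale {self.cyto_scale!r}")

    @property
    def ordinal_levels(self) -> int | None:
        if self.cyto_scale.startswith("ordinal:"):
            return int(self.cyto_scale.split(":", 1)[1])
        return None


@dataclass
class SyntheticCortex:
    connectome: Connectome
    laminar: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _rng_for(spec: SyntheticSpec, stage: str) -> np.random.Generator:
    # one substream per stage so stages are individually reproducible;
    # crc32 is stable across processes (str hash is not)
    return np.random.default_rng([spec.seed, zlib.crc32(stage.encode())])


def _positions(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_areas
    if spec.layout == "line":
        xy = np.column_stack([np.linspace(0.0, 1.0, n), np.zeros(n)])
    elif spec.layout == "grid2d":
        side = int(np.ceil(np.sqrt(n)))
        gx, gy = np.meshgrid(np.arange(side), np.arange(side))
        xy = np.column_stack([gx.ravel(), gy.ravel()])[:n].astype(float)
        xy /= max(side - 1, 1)
    else:  # uniform2d
        xy = rng.uniform(0.0, 1.0, size=(n, 2))
    return xy


def generate_areas(spec: SyntheticSpec) -> list[Area]:
    """Place areas and assign a cytoarchitectonic gradient.

    cyto is a monotone (increasing) function of distance to the gradient
    origin plus Gaussian noise; ordinal scales bin the noisy values into
    equal-frequency levels 1..k so all levels are populated.  The
    rostrocaudal coordinate is the first spatial coordinate rescaled to
    [0,1] (largest coordinate = 1 = most rostral).
    """
    rng = _rng_for(spec, "areas")
    xy = _positions(spec, rng)
    origin = np.asarray(spec.gradient_origin, dtype=float)
    grad = np.linalg.norm(xy - origin[None, :], axis=1)
    raw = grad + rng.normal(0.0, spec.gradient_noise_sd, size=spec.n_areas)
    k = spec.ordinal_levels
    if k is not None:
        order = np.argsort(raw, kind="stable")
        levels = np.empty(spec.n_areas, dtype=float)
        # equal-frequency binning: contiguous rank blocks -> levels 1..k
        splits = np.array_split(order, k)
        for lev, block in enumerate(splits, start=1):
            levels[block] = lev
        cyto = levels
        kind = "type"
    else:
        cyto = raw - raw.min() + 1.0  # keep strictly positive
        kind = "density" if spec.cyto_scale == "continuous" else "type"
    rc = rescale01(xy[:, 0])
    areas = []
    for i in range(spec.n_areas):
        areas.append(
            Area(
                id=f"A{i:03d}",
                cyto=float(cyto[i]),
                name=f"synthetic area {i}",
                coords=np.array([xy[i, 0], xy[i, 1], 0.0]),
                rostrocaudal=float(rc[i]),
                cyto_kind=kind,
            )
        )
    return areas


def generate_connectome(areas: list[Area], spec: SyntheticSpec) -> tuple[Connectome, np.ndarray]:
    """Sample a directed connectome from the logistic wiring model.

    P(present) = logistic(beta0 + beta_d * d01 + beta_c * c01) with the two
    regressors rescaled to [0,1] over all ordered pairs; statuses sampled
    independently.  Returns the connectome and the (n, n) matrix of
    generative probabilities (diagonal set to NaN).
    """
    rng = _rng_for(spec, "connectome")
    n = len(areas)
    coords = np.stack([a.coords for a in areas])
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cyto = np.array([a.cyto for a in areas])
    dissim = np.abs(cyto[:, None] - cyto[None, :])
    off = ~np.eye(n, dtype=bool)
    if np.ptp(dist[off]) == 0:
        raise ConnectomeError("need at least two distinct pair distances")
    d01 = np.full((n, n), np.nan)
    c01 = np.full((n, n), np.nan)
    d01[off] = rescale01(dist[off])
    c01[off] = rescale01(dissim[off])
    prob = np.full((n, n), np.nan)
    prob[off] = expit(spec.beta0 + spec.beta_d * d01[off] + spec.beta_c * c01[off])
    status = np.full((n, n), ABSENT, dtype=np.int8)
    draws = rng.random((n, n))
    status[off] = np.where(draws[off] < prob[off], PRESENT, ABSENT)
    np.fill_diagonal(status, ABSENT)
    conn = Connectome(
        areas=areas,
        status=status,
        distance=dist,
        species=f"synthetic-{spec.seed}",
        distance_kind="euclidean",
    )
    return conn, prob


def generate_laminar(areas: list[Area], connectome: Connectome, spec: SyntheticSpec) -> pd.DataFrame:
    """NSG% per present edge: 50 + slope * z(signed cyto difference) + noise.

    The signed difference is cyto(origin) - cyto(termination), standardized
    over present edges; values are clipped to [0,100].
    """
    rng = _rng_for(spec, "laminar")
    cyto = {a.id: a.cyto for a in areas}
    rc = {a.id: a.rostrocaudal for a in areas}
    ids = connectome.ids
    src_i, tgt_i = np.nonzero(connectome.status == PRESENT)
    if src_i.size == 0:
        raise ConnectomeError("connectome has no present edges")
    origins = [ids[connectome.source_index[i]] for i in src_i]
    terms = [ids[j] for j in tgt_i]
    diff = np.array([cyto[o] - cyto[t] for o, t in zip(origins, terms)])
    sd = diff.std()
    z = (diff - diff.mean()) / sd if sd > 0 else np.zeros_like(diff)
    nsg = 50.0 + spec.nsg_slope * z + rng.normal(0.0, spec.nsg_noise_sd, size=z.size)
    return pd.DataFrame(
        {
            "origin": origins,
            "termination": terms,
            "nsg": np.clip(nsg, 0.0, 100.0),
            "cyto_diff": diff,
            "rc_diff": [rc[o] - rc[t] for o, t in zip(origins, terms)],
        }
    )


def plant_core(connectome: Connectome, k: int, seed: int) -> tuple[Connectome, list[str]]:
    """Set all ordered pairs among k randomly chosen areas to present.

    Returns the modified copy and the planted area ids; statuses outside
    the planted block are untouched.
    """
    if k < 2:
        raise ValueError("planted core size must be >= 2")
    n = len(connectome.areas)
    if k > n:
        raise ValueError("planted core size exceeds number of areas")
    if not connectome.is_square:
        raise ConnectomeError("plant_core requires a square connectome")
    rng = np.random.default_rng(seed)
    members = np.sort(rng.choice(n, size=k, replace=False))
    status = connectome.status.copy()
    for i in members:
        for j in members:
            if i != j:
                status[i, j] = PRESENT
    new = Connectome(
        areas=[dataclasses.replace(a, coords=a.coords.copy()) for a in connectome.areas],
        status=status,
        distance=connectome.distance.copy(),
        species=connectome.species,
        distance_kind=connectome.distance_kind,
    )
    return new, [connectome.areas[i].id for i in members]


def generate_cortex(spec: SyntheticSpec) -> SyntheticCortex:
    """Run the full generative chain for one spec."""
    areas = generate_areas(spec)
    conn, prob = generate_connectome(areas, spec)
    planted: list[str] = []
    if spec.planted_core_size:
        conn, planted = plant_core(conn, spec.planted_core_size, spec.seed + 7919)
    laminar = generate_laminar(areas, conn, spec)
    truth = {
        "spec": copy.deepcopy(spec),
        "probability": prob,
        "planted_core": planted,
    }
    return SyntheticCortex(connectome=conn, laminar=laminar, truth=truth)
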