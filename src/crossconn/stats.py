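"""Resampling-based statistical kernel.

Two-sample tests (logarithmic-potential energy statistic, Kolmogorov-
Smirnov) with label-permutation significance, Spearman and partial Spearman
rank correlations, and ROC AUC.  All permutation p-values follow the
add-one rule p = (b + 1) / (n_perm + 1), so they lie in (0, 1] and are
never exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "perm_pvalue",
    "energy_statistic",
    "energy_test",
    "ks_statistic",
    "ks_perm_test",
    "spearman_rho",
    "partial_spearman",
    "roc_auc",
]

#: regularizer for coincident points in the energy potential R(r) = -ln r
ENERGY_EPS = 1e-8


@dataclass
class TestResult:
    statistic: float
    p_value: float
    null_values: np.ndarray
    n_perm: int
    seed: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if self.null_values.size != self.n_perm:
            raise ValueError("null_values length must equal n_perm")

    def to_json(self) -> str:
        return json.dumps(
            {
                "statistic": self.statistic,
                "p_value": self.p_value,
                "n_perm": self.n_perm,
                "seed": self.seed,
                "null_values": self.null_values.tolist(),
                **self.extra,
            }
        )


def perm_pvalue(null_values: np.ndarray, observed: float) -> float:
    """Add-one permutation p-value: (#{null >= observed} + 1) / (n + 1)."""
    null_values = np.asarray(null_values, dtype=float)
    return (np.count_nonzero(null_values >= observed) + 1) / (null_values.size + 1)


# ---------------------------------------------------------------------------
# Energy test (Aslan-Zech logarithmic potential)
# ---------------------------------------------------------------------------

def _log_potential_matrix(pooled: np.ndarray) -> np.ndarray:
    d = np.abs(pooled[:, None] - pooled[None, :])
    np.fill_diagonal(d, 1.0)  # diagonal never used
    return np.log(np.maximum(d, ENERGY_EPS))


def _energy_from_mask(L: np.ndarray, in_x: np.ndarray) -> float:
    # s^T L s counts each unordered pair twice, so within-sample sums carry 1/2
    s = in_x.astype(float)
    t = 1.0 - s
    n = s.sum()
    m = t.sum()
    sum_xx = 0.5 * (s @ L @ s - 0.0)  # diagonal of L is log(1)=0 after fill
    sum_yy = 0.5 * (t @ L @ t)
    sum_xy = s @ L @ t
    return float(-sum_xx / n**2 - sum_yy / m**2 + sum_xy / (n * m))


def energy_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample energy statistic with potential R(r) = -ln r.

    Phi = -(1/n^2) sum_{i<j} ln|x_i - x_j| - (1/m^2) sum_{i<j} ln|y_i - y_j|
          + (1/nm) sum_{i,j} ln|x_i - y_j|,
    with distances clipped below at a small epsilon.  Larger values indicate
    better-separated samples; the statistic is symmetric in (x, y).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("energy_statistic needs at least 2 values per sample")
    pooled = np.concatenate([x, y])
    L = _log_potential_matrix(pooled)
    in_x = np.zeros(pooled.size, dtype=bool)
    in_x[: x.size] = True
    return _energy_from_mask(L, in_x)


def energy_test(x: np.ndarray, y: np.ndarray, n_perm: int = 1000, seed: int = 0) -> TestResult:
    """Permutation energy test: pool, re-split labels ``n_perm`` times."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("energy_test needs at least 2 values per sample")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    pooled = np.concatenate([x, y])
    L = _log_potential_matrix(pooled)
    in_x = np.zeros(pooled.size, dtype=bool)
    in_x[: x.size] = True
    observed = _energy_from_mask(L, in_x)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    mask = in_x.copy()
    for b in range(n_perm):
        rng.shuffle(mask)
        null[b] = _energy_from_mask(L, mask)
    return TestResult(observed, perm_pvalue(null, observed), null, n_perm, seed)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov with permutation significance
# ---------------------------------------------------------------------------

def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """sup |ECDF_x - ECDF_y| over the pooled sample points."""
    x = np.sort(np.asarray(x, dtype=float).ravel())
    y = np.sort(np.asarray(y, dtype=float).ravel())
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    return float(np.abs(cdf_x - cdf_y).max())


def ks_perm_test(x: np.ndarray, y: np.ndarray, n_perm: int = 1000, seed: int = 0) -> TestResult:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("ks_perm_test needs at least 2 values per sample")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = ks_statistic(x, y)
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(pooled)
        null[b] = ks_statistic(perm[: x.size], perm[x.size:])
    return TestResult(observed, perm_pvalue(null, observed), null, n_perm, seed)


# ---------------------------------------------------------------------------
# Rank correlations and AUC
# ---------------------------------------------------------------------------

def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman_rho needs equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman_rho undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def partial_spearman(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Partial Spearman correlation of x and y controlling for z."""
    x, y, z = (np.asarray(v, dtype=float).ravel() for v in (x, y, z))
    if not (x.size == y.size == z.size) or x.size < 4:
        raise ValueError("partial_spearman needs equal-length vectors of size >= 4")
    r_xy = spearman_rho(x, y)
    r_xz = spearman_rho(x, z)
    r_yz = spearman_rho(y, z)
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("partial_spearman degenerate: a control correlation is +-1")
    return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney U statistic; ties count 0.5."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    n_pos = int(np.count_nonzero(labels == 1))
    n_neg = int(np.count_nonzero(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = sps.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
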