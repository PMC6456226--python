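"""Wiring analysis: does connection existence track distance and cytology?

Single-species binary logistic fits of connection existence on rescaled
distance and cytoarchitectonic dissimilarity, pooled two-species models
with a species dummy and a species-by-dissimilarity interaction (compared
by likelihood-ratio test), energy-test comparisons of present vs absent
pairs, and robustness of the dissimilarity coefficient to random
reassignment of ordinal cortical types.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectome import Connectome, ConnectomeError, build_pair_table
from .stats import TestResult, energy_test

__all__ = [
    "LogisticFit",
    "LRComparison",
    "compare_present_absent",
    "fit_logistic",
    "fit_species_interaction",
    "probability_curve",
    "type_reassignment_robustness",
]


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference."""

    regressors: list[str]              # includes "intercept" first
    coef: dict[str, float]
    se: dict[str, float]
    wald_p: dict[str, float]
    log_likelihood: float
    n_obs: int
    converged: bool

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        beta = np.array([self.coef[r] for r in self.regressors])
        return X @ beta


@dataclass
class LRComparison:
    lr_statistic: float
    df: int
    p_value: float


def _irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100):
    """IRLS for logistic regression; returns (beta, ll, cov, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError:
            break
        beta = beta_new
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
        converged = False
    # heuristic perfect-separation flag: fitted probabilities pinned at 0/1
    if np.all((mu < 1e-6) | (mu > 1 - 1e-6)):
        converged = False
    return beta, ll_old, cov, converged


def _design(pairs: pd.DataFrame, regressors: list[str]) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack([np.ones(len(pairs))] + [pairs[r].to_numpy(float) for r in regressors])
    y = pairs["status"].to_numpy(float)
    return X, y


def fit_logistic(pairs: pd.DataFrame, regressors: list[str] = ("d01", "c01")) -> LogisticFit:
    """ML logistic fit of connection status on the named pair-table columns.

    Fits by iteratively reweighted least squares (log-likelihood tolerance
    1e-8, at most 100 iterations) with Wald standard errors from the
    observed information.  Perfect separation or non-convergence is flagged
    (``converged=False``) with a warning rather than raised.
    """
    regressors = list(regressors)
    if len(pairs) < 20:
        raise ConnectomeError("fit_logistic needs at least 20 pair records")
    y = pairs["status"].to_numpy(float)
    if y.min() == y.max():
        raise ConnectomeError("perfect separation: all pairs share one status")
    X, y = _design(pairs, regressors)
    beta, ll, cov, converged = _irls(X, y)
    if not converged:
        warnings.warn("logistic fit did not converge (possible perfect separation)")
    names = ["intercept"] + regressors
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = beta / se
    pvals = 2 * sps.norm.sf(np.abs(zval))
    return LogisticFit(
        regressors=names,
        coef=dict(zip(names, map(float, beta))),
        se=dict(zip(names, map(float, se))),
        wald_p=dict(zip(names, map(float, pvals))),
        log_likelihood=float(ll),
        n_obs=len(pairs),
        converged=bool(converged),
    )


def compare_present_absent(
    pairs: pd.DataFrame, feature: str = "c01", n_perm: int = 1000, seed: int = 0
) -> TestResult:
    """Energy test of a pair-table feature between present and absent pairs."""
    if feature not in {"d01", "c01"}:
        raise ValueError("feature must be 'd01' or 'c01'")
    present = pairs.loc[pairs["status"] == 1, feature].to_numpy(float)
    absent = pairs.loc[pairs["status"] == 0, feature].to_numpy(float)
    if present.size < 2 or absent.size < 2:
        raise ConnectomeError("both statuses must be represented")
    res = energy_test(present, absent, n_perm=n_perm, seed=seed)
    res.extra["median_present"] = float(np.median(present))
    res.extra["median_absent"] = float(np.median(absent))
    return res


def _pooled_table(pairs_a: pd.DataFrame, pairs_b: pd.DataFrame) -> pd.DataFrame:
    """Stack two per-species pair tables with a 0/1 species dummy.

    The alphabetically first species label is the reference (dummy 0).
    Rescaling must already have been done per species (build_pair_table
    guarantees this).
    """
    sp_a = pairs_a.attrs.get("species", "a")
    sp_b = pairs_b.attrs.get("species", "b")
    first, second = sorted([sp_a, sp_b])
    parts = []
    for tab, sp in ((pairs_a, sp_a), (pairs_b, sp_b)):
        t = tab.copy()
        t["species"] = 0.0 if sp == first else 1.0
        parts.append(t)
    pooled = pd.concat(parts, ignore_index=True)
    pooled["species_x_c01"] = pooled["species"] * pooled["c01"]
    pooled.attrs["species_levels"] = {first: 0, second: 1}
    return pooled


def fit_species_interaction(
    pairs_a: pd.DataFrame, pairs_b: pd.DataFrame
) -> tuple[LogisticFit, LRComparison]:
    """Pooled two-species fit with a species-by-dissimilarity interaction.

    Full model regressors: d01, c01, species, species x c01.  The reduced
    model drops the interaction; the two are compared with a
    likelihood-ratio test on 1 degree of freedom.
    """
    if len(pairs_a) == 0 or len(pairs_b) == 0:
        raise ConnectomeError("both species tables must be nonempty")
    pooled = _pooled_table(pairs_a, pairs_b)
    full = fit_logistic(pooled, ["d01", "c01", "species", "species_x_c01"])
    reduced = fit_logistic(pooled, ["d01", "c01", "species"])
    lr = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    lr = max(lr, 0.0)
    comp = LRComparison(lr_statistic=float(lr), df=1, p_value=float(sps.chi2.sf(lr, 1)))
    return full, comp


def probability_curve(
    fit: LogisticFit,
    d01_values: np.ndarray,
    c01_grid: np.ndarray,
    species_level: float = 0.0,
) -> np.ndarray:
    """Predicted connection probability over a (distance, dissimilarity) grid.

    Returns a (len(d01_values), len(c01_grid)) matrix of inverse-link
    evaluations; species terms (if present in the fit) are held at
    ``species_level``.
    """
    d01_values = np.asarray(d01_values, dtype=float)
    c01_grid = np.asarray(c01_grid, dtype=float)
    out = np.empty((d01_values.size, c01_grid.size))
    for i, d in enumerate(d01_values):
        eta = fit.coef["intercept"] + fit.coef.get("d01", 0.0) * d
        eta = eta + fit.coef.get("species", 0.0) * species_level
        slope = fit.coef.get("c01", 0.0) + fit.coef.get("species_x_c01", 0.0) * species_level
        out[i, :] = 1.0 / (1.0 + np.exp(-(eta + slope * c01_grid)))
    return out


def _reassign_types(
    cyto: np.ndarray, fraction: float, mode: str, rng: np.random.Generator,
    lo: float, hi: float,
) -> np.ndarray:
    n = cyto.size
    k = int(np.ceil(fraction * n))
    new = cyto.copy()
    if k == 0:
        return new
    chosen = rng.choice(n, size=k, replace=False)
    step = rng.choice([-1.0, 1.0], size=k)
    moved = new[chosen] + step
    if mode == "clamped":
        # reflect at both scale ends
        moved = np.where(moved > hi, hi - 1.0, moved)
        moved = np.where(moved < lo, lo + 1.0, moved)
    elif mode == "stretched":
        moved = np.where(moved < lo, lo + 1.0, moved)  # only the top may stretch
    else:
        raise ValueError(f"unknown reassignment mode {mode!r}")
    new[chosen] = moved
    return new


def type_reassignment_robustness(
    c: Connectome,
    fractions: np.ndarray,
    n_rep: int = 100,
    mode: str = "clamped",
    seed: int = 0,
    n_null: int = 100,
) -> pd.DataFrame:
    """Stability of the dissimilarity coefficient under type reassignment.

    For each fraction f, ``n_rep`` times: move ceil(f*n) randomly chosen
    areas one ordinal level up or down (clamped: reflected at the scale
    ends; stretched: the top level may be exceeded), rebuild the pair table
    and refit the logistic model, recording the c01 coefficient.  A
    label-permutation null (cyto values shuffled across areas) is included
    with fraction = NaN rows.
    """
    cyto = np.array([a.cyto for a in c.areas])
    if c.areas[0].cyto_kind != "type" or not np.allclose(cyto * 2, np.round(cyto * 2)):
        raise ConnectomeError("type reassignment requires an ordinal cyto scale")
    rng = np.random.default_rng(seed)
    lo, hi = cyto.min(), cyto.max()
    rows = []

    def _refit(values: np.ndarray) -> float:
        areas = [dataclasses.replace(a, cyto=float(v)) for a, v in zip(c.areas, values)]
        conn = Connectome(
            areas=areas,
            status=c.status,
            distance=c.distance,
            species=c.species,
            distance_kind=c.distance_kind,
            source_index=c.source_index,
        )
        fit = fit_logistic(build_pair_table(conn), ["d01", "c01"])
        return fit.coef["c01"]

    baseline = _refit(cyto)
    for f in np.asarray(fractions, dtype=float):
        for rep in range(n_rep if f > 0 else 1):
            coefficient = baseline if f == 0 else _refit(
                _reassign_types(cyto, f, mode, rng, lo, hi)
            )
            rows.append({"fraction": f, "rep": rep, "coef_c01": coefficient, "null": False})
    for rep in range(n_null):
        coefficient = _refit(rng.permutation(cyto))
        rows.append({"fraction": np.nan, "rep": rep, "coef_c01": coefficient, "null": True})
    out = pd.DataFrame(rows)
    out.attrs["baseline_coef"] = baseline
    out.attrs["mode"] = mode
    return out
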