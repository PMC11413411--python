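"""Ordinary kriging of infection frequency with prediction variance and LOOCV.

Ordinary kriging is the best linear unbiased predictor under an unknown
constant mean: the predictor z*(x0) = sum_i w_i z(x_i) uses weights that
solve the (n+1) system

    [ Gamma  1 ] [ w ]   [ gamma0 ]
    [ 1^T    0 ] [ l ] = [ 1      ]

where Gamma_ik = gamma(d_ik) for i != k (zero diagonal), gamma0_i is the
variogram to the target, and the Lagrange multiplier l enforces
sum w = 1. The kriging variance sum_i w_i gamma0_i + l depends only on
site geometry and the variogram model, never on the observed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .geodesy import Grid, SiteSet, cross_distance_matrix, distance_matrix
from .variogram import VariogramModel

__all__ = [
    "KrigingPrediction",
    "KrigingSurface",
    "LoocvResult",
    "SingularKrigingSystem",
    "solve_ok_system",
    "predict_point",
    "predict_points",
    "predict_grid",
    "loocv",
]

_RIDGE = 1e-10
_DUPLICATE_TOL_KM = 1e-9


class SingularKrigingSystem(ValueError):
    """The kriging system is singular (coincident sites)."""


@dataclass(frozen=True)
class KrigingPrediction:
    location: tuple[float, float]
    z_hat: float
    krig_var: float
    weights: np.ndarray | None = None
    z_hat_raw: float | None = None

    def __post_init__(self) -> None:
        if self.weights is not None and abs(float(np.sum(self.weights)) - 1.0) > 1e-6:
            raise ValueError("kriging weights must sum to 1")


@dataclass(frozen=True)
class KrigingSurface:
    """Gridded predictions; arrays are flat in the grid's lat-major order."""

    grid: Grid
    z_hat: np.ndarray
    krig_var: np.ndarray
    z_hat_raw: np.ndarray
    model: VariogramModel
    clamp_applied: bool

    def __post_init__(self) -> None:
        npts = len(self.grid)
        for name in ("z_hat", "krig_var", "z_hat_raw"):
            if len(getattr(self, name)) != npts:
                raise ValueError(f"{name} length != grid size {npts}")

    def to_frame(self):
        import pandas as pd

        pts = self.grid.points
        return pd.DataFrame(
            {
                "lat": pts[:, 0],
                "lon": pts[:, 1],
                "z_hat": self.z_hat,
                "krig_var": self.krig_var,
                "z_hat_raw": self.z_hat_raw,
            }
        )


@dataclass(frozen=True)
class LoocvResult:
    """Leave-one-out residual diagnostics for a kriging model."""

    residuals: np.ndarray  # observed - predicted
    z_hat: np.ndarray
    krig_var: np.ndarray
    mean_error: float
    rmse: float
    coverage95: float
    std_resid_var: float


def _gamma_matrix(model: VariogramModel, sites_arr: np.ndarray) -> np.ndarray:
    d = distance_matrix(sites_arr)
    off = ~np.eye(len(sites_arr), dtype=bool)
    if np.any(d[off] < _DUPLICATE_TOL_KM):
        raise SingularKrigingSystem(
            "coincident site coordinates make the kriging system singular; "
            "deduplicate locations first (filter_duplicate_locations)"
        )
    g = model.C0 + model.C1 * (1.0 - np.exp(-3.0 * d / model.b))
    np.fill_diagonal(g, 0.0)
    return g


def _build_lhs(model: VariogramModel, sites_arr: np.ndarray) -> np.ndarray:
    n = len(sites_arr)
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = _gamma_matrix(model, sites_arr)
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    return a


def _factorize(a: np.ndarray):
    n = a.shape[0]
    try:
        cond = np.linalg.cond(a)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            "near-singular kriging system; adding 1e-10 diagonal ridge",
            RuntimeWarning,
            stacklevel=3,
        )
        a = a + _RIDGE * np.eye(n)
    return linalg.lu_factor(a)


def _rhs(model: VariogramModel, sites_arr: np.ndarray, targets_arr: np.ndarray) -> np.ndarray:
    d0 = cross_distance_matrix(sites_arr, targets_arr)
    g0 = np.where(d0 > 0, model.C0 + model.C1 * (1.0 - np.exp(-3.0 * d0 / model.b)), 0.0)
    rhs = np.vstack([g0, np.ones(targets_arr.shape[0])])
    return rhs


def solve_ok_system(
    model: VariogramModel, sites: SiteSet | np.ndarray, target
) -> tuple[np.ndarray, float]:
    """Weights and Lagrange multiplier for one prediction location."""
    arr = sites.as_array() if isinstance(sites, SiteSet) else np.asarray(sites, float).reshape(-1, 2)
    if len(arr) < 1:
        raise ValueError("need at least one site")
    lu = _factorize(_build_lhs(model, arr))
    sol = linalg.lu_solve(lu, _rhs(model, arr, np.asarray(target, float).reshape(1, 2))[:, 0])
    return sol[:-1], float(sol[-1])


def predict_points(
    model: VariogramModel,
    sites: SiteSet | np.ndarray,
    z,
    targets: np.ndarray,
    clamp: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ordinary kriging at many targets sharing one site set.

    Returns (z_hat, krig_var, z_hat_raw); ``z_hat`` is clamped to [0, 1]
    when ``clamp`` (predictions are frequencies), the raw BLUP retained.
    """
    arr = sites.as_array() if isinstance(sites, SiteSet) else np.asarray(sites, float).reshape(-1, 2)
    z = np.asarray(z, dtype=float)
    targets = np.asarray(targets, dtype=float).reshape(-1, 2)
    if len(z) != len(arr):
        raise ValueError(f"{len(z)} observations for {len(arr)} sites")
    lu = _factorize(_build_lhs(model, arr))
    rhs = _rhs(model, arr, targets)
    sol = linalg.lu_solve(lu, rhs)  # (n+1, m)
    w, lam = sol[:-1, :], sol[-1, :]
    z_raw = w.T @ z
    krig_var = np.maximum(np.einsum("im,im->m", w, rhs[:-1, :]) + lam, 0.0)
    z_hat = np.clip(z_raw, 0.0, 1.0) if clamp else z_raw
    return z_hat, krig_var, z_raw


def predict_point(
    model: VariogramModel,
    sites: SiteSet | np.ndarray,
    z,
    target,
    clamp: bool = True,
) -> KrigingPrediction:
    """Ordinary kriging prediction with variance at a single location."""
    arr = sites.as_array() if isinstance(sites, SiteSet) else np.asarray(sites, float).reshape(-1, 2)
    z = np.asarray(z, dtype=float)
    w, lam = solve_ok_system(model, arr, target)
    g0 = _rhs(model, arr, np.asarray(target, float).reshape(1, 2))[:-1, 0]
    z_raw = float(w @ z)
    krig_var = max(float(w @ g0 + lam), 0.0)
    z_hat = float(np.clip(z_raw, 0.0, 1.0)) if clamp else z_raw
    return KrigingPrediction(
        location=(float(np.asarray(target).ravel()[0]), float(np.asarray(target).ravel()[1])),
        z_hat=z_hat,
        krig_var=krig_var,
        weights=w,
        z_hat_raw=z_raw,
    )


def predict_grid(
    model: VariogramModel,
    sites: SiteSet | np.ndarray,
    z,
    grid: Grid,
    neighborhood: int | None = None,
    clamp: bool = True,
) -> KrigingSurface:
    """Krige a whole grid; optionally restrict each point to its k nearest sites."""
    if len(grid) == 0:
        raise ValueError("empty grid")
    arr = sites.as_array() if isinstance(sites, SiteSet) else np.asarray(sites, float).reshape(-1, 2)
    z = np.asarray(z, dtype=float)
    pts = grid.points
    if neighborhood is None or neighborhood >= len(arr):
        z_hat, krig_var, z_raw = predict_points(model, arr, z, pts, clamp=clamp)
    else:
        k = int(neighborhood)
        d0 = cross_distance_matrix(arr, pts)  # (n, m)
        z_hat = np.full(len(pts), np.nan)
        krig_var = np.full(len(pts), np.nan)
        z_raw = np.full(len(pts), np.nan)
        for j in range(len(pts)):
            near = np.argsort(d0[:, j], kind="stable")[:k]
            try:
                zh, kv, zr = predict_points(model, arr[near], z[near], pts[j:j + 1], clamp=clamp)
            except SingularKrigingSystem:
                continue  # recorded as NaN, not fatal
            z_hat[j], krig_var[j], z_raw[j] = zh[0], kv[0], zr[0]
    return KrigingSurface(
        grid=grid, z_hat=z_hat, krig_var=krig_var, z_hat_raw=z_raw,
        model=model, clamp_applied=bool(clamp),
    )


def loocv(model: VariogramModel, sites: SiteSet | np.ndarray, z, clamp: bool = False) -> LoocvResult:
    """Leave-one-out cross-validation: each site predicted from the others.

    Residuals are observed minus predicted; ``std_resid_var`` is the
    variance of residuals standardized by the kriging standard error —
    near 1 for a well-specified model.
    """
    arr = sites.as_array() if isinstance(sites, SiteSet) else np.asarray(sites, float).reshape(-1, 2)
    z = np.asarray(z, dtype=float)
    n = len(arr)
    if n < 3:
        raise ValueError("need at least 3 sites for LOOCV")
    z_hat = np.empty(n)
    kv = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        rest = idx != i
        zh, v, _ = predict_points(model, arr[rest], z[rest], arr[i:i + 1], clamp=clamp)
        z_hat[i], kv[i] = zh[0], v[0]
    resid = z - z_hat
    with np.errstate(divide="ignore", invalid="ignore"):
        std = resid / np.sqrt(kv)
    std = std[np.isfinite(std)]
    coverage = float(np.mean(np.abs(resid) <= 1.96 * np.sqrt(np.maximum(kv, 0.0))))
    return LoocvResult(
        residuals=resid,
        z_hat=z_hat,
        krig_var=kv,
        mean_error=float(resid.mean()),
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        coverage95=coverage,
        std_resid_var=float(np.var(std, ddof=1)) if len(std) > 1 else float("nan"),
    )
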