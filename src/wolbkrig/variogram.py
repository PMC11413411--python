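"""Empirical semivariograms, anisotropy diagnostics, and exponential model fits.

The regionalized variable is the per-population infection frequency z.
For sites i, k separated by distance r the semivariance is half the
expected squared difference of z; the empirical estimator averages
(z_i - z_k)^2 / 2 over site pairs whose separation falls in a distance
bin. Spatial structure is summarized with the exponential model

    gamma(r) = C0 + C1 * (1 - exp(-3 r / b)),   gamma(0) = 0,

with nugget C0 (variance not spatially structured, including binomial
sampling noise), partial sill C1 (spatially structured variance), and
practical range b — the distance at which the curve reaches a fraction
1 - e^-3 (~95%) of C1 above the nugget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .geodesy import EARTH_RADIUS_KM, SiteSet, distance_matrix

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "FittedVariogram",
    "VariogramMap",
    "FitError",
    "EmptyVariogramError",
    "empirical_variogram",
    "directional_variograms",
    "variogram_map",
    "exponential_gamma",
    "fit_exponential",
    "practical_range",
]

DEFAULT_LAG_KM = 60.0
DEFAULT_CUTOFF_KM = 2000.0
FULL_RANGE_CUTOFF_KM = 6300.0
WEIGHT_MODES = ("npairs_over_h2", "npairs", "equal")


class EmptyVariogramError(ValueError):
    """No site pair falls inside the cutoff."""


class FitError(RuntimeError):
    """Variogram fit failed to converge; carries the best model found."""

    def __init__(self, message: str, best: "FittedVariogram | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned semivariance estimates; bins with no pairs are omitted."""

    lag_centers: np.ndarray
    gamma_hat: np.ndarray
    n_pairs: np.ndarray
    lag_width: float
    cutoff: float

    def __post_init__(self) -> None:
        lc = np.asarray(self.lag_centers, float)
        if not (len(lc) == len(self.gamma_hat) == len(self.n_pairs)):
            raise ValueError("lag_centers, gamma_hat, n_pairs must have equal length")
        if len(lc) > 1 and not np.all(np.diff(lc) > 0):
            raise ValueError("lag centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.lag_centers)


@dataclass(frozen=True)
class VariogramModel:
    """Exponential variogram parameters (nugget, partial sill, practical range)."""

    C0: float
    C1: float
    b: float

    def __post_init__(self) -> None:
        if self.C0 < 0 or self.C1 < 0:
            raise ValueError("C0 and C1 must be >= 0")
        if self.b <= 0:
            raise ValueError("b must be > 0")

    @property
    def sill(self) -> float:
        return self.C0 + self.C1


@dataclass(frozen=True)
class FittedVariogram:
    """A fitted model with its weighted SSE and identifiability flag."""

    model: VariogramModel
    sse: float
    weight_mode: str
    n_bins: int
    b_identifiable: bool = True


@dataclass(frozen=True)
class VariogramMap:
    """Semivariance on a lattice of separation vectors (dx east, dy north, km).

    Centrally symmetric by construction: each pair contributes to both
    (dx, dy) and (-dx, -dy).
    """

    cell_size: float
    cells: dict  # (ix, iy) -> (mean_semivariance, n_pairs)

    def gamma(self, ix: int, iy: int) -> float:
        return self.cells[(ix, iy)][0]


def _pairwise(sites: SiteSet | np.ndarray, z) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle distances, squared half-differences, and index pairs."""
    arr = sites.as_array() if isinstance(sites, SiteSet) else np.asarray(sites, float).reshape(-1, 2)
    z = np.asarray(z, dtype=float)
    if len(z) != len(arr):
        raise ValueError(f"{len(z)} values for {len(arr)} sites")
    if len(arr) < 2:
        raise ValueError("need at least 2 sites")
    d = distance_matrix(arr)
    iu, ju = np.triu_indices(len(arr), k=1)
    semiv = 0.5 * (z[iu] - z[ju]) ** 2
    return d[iu, ju], semiv, np.column_stack([iu, ju])


def _bin(dists: np.ndarray, semiv: np.ndarray, lag_width: float, cutoff: float) -> EmpiricalVariogram:
    inside = dists <= cutoff
    if not np.any(inside):
        raise EmptyVariogramError(f"no pair within cutoff {cutoff} km")
    d, s = dists[inside], semiv[inside]
    # bin j covers ((j-1) w, j w]; coincident pairs (d = 0) join bin 1
    idx = np.maximum(np.ceil(d / lag_width).astype(int), 1)
    nbins = int(idx.max())
    counts = np.bincount(idx, minlength=nbins + 1)[1:]
    sums = np.bincount(idx, weights=s, minlength=nbins + 1)[1:]
    nonempty = counts > 0
    centers = (np.arange(1, nbins + 1) - 0.5) * lag_width
    return EmpiricalVariogram(
        lag_centers=centers[nonempty],
        gamma_hat=sums[nonempty] / counts[nonempty],
        n_pairs=counts[nonempty],
        lag_width=float(lag_width),
        cutoff=float(cutoff),
    )


def empirical_variogram(
    sites: SiteSet | np.ndarray,
    z,
    lag_width: float = DEFAULT_LAG_KM,
    cutoff: float = DEFAULT_CUTOFF_KM,
) -> EmpiricalVariogram:
    """Omnidirectional empirical semivariogram with fixed-width distance bins."""
    if lag_width <= 0 or cutoff <= 0:
        raise ValueError("lag_width and cutoff must be > 0")
    dists, semiv, _ = _pairwise(sites, z)
    return _bin(dists, semiv, lag_width, cutoff)


def _local_plane_offsets(arr: np.ndarray, pairs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pair separation vectors (dx east, dy north) in km on a local tangent plane.

    Equirectangular approximation at each pair's mean latitude; adequate
    for separations well below the cutoff scales used here.
    """
    km_per_deg = np.pi * EARTH_RADIUS_KM / 180.0
    lat1, lon1 = arr[pairs[:, 0], 0], arr[pairs[:, 0], 1]
    lat2, lon2 = arr[pairs[:, 1], 0], arr[pairs[:, 1], 1]
    mean_lat = np.radians(0.5 * (lat1 + lat2))
    dx = (lon2 - lon1) * np.cos(mean_lat) * km_per_deg
    dy = (lat2 - lat1) * km_per_deg
    return dx, dy


def directional_variograms(
    sites: SiteSet | np.ndarray,
    z,
    angles=(0.0, 45.0, 90.0, 135.0),
    tol: float = 22.5,
    lag_width: float = DEFAULT_LAG_KM,
    cutoff: float = DEFAULT_CUTOFF_KM,
) -> list[EmpiricalVariogram]:
    """Directional semivariograms for anisotropy diagnosis.

    ``angles`` are bearings in degrees clockwise from north (axes, so
    modulo 180). A pair joins the sector whose angular distance to its
    bearing is within [-tol, tol); pairs outside every sector are dropped.
    Sectors must not overlap.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    angles = [a % 180.0 for a in angles]
    for i, a in enumerate(angles):
        for bgl in angles[i + 1:]:
            sep = abs(((a - bgl) + 90.0) % 180.0 - 90.0)
            if sep < 2.0 * tol - 1e-12:
                raise ValueError(
                    f"sectors at {a} and {bgl} degrees overlap with tol={tol}"
                )
    arr = sites.as_array() if isinstance(sites, SiteSet) else np.asarray(sites, float).reshape(-1, 2)
    dists, semiv, pairs = _pairwise(arr, z)
    dx, dy = _local_plane_offsets(arr, pairs)
    bearing = np.degrees(np.arctan2(dx, dy)) % 180.0
    out = []
    empty = EmpiricalVariogram(np.empty(0), np.empty(0), np.empty(0, dtype=int),
                               float(lag_width), float(cutoff))
    for a in angles:
        diff = ((bearing - a) + 90.0) % 180.0 - 90.0
        mask = (diff >= -tol) & (diff < tol)
        if not np.any(dists[mask] <= cutoff):  # a sector may simply be empty
            out.append(empty)
            continue
        out.append(_bin(dists[mask], semiv[mask], lag_width, cutoff))
    return out


def variogram_map(
    sites: SiteSet | np.ndarray,
    z,
    cell_size: float,
    cutoff: float = DEFAULT_CUTOFF_KM,
) -> VariogramMap:
    """Semivariance binned on separation vectors, for visual anisotropy checks."""
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    arr = sites.as_array() if isinstance(sites, SiteSet) else np.asarray(sites, float).reshape(-1, 2)
    dists, semiv, pairs = _pairwise(arr, z)
    dx, dy = _local_plane_offsets(arr, pairs)
    keep = dists <= cutoff
    ix = np.round(dx[keep] / cell_size).astype(int)
    iy = np.round(dy[keep] / cell_size).astype(int)
    acc: dict[tuple[int, int], list[float]] = {}
    for gx, gy, s in zip(ix, iy, semiv[keep]):
        for key in ((int(gx), int(gy)), (int(-gx), int(-gy))):
            acc.setdefault(key, [0.0, 0])
            acc[key][0] += s
            acc[key][1] += 1
    cells = {key: (tot / cnt, cnt) for key, (tot, cnt) in acc.items()}
    return VariogramMap(cell_size=float(cell_size), cells=cells)


def exponential_gamma(model: VariogramModel, r) -> np.ndarray | float:
    """gamma(r) = C0 + C1 (1 - exp(-3 r / b)); gamma(0) = 0 by convention."""
    r = np.asarray(r, dtype=float)
    g = np.where(r > 0, model.C0 + model.C1 * (1.0 - np.exp(-3.0 * r / model.b)), 0.0)
    return float(g) if g.ndim == 0 else g


def _weights(emp: EmpiricalVariogram, mode: str) -> np.ndarray:
    if mode == "npairs_over_h2":
        return emp.n_pairs / np.asarray(emp.lag_centers, float) ** 2
    if mode == "npairs":
        return emp.n_pairs.astype(float)
    if mode == "equal":
        return np.ones(len(emp), dtype=float)
    raise ValueError(f"unknown weight_mode {mode!r}; choose from {WEIGHT_MODES}")


def fit_exponential(
    emp: EmpiricalVariogram,
    weight_mode: str = "npairs_over_h2",
    init: VariogramModel | None = None,
) -> FittedVariogram:
    """Weighted least-squares fit of the exponential model to binned semivariances.

    Minimizes sum_j w_j (gamma_hat_j - gamma(h_j))^2 with bin weights
    w_j = N_j / h_j^2 by default, subject to C0, C1 >= 0 and b > 0.
    Exponential WLS surfaces are multimodal in b, so the bounded
    trust-region solver is restarted from five deterministic initial
    ranges; ties resolve to the lowest SSE, then the smallest b.
    """
    if len(emp) < 3:
        raise FitError(f"need >= 3 nonempty bins, got {len(emp)}")
    h = np.asarray(emp.lag_centers, float)
    g = np.asarray(emp.gamma_hat, float)
    w = _weights(emp, weight_mode)
    sw = np.sqrt(w)
    gmax = float(g.max())

    if gmax <= 0.0:  # constant field: pure zero variogram
        model = VariogramModel(0.0, 0.0, float(h[-1]))
        return FittedVariogram(model, 0.0, weight_mode, len(emp), b_identifiable=False)

    def residuals(theta):
        c0, c1, b = theta
        return sw * (g - (c0 + c1 * (1.0 - np.exp(-3.0 * h / b))))

    def sse(theta) -> float:
        return float(np.sum(residuals(theta) ** 2))

    # b initialized around the distance at which gamma_hat first reaches 80% of max
    reach = h[np.argmax(g >= 0.8 * gmax)]
    reach = max(float(reach), float(h[0]))
    c0_0 = max(float(g.min()), 0.0)
    c1_0 = max(gmax - c0_0, 1e-12)
    b_hi = max(10.0 * h[-1], 10.0 * reach)
    best: tuple[float, float, np.ndarray] | None = None
    any_success = False
    for mult in (0.25, 0.5, 1.0, 2.0, 4.0):
        x0 = np.array([c0_0, c1_0, np.clip(mult * reach, 1e-6, b_hi)])
        try:
            res = optimize.least_squares(
                residuals,
                x0,
                bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, b_hi]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        any_success = any_success or res.success
        cand = (sse(res.x), float(res.x[2]), res.x)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        raise FitError("all optimizer starts failed")
    fit_sse, _, x = best
    # never worse than the initial guess
    x0_def = np.array([c0_0, c1_0, reach])
    if sse(x0_def) < fit_sse:
        x, fit_sse = x0_def, sse(x0_def)
    c0, c1, b = float(x[0]), float(x[1]), float(x[2])
    identifiable = c1 > 1e-8 * max(gmax, 1e-12)
    if not identifiable:
        c1 = 0.0
    fitted = FittedVariogram(
        VariogramModel(c0, c1, b), fit_sse, weight_mode, len(emp), b_identifiable=identifiable
    )
    if not any_success:
        raise FitError("variogram fit did not converge", best=fitted)
    return fitted


def practical_range(model: VariogramModel) -> float:
    """Distance r* at which gamma reaches 95% of the total sill C0 + C1.

    Solves C0 + C1 (1 - exp(-3 r / b)) = 0.95 (C0 + C1) in closed form:
    r* = -(b/3) ln(0.05 (C0 + C1) / C1). With zero nugget r* ~ 0.9986 b;
    with C0 > 0 the 95% point and b differ — both are informative, so the
    model's b stays accessible as ``model.b``. Returns 0 when the nugget
    alone already exceeds the 95% level.
    """
    if model.C1 <= 0:
        raise ValueError("practical range undefined for a pure-nugget model (C1 = 0)")
    arg = 0.05 * model.sill / model.C1
    if arg >= 1.0:
        return 0.0
    return float(-(model.b / 3.0) * np.log(arg))
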