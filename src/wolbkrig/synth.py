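"""Synthetic population tables with controlled spatial structure.

Generates datasets that look like the real survey — sites scattered over
a European-scale bounding box, a latent spatially autocorrelated
infection-frequency surface with exponential covariance, and small
binomial samples per site — so every pipeline stage is testable without
external data, and so parameter-recovery experiments can quantify how
well variogram fitting and kriging work at realistic sample sizes.

The covariance of the latent Gaussian field is C0*I + C1*exp(-3 d / b),
the covariance counterpart of the exponential variogram. Links map the
Gaussian to [0, 1]:

``truncate`` (default)
    Distribution-matched clipping (a NORTA-type construction): the
    clipped-normal marginal is moment-matched so the field's mean and
    variance equal mean_p and C0 + C1, and the latent Gaussian
    correlation is pre-distorted through the numerically inverted
    pair-correlation map of the clipping transform, so the *output*
    field carries the nominal correlation (C1/(C0+C1)) exp(-3 d / b) —
    i.e. the generated field's variogram is the one the parameters
    name. Near the attainable maximum variance mean_p(1-mean_p) the
    field becomes strongly bimodal — exactly the regime of the real
    data, where most populations are near 0% or 100% infected.
``clip``
    Plain clipping of the nominal-scale Gaussian (variance and
    correlation both attenuated; the simple textbook variant).
``logit``
    Variance-matched logistic transform of the standardized field
    (correlation approximate).
``identity``
    No transform; for calibration studies on the Gaussian scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, special

from .datamodel import PopulationSample, PopulationTable
from .geodesy import DEFAULT_BBOX, SiteSet, distance_matrix
from .variogram import VariogramModel

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "DEFAULT_TRUTH",
    "simulate_sites",
    "simulate_latent_field",
    "simulate_counts",
    "generate_dataset",
]

# Default truth parameters for simulation fixtures (synthetic choices, not
# field estimates): moderate nugget, strong spatial structure, 600 km range.
DEFAULT_TRUTH = VariogramModel(C0=0.05, C1=0.20, b=600.0)

# Native-range per-population sample sizes from the packaged survey; the
# empirical law resamples these with a 5% uniform right tail on 1..68,
# giving mean ~= 12 and range 1-68.
_SURVEY_SIZES = np.array([12, 12, 12, 12, 12, 12, 9, 10, 12, 2, 12, 12, 11, 5])
_TAIL_PROB = 0.05
_MAX_N = 68

LINKS = ("truncate", "clip", "logit", "identity")


@dataclass(frozen=True)
class SimulationConfig:
    n_sites: int = 238
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX
    model: VariogramModel = DEFAULT_TRUTH
    mean_p: float = 0.5
    sample_size_law: str | int = "empirical"  # or a fixed integer N
    link: str = "truncate"
    clustered: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_p <= 1.0:
            raise ValueError("mean_p must be in [0, 1]")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.link not in LINKS:
            raise ValueError(f"link must be one of {LINKS}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything the generator knows: sites, latent field, counts, parameters."""

    sites: SiteSet
    latent_p: np.ndarray
    n: np.ndarray
    k: np.ndarray
    config: SimulationConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.config.seed,
            "n_sites": self.config.n_sites,
            "model": {"C0": self.config.model.C0, "C1": self.config.model.C1,
                      "b": self.config.model.b},
            "mean_p": self.config.mean_p,
            "link": self.config.link,
            "latent_p": [float(x) for x in self.latent_p],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _spawn_rngs(seed: int, n: int = 3) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_sites(config: SimulationConfig) -> SiteSet:
    """Scatter sites over the bounding box.

    Uniform by default; in clustered mode a Thomas-like process (uniform
    parents, Gaussian offspring, clipped to the box) mimics the dense
    Central-European sampling of the real dataset.
    """
    rng = _spawn_rngs(config.seed)[0]
    lat_min, lat_max, lon_min, lon_max = config.bbox
    m = config.n_sites
    if m == 0:
        return SiteSet(())
    if not config.clustered:
        lats = rng.uniform(lat_min, lat_max, m)
        lons = rng.uniform(lon_min, lon_max, m)
    else:
        n_parents = max(1, m // 10)
        plat = rng.uniform(lat_min, lat_max, n_parents)
        plon = rng.uniform(lon_min, lon_max, n_parents)
        which = rng.integers(n_parents, size=m)
        sigma = 0.02 * min(lat_max - lat_min, lon_max - lon_min)
        lats = np.clip(plat[which] + sigma * rng.standard_normal(m), lat_min, lat_max)
        lons = np.clip(plon[which] + sigma * rng.standard_normal(m), lon_min, lon_max)
    return SiteSet.from_array(np.column_stack([lats, lons]))


def _clipped_moments(mu: float, tau: float) -> tuple[float, float]:
    """Mean and variance of clip(N(mu, tau^2), 0, 1), in closed form."""
    from scipy.stats import norm

    a, bq = (0.0 - mu) / tau, (1.0 - mu) / tau
    Fa, Fb = norm.cdf(a), norm.cdf(bq)
    fa, fb = norm.pdf(a), norm.pdf(bq)
    # moments of the clipped variable (point masses at 0 and 1)
    mid = Fb - Fa
    ey = (1.0 - Fb) + mu * mid - tau * (fb - fa)
    # E[X^2 1{a<Z<b}] with X = mu + tau Z
    ex2_mid = (mu ** 2 + tau ** 2) * mid - tau * ((1.0 + mu) * fb - mu * fa)
    ey2 = (1.0 - Fb) + ex2_mid
    return float(ey), float(ey2 - ey ** 2)


def _clipped_normal_var(mu: float, tau: float) -> float:
    return _clipped_moments(mu, tau)[1]


def _match_clip_location_scale(mean_p: float, target_var: float) -> tuple[float, float]:
    """Latent (location, scale) so the clipped normal has the target moments.

    The attainable variance supremum is mean_p (1 - mean_p) (Bernoulli
    limit); unattainable targets fall back to the scale cap with the
    mean still matched.
    """
    if target_var <= 0:
        return float(mean_p), 0.0

    def objective(theta):
        m, logt = theta
        ey, vy = _clipped_moments(m, float(np.exp(logt)))
        return [ey - mean_p, vy - target_var]

    sol = optimize.least_squares(
        objective, x0=[mean_p, 0.0],
        bounds=([-5.0, np.log(1e-6)], [6.0, np.log(_TAU_MAX)]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    m, tau = float(sol.x[0]), float(np.exp(sol.x[1]))
    return m, tau


def _clip_corr_inverter(m: float, tau: float, n_grid: int = 33):
    """Invert the pair-correlation map of Y = clip(m + tau Z, 0, 1).

    For latent Gaussians (Z1, Z2) with correlation rho, corr(Y1, Y2) is
    an increasing function g(rho); returns a callable mapping a desired
    output correlation in [0, g(1)=1] back to the latent rho, tabulated
    by Gauss-Hermite quadrature and monotone interpolation.
    """
    x, w = np.polynomial.hermite.hermgauss(64)
    w = w / np.sqrt(np.pi)
    x = x * np.sqrt(2.0)
    f = np.clip(m + tau * x, 0.0, 1.0)
    m1 = float(np.sum(w * f))
    v1 = float(np.sum(w * f ** 2) - m1 ** 2)
    rhos = np.linspace(0.0, 1.0, n_grid)
    corrs = np.empty(n_grid)
    for i, rho in enumerate(rhos[:-1]):
        # E[f(Z1) f(Z2)] with Z2 = rho Z1 + sqrt(1-rho^2) Z3
        inner = np.clip(m + tau * (rho * x[:, None] + np.sqrt(1.0 - rho ** 2) * x[None, :]),
                        0.0, 1.0) @ w
        corrs[i] = (float(np.sum(w * f * inner)) - m1 ** 2) / v1
    corrs[-1] = 1.0
    corrs = np.maximum.accumulate(corrs)  # guard tiny quadrature wiggles

    def invert(target: np.ndarray) -> np.ndarray:
        return np.interp(np.clip(target, corrs[0], 1.0), corrs, rhos)

    return invert


def _nearest_psd_cholesky(r: np.ndarray) -> np.ndarray:
    """Cholesky factor, clipping tiny negative eigenvalues if needed."""
    try:
        return np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        pass
    vals, vecs = np.linalg.eigh(r)
    vals = np.clip(vals, 1e-10, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    try:
        return np.linalg.cholesky(fixed)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("latent correlation not positive definite after repair") from exc


def _logit_var(mu: float, tau: float) -> float:
    """Variance of expit(logit(mu) + tau Z) by Gauss-Hermite quadrature."""
    x, w = np.polynomial.hermite.hermgauss(101)
    vals = special.expit(special.logit(np.clip(mu, 1e-12, 1 - 1e-12)) + tau * np.sqrt(2.0) * x)
    w = w / np.sqrt(np.pi)
    m = float(np.sum(w * vals))
    return float(np.sum(w * vals ** 2) - m ** 2)


_TAU_MAX = 50.0


def _match_scale(var_fn, mu: float, target_var: float) -> float:
    """Smallest tau with var_fn(mu, tau) = target_var, capped at tau_max.

    var_fn is increasing in tau toward the Bernoulli limit mu-independent
    supremum of 0.25; when the target is unattainable the cap applies.
    """
    if target_var <= 0:
        return 0.0
    if var_fn(mu, _TAU_MAX) <= target_var:
        return _TAU_MAX
    return float(optimize.brentq(lambda t: var_fn(mu, t) - target_var, 1e-8, _TAU_MAX))


def simulate_latent_field(
    sites: SiteSet | np.ndarray,
    model: VariogramModel,
    mean_p: float,
    link: str = "truncate",
    seed: int = 0,
) -> np.ndarray:
    """Draw one latent frequency surface at the given sites.

    A Gaussian vector with covariance C0*I + C1*exp(-3 D / b) is drawn
    (Cholesky, with eigenvalue-clipping repair if needed), then mapped to
    [0, 1] by the link (see module docstring). The default ``truncate``
    link pre-distorts the latent correlation so the output field itself
    has the nominal exponential variogram.
    """
    arr = sites.as_array() if isinstance(sites, SiteSet) else np.asarray(sites, float).reshape(-1, 2)
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    m = len(arr)
    if m == 0:
        return np.empty(0)
    sigma2 = model.C0 + model.C1
    if sigma2 == 0.0:
        return np.full(m, float(mean_p))
    if link not in LINKS:
        raise ValueError(f"unknown link {link!r}")
    d = distance_matrix(arr)
    eps = rng.standard_normal(m)
    if link == "truncate":
        loc, tau = _match_clip_location_scale(mean_p, sigma2)
        target_corr = (model.C1 / sigma2) * np.exp(-3.0 * d / model.b)
        np.fill_diagonal(target_corr, 1.0)
        if tau == 0.0:
            return np.full(m, float(mean_p))
        invert = _clip_corr_inverter(loc, tau)
        r_latent = invert(target_corr)
        np.fill_diagonal(r_latent, 1.0)
        chol = _nearest_psd_cholesky(r_latent)
        return np.clip(loc + tau * (chol @ eps), 0.0, 1.0)
    cov = model.C1 * np.exp(-3.0 * d / model.b) + model.C0 * np.eye(m)
    chol = _nearest_psd_cholesky(cov / sigma2) * np.sqrt(sigma2)
    x = mean_p + chol @ eps
    if link == "identity":
        return x
    if link == "clip":
        return np.clip(x, 0.0, 1.0)
    # logit: variance-matched logistic transform of the standardized field
    zstd = (x - mean_p) / np.sqrt(sigma2)
    tau = _match_scale(_logit_var, mean_p, sigma2)
    return special.expit(special.logit(np.clip(mean_p, 1e-12, 1 - 1e-12)) + tau * zstd)


def draw_sample_sizes(law: str | int, m: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(law, (int, np.integer)):
        if law < 1:
            raise ValueError("fixed sample size must be >= 1")
        return np.full(m, int(law))
    if law == "empirical":
        base = rng.choice(_SURVEY_SIZES, size=m)
        tail = rng.integers(1, _MAX_N + 1, size=m)
        return np.where(rng.random(m) < _TAIL_PROB, tail, base).astype(int)
    raise ValueError(f"unknown sample_size_law {law!r}")


def simulate_counts(
    latent_p: np.ndarray, sample_size_law: str | int, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site sample sizes n and infected counts k ~ Binomial(n, latent_p)."""
    p = np.asarray(latent_p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("latent_p must lie in [0, 1]")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    n = draw_sample_sizes(sample_size_law, len(p), rng)
    k = rng.binomial(n, p)
    return n, k


def generate_dataset(config: SimulationConfig) -> tuple[PopulationTable, SyntheticTruth]:
    """Compose site, field, and count simulators into a validated table."""
    rng_sites, rng_field, rng_counts = _spawn_rngs(config.seed)
    sites = simulate_sites(config)
    latent = simulate_latent_field(sites, config.model, config.mean_p, config.link, rng_field)
    # identity-link fields can stray outside [0, 1]; counts are binomial so clip
    n, k = simulate_counts(np.clip(latent, 0.0, 1.0), config.sample_size_law, rng_counts)
    width = max(3, len(str(max(config.n_sites - 1, 0))))
    samples = [
        PopulationSample(
            id=f"site_{i:0{width}d}",
            lat=float(lat),
            lon=float(lon),
            year=2020,
            n=int(n[i]),
            k=int(k[i]),
        )
        for i, (lat, lon) in enumerate(sites.coordinates)
    ]
    table = PopulationTable(samples)
    return table, SyntheticTruth(sites=sites, latent_p=latent, n=n, k=k, config=config)
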