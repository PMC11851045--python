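"""Seed-deterministic synthetic data with the structure the analysis assumes.

The panel generator draws from the spatial Durbin reduced form

    y_t = (I - rho W)^{-1} (alpha + X_t beta + W X_t theta + mu + nu_t 1 + eps_t)

and returns the true parameters alongside the data, so estimator-recovery
tests can compare against ground truth.  Unit fixed effects can be made
correlated with the covariates (``fe_x_corr``), which is exactly the setting
where pooled OLS is biased and the within estimator is not — the module's
core purpose.

Default dimensions mirror a 31-region x 8-year study panel with five
covariates playing the roles of a sex ratio, a dependency ratio, an
urbanization rate, an education share, and log per-capita regional product.
The monthly generator produces within-year search-volume series whose
seasonal peak location and strength are controlled by ``peak_month`` and
``kappa`` (a circular von-Mises-style bump; ``kappa = 0`` gives
exchangeable months).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import PanelData
from .temporal import MonthlySeries
from .weights import RegionSet, SpatialWeights, build_rook_from_edges, china_provinces

__all__ = [
    "SdmDgpConfig",
    "make_lattice",
    "lattice_weights",
    "simulate_sdm_panel",
    "simulate_monthly_series",
    "make_blocky_attribute",
    "default_study_config",
]

# covariate roles mirroring the study's five explanatory variables:
# (name, mean, sd) — units: ratio, ratio, percent, percent, log-currency
_DEFAULT_COVARIATES = (
    ("male_female_ratio", 1.05, 0.04),
    ("gross_dependency_ratio", 0.42, 0.07),
    ("urbanization_rate", 60.0, 12.0),
    ("education_rate", 30.0, 10.0),
    ("ln_grdp_pc", 11.0, 0.45),
)


@dataclass
class SdmDgpConfig:
    """True parameters of the SDM data-generating process."""

    n_units: int = 31
    T: int = 8
    rho: float = 0.4
    beta: tuple[float, ...] = (0.06, -0.002, -0.15, 0.07, 0.02)
    theta: tuple[float, ...] = (0.02, -0.04, -0.09, -0.2, -0.01)
    alpha: float = 0.5
    sigma: float = 0.1
    fe_unit_sd: float = 0.3
    fe_time_sd: float = 0.15
    fe_x_corr: float = 0.0  # correlation between unit effects and covariate means
    covariate_spec: tuple[tuple[str, float, float], ...] = _DEFAULT_COVARIATES
    x_ar1: float = 0.0  # within-unit AR(1) of covariates over time (0 = iid)
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        k = len(self.covariate_spec)
        if len(self.beta) != k or len(self.theta) != k:
            raise ValueError("beta/theta/covariate_spec lengths disagree")
        if not -1 < self.fe_x_corr < 1:
            raise ValueError("|fe_x_corr| must be < 1")

    @property
    def k(self) -> int:
        return len(self.covariate_spec)

    @property
    def x_names(self) -> tuple[str, ...]:
        return tuple(nm for nm, _, _ in self.covariate_spec)


def default_study_config(seed: int = 0, **overrides) -> SdmDgpConfig:
    """The 31-unit x 8-year study-like configuration (signs of the true
    effects echo a positive sex-ratio/education/income gradient and a
    negative urbanization gradient, with no claim about magnitudes)."""
    kw = dict(n_units=31, T=8, fe_x_corr=0.5, x_ar1=0.8, seed=seed)
    kw.update(overrides)
    return SdmDgpConfig(**kw)


def make_lattice(rows: int, cols: int) -> list[tuple[str, str]]:
    """Rook edges of an rows x cols grid; region ids are "r{i}c{j}"."""
    if rows < 2 or cols < 2:
        raise ValueError("lattice needs rows >= 2 and cols >= 2")
    edges = []
    for i in range(rows):
        for j in range(cols):
            if j + 1 < cols:
                edges.append((f"r{i}c{j}", f"r{i}c{j + 1}"))
            if i + 1 < rows:
                edges.append((f"r{i}c{j}", f"r{i + 1}c{j}"))
    return edges


def lattice_weights(rows: int, cols: int) -> SpatialWeights:
    ids = tuple(f"r{i}c{j}" for i in range(rows) for j in range(cols))
    return build_rook_from_edges(make_lattice(rows, cols), RegionSet(ids))


@dataclass(frozen=True)
class SdmTruth:
    """Machine-readable truth record emitted with every simulated panel."""

    rho: float
    beta: tuple[float, ...]
    theta: tuple[float, ...]
    alpha: float
    sigma: float
    mu: np.ndarray
    nu: np.ndarray
    x_names: tuple[str, ...]
    seed: int

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "beta": list(self.beta),
            "theta": list(self.theta),
            "alpha": self.alpha,
            "sigma": self.sigma,
            "mu": self.mu.tolist(),
            "nu": self.nu.tolist(),
            "x_names": list(self.x_names),
            "seed": self.seed,
        }


def simulate_sdm_panel(
    w: SpatialWeights, cfg: SdmDgpConfig
) -> tuple[PanelData, SdmTruth]:
    """Draw a balanced panel from the SDM reduced form; returns data + truth."""
    n, T, k = w.n, cfg.T, cfg.k
    if n != cfg.n_units:
        raise ValueError(f"weights have {n} regions but cfg.n_units={cfg.n_units}")
    rng = np.random.default_rng(cfg.seed)
    W = w.W

    # unit-level covariate means give the channel correlating FE with X
    means = np.array([m for _, m, _ in cfg.covariate_spec])
    sds = np.array([s for _, _, s in cfg.covariate_spec])
    unit_means = means + rng.standard_normal((n, k)) * sds

    X = np.empty((n, T, k))
    innov_sd = sds * 0.3  # within-unit variation around the unit mean
    if cfg.x_ar1 == 0.0:
        X = unit_means[:, None, :] + rng.standard_normal((n, T, k)) * innov_sd
    else:
        phi = cfg.x_ar1
        stat_sd = innov_sd / np.sqrt(1 - phi**2)
        dev = np.empty((n, T, k))
        dev[:, 0, :] = rng.standard_normal((n, k)) * stat_sd
        for t in range(1, T):
            dev[:, t, :] = phi * dev[:, t - 1, :] + rng.standard_normal((n, k)) * innov_sd
        X = unit_means[:, None, :] + dev

    # unit effects: correlated with the standardized first-covariate unit mean
    z1 = (unit_means[:, 0] - means[0]) / sds[0]
    mu = cfg.fe_unit_sd * (
        cfg.fe_x_corr * z1 + np.sqrt(1 - cfg.fe_x_corr**2) * rng.standard_normal(n)
    )
    nu = cfg.fe_time_sd * rng.standard_normal(T)

    beta = np.asarray(cfg.beta)
    theta = np.asarray(cfg.theta)
    A_inv = np.linalg.inv(np.eye(n) - cfg.rho * W)
    y = np.empty((n, T))
    for t in range(T):
        xb = X[:, t, :] @ beta + (W @ X[:, t, :]) @ theta
        eps = cfg.sigma * rng.standard_normal(n)
        y[:, t] = A_inv @ (cfg.alpha + xb + mu + nu[t] + eps)

    panel = PanelData(w.regions.ids, tuple(range(2015, 2015 + T)), y, X, cfg.x_names)
    truth = SdmTruth(
        rho=cfg.rho, beta=cfg.beta, theta=cfg.theta, alpha=cfg.alpha,
        sigma=cfg.sigma, mu=mu, nu=nu, x_names=cfg.x_names, seed=cfg.seed,
    )
    return panel, truth


def simulate_monthly_series(
    years: tuple[int, ...] | range,
    peak_month: int = 11,
    kappa: float = 2.0,
    base_level: float = 50_000.0,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> list[MonthlySeries]:
    """Monthly search-volume totals with a circular seasonal bump.

    Expected volume in month m is ``base_level * exp(kappa * cos(2*pi*(m -
    peak_month)/12))`` (normalized to keep the annual total near 12 *
    base_level), times a lognormal noise factor with coefficient of
    variation ``noise_cv``.  ``kappa = 0`` makes months exchangeable.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if not 1 <= peak_month <= 12:
        raise ValueError("peak_month must be in 1..12")
    rng = np.random.default_rng(seed)
    months = np.arange(1, 13)
    bump = np.exp(kappa * np.cos(2 * np.pi * (months - peak_month) / 12.0))
    bump *= 12.0 / bump.sum()
    s = np.sqrt(np.log(1 + noise_cv**2))
    out = []
    for yr in years:
        noise = rng.lognormal(-0.5 * s**2, s, size=12)
        counts = base_level * bump * noise
        out.append(MonthlySeries(int(yr), counts))
    return out


def make_blocky_attribute(
    w: SpatialWeights,
    high_block: set[str] | frozenset[str],
    effect: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Attribute vector with a high-valued block and low-valued complement,
    the canonical fixture for recovering HH/LL clusters with LISA."""
    unknown = set(high_block) - set(w.regions.ids)
    if unknown:
        raise ValueError(f"block ids not in regions: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    x = np.where(
        np.isin(w.regions.ids, list(high_block)), float(effect), -float(effect)
    )
    return x + noise_sd * rng.standard_normal(w.n)
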