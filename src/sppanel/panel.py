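"""Spatial panel econometrics: SAR / SEM / SDM maximum likelihood, the
model-selection test battery, and the LeSage–Pace effect decomposition.

The spatial Durbin model (SDM) for a balanced panel of ``n`` units over
``T`` periods is

    y_t = rho * W y_t + X_t beta + W X_t theta + mu + nu_t * 1 + eps_t,

where ``W`` is a row-standardized spatial weight matrix, ``mu`` unit fixed
effects, ``nu_t`` time fixed effects and ``eps_t ~ N(0, sigma^2 I)``.
Setting ``theta = 0`` gives the spatial autoregressive model (SAR); the
spatial error model (SEM) replaces the outcome lag with spatially
autocorrelated errors ``u_t = lambda W u_t + eps_t`` and is nested in the
SDM through the common-factor restriction ``theta = -rho * beta``.

Estimation is by concentrated maximum likelihood: fixed effects are removed
by within-demeaning, ``beta`` (and ``theta``) and ``sigma^2`` are profiled
out, and the scalar spatial parameter is maximized over the interval
``(1/omega_min, 1/omega_max)`` given by the extreme eigenvalues of ``W``,
with the Jacobian term ``T * ln|I - rho W|`` computed from precomputed
eigenvalues.  Random effects use ML with the quasi-demeaning weight
``phi = sigma_e / sqrt(T sigma_mu^2 + sigma_e^2)`` profiled jointly with
``rho``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .weights import SpatialWeights

__all__ = [
    "PanelData",
    "PanelFit",
    "TestResult",
    "EffectsResult",
    "fit_panel_ols",
    "fit_spatial_panel",
    "lm_spatial_tests",
    "wald_reduction_tests",
    "lr_test",
    "hausman_test",
    "decompose_effects",
    "vif",
]

_EFFECTS = ("pooled", "space", "time", "both", "random")
_MODELS = ("OLS", "SAR", "SEM", "SDM")


class PanelError(ValueError):
    pass


class RankError(PanelError):
    """Regressor matrix rank deficient after demeaning."""


class ConvergenceError(PanelError):
    pass


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

@dataclass
class PanelData:
    """Balanced unit-by-time panel: outcome ``y`` (n, T) and covariates
    ``X`` (n, T, k), with unit ids shared with the weight matrix."""

    unit_ids: tuple[str, ...]
    times: tuple[int, ...]
    y: np.ndarray
    X: np.ndarray
    x_names: tuple[str, ...]

    def __post_init__(self) -> None:
        n, T = len(self.unit_ids), len(self.times)
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.y.shape != (n, T):
            raise PanelError(f"y shape {self.y.shape} != ({n}, {T})")
        if self.X.ndim != 3 or self.X.shape[:2] != (n, T):
            raise PanelError(f"X shape {self.X.shape} != ({n}, {T}, k)")
        if self.X.shape[2] != len(self.x_names):
            raise PanelError("x_names length does not match X")
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise PanelError("panel contains missing cells; unbalanced panels are rejected")

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    @property
    def T(self) -> int:
        return len(self.times)

    @property
    def k(self) -> int:
        return self.X.shape[2]

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        unit_col: str = "unit_id",
        time_col: str = "year",
        y_col: str = "pbi",
        x_cols: Sequence[str] | None = None,
    ) -> "PanelData":
        """Build a balanced panel from a long table; missing unit-year cells
        are an error (no imputation)."""
        if x_cols is None:
            x_cols = [c for c in df.columns if c not in (unit_col, time_col, y_col)]
        units = tuple(sorted(df[unit_col].astype(str).unique()))
        times = tuple(sorted(df[time_col].unique()))
        n, T = len(units), len(times)
        if len(df) != n * T or df.duplicated([unit_col, time_col]).any():
            raise PanelError(
                f"panel is not balanced: expected {n * T} unique unit-time rows, got {len(df)}"
            )
        idx = df.set_index([unit_col, time_col]).sort_index()
        y = np.empty((n, T))
        X = np.empty((n, T, len(x_cols)))
        for i, u in enumerate(units):
            block = idx.loc[u].reindex(list(times))
            if block[y_col].isna().any() or block[list(x_cols)].isna().any().any():
                raise PanelError(f"unit {u!r}: missing outcome/covariate cells")
            y[i] = block[y_col].to_numpy(dtype=float)
            X[i] = block[list(x_cols)].to_numpy(dtype=float)
        return cls(units, tuple(int(t) for t in times), y, X, tuple(x_cols))

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, u in enumerate(self.unit_ids):
            for t, yr in enumerate(self.times):
                rows.append(
                    {"unit_id": u, "year": yr, "pbi": self.y[i, t]}
                    | dict(zip(self.x_names, self.X[i, t]))
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class PanelFit:
    model: str
    effects: str
    beta: pd.Series
    sigma2: float  # degrees-of-freedom corrected
    sigma2_ml: float
    loglik: float
    nobs: int
    n: int
    T: int
    rho: float | None = None
    lam: float | None = None
    theta: pd.Series | None = None
    vcov: pd.DataFrame | None = None
    converged: bool = True
    boundary: bool = False
    phi: float | None = None  # RE quasi-demeaning weight
    fe_unit: pd.Series | None = None
    fe_time: pd.Series | None = None
    x_names: tuple[str, ...] = ()
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def params(self) -> pd.Series:
        """All estimated slope/spatial parameters in vcov order."""
        parts = [self.beta]
        if self.theta is not None:
            parts.append(self.theta)
        s = pd.concat(parts)
        if self.rho is not None:
            s = pd.concat([s, pd.Series({"rho": self.rho})])
        if self.lam is not None:
            s = pd.concat([s, pd.Series({"lambda": self.lam})])
        return s

    def summary(self) -> pd.DataFrame:
        """Coefficients with SEs, z, p and 95% CI (needs vcov)."""
        if self.vcov is None:
            raise PanelError("fit carries no vcov")
        est = self.params
        names = [p for p in est.index if p in self.vcov.index]
        se = np.sqrt(np.diag(self.vcov.loc[names, names]))
        z = est[names] / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "coef": est[names],
                "se": se,
                "z": z,
                "p": p,
                "ci_low": est[names] - 1.959963984540054 * se,
                "ci_high": est[names] + 1.959963984540054 * se,
            },
            index=names,
        )


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: int
    p: float
    alpha: float = 0.1
    note: str = ""

    @property
    def reject(self) -> bool:
        return self.p < self.alpha


@dataclass(frozen=True)
class EffectsResult:
    x_names: tuple[str, ...]
    direct: np.ndarray
    indirect: np.ndarray
    total: np.ndarray
    direct_se: np.ndarray
    indirect_se: np.ndarray
    total_se: np.ndarray
    direct_p: np.ndarray
    indirect_p: np.ndarray
    total_p: np.ndarray
    ci: dict  # {"direct": (lo, hi), ...} percentile CIs per covariate
    n_draws: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for which in ("direct", "indirect", "total"):
            est = getattr(self, which)
            se = getattr(self, which + "_se")
            p = getattr(self, which + "_p")
            lo, hi = self.ci[which]
            for j, name in enumerate(self.x_names):
                rows.append(
                    {
                        "effect": which,
                        "variable": name,
                        "estimate": est[j],
                        "se": se[j],
                        "p": p[j],
                        "ci_low": lo[j],
                        "ci_high": hi[j],
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Demeaning machinery (two-way within transformation)
# ---------------------------------------------------------------------------

def _demean(arr: np.ndarray, effects: str) -> np.ndarray:
    """Within transformation of an (n, T) or (n, T, k) array."""
    a = arr.astype(float, copy=True)
    if effects in ("space", "both"):
        a -= a.mean(axis=1, keepdims=True)
    if effects in ("time", "both"):
        a -= a.mean(axis=0, keepdims=True)
    # subtracting both means removes the grand mean twice; sequential
    # demeaning as written already adds it back implicitly:
    # a - ai. - a.t + a.. is exactly mean(axis=1) then mean(axis=0)
    return a

def _df_effective(n: int, T: int, effects: str) -> int:
    if effects == "both":
        return (n - 1) * (T - 1)
    if effects == "space":
        return n * (T - 1)
    if effects == "time":
        return (n - 1) * T
    return n * T


def _stack(arr: np.ndarray) -> np.ndarray:
    """(n, T) -> (n*T,) or (n, T, k) -> (n*T, k), time-major blocks of n."""
    if arr.ndim == 2:
        return arr.T.reshape(-1)
    return arr.transpose(1, 0, 2).reshape(-1, arr.shape[2])


def _apply_W(arr: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Spatial lag per period of an (n, T) or (n, T, k) array."""
    if arr.ndim == 2:
        return W @ arr
    return np.einsum("ij,jtk->itk", W, arr)


def _check_rank(Z: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # name columns whose removal restores full column rank
        bad = []
        for j in range(Z.shape[1]):
            keep = [c for c in range(Z.shape[1]) if c != j]
            if np.linalg.matrix_rank(Z[:, keep]) == rank:
                bad.append(names[j])
        raise RankError(
            f"regressor matrix rank deficient after demeaning; "
            f"collinear or degenerate columns: {bad}"
        )


def _recover_fe(panel: PanelData, resid_raw: np.ndarray, effects: str):
    """Unit/time fixed-effect estimates from raw-scale residual means."""
    fe_unit = fe_time = None
    if effects in ("space", "both"):
        fe_unit = pd.Series(resid_raw.mean(axis=1) - resid_raw.mean(), index=panel.unit_ids)
    if effects in ("time", "both"):
        fe_time = pd.Series(resid_raw.mean(axis=0) - resid_raw.mean(), index=panel.times)
    return fe_unit, fe_time


# ---------------------------------------------------------------------------
# OLS (within) baseline
# ---------------------------------------------------------------------------

def fit_panel_ols(panel: PanelData, effects: str = "both") -> PanelFit:
    """Within (fixed-effects-demeaned) least squares baseline.

    Residuals and design pieces are cached on the fit for the LM spatial
    battery.
    """
    if effects not in ("pooled", "space", "time", "both"):
        raise PanelError(f"effects must be one of pooled/space/time/both, got {effects!r}")
    yd = _demean(panel.y, effects)
    Xd = _demean(panel.X, effects)
    yv = _stack(yd)
    Z = _stack(Xd)
    names = list(panel.x_names)
    if effects == "pooled":
        Z = np.column_stack([np.ones(len(yv)), Z])
        names = ["const"] + names
    _check_rank(Z, names)
    coef, *_ = np.linalg.lstsq(Z, yv, rcond=None)
    e = yv - Z @ coef
    nobs = panel.n * panel.T
    sigma2_ml = float(e @ e / nobs)
    dfe = max(_df_effective(panel.n, panel.T, effects) - panel.k, 1)
    sigma2 = float(e @ e / dfe)
    loglik = -0.5 * nobs * (np.log(2 * np.pi) + np.log(sigma2_ml) + 1.0)
    XtX_inv = np.linalg.inv(Z.T @ Z)
    vcov = pd.DataFrame(sigma2 * XtX_inv, index=names, columns=names)
    beta = pd.Series(coef, index=names)
    resid_raw = panel.y - np.einsum("ntk,k->nt", panel.X, beta[list(panel.x_names)].to_numpy())
    if "const" in beta.index:
        resid_raw = resid_raw - beta["const"]
    fe_unit, fe_time = _recover_fe(panel, resid_raw, effects)
    fit = PanelFit(
        model="OLS",
        effects=effects,
        beta=beta,
        sigma2=sigma2,
        sigma2_ml=sigma2_ml,
        loglik=loglik,
        nobs=nobs,
        n=panel.n,
        T=panel.T,
        vcov=vcov,
        fe_unit=fe_unit,
        fe_time=fe_time,
        x_names=panel.x_names,
    )
    fit._cache.update({"e": e, "Z": Z, "y": yv, "yd": yd, "Xd": Xd, "names": names})
    return fit


# ---------------------------------------------------------------------------
# LM spatial battery (pooled Anselin/Elhorst forms on demeaned data)
# ---------------------------------------------------------------------------

def lm_spatial_tests(
    ols: PanelFit, w: SpatialWeights, alpha: float = 0.1
) -> dict[str, TestResult]:
    """LM-lag, LM-error and their robust variants on within-OLS residuals.

    All four statistics are referred to chi-square(1).
    """
    if "e" not in ols._cache:
        raise PanelError("fit carries no cached residuals; use fit_panel_ols")
    W = w.W
    e = ols._cache["e"]
    Z = ols._cache["Z"]
    yv = ols._cache["y"]
    yd = ols._cache["yd"]
    Xd = ols._cache["Xd"]
    n, T = ols.n, ols.T
    nobs = n * T
    sigma2 = float(e @ e / nobs)
    if sigma2 <= 0 or not np.isfinite(sigma2):
        raise PanelError("degenerate residual variance")

    Wy = _stack(_apply_W(yd, W))
    We = _stack(_apply_W(e.reshape(T, n).T, W))
    T_w = T * float(np.trace(W.T @ W + W @ W))

    d_lag = float(e @ Wy) / sigma2
    d_err = float(e @ We) / sigma2

    slope_names = [nm for nm in ols._cache["names"] if nm != "const"]
    bhat = ols.beta[slope_names].to_numpy()
    WXb = _stack(_apply_W(np.einsum("ntk,k->nt", Xd, bhat), W))
    # M-projection residual of WXb on the regressors
    proj, *_ = np.linalg.lstsq(Z, WXb, rcond=None)
    MWXb = WXb - Z @ proj
    J = (float(MWXb @ MWXb) + T_w * sigma2) / sigma2

    lm_lag = d_lag**2 / J
    lm_err = d_err**2 / T_w
    rlm_lag = (d_lag - d_err) ** 2 / (J - T_w)
    rlm_err = (d_err - (T_w / J) * d_lag) ** 2 / (T_w * (1 - T_w / J))

    out = {}
    for name, stat in (
        ("LM-lag", lm_lag),
        ("LM-error", lm_err),
        ("robust LM-lag", rlm_lag),
        ("robust LM-error", rlm_err),
    ):
        stat = float(max(stat, 0.0))
        out[name] = TestResult(name, stat, 1, float(stats.chi2.sf(stat, 1)), alpha)
    return out


# ---------------------------------------------------------------------------
# Spatial panel ML
# ---------------------------------------------------------------------------

def _eigen_interval(W: np.ndarray, W0: np.ndarray | None = None):
    """Real eigenvalues of row-standardized W (similar to a symmetric matrix
    when W0 is symmetric) and the admissible spatial-parameter interval."""
    if W0 is not None:
        d = W0.sum(axis=1)
        Ws = W0 / np.sqrt(np.outer(d, d))
        omega = np.linalg.eigvalsh(Ws)
    else:
        omega = np.real(np.linalg.eigvals(W))
        omega.sort()
    lo = 1.0 / omega[0] if omega[0] < 0 else -np.inf
    hi = 1.0 / omega[-1]
    return omega, lo + 1e-6, hi - 1e-6


def _opt_scalar(neg_obj, lo: float, hi: float, n_grid: int = 50):
    """Coarse grid to bracket the optimum, then bounded Brent refinement."""
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([neg_obj(r) for r in grid])
    j = int(np.argmin(vals))
    a = grid[max(j - 1, 0)]
    b = grid[min(j + 1, n_grid - 1)]
    res = optimize.minimize_scalar(neg_obj, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise ConvergenceError(f"scalar optimization failed: {res}")
    return float(res.x), res


def _sar_sdm_vcov(
    Z: np.ndarray, delta: np.ndarray, rho: float, sigma2: float,
    W: np.ndarray, n: int, T: int, names: list[str],
) -> pd.DataFrame:
    """Analytic information matrix for the within SAR/SDM ML estimator."""
    A = np.eye(n) - rho * W
    G = W @ np.linalg.inv(A)
    u = np.empty(len(Z))
    Zd = Z @ delta
    for t in range(T):
        u[t * n : (t + 1) * n] = G @ Zd[t * n : (t + 1) * n]
    k = Z.shape[1]
    dim = k + 2  # delta, rho, sigma2
    info = np.zeros((dim, dim))
    info[:k, :k] = Z.T @ Z / sigma2
    info[:k, k] = Z.T @ u / sigma2
    info[k, :k] = info[:k, k]
    info[k, k] = T * np.trace(G @ G + G.T @ G) + float(u @ u) / sigma2
    info[k, k + 1] = T * np.trace(G) / sigma2
    info[k + 1, k] = info[k, k + 1]
    info[k + 1, k + 1] = n * T / (2 * sigma2**2)
    vc = np.linalg.inv(info)
    all_names = names + ["rho", "sigma2"]
    return pd.DataFrame(vc, index=all_names, columns=all_names)


def _sem_vcov(
    Xs: np.ndarray, lam: float, sigma2: float, W: np.ndarray,
    n: int, T: int, names: list[str],
) -> pd.DataFrame:
    B = np.eye(n) - lam * W
    G = W @ np.linalg.inv(B)
    k = Xs.shape[1]
    dim = k + 2
    info = np.zeros((dim, dim))
    info[:k, :k] = Xs.T @ Xs / sigma2
    info[k, k] = T * np.trace(G @ G + G.T @ G)
    info[k, k + 1] = T * np.trace(G) / sigma2
    info[k + 1, k] = info[k, k + 1]
    info[k + 1, k + 1] = n * T / (2 * sigma2**2)
    vc = np.linalg.inv(info)
    all_names = names + ["lambda", "sigma2"]
    return pd.DataFrame(vc, index=all_names, columns=all_names)


def fit_spatial_panel(
    panel: PanelData,
    w: SpatialWeights,
    model: str = "SDM",
    effects: str = "both",
    constrain_rho: float | None = None,
) -> PanelFit:
    """ML estimation of SAR / SEM / SDM spatial panels.

    ``effects`` selects pooled, unit (``space``), time, two-way (``both``)
    fixed effects, or ``random`` (quasi-demeaned ML, SAR/SDM only).
    ``constrain_rho`` pins the spatial parameter (0 collapses SAR/SDM to the
    within regression).
    """
    model = model.upper()
    if model not in ("SAR", "SEM", "SDM"):
        raise PanelError(f"model must be SAR, SEM or SDM, got {model!r}")
    if effects not in _EFFECTS:
        raise PanelError(f"unknown effects spec {effects!r}")
    W = w.W
    n, T, k = panel.n, panel.T, panel.k
    nobs = n * T
    omega, lo, hi = _eigen_interval(W, w.W0)

    if effects == "random":
        if model == "SEM":
            raise NotImplementedError(
                "random-effects SEM is not supported; run the Hausman "
                "comparison on the SAR/SDM or non-spatial specification"
            )
        # time dummies are kept in the RE specification so that the Hausman
        # comparison against a two-way FE fit contrasts like with like
        return _fit_re(panel, w, model, omega, lo, hi)

    yd = _demean(panel.y, effects)
    Xd = _demean(panel.X, effects)
    names = list(panel.x_names)
    if model == "SDM":
        WXd = _demean(_apply_W(panel.X, W), effects)
        Z = np.column_stack([_stack(Xd), _stack(WXd)])
        names = names + [f"W_{nm}" for nm in panel.x_names]
    else:
        Z = _stack(Xd)
    yv = _stack(yd)
    if effects == "pooled":
        Z = np.column_stack([np.ones(nobs), Z])
        names = ["const"] + names
    _check_rank(Z, names)

    # Effective dimensions of the orthonormal (Helmert-style) within
    # transformations that eliminate the fixed effects exactly: removing
    # unit effects loses one period, removing time effects loses one
    # cross-sectional dimension -- and, with row-standardized W, drops the
    # unit eigenvalue from the Jacobian since |I_n - pW| = (1-p)|I_{n-1} - pW*|.
    # Estimating on this likelihood removes the O(1/n), O(1/T)
    # incidental-parameter biases of the plain demeaned QML.
    Teff = T - 1 if effects in ("space", "both") else T
    drop_unit_eig = effects in ("time", "both")
    if drop_unit_eig:
        omega_eff = np.delete(omega, int(np.argmin(np.abs(omega - 1.0))))
    else:
        omega_eff = omega
    neff = (n - 1 if drop_unit_eig else n) * Teff

    if model in ("SAR", "SDM"):
        Wyv = _stack(_demean(_apply_W(panel.y, W), effects))
        ZtZ_inv = np.linalg.inv(Z.T @ Z)
        b0 = ZtZ_inv @ (Z.T @ yv)
        b1 = ZtZ_inv @ (Z.T @ Wyv)
        e0 = yv - Z @ b0
        e1 = Wyv - Z @ b1
        a_, b_, c_ = float(e0 @ e0), float(e0 @ e1), float(e1 @ e1)

        def neg_conc(rho: float) -> float:
            # bias-corrected (transformed-data) concentrated likelihood
            rss = a_ - 2 * b_ * rho + c_ * rho**2
            logdet = np.sum(np.log(1.0 - rho * omega_eff))
            return 0.5 * neff * np.log(rss / neff) - Teff * logdet

        def neg_direct(rho: float) -> float:
            # plain demeaned QML, the common scale for LR comparisons
            rss = a_ - 2 * b_ * rho + c_ * rho**2
            return 0.5 * nobs * np.log(rss / nobs) - T * np.sum(
                np.log(1.0 - rho * omega)
            )

        if constrain_rho is not None:
            rho_hat, boundary = float(constrain_rho), False
            rho_direct = rho_hat
        else:
            rho_hat, _res = _opt_scalar(neg_conc, lo, hi)
            rho_direct, _ = _opt_scalar(neg_direct, lo, hi)
            boundary = min(rho_hat - lo, hi - rho_hat) < 1e-4
        delta = b0 - rho_hat * b1
        e = e0 - rho_hat * e1
        sigma2_ml = float(e @ e / nobs)
        sigma2 = float(e @ e / max(neff - Z.shape[1], 1))
        rss_d = a_ - 2 * b_ * rho_direct + c_ * rho_direct**2
        loglik = (
            -0.5 * nobs * (np.log(2 * np.pi) + np.log(rss_d / nobs) + 1.0)
            + T * np.sum(np.log(1.0 - rho_direct * omega))
        )
        # df-corrected sigma2 in the information matrix compensates the
        # incidental-parameter shrinkage of the within ML variance
        vcov = _sar_sdm_vcov(Z, delta, rho_hat, sigma2, W, n, T, names)
        beta = pd.Series(delta[: k + (effects == "pooled")],
                         index=names[: k + (effects == "pooled")])
        theta = None
        if model == "SDM":
            theta = pd.Series(delta[-k:], index=names[-k:])
        resid_raw = panel.y - rho_hat * _apply_W(panel.y, W) - np.einsum(
            "ntk,k->nt", panel.X, beta[list(panel.x_names)].to_numpy()
        )
        if theta is not None:
            resid_raw -= np.einsum(
                "ntk,k->nt", _apply_W(panel.X, W), theta.to_numpy()
            )
        fe_unit, fe_time = _recover_fe(panel, resid_raw, effects)
        fit = PanelFit(
            model=model, effects=effects, beta=beta, theta=theta,
            rho=rho_hat, sigma2=sigma2, sigma2_ml=sigma2_ml, loglik=loglik,
            nobs=nobs, n=n, T=T, vcov=vcov, boundary=boundary,
            fe_unit=fe_unit, fe_time=fe_time, x_names=panel.x_names,
        )
        fit._cache.update({"e": e, "Z": Z, "names": names, "neg_conc": neg_conc})
        return fit

    # --- SEM ---------------------------------------------------------------
    ym = yd  # (n, T)
    Xm = Xd  # (n, T, k)

    def sem_pieces(lam: float):
        ystar = _stack(ym - lam * _apply_W(ym, W))
        Xstar = _stack(Xm - lam * _apply_W(Xm, W))
        if effects == "pooled":
            ones = np.ones((n, T))
            const_star = _stack(ones - lam * _apply_W(ones, W))
            Xstar = np.column_stack([const_star, Xstar])
        bhat, *_ = np.linalg.lstsq(Xstar, ystar, rcond=None)
        e = ystar - Xstar @ bhat
        return bhat, e, Xstar

    def neg_conc_sem(lam: float) -> float:
        _, e, _ = sem_pieces(lam)
        logdet = np.sum(np.log(1.0 - lam * omega_eff))
        return 0.5 * neff * np.log(float(e @ e) / neff) - Teff * logdet

    def neg_direct_sem(lam: float) -> float:
        _, e, _ = sem_pieces(lam)
        return 0.5 * nobs * np.log(float(e @ e) / nobs) - T * np.sum(
            np.log(1.0 - lam * omega)
        )

    lam_hat, _res = _opt_scalar(neg_conc_sem, lo, hi)
    lam_direct, _ = _opt_scalar(neg_direct_sem, lo, hi)
    boundary = min(lam_hat - lo, hi - lam_hat) < 1e-4
    bhat, e, Xstar = sem_pieces(lam_hat)
    sigma2_ml = float(e @ e / nobs)
    sigma2 = float(e @ e / max(neff - Xstar.shape[1], 1))
    _, e_d, _ = sem_pieces(lam_direct)
    loglik = (
        -0.5 * nobs * (np.log(2 * np.pi) + np.log(float(e_d @ e_d) / nobs) + 1.0)
        + T * np.sum(np.log(1.0 - lam_direct * omega))
    )
    vcov = _sem_vcov(Xstar, lam_hat, sigma2, W, n, T, names)
    beta = pd.Series(bhat, index=names)
    resid_raw = panel.y - np.einsum(
        "ntk,k->nt", panel.X, beta[list(panel.x_names)].to_numpy()
    )
    if "const" in beta.index:
        resid_raw = resid_raw - beta["const"]
    fe_unit, fe_time = _recover_fe(panel, resid_raw, effects)
    fit = PanelFit(
        model="SEM", effects=effects, beta=beta, lam=lam_hat,
        sigma2=sigma2, sigma2_ml=sigma2_ml, loglik=loglik, nobs=nobs,
        n=n, T=T, vcov=vcov, boundary=boundary,
        fe_unit=fe_unit, fe_time=fe_time, x_names=panel.x_names,
    )
    fit._cache.update({"e": e, "Z": Xstar, "names": names, "neg_conc": neg_conc_sem})
    return fit


def _fit_re(panel, w, model, omega, lo, hi) -> PanelFit:
    """Random-effects SAR/SDM by ML with quasi-demeaning weight phi profiled
    jointly with rho; phi = sigma_e / sqrt(T sigma_mu^2 + sigma_e^2)."""
    W = w.W
    n, T, k = panel.n, panel.T, panel.k
    nobs = n * T
    names = list(panel.x_names)
    Xall = panel.X
    if model == "SDM":
        Xall = np.concatenate([panel.X, _apply_W(panel.X, W)], axis=2)
        names = names + [f"W_{nm}" for nm in panel.x_names]
    Wy = _apply_W(panel.y, W)
    ones = np.ones((n, T))
    # time dummies (first period is the base) stay in the RE specification,
    # matching the two-way FE fits it is compared against
    dummies = np.zeros((n, T, T - 1))
    for t in range(1, T):
        dummies[:, t, t - 1] = 1.0
    dummy_names = [f"t_{panel.times[t]}" for t in range(1, T)]

    def qd(arr, phi):
        return arr - (1.0 - phi) * arr.mean(axis=1, keepdims=True)

    def design(phi):
        return np.column_stack(
            [_stack(qd(ones, phi)), _stack(qd(dummies, phi)), _stack(qd(Xall, phi))]
        )

    def neg_loglik(p):
        rho, phi = p
        ys = _stack(qd(panel.y, phi) - rho * qd(Wy, phi))
        Zs = design(phi)
        bhat, *_ = np.linalg.lstsq(Zs, ys, rcond=None)
        e = ys - Zs @ bhat
        rss = float(e @ e)
        logdet = np.sum(np.log(1.0 - rho * omega))
        return 0.5 * nobs * np.log(rss / nobs) - T * logdet - n * np.log(phi)

    # coarse grid then bounded quasi-Newton
    best, bestval = None, np.inf
    for rho0 in np.linspace(lo + 0.05, hi - 0.05, 9):
        for phi0 in (0.2, 0.5, 0.8):
            v = neg_loglik((rho0, phi0))
            if v < bestval:
                best, bestval = (rho0, phi0), v
    res = optimize.minimize(
        neg_loglik, best, method="L-BFGS-B",
        bounds=[(lo, hi), (1e-4, 1.0)],
    )
    if not res.success:
        raise ConvergenceError(f"RE optimization failed: {res.message}")
    rho_hat, phi_hat = res.x
    ys = _stack(qd(panel.y, phi_hat) - rho_hat * qd(Wy, phi_hat))
    Zs = design(phi_hat)
    all_names = ["const"] + dummy_names + names
    bhat, *_ = np.linalg.lstsq(Zs, ys, rcond=None)
    e = ys - Zs @ bhat
    sigma2_ml = float(e @ e / nobs)
    loglik = (
        -0.5 * nobs * (np.log(2 * np.pi) + np.log(sigma2_ml) + 1.0)
        + T * np.sum(np.log(1.0 - rho_hat * omega))
        + n * np.log(phi_hat)
    )

    # numerical Hessian of the full likelihood in (b, rho, log phi, log s2)
    def full_nll(p):
        b = p[: len(all_names)]
        rho = p[len(all_names)]
        phi = np.exp(p[len(all_names) + 1])
        s2 = np.exp(p[len(all_names) + 2])
        if not (lo < rho < hi) or not (0 < phi <= 1.0):
            return np.inf
        ys_ = _stack(qd(panel.y, phi) - rho * qd(Wy, phi))
        e_ = ys_ - design(phi) @ b
        logdet = np.sum(np.log(1.0 - rho * omega))
        return (
            0.5 * nobs * np.log(2 * np.pi * s2)
            + float(e_ @ e_) / (2 * s2)
            - T * logdet
            - n * np.log(phi)
        )

    p0 = np.concatenate([bhat, [rho_hat, np.log(phi_hat), np.log(sigma2_ml)]])
    H = _num_hessian(full_nll, p0)
    vc = np.linalg.pinv(H)
    vc_names = all_names + ["rho", "log_phi", "log_sigma2"]
    vcov = pd.DataFrame(vc, index=vc_names, columns=vc_names)

    n_base = 1 + (T - 1) + k  # const, time dummies, covariates
    beta = pd.Series(bhat[:n_base], index=all_names[:n_base])
    theta = None
    if model == "SDM":
        theta = pd.Series(bhat[n_base:], index=all_names[n_base:])
    fit = PanelFit(
        model=model, effects="random", beta=beta, theta=theta, rho=float(rho_hat),
        sigma2=sigma2_ml * nobs / max(nobs - len(all_names), 1), sigma2_ml=sigma2_ml,
        loglik=float(loglik), nobs=nobs, n=n, T=T, vcov=vcov,
        phi=float(phi_hat), converged=bool(res.success), x_names=panel.x_names,
    )
    fit._cache.update({"e": e, "Z": Zs, "names": all_names})
    return fit


def _num_hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; steps scaled by parameter magnitude."""
    m = len(x0)
    h = rel_step * np.maximum(np.abs(x0), 1.0)
    H = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# Specification tests
# ---------------------------------------------------------------------------

def wald_reduction_tests(sdm: PanelFit, alpha: float = 0.1) -> dict[str, TestResult]:
    """Wald tests of the SDM reductions: theta = 0 (to SAR) and the
    common-factor restriction theta + rho*beta = 0 (to SEM)."""
    if sdm.model != "SDM" or sdm.theta is None or sdm.vcov is None:
        raise PanelError("wald_reduction_tests needs a converged SDM fit with vcov")
    k = len(sdm.x_names)
    th_names = list(sdm.theta.index)
    b_names = [nm for nm in sdm.beta.index if nm != "const"]
    theta = sdm.theta.to_numpy()
    beta = sdm.beta[b_names].to_numpy()
    rho = sdm.rho

    Vtt = sdm.vcov.loc[th_names, th_names].to_numpy()
    note = ""
    try:
        Vtt_inv = np.linalg.inv(Vtt)
    except np.linalg.LinAlgError:
        Vtt_inv = np.linalg.pinv(Vtt)
        note = "singular restriction covariance; pseudo-inverse used"
    w_sar = float(theta @ Vtt_inv @ theta)
    out = {
        "Wald SDM->SAR": TestResult(
            "Wald SDM->SAR", max(w_sar, 0.0), k,
            float(stats.chi2.sf(max(w_sar, 0.0), k)), alpha, note,
        )
    }

    # delta method on g = theta + rho*beta over (beta, theta, rho)
    pnames = b_names + th_names + ["rho"]
    V = sdm.vcov.loc[pnames, pnames].to_numpy()
    Jac = np.zeros((k, 2 * k + 1))
    Jac[:, :k] = rho * np.eye(k)
    Jac[:, k : 2 * k] = np.eye(k)
    Jac[:, 2 * k] = beta
    g = theta + rho * beta
    Vg = Jac @ V @ Jac.T
    note = ""
    try:
        Vg_inv = np.linalg.inv(Vg)
    except np.linalg.LinAlgError:
        Vg_inv = np.linalg.pinv(Vg)
        note = "singular restriction covariance; pseudo-inverse used"
    w_sem = float(g @ Vg_inv @ g)
    out["Wald SDM->SEM"] = TestResult(
        "Wald SDM->SEM", max(w_sem, 0.0), k,
        float(stats.chi2.sf(max(w_sem, 0.0), k)), alpha, note,
    )
    return out


def lr_test(restricted: PanelFit, full: PanelFit, df: int,
            name: str = "LR", alpha: float = 0.1) -> TestResult:
    """Likelihood-ratio test of a nested restriction."""
    diff = full.loglik - restricted.loglik
    if diff < -1e-6:
        raise PanelError(
            f"restricted loglik ({restricted.loglik:.6f}) exceeds full "
            f"({full.loglik:.6f}): models not nested or optimizer failed"
        )
    lr = max(2.0 * diff, 0.0)
    return TestResult(name, lr, df, float(stats.chi2.sf(lr, df)), alpha)


def hausman_test(fe: PanelFit, re: PanelFit, alpha: float = 0.1) -> TestResult:
    """Hausman FE-vs-RE comparison on the common slope coefficients
    (beta and, for SDM, theta; spatial rho excluded)."""
    common = [
        nm for nm in fe.params.index
        if nm in re.params.index and nm not in ("rho", "lambda", "const")
    ]
    if not common:
        raise PanelError("no common slope coefficients between FE and RE fits")
    if fe.vcov is None or re.vcov is None:
        raise PanelError("both fits need vcov for the Hausman test")
    d = fe.params[common].to_numpy() - re.params[common].to_numpy()
    Vd = (
        fe.vcov.loc[common, common].to_numpy()
        - re.vcov.loc[common, common].to_numpy()
    )
    note = ""
    try:
        eigs = np.linalg.eigvalsh((Vd + Vd.T) / 2)
        if eigs.min() <= 0:
            raise np.linalg.LinAlgError
        Vd_inv = np.linalg.inv(Vd)
    except np.linalg.LinAlgError:
        Vd_inv = np.linalg.pinv((Vd + Vd.T) / 2)
        note = "covariance difference not positive definite; pseudo-inverse used"
    H = float(d @ Vd_inv @ d)
    H = max(H, 0.0)
    df = len(common)
    return TestResult("Hausman", H, df, float(stats.chi2.sf(H, df)), alpha, note)


# ---------------------------------------------------------------------------
# Effects decomposition (LeSage-Pace partial derivatives)
# ---------------------------------------------------------------------------

def decompose_effects(
    fit: PanelFit,
    w: SpatialWeights,
    n_draws: int = 1000,
    seed: int | None = None,
) -> EffectsResult:
    """Direct / indirect / total covariate effects through the spatial
    multiplier.

    For covariate k, ``S_k(W) = (I - rho W)^{-1} (I beta_k + W theta_k)``;
    the direct effect is the mean diagonal of ``S_k``, the total effect the
    mean row sum, and the indirect (spillover) effect their difference.
    Inference simulates (rho, beta, theta) from the fit's asymptotic normal
    and summarizes the decomposition per draw.
    """
    if fit.model not in ("SAR", "SDM"):
        raise PanelError("effects decomposition applies to SAR/SDM fits")
    if fit.rho is None or abs(fit.rho) >= 1:
        raise PanelError("need a converged fit with |rho| < 1")
    if seed is None:
        raise ValueError("decompose_effects requires a seed")
    W = w.W
    n = w.n
    x_names = list(fit.x_names)
    k = len(x_names)
    beta = fit.beta[x_names].to_numpy()
    theta = (
        fit.theta.to_numpy() if fit.theta is not None else np.zeros(k)
    )

    def point(rho_v, b_v, t_v):
        A_inv = np.linalg.inv(np.eye(n) - rho_v * W)
        direct = np.empty(k)
        total = np.empty(k)
        for j in range(k):
            Sk = A_inv * b_v[j] + (A_inv @ W) * t_v[j]
            direct[j] = np.trace(Sk) / n
            total[j] = Sk.sum() / n
        return direct, total

    direct, total = point(fit.rho, beta, theta)
    indirect = total - direct

    # simulate parameter uncertainty
    th_names = list(fit.theta.index) if fit.theta is not None else []
    pnames = x_names + th_names + ["rho"]
    if fit.vcov is None or not set(pnames) <= set(fit.vcov.index):
        raise PanelError("fit vcov does not cover (beta, theta, rho)")
    mean = np.concatenate([beta, theta[: len(th_names)], [fit.rho]])
    V = fit.vcov.loc[pnames, pnames].to_numpy()
    V = (V + V.T) / 2
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, V, size=n_draws, method="svd")
    d_mat = np.empty((n_draws, k))
    t_mat = np.empty((n_draws, k))
    for m in range(n_draws):
        b_v = draws[m, :k]
        t_v = draws[m, k : k + len(th_names)] if th_names else np.zeros(k)
        rho_v = np.clip(draws[m, -1], -0.9999, 0.9999)
        d_m, tt_m = point(rho_v, b_v, t_v)
        d_mat[m] = d_m
        t_mat[m] = tt_m
    i_mat = t_mat - d_mat

    def summarize(mat):
        se = mat.std(axis=0, ddof=1)
        zstat = mat.mean(axis=0) / se
        p = 2 * stats.norm.sf(np.abs(zstat))
        lo = np.percentile(mat, 2.5, axis=0)
        hi = np.percentile(mat, 97.5, axis=0)
        return se, p, (lo, hi)

    d_se, d_p, d_ci = summarize(d_mat)
    i_se, i_p, i_ci = summarize(i_mat)
    t_se, t_p, t_ci = summarize(t_mat)
    return EffectsResult(
        x_names=tuple(x_names),
        direct=direct, indirect=indirect, total=total,
        direct_se=d_se, indirect_se=i_se, total_se=t_se,
        direct_p=d_p, indirect_p=i_p, total_p=t_p,
        ci={"direct": d_ci, "indirect": i_ci, "total": t_ci},
        n_draws=n_draws, seed=seed,
    )


# ---------------------------------------------------------------------------
# Multicollinearity diagnostics
# ---------------------------------------------------------------------------

def vif(X: np.ndarray | pd.DataFrame, names: Sequence[str] | None = None) -> pd.DataFrame:
    """Variance inflation factors: VIF_k = 1/(1 - R^2_k), R^2_k from
    regressing column k on the others with intercept.  Perfectly collinear
    columns get infinite VIF and a diagnostic flag."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if names is None:
            names = [f"x{j + 1}" for j in range(X.shape[1])]
    if X.ndim == 3:  # panel covariates: pool over unit-time
        X = X.reshape(-1, X.shape[2])
    if X.shape[1] < 2:
        raise PanelError("VIF needs at least 2 covariates")
    rows = []
    for j in range(X.shape[1]):
        target = X[:, j]
        others = np.column_stack(
            [np.ones(len(X))] + [X[:, c] for c in range(X.shape[1]) if c != j]
        )
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        tss = float(np.sum((target - target.mean()) ** 2))
        if tss == 0:
            raise PanelError(f"constant covariate {names[j]!r}")
        r2 = 1.0 - float(resid @ resid) / tss
        if r2 >= 1.0 - 1e-12:
            rows.append({"variable": names[j], "r_squared": 1.0,
                         "vif": np.inf, "collinear": True})
        else:
            rows.append({"variable": names[j], "r_squared": r2,
                         "vif": 1.0 / (1.0 - r2), "collinear": False})
    return pd.DataFrame(rows)
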