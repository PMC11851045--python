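"""Global and local Moran's I with analytic and permutation inference.

Global Moran's I for an attribute vector ``x`` over ``n`` regions with
weights ``w_ij``:

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   z = x - mean(x)

with ``S0 = sum_ij w_ij``.  Its null expectation is ``-1/(n-1)``; analytic
z-scores use either the normality- or randomization-assumption variance, and
a permutation test gives the pseudo p-value

    p = (1 + #{|I_perm - E[I]| >= |I_obs - E[I]|}) / (n_perm + 1).

The local statistic ``I_i = (z_i / m2) * sum_j w_ij z_j`` (``m2 = sum z^2/n``)
decomposes the global one: ``sum_i I_i = S0 * I``.  Each unit is classified
into the Moran-scatterplot quadrant — HH or LL clusters, HL or LH outliers —
by the signs of its own deviation and of its spatial lag; significance comes
from conditional permutation (unit i's value held fixed, all others permuted
over the remaining positions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .weights import SpatialWeights

__all__ = ["MoranGlobalResult", "LisaResult", "global_moran", "local_moran", "classify_clusters"]


class DegenerateInputError(ValueError):
    """Attribute vector has no variance (Moran's I undefined)."""


@dataclass(frozen=True)
class MoranGlobalResult:
    I: float
    expected_I: float
    z: float
    p_analytic: float
    variance: float
    inference: str
    p_perm: float | None = None
    n_perm: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class LisaResult:
    region_ids: tuple[str, ...]
    Ii: np.ndarray
    z_values: np.ndarray  # standardized attribute (z-score)
    lag: np.ndarray  # spatial lag of the standardized attribute
    quadrant: tuple[str, ...]  # HH / LL / HL / LH per unit
    p_perm: np.ndarray
    significant: np.ndarray  # bool, at alpha
    alpha: float
    n_perm: int
    seed: int
    tied_zero: tuple[str, ...] = ()  # units with z_i == 0 (tie rule applied)


def _validate(x: np.ndarray, w: SpatialWeights) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (w.n,):
        raise ValueError(f"attribute length {x.shape} != n regions ({w.n})")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant attribute vector: Moran's I undefined")
    return x


def _moran_stat(z: np.ndarray, W: np.ndarray, S0: float) -> float:
    n = z.size
    return float(n / S0 * (z @ W @ z) / (z @ z))


def _analytic_variance(z: np.ndarray, W: np.ndarray, assumption: str) -> float:
    # Cliff-Ord moments of I under the normality / randomization null
    n = z.size
    S0 = W.sum()
    S1 = 0.5 * np.sum((W + W.T) ** 2)
    S2 = np.sum((W.sum(axis=1) + W.sum(axis=0)) ** 2)
    EI = -1.0 / (n - 1)
    if assumption == "normality":
        var = (n * n * S1 - n * S2 + 3 * S0 * S0) / (S0 * S0 * (n * n - 1)) - EI * EI
    else:  # randomization
        m2 = np.sum(z**2) / n
        m4 = np.sum(z**4) / n
        b2 = m4 / (m2 * m2)
        num = n * ((n * n - 3 * n + 3) * S1 - n * S2 + 3 * S0 * S0) - b2 * (
            (n * n - n) * S1 - 2 * n * S2 + 6 * S0 * S0
        )
        var = num / ((n - 1) * (n - 2) * (n - 3) * S0 * S0) - EI * EI
    return float(var)


def global_moran(
    x: np.ndarray,
    w: SpatialWeights,
    inference: str = "analytic_randomization",
    n_perm: int = 999,
    seed: int | None = None,
    binary: bool = False,
) -> MoranGlobalResult:
    """Global Moran's I with the chosen inference mode.

    ``inference`` is one of ``analytic_randomization`` (default, Cliff-Ord
    randomization variance), ``analytic_normality``, or ``permutation``
    (which also reports the analytic randomization z alongside the pseudo p).
    """
    x = _validate(x, w)
    W = w.matrix(binary=binary)
    S0 = W.sum()
    z = x - x.mean()
    I_obs = _moran_stat(z, W, S0)
    n = w.n
    EI = -1.0 / (n - 1)

    assumption = "normality" if inference == "analytic_normality" else "randomization"
    var = _analytic_variance(z, W, assumption)
    zscore = (I_obs - EI) / np.sqrt(var)
    p_analytic = float(2 * stats.norm.sf(abs(zscore)))

    p_perm = None
    if inference == "permutation":
        if seed is None:
            raise ValueError("permutation inference requires a seed")
        rng = np.random.default_rng(seed)
        # all permutations share z's values; build a (n_perm, n) matrix
        perms = z[np.argsort(rng.random((n_perm, n)), axis=1)]
        I_perm = n / S0 * np.einsum("pi,pi->p", perms, perms @ W.T) / (z @ z)
        exceed = np.sum(np.abs(I_perm - EI) >= np.abs(I_obs - EI) - 1e-14)
        p_perm = float((1 + exceed) / (n_perm + 1))
    elif inference not in ("analytic_randomization", "analytic_normality"):
        raise ValueError(f"unknown inference mode {inference!r}")

    return MoranGlobalResult(
        I=I_obs,
        expected_I=EI,
        z=float(zscore),
        p_analytic=p_analytic,
        variance=var,
        inference=inference,
        p_perm=p_perm,
        n_perm=n_perm if inference == "permutation" else None,
        seed=seed,
    )


def _quadrant(zi: float, lagi: float) -> tuple[str, bool]:
    """Moran-scatterplot quadrant; ties at z_i == 0 default the own-axis to L
    and are flagged (measure-zero under continuous attributes)."""
    if zi == 0:
        return ("LH" if lagi > 0 else "LL"), True
    own = "H" if zi > 0 else "L"
    nbr = "H" if lagi > 0 else "L"
    return own + nbr, False


def local_moran(
    x: np.ndarray,
    w: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    binary: bool = False,
) -> LisaResult:
    """Local Moran's I with conditional-permutation pseudo p-values.

    Every unit receives a quadrant label; non-significant units are flagged,
    never dropped.
    """
    x = _validate(x, w)
    if seed is None:
        raise ValueError("local_moran requires a seed for the permutation test")
    W = w.matrix(binary=binary)
    n = w.n
    z = x - x.mean()
    m2 = np.sum(z**2) / n
    lag = W @ z
    Ii = z / m2 * lag

    sd = np.sqrt(np.sum(z**2) / n)
    zstd = z / sd
    lag_std = W @ zstd

    rng = np.random.default_rng(seed)
    p_perm = np.empty(n)
    for i in range(n):
        others = np.delete(z, i)
        wi = np.delete(W[i], i)
        nz = np.flatnonzero(wi)
        # conditional permutation: draw neighbors' values from the other n-1
        idx = np.argsort(rng.random((n_perm, others.size)), axis=1)[:, : nz.size]
        lag_perm = others[idx] @ wi[nz]
        Ii_perm = z[i] / m2 * lag_perm
        exceed = np.sum(np.abs(Ii_perm) >= abs(Ii[i]) - 1e-14)
        p_perm[i] = (1 + exceed) / (n_perm + 1)

    quadrants, tied = [], []
    for i in range(n):
        q, was_tied = _quadrant(z[i], lag[i])
        quadrants.append(q)
        if was_tied:
            tied.append(w.regions.ids[i])

    return LisaResult(
        region_ids=w.regions.ids,
        Ii=Ii,
        z_values=zstd,
        lag=lag_std,
        quadrant=tuple(quadrants),
        p_perm=p_perm,
        significant=p_perm <= alpha,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
        tied_zero=tuple(tied),
    )


def classify_clusters(lisa: LisaResult, alpha: float | None = None) -> pd.DataFrame:
    """Per-unit cluster table; filter on ``significant`` for a Table-2-style
    view listing only significant cluster/outlier units."""
    alpha = lisa.alpha if alpha is None else alpha
    return pd.DataFrame(
        {
            "unit_id": lisa.region_ids,
            "Ii": lisa.Ii,
            "quadrant": lisa.quadrant,
            "p_perm": lisa.p_perm,
            "significant": lisa.p_perm <= alpha,
        }
    )
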