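"""Temporal analysis of regional search-volume series.

Two transforms live here.  ``dbi_to_pbi`` converts a raw search-volume index
(daily-average index per unit-year) into a per-capita index by dividing by
year-end population.  The concentration statistics measure how unevenly a
year's search volume spreads over its 12 months: with monthly shares
``r_1..r_12`` (summing to 1),

    R = sqrt( sum_i (r_i - 1/12)^2 )          # Euclidean deviation from uniform
    M = R / sqrt(11/12)                        # rescaled to [0, 1]

``M`` is 0 exactly at the uniform distribution and 1 exactly when all volume
falls in a single month; values below 0.3 are conventionally read as a
relatively uniform within-year distribution, larger values as seasonal
aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MonthlySeries",
    "ConcentrationResult",
    "dbi_to_pbi",
    "monthly_shares",
    "concentration",
    "annual_summary",
    "UNIFORMITY_THRESHOLD",
]

UNIFORMITY_THRESHOLD = 0.3
_M_NORM = np.sqrt(11.0 / 12.0)  # R at full single-month concentration


class TemporalError(ValueError):
    pass


@dataclass(frozen=True)
class MonthlySeries:
    """Twelve monthly search-volume totals for one calendar year."""

    year: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (12,):
            raise TemporalError(f"need exactly 12 monthly counts, got {c.shape}")
        if np.any(c < 0):
            raise TemporalError("monthly counts must be non-negative")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class ConcentrationResult:
    year: int | None
    r: np.ndarray  # 12 monthly shares
    R: float  # dispersion, >= 0
    M: float  # concentration in [0, 1]
    label: str  # "uniform" if M < threshold else "aggregated"
    threshold: float = UNIFORMITY_THRESHOLD


def dbi_to_pbi(dbi, population):
    """Per-capita index: search index divided by year-end population.

    Vectorized; pandas inputs keep their index.  Any non-positive or missing
    population is an error (the ratio would be meaningless).
    """
    dbi_a = np.asarray(dbi, dtype=float)
    pop_a = np.asarray(population, dtype=float)
    if np.any(np.isnan(pop_a)):
        raise TemporalError("missing population value(s)")
    if np.any(pop_a <= 0):
        raise TemporalError("population must be positive")
    if np.any(np.isnan(dbi_a)) or np.any(dbi_a < 0):
        raise TemporalError("search index must be non-negative and non-missing")
    out = dbi_a / pop_a
    if isinstance(dbi, pd.Series):
        return pd.Series(out, index=dbi.index, name="pbi")
    if np.ndim(dbi) == 0:
        return float(out)
    return out


def monthly_shares(series: MonthlySeries) -> np.ndarray:
    total = series.counts.sum()
    if total <= 0:
        raise TemporalError(f"year {series.year}: all-zero monthly counts")
    return series.counts / total


def concentration(
    r: np.ndarray,
    year: int | None = None,
    threshold: float = UNIFORMITY_THRESHOLD,
) -> ConcentrationResult:
    """Dispersion R and concentration M of a vector of 12 monthly shares."""
    r = np.asarray(r, dtype=float)
    if r.shape != (12,):
        raise TemporalError("shares must have length 12")
    if abs(r.sum() - 1.0) > 1e-8 or np.any(r < 0):
        raise TemporalError("shares must be non-negative and sum to 1")
    R = float(np.sqrt(np.sum((r - 1.0 / 12.0) ** 2)))
    M = R / _M_NORM
    # clip the inevitable last-ulp overshoot at full concentration
    M = float(min(max(M, 0.0), 1.0))
    label = "uniform" if M < threshold else "aggregated"
    return ConcentrationResult(year=year, r=r, R=R, M=M, label=label, threshold=threshold)


def _peak_months(r: np.ndarray, k: int = 3) -> list[int]:
    # top-k months by share; ties broken by calendar order (stable sort)
    order = np.argsort(-r, kind="stable")
    return [int(m) + 1 for m in order[:k]]


def annual_summary(
    records: pd.DataFrame,
    threshold: float = UNIFORMITY_THRESHOLD,
) -> pd.DataFrame:
    """Per-year index level and concentration from long monthly records.

    ``records`` needs columns ``year``, ``month``, ``dbi`` (a ``unit_id``
    column, if present, is summed out first — concentration is a property of
    the aggregate series).  Years with missing months are excluded with a
    warning rather than silently averaged.

    Returns a tidy table: year, mean_dbi, R, M, label, peak_months.
    """
    required = {"year", "month", "dbi"}
    if not required <= set(records.columns):
        raise TemporalError(f"records must have columns {sorted(required)}")
    agg = records.groupby(["year", "month"], as_index=False)["dbi"].sum()
    rows = []
    for year, grp in agg.groupby("year"):
        months = set(grp["month"].astype(int))
        if months != set(range(1, 13)):
            warnings.warn(
                f"year {year}: incomplete months {sorted(months)}; excluded",
                stacklevel=2,
            )
            continue
        counts = (
            grp.set_index(grp["month"].astype(int))["dbi"]
            .reindex(range(1, 13))
            .to_numpy(dtype=float)
        )
        series = MonthlySeries(int(year), counts)
        res = concentration(monthly_shares(series), year=int(year), threshold=threshold)
        rows.append(
            {
                "year": int(year),
                "mean_dbi": float(counts.mean()),
                "R": res.R,
                "M": res.M,
                "label": res.label,
                "peak_months": _peak_months(res.r),
            }
        )
    return pd.DataFrame(rows, columns=["year", "mean_dbi", "R", "M", "label", "peak_months"])
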