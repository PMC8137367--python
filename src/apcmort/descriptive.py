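"""Crude and directly age-standardized perinatal mortality rates.

The crude rate for a cell is 1000 * deaths / (births + deaths).  Direct
standardization averages the age-specific rates of each worker type and
period with a fixed set of age weights: the combined (both worker types)
exposure distribution over age in a reference year (1995 by default), i.e.
the "total population" age structure of the standard year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CountsTable

__all__ = [
    "crude_rate",
    "standard_weights",
    "age_standardized_rate",
    "rate_table",
    "RateTable",
]


def crude_rate(deaths, births):
    """Perinatal deaths per 1,000 of (births + deaths).  Vectorized.

    Raises on any cell with zero exposure (rate undefined there).
    """
    d = np.asarray(deaths, dtype=float)
    b = np.asarray(births, dtype=float)
    n = d + b
    if np.any(n <= 0):
        raise ValueError("rate undefined where births + deaths == 0")
    out = 1000.0 * d / n
    return out if out.ndim else float(out)


def standard_weights(t: CountsTable, ref_year: int = 1995) -> np.ndarray:
    """Standard-population age weights: combined exposure shares in ref_year."""
    if ref_year not in t.years:
        raise ValueError(f"reference year {ref_year} not in table years {t.years}")
    ip = t.years.index(ref_year)
    totals = t.exposure[:, :, ip].sum(axis=0).astype(float)
    return totals / totals.sum()


def age_standardized_rate(rates_by_age, weights) -> float:
    """Weighted average of age-specific rates under the standard population."""
    r = np.asarray(rates_by_age, dtype=float)
    w = np.asarray(weights, dtype=float)
    if r.shape[-1] != w.shape[0]:
        raise ValueError(f"{r.shape[-1]} rates vs {w.shape[0]} weights")
    return (r * w).sum(axis=-1)


@dataclass(frozen=True)
class RateTable:
    """Crude rates per cell and standardized rates per worker type x period."""

    rates: np.ndarray      # (workers, ages, periods), per 1,000
    std_rates: np.ndarray  # (workers, periods), per 1,000
    age_labels: tuple[str, ...]
    years: tuple[int, ...]
    worker_types: tuple[str, ...]

    def to_frame(self, decimals: int | None = 1) -> pd.DataFrame:
        """Wide layout: one row per worker type and year, ages as columns
        plus the age-standardized column.  ``decimals=None`` disables
        rounding (rates are always computed unrounded)."""
        rows = []
        for iw, w in enumerate(self.worker_types):
            for ip, y in enumerate(self.years):
                vals = list(self.rates[iw, :, ip]) + [self.std_rates[iw, ip]]
                if decimals is not None:
                    vals = [round(v, decimals) for v in vals]
                rows.append([w, y] + vals)
        cols = ["worker_type", "year", *self.age_labels, "age_standardized"]
        return pd.DataFrame(rows, columns=cols)


def rate_table(t: CountsTable, ref_year: int = 1995) -> RateTable:
    """All crude rates plus the standardized rate for every worker x period.

    Standardization is applied to the unrounded age-specific rates; rounding
    happens only at display time in :meth:`RateTable.to_frame`.
    """
    rates = crude_rate(t.deaths, t.births)
    w = standard_weights(t, ref_year=ref_year)
    std = age_standardized_rate(np.moveaxis(rates, 1, -1), w)
    return RateTable(rates=rates, std_rates=std, age_labels=t.age_labels,
                     years=t.years, worker_types=t.worker_types)
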