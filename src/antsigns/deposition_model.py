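"""Passive-deposition noise model.

If every ant passively rubs off chemicals onto the floor of the chamber it
occupies, a chamber housing N ants accumulates a total signal T that is the
sum of N i.i.d. per-ant deposits, so E[T] = m_ant * N and the dispersion
around the line obeys sd(N) = sigma_ant * sqrt(N). The module fits both
stages: m_ant from ordinary least squares of T on N, sigma_ant from the
square-root law through the binned residual standard deviations. A
sigma_ant much larger than m_ant indicates that a few ants contribute most
of the signal — evidence against uniform passive shedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BinningError, ParameterError

__all__ = ["DepositionFit", "fit_mean_line", "fit_sqrt_noise", "deposition_report"]

RECORD_COLUMNS = ("n_ants", "total_signal")


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ParameterError(f"records missing column(s) {missing}")
    if (records["n_ants"] < 0).any() or (records["total_signal"] < 0).any():
        raise ParameterError("n_ants and total_signal must be nonnegative")
    return records


@dataclass
class DepositionFit:
    """Bundled two-stage fit of the passive-deposition model."""

    m_ant: float
    intercept: float
    sigma_ant: float
    ratio: float
    bins: pd.DataFrame
    pearson_r: float
    queen_residual_sd: dict | None = None


def fit_mean_line(records: pd.DataFrame, force_origin: bool = False) -> tuple:
    """OLS slope (m_ant) and intercept of total signal versus mean ant count."""
    records = _validate_records(records)
    n = records["n_ants"].to_numpy(float)
    t = records["total_signal"].to_numpy(float)
    if np.unique(n).size < 2:
        raise ParameterError("need >= 2 distinct ant counts for a line fit")
    if force_origin:
        slope = float(n @ t / (n @ n))
        return slope, 0.0
    slope, intercept = np.polyfit(n, t, 1)
    return float(slope), float(intercept)


def fit_sqrt_noise(
    records: pd.DataFrame,
    line: tuple,
    n_bins: int = 5,
    binning: str = "equal_count",
) -> float:
    """sigma_ant from the square-root residual-noise law.

    Chambers are split into `n_bins` equal-count bins by ant count; the
    residual standard deviation of each bin is regressed (through the
    origin) on the square root of the bin's mean ant count.
    """
    if binning != "equal_count":
        raise ParameterError(f"unknown binning {binning!r}")
    records = _validate_records(records).sort_values("n_ants")
    m, b = line
    n = records["n_ants"].to_numpy(float)
    resid = records["total_signal"].to_numpy(float) - (m * n + b)
    chunks_n = np.array_split(n, n_bins)
    chunks_r = np.array_split(resid, n_bins)
    too_small = [len(c) for c in chunks_n if len(c) < 3]
    if too_small:
        raise BinningError(
            f"{len(too_small)} bin(s) hold fewer than 3 records; use fewer bins"
        )
    mean_n = np.array([c.mean() for c in chunks_n])
    sd = np.array([c.std(ddof=1) for c in chunks_r])
    sqrt_n = np.sqrt(mean_n)
    sigma = float(sd @ sqrt_n / (sqrt_n @ sqrt_n))
    return max(sigma, 0.0)


def deposition_report(
    records: pd.DataFrame,
    force_origin: bool = False,
    n_bins: int = 5,
    queen_threshold: float = 0.5,
) -> DepositionFit:
    """Both fits plus the count/signal correlation and a queen-residual split.

    The queen split compares residual dispersion among chambers where the
    queen spent more versus less than `queen_threshold` of her time; it is
    omitted when the records carry no queen_fraction column (or it is all
    zero).
    """
    records = _validate_records(records)
    m, b = fit_mean_line(records, force_origin=force_origin)
    sigma = fit_sqrt_noise(records, (m, b), n_bins=n_bins)
    n = records["n_ants"].to_numpy(float)
    t = records["total_signal"].to_numpy(float)
    resid = t - (m * n + b)
    r, _ = stats.pearsonr(n, t)

    order = np.argsort(n, kind="stable")
    bins = pd.DataFrame(
        {
            "mean_n": [c.mean() for c in np.array_split(n[order], n_bins)],
            "resid_sd": [c.std(ddof=1) for c in np.array_split(resid[order], n_bins)],
        }
    )

    queen_summary = None
    if "queen_fraction" in records.columns:
        qf = records["queen_fraction"].to_numpy(float)
        if np.nanmax(qf, initial=0.0) > 0:
            high = qf >= queen_threshold
            queen_summary = {
                "high_queen_sd": float(np.std(resid[high], ddof=1)) if high.sum() > 1 else float("nan"),
                "low_queen_sd": float(np.std(resid[~high], ddof=1)) if (~high).sum() > 1 else float("nan"),
                "n_high": int(high.sum()),
                "n_low": int((~high).sum()),
            }
    return DepositionFit(
        m_ant=m,
        intercept=b,
        sigma_ant=sigma,
        ratio=sigma / m if m else float("nan"),
        bins=bins,
        pearson_r=float(r),
        queen_residual_sd=queen_summary,
    )
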