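"""Two-feature chamber representation of GC peak tables.

Each chamber sample is reduced to the total chromatogram area below
(``light``, Dufour's-gland alkanes up to and including heneicosane) and
above (``heavy``, cuticular hydrocarbons) a retention boundary, and each
feature is normalized so that its sum over one experiment's internal
chambers is one; arena samples share the divisor, so they may exceed the
simplex. The module also hosts the compound-redundancy analyses: heavy
subset features, leave-self-out compound/total correlations, and the
brood versus non-brood heavy-intensity contrast.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import PeakTable
from .errors import NormalizationError, ParameterError, SampleSizeError

__all__ = [
    "split_light_heavy",
    "normalize_experiment",
    "make_features",
    "heavy_subset_features",
    "compound_total_correlation",
    "brood_contrast",
]

log = logging.getLogger(__name__)

#: heneicosane (C21) retention in the synthetic tables, minutes
DEFAULT_BOUNDARY_MIN = 21.0

FEATURES = ("light", "heavy")


def _light_mask(frame: pd.DataFrame, boundary: float, include_boundary: bool):
    ret = frame["retention_min"].to_numpy(float)
    return ret <= boundary if include_boundary else ret < boundary


def split_light_heavy(
    peaks: PeakTable,
    boundary: float = DEFAULT_BOUNDARY_MIN,
    include_boundary_in_light: bool = True,
) -> pd.DataFrame:
    """Per-chamber (light_raw, heavy_raw) area sums split at the boundary.

    The boundary peak (heneicosane) belongs to the light section by default.
    light_raw + heavy_raw equals the chamber's total area exactly.
    """
    f = peaks.frame
    ret = f["retention_min"].to_numpy(float)
    if len(f) and not (ret.min() <= boundary <= ret.max()):
        log.warning("boundary %.2f min outside the retention range [%.2f, %.2f]",
                    boundary, ret.min(), ret.max())
    light = _light_mask(f, boundary, include_boundary_in_light)
    out = (
        f.assign(
            light_raw=np.where(light, f["area"], 0.0),
            heavy_raw=np.where(light, 0.0, f["area"]),
        )
        .groupby(["experiment_id", "chamber_id"], as_index=False)[
            ["light_raw", "heavy_raw"]
        ]
        .sum()
    )
    empty = (out["light_raw"] + out["heavy_raw"]) == 0
    if empty.any():
        log.warning("chamber(s) with no signal: %s",
                    list(out.loc[empty, "chamber_id"]))
    return out


def normalize_experiment(features: pd.DataFrame) -> pd.DataFrame:
    """Divide each feature by its sum over the experiment's internal chambers.

    Expects one experiment's rows with columns light_raw, heavy_raw and
    is_internal. Arena (non-internal) rows are scaled by the same divisor and
    are excluded from the sum, so internal *_norm columns sum to one exactly.
    Idempotent on already-normalized internal features.
    """
    if features["experiment_id"].nunique() > 1:
        raise ParameterError("normalize_experiment expects a single experiment")
    out = features.copy()
    internal = out["is_internal"].to_numpy(bool)
    if not internal.any():
        raise NormalizationError("experiment has no internal chamber")
    for feat in FEATURES:
        denom = float(out.loc[internal, f"{feat}_raw"].sum())
        if denom <= 0:
            raise NormalizationError(
                f"internal {feat} sum is zero in experiment "
                f"{out['experiment_id'].iloc[0]!r}"
            )
        out[f"{feat}_norm"] = out[f"{feat}_raw"] / denom
    return out


def make_features(
    peaks: PeakTable,
    roles: pd.DataFrame,
    boundary: float = DEFAULT_BOUNDARY_MIN,
    include_boundary_in_light: bool = True,
) -> pd.DataFrame:
    """Full feature table: split, attach roles, normalize per experiment.

    roles: DataFrame with columns experiment_id, chamber_id, role (arena rows
    marked with role 'arena'). Returns one row per chamber sample with
    light/heavy raw and normalized features, role and is_internal columns.
    """
    raw = split_light_heavy(peaks, boundary, include_boundary_in_light)
    merged = raw.merge(roles, on=["experiment_id", "chamber_id"], how="left")
    if merged["role"].isna().any():
        missing = merged.loc[merged["role"].isna(), ["experiment_id", "chamber_id"]]
        raise ParameterError(f"unlabelled chamber sample(s):\n{missing}")
    merged["is_internal"] = merged["role"] != "arena"
    return (
        merged.groupby("experiment_id", group_keys=False)[merged.columns]
        .apply(normalize_experiment)
        .reset_index(drop=True)
    )


def heavy_subset_features(
    peaks: PeakTable,
    subset,
    roles: pd.DataFrame | None = None,
    boundary: float = DEFAULT_BOUNDARY_MIN,
    include_boundary_in_light: bool = True,
) -> pd.DataFrame:
    """Heavy feature restricted to a subset of heavy compounds.

    Same contract as heavy_raw/heavy_norm with the sum running over `subset`
    only. Raises if the subset contains a light-section compound. The
    normalized column is added when `roles` is given.
    """
    subset = set(subset)
    f = peaks.frame
    light = _light_mask(f, boundary, include_boundary_in_light)
    light_ids = set(f.loc[light, "compound_id"])
    offending = subset & light_ids
    if offending:
        raise ParameterError(f"subset contains light compound(s): {sorted(offending)}")
    unknown = subset - set(f["compound_id"])
    if unknown:
        raise ParameterError(f"unknown compound(s): {sorted(unknown)}")
    sel = f[f["compound_id"].isin(subset)]
    out = (
        sel.groupby(["experiment_id", "chamber_id"], as_index=False)["area"]
        .sum()
        .rename(columns={"area": "subset_raw"})
    )
    # chambers where no subset compound was detected contribute zero
    all_chambers = f[["experiment_id", "chamber_id"]].drop_duplicates()
    out = all_chambers.merge(out, on=["experiment_id", "chamber_id"], how="left")
    out["subset_raw"] = out["subset_raw"].fillna(0.0)
    if roles is not None:
        out = out.merge(roles, on=["experiment_id", "chamber_id"], how="left")
        out["is_internal"] = out["role"] != "arena"

        def _norm(grp):
            denom = grp.loc[grp["is_internal"], "subset_raw"].sum()
            if denom <= 0:
                raise NormalizationError(
                    f"internal subset sum is zero in experiment "
                    f"{grp['experiment_id'].iloc[0]!r}"
                )
            return grp.assign(subset_norm=grp["subset_raw"] / denom)

        out = (
            out.groupby("experiment_id", group_keys=False)[out.columns]
            .apply(_norm)
            .reset_index(drop=True)
        )
    return out


def compound_total_correlation(
    peaks: PeakTable,
    boundary: float = DEFAULT_BOUNDARY_MIN,
    include_boundary_in_light: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of each heavy compound with the leave-self-out
    total of all other heavy compounds, across chamber samples."""
    f = peaks.frame
    heavy = f[~_light_mask(f, boundary, include_boundary_in_light)]
    wide = heavy.pivot_table(
        index=["experiment_id", "chamber_id"],
        columns="compound_id",
        values="area",
        fill_value=0.0,
        aggfunc="sum",
    )
    if len(wide) < 3:
        raise SampleSizeError(f"need >= 3 samples, got {len(wide)}")
    total = wide.sum(axis=1)
    records = []
    for cid in wide.columns:
        x = wide[cid].to_numpy(float)
        y = (total - wide[cid]).to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            records.append({"compound_id": cid, "correlation": np.nan, "constant": True})
            continue
        r, _ = stats.pearsonr(x, y)
        records.append({"compound_id": cid, "correlation": float(r), "constant": False})
    return pd.DataFrame(records)


def brood_contrast(features: pd.DataFrame) -> dict:
    """Mean +/- s.e.m. of heavy_norm for brood vs non-brood worker chambers,
    with a two-sided two-sample Kolmogorov-Smirnov p-value."""
    brood = features.loc[features["role"] == "worker_brood", "heavy_norm"]
    nonbrood = features.loc[features["role"] == "worker_nonbrood", "heavy_norm"]
    if len(brood) == 0 or len(nonbrood) == 0:
        raise SampleSizeError(
            f"both groups must be non-empty (brood={len(brood)}, "
            f"non-brood={len(nonbrood)})"
        )
    ks = stats.ks_2samp(brood, nonbrood, alternative="two-sided")
    return {
        "brood_mean": float(brood.mean()),
        "brood_sem": float(brood.sem()) if len(brood) > 1 else float("nan"),
        "brood_n": int(len(brood)),
        "nonbrood_mean": float(nonbrood.mean()),
        "nonbrood_sem": float(nonbrood.sem()) if len(nonbrood) > 1 else float("nan"),
        "nonbrood_n": int(len(nonbrood)),
        "ks_statistic": float(ks.statistic),
        "p_value": float(ks.pvalue),
    }
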