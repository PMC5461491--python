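"""Occupancy profiles, spatial-fidelity summaries and chamber-role labelling.

Tracking tables are mapped sample-by-sample onto nest regions
(point-in-polygon), aggregated into per-ant occupancy profiles (the fraction
of time spent in each chamber), and summarized: how faithful ants are to a
single preferred chamber, how often they excurse from it, and whether ants
that leave the nest return to the chamber they exited (an exact binomial
tail test against the uniform 1/K null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .data_io import NestGeometry, TrackTable
from .errors import ParameterError
from .exact_stats import binom_tail

__all__ = [
    "OccupancyProfiles",
    "ChamberRoles",
    "assign_regions",
    "occupancy_profiles",
    "fidelity_summary",
    "exit_return_test",
    "label_chamber_roles",
]

log = logging.getLogger(__name__)

OUTSIDE = "outside"
ARENA = "arena"


@dataclass
class OccupancyProfiles:
    """Per-ant occupancy vectors.

    fractions: DataFrame indexed by ant_id, one column per chamber; rows sum
    to 1 when in-nest renormalization is on. in_nest: fraction of all samples
    inside any chamber. n_excursions: maximal debounced runs outside the
    preferred chamber.
    """

    fractions: pd.DataFrame
    in_nest: pd.Series
    n_excursions: pd.Series

    @property
    def ant_ids(self) -> list:
        return list(self.fractions.index)


@dataclass(frozen=True)
class ChamberRoles:
    """Map chamber_id -> {entrance, queen, worker_brood, worker_nonbrood, arena}."""

    mapping: dict
    flags: tuple = ()

    def __post_init__(self) -> None:
        roles = list(self.mapping.values())
        if roles.count("entrance") != 1:
            raise ParameterError("exactly one entrance chamber is required")
        if roles.count("queen") > 1:
            raise ParameterError("at most one queen chamber is allowed")


def assign_regions(tracks: TrackTable, geometry: NestGeometry) -> pd.DataFrame:
    """Label every sample with its region (chamber id, 'arena' or 'outside').

    Boundary points are attributed to the chamber with the lexicographically
    smallest id (chambers are tested in sorted order, boundary-inclusive).
    """
    frame = tracks.frame.copy()
    pts = shapely.points(frame["x_cm"].to_numpy(), frame["y_cm"].to_numpy())
    region = np.full(len(frame), OUTSIDE, dtype=object)
    unassigned = np.ones(len(frame), dtype=bool)
    polys = geometry.chamber_polygons()
    for cid in sorted(polys):
        hit = unassigned & shapely.covers(polys[cid], pts)
        region[hit] = cid
        unassigned &= ~hit
    arena_hit = unassigned & shapely.covers(geometry.arena_polygon(), pts)
    region[arena_hit] = ARENA
    frame["region"] = region
    return frame


def _excursion_count(regions: np.ndarray, preferred: str, debounce: int) -> int:
    """Maximal runs outside `preferred`, bounded by samples inside it, with
    runs shorter than `debounce` treated as tracking flicker."""
    out = regions != preferred
    if not out.any() or out.all():
        return 0
    n = 0
    i = 0
    while i < len(out):
        if out[i]:
            j = i
            while j < len(out) and out[j]:
                j += 1
            bounded = i > 0 and j < len(out)
            if bounded and (j - i) >= debounce:
                n += 1
            i = j
        else:
            i += 1
    return n


def occupancy_profiles(
    labelled: pd.DataFrame,
    geometry: NestGeometry,
    window: tuple | None = None,
    renormalize_in_nest: bool = True,
    debounce: int = 2,
) -> OccupancyProfiles:
    """Aggregate labelled samples into per-ant occupancy profiles.

    window: optional (t0, t1) seconds, inclusive. With renormalization on,
    fractions are shares of in-nest time; otherwise shares of all samples in
    the window. Ants with no in-nest sample (or no sample at all) in the
    window are excluded and reported in the log.
    """
    df = labelled
    if window is not None:
        t0, t1 = window
        df = df[(df["time_s"] >= t0) & (df["time_s"] <= t1)]
    chamber_ids = geometry.chamber_ids
    rows, in_nest, excursions = {}, {}, {}
    for ant, grp in df.sort_values("time_s").groupby("ant_id", sort=True):
        regions = grp["region"].to_numpy(object)
        n_total = len(regions)
        if n_total == 0:
            log.warning("ant %r has no samples in window; excluded", ant)
            continue
        counts = pd.Series(regions).value_counts()
        nest_counts = counts.reindex(chamber_ids).fillna(0.0)
        n_nest = float(nest_counts.sum())
        denom = n_nest if renormalize_in_nest else float(n_total)
        if denom == 0:
            log.warning("ant %r never inside the nest in window; excluded", ant)
            continue
        frac = nest_counts / denom
        preferred = str(frac.idxmax())
        rows[ant] = frac
        in_nest[ant] = n_nest / n_total
        excursions[ant] = _excursion_count(regions, preferred, debounce)
    fractions = pd.DataFrame(rows).T
    fractions = fractions.reindex(columns=chamber_ids).fillna(0.0)
    fractions.index.name = "ant_id"
    return OccupancyProfiles(
        fractions=fractions,
        in_nest=pd.Series(in_nest, name="in_nest_fraction", dtype=float),
        n_excursions=pd.Series(excursions, name="n_excursions", dtype=int),
    )


def fidelity_summary(profiles: OccupancyProfiles, in_nest_threshold: float = 0.75) -> dict:
    """Fidelity statistics over ants spending >= threshold of their time in-nest."""
    if not (0.0 < in_nest_threshold <= 1.0):
        raise ParameterError(f"threshold must be in (0, 1], got {in_nest_threshold}")
    keep = profiles.in_nest[profiles.in_nest >= in_nest_threshold].index
    if len(keep) == 0:
        log.warning("no ant passes the in-nest threshold %.2f", in_nest_threshold)
        return {
            "n_kept": 0,
            "mean_max_fraction": float("nan"),
            "median_excursions": float("nan"),
            "preferred_chamber": {},
        }
    frac = profiles.fractions.loc[keep]
    return {
        "n_kept": int(len(keep)),
        "mean_max_fraction": float(frac.max(axis=1).mean()),
        "median_excursions": float(profiles.n_excursions.loc[keep].median()),
        "preferred_chamber": {a: str(c) for a, c in frac.idxmax(axis=1).items()},
    }


def exit_return_test(labelled: pd.DataFrame, geometry: NestGeometry) -> dict:
    """Do ants return to the chamber they exited?

    An exit episode is a nest -> arena -> nest excursion; it is a success if
    the first chamber re-entered equals the last chamber before the exit.
    The p-value is the exact binomial tail of k-or-more successes in n
    episodes under the uniform null p = 1/n_chambers.
    """
    chamber_ids = set(geometry.chamber_ids)
    k = n = 0
    for _, grp in labelled.sort_values("time_s").groupby("ant_id", sort=True):
        # compress to the chamber/arena visit sequence, ignoring 'outside'
        seq = [r for r in grp["region"] if r in chamber_ids or r == ARENA]
        compressed = [r for i, r in enumerate(seq) if i == 0 or r != seq[i - 1]]
        for i, r in enumerate(compressed):
            if r == ARENA and 0 < i < len(compressed) - 1:
                n += 1
                if compressed[i - 1] == compressed[i + 1]:
                    k += 1
    if n == 0:
        return {"k": 0, "n": 0, "p_hat": float("nan"), "p_value": float("nan"),
                "status": "no exits"}
    p_null = 1.0 / len(chamber_ids)
    return {
        "k": k,
        "n": n,
        "p_hat": k / n,
        "p_value": binom_tail(k, n, p_null),
        "status": "ok",
    }


def label_chamber_roles(
    profiles: OccupancyProfiles,
    queen_id: str,
    brood_counts: dict,
    geometry: NestGeometry,
    queen_threshold: float = 0.5,
    brood_threshold: float = 1.0,
) -> ChamberRoles:
    """Label chambers as entrance / queen / worker_brood / worker_nonbrood.

    Entrance: the chamber whose centroid is nearest the door (lexicographic
    tie-break, flagged). Queen chamber: where the queen's occupancy fraction
    exceeds `queen_threshold` (unassigned and flagged otherwise). Remaining
    chambers are worker chambers, brood if their mean brood-item count is at
    least `brood_threshold`.
    """
    if queen_id not in profiles.fractions.index:
        raise ParameterError(f"queen {queen_id!r} not among profiled ants")
    flags = []
    polys = geometry.chamber_polygons()
    door = np.asarray(geometry.door, dtype=float)
    dists = {
        cid: float(np.hypot(*(np.asarray(polys[cid].centroid.coords[0]) - door)))
        for cid in polys
    }
    dmin = min(dists.values())
    nearest = sorted(c for c, d in dists.items() if np.isclose(d, dmin))
    if len(nearest) > 1:
        flags.append(f"entrance tie between {nearest}; took {nearest[0]!r}")
    entrance = nearest[0]

    queen_frac = profiles.fractions.loc[queen_id]
    queen_chamber = None
    top = queen_frac.idxmax()
    if queen_frac[top] > queen_threshold and top != entrance:
        queen_chamber = str(top)
    else:
        flags.append("no chamber holds the queen more than "
                     f"{queen_threshold:.0%} of the time; queen role unassigned")

    mapping = {}
    for cid in geometry.chamber_ids:
        if cid == entrance:
            mapping[cid] = "entrance"
        elif cid == queen_chamber:
            mapping[cid] = "queen"
        else:
            mean_brood = float(brood_counts.get(cid, 0.0))
            mapping[cid] = (
                "worker_brood" if mean_brood >= brood_threshold else "worker_nonbrood"
            )
    return ChamberRoles(mapping=mapping, flags=tuple(flags))
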