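"""Synthetic generators for tracking, floor-shuffle, chromatogram and
deposition data.

Each generator reproduces the statistical structure the downstream analyses
assume — Markovian chamber occupancy with a prescribed stationary fidelity,
Dirichlet occupancy profiles under floor-following versus null hypotheses,
peak tables whose light/heavy composition separates chamber classes, and
overdispersed per-ant chemical deposits — so every stage of the pipeline is
testable without the original colony recordings. All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely

from .data_io import NestGeometry, PeakTable, TrackTable
from .errors import ParameterError
from .floor_permutation import FloorAssignment

__all__ = [
    "ShuffleScenario",
    "ChromatogramClassParams",
    "simulate_tracks",
    "simulate_shuffle",
    "simulate_chromatograms",
    "simulate_deposition",
]

SEGMENT_IDS = ("1", "2", "3", "Q")
LOCATION_IDS = ("E", "N", "S", "W")

#: canonical realized assignment (a quarter-turn of the four floor segments)
DEFAULT_ASSIGNMENT = FloorAssignment({"Q": "N", "1": "E", "2": "S", "3": "W"})


# ---------------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------------


def _uniform_points_in_polygon(polygon, n, rng):
    """Rejection-sample n points uniformly inside a shapely polygon."""
    minx, miny, maxx, maxy = polygon.bounds
    xs = np.empty(n)
    ys = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 16)
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        ok = shapely.contains_xy(polygon, cx, cy)
        take = min(int(ok.sum()), n - filled)
        xs[filled : filled + take] = cx[ok][:take]
        ys[filled : filled + take] = cy[ok][:take]
        filled += take
    return xs, ys


def simulate_tracks(
    geometry: NestGeometry,
    n_ants: int,
    fidelity: float,
    duration: float,
    rate: float = 8.0,
    seed: int = 0,
    mean_dwell_s: float = 5.0,
    return_homes: bool = False,
):
    """Markov-chain chamber occupancy with stationary home fidelity.

    Each ant has a home chamber. Every frame it keeps its chamber with
    probability 1 - lambda and otherwise re-draws a chamber from the
    stationary law (home with probability `fidelity`, the rest uniform), so
    home occupancy is exactly `fidelity` in the long run, with mean dwell
    time controlled by `mean_dwell_s`. Positions are uniform inside the
    occupied chamber polygon. With `return_homes` the (TrackTable, homes)
    pair is returned, homes mapping ant_id -> home chamber id.
    """
    if not (0.0 <= fidelity <= 1.0):
        raise ParameterError(f"fidelity must be in [0, 1], got {fidelity}")
    if n_ants < 1 or duration <= 0 or rate <= 0:
        raise ParameterError("n_ants, duration and rate must be positive")
    rng = np.random.default_rng(seed)
    polys = geometry.chamber_polygons()
    chamber_ids = sorted(polys)
    k = len(chamber_ids)
    if k < 2 and fidelity < 1.0:
        raise ParameterError("need at least two chambers for fidelity < 1")
    pi = np.full(k, (1.0 - fidelity) / max(k - 1, 1))
    n_frames = int(round(duration * rate))
    leave = min(1.0, 1.0 / (mean_dwell_s * rate))
    frames = []
    homes_out = {}
    width = len(str(max(n_ants - 1, 1)))
    times = np.arange(n_frames) / rate
    for i in range(n_ants):
        home = int(rng.integers(k))
        homes_out[f"ant{i:0{width}d}"] = chamber_ids[home]
        p = pi.copy()
        p[home] = fidelity
        p /= p.sum()
        states = np.empty(n_frames, dtype=int)
        states[0] = rng.choice(k, p=p)
        redraw = rng.random(n_frames) < leave
        draws = rng.choice(k, size=n_frames, p=p)
        for t in range(1, n_frames):
            states[t] = draws[t] if redraw[t] else states[t - 1]
        xs = np.empty(n_frames)
        ys = np.empty(n_frames)
        for c in range(k):
            sel = states == c
            if sel.any():
                xs[sel], ys[sel] = _uniform_points_in_polygon(
                    polys[chamber_ids[c]], int(sel.sum()), rng
                )
        frames.append(
            pd.DataFrame(
                {
                    "time_s": times,
                    "ant_id": f"ant{i:0{width}d}",
                    "x_cm": xs,
                    "y_cm": ys,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    tracks = TrackTable(frame=table, sampling_rate=float(rate))
    return (tracks, homes_out) if return_homes else tracks


# ---------------------------------------------------------------------------
# Floor shuffle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShuffleScenario:
    """Study conditions for a floor-shuffle experiment.

    fidelity: expected occupancy of an ant's home segment (>= 1/n_segments).
    follow_strength: probability an ant's post-shuffle home tracks its floor
    segment to its new location (0 is the null hypothesis of no floor
    following). concentration: Dirichlet concentration of the profiles.
    """

    n_ants: int
    n_segments: int = 4
    fidelity: float = 0.71
    follow_strength: float = 0.0
    sigma_true: FloorAssignment | None = None
    seed: int = 0
    concentration: float = 20.0

    def __post_init__(self) -> None:
        if self.n_ants < 1:
            raise ParameterError("n_ants must be positive")
        if not (1.0 / self.n_segments <= self.fidelity <= 1.0):
            raise ParameterError(
                f"fidelity must lie in [1/{self.n_segments}, 1], got {self.fidelity}"
            )
        if not (0.0 <= self.follow_strength <= 1.0):
            raise ParameterError("follow_strength must be in [0, 1]")

    def segment_ids(self):
        if self.n_segments == 4:
            return list(SEGMENT_IDS)
        return [f"s{i}" for i in range(self.n_segments)]

    def location_ids(self):
        if self.n_segments == 4:
            return list(LOCATION_IDS)
        return [f"L{i}" for i in range(self.n_segments)]

    def assignment(self) -> FloorAssignment:
        if self.sigma_true is not None:
            return self.sigma_true
        if self.n_segments == 4:
            return DEFAULT_ASSIGNMENT
        segs, locs = self.segment_ids(), self.location_ids()
        return FloorAssignment(dict(zip(segs, locs)))


def _concentrated_profiles(rng, homes, regions, fidelity, concentration):
    k = len(regions)
    out = np.empty((len(homes), k))
    if fidelity >= 1.0:
        out[:] = 0.0
        out[np.arange(len(homes)), homes] = 1.0
        return out
    base = concentration * (1.0 - fidelity) / (k - 1)
    for i, h in enumerate(homes):
        alpha = np.full(k, base)
        alpha[h] = concentration * fidelity
        out[i] = rng.dirichlet(alpha)
    return out


def simulate_shuffle(scenario: ShuffleScenario):
    """Before/after occupancy profiles under a floor-shuffle experiment.

    Before-profiles are Dirichlet vectors concentrated on each ant's home
    segment at level `fidelity`. After the shuffle, with probability
    `follow_strength` an ant's concentration moves to sigma_true(home) —
    i.e. it followed its floor — and otherwise to a uniformly random
    location. Returns (before, after, sigma_true) with profiles as
    DataFrames indexed by ant id.
    """
    rng = np.random.default_rng(scenario.seed)
    segs = scenario.segment_ids()
    locs = scenario.location_ids()
    sigma = scenario.assignment()
    if sorted(sigma.segments) != sorted(segs) or sigma.locations != sorted(locs):
        raise ParameterError("sigma_true does not map the scenario's segments to its locations")
    k = scenario.n_segments
    homes = rng.integers(k, size=scenario.n_ants)
    before = _concentrated_profiles(rng, homes, segs, scenario.fidelity,
                                    scenario.concentration)
    loc_index = {l: j for j, l in enumerate(locs)}
    follows = rng.random(scenario.n_ants) < scenario.follow_strength
    random_homes = rng.integers(k, size=scenario.n_ants)
    after_homes = np.where(
        follows,
        [loc_index[sigma[segs[h]]] for h in homes],
        random_homes,
    )
    after = _concentrated_profiles(rng, after_homes, locs, scenario.fidelity,
                                   scenario.concentration)
    ants = [f"ant{i:03d}" for i in range(scenario.n_ants)]
    return (
        pd.DataFrame(before, index=pd.Index(ants, name="ant_id"), columns=segs),
        pd.DataFrame(after, index=pd.Index(ants, name="ant_id"), columns=locs),
        sigma,
    )


# ---------------------------------------------------------------------------
# Chromatograms
# ---------------------------------------------------------------------------

LIGHT_COMPOUNDS = {"C17": 17.0, "C19": 19.0, "C21": 21.0}
LIGHT_BOUNDARY_MIN = 21.0  # heneicosane retention; the light/heavy split
LIGHT_WEIGHTS = (0.40, 0.35, 0.25)


@dataclass(frozen=True)
class ChromatogramClassParams:
    """Per-class normalized light/heavy means for the chamber generator.

    Means of each feature over one experiment's internal chambers
    (entrance + queen + 3 workers, with `n_brood` brood chambers) sum to ~1,
    matching the per-experiment normalization contract. Standard deviations
    are `cv` times the mean. Heavy totals are decomposed over
    `n_heavy_compounds` whose per-sample areas share the chamber total up to
    idiosyncratic noise controlled by `heavy_correlation` (1 = perfectly
    proportional compounds).
    """

    light_means: dict = field(
        default_factory=lambda: {
            "queen": 0.10,
            "worker_brood": 0.13,
            "worker_nonbrood": 0.13,
            "entrance": 0.50,
            "arena": 0.60,
        }
    )
    heavy_means: dict = field(
        default_factory=lambda: {
            "queen": 0.45,
            "worker_brood": 0.19,
            "worker_nonbrood": 0.11,
            "entrance": 0.06,
            "arena": 0.01,
        }
    )
    cv: float = 0.25
    n_heavy_compounds: int = 8
    heavy_correlation: float = 0.8
    n_brood: int = 2  # of the 3 worker chambers
    light_scale: float = 1.0e5
    heavy_scale: float = 4.0e5

    def __post_init__(self) -> None:
        for d in (self.light_means, self.heavy_means):
            if any(v < 0 for v in d.values()):
                raise ParameterError("class means must be nonnegative")
        if not (0.0 <= self.heavy_correlation <= 1.0):
            raise ParameterError("heavy_correlation must be in [0, 1]")
        if not (0 <= self.n_brood <= 3):
            raise ParameterError("n_brood must be between 0 and 3")


def _gamma_around(rng, mean, cv, size=None):
    """Positive draws with the requested mean and coefficient of variation."""
    mean = np.asarray(mean, dtype=float)
    if cv <= 0:
        return np.broadcast_to(mean, np.shape(mean) if size is None else size).copy()
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean * cv**2, size=size)


def simulate_chromatograms(
    n_experiments: int,
    params: ChromatogramClassParams | None = None,
    seed: int = 0,
):
    """Peak tables for synthetic experiments of 7 chamber samples each
    (2 arena, 1 entrance, 1 queen, 3 worker).

    Returns (PeakTable, labels) where labels is a DataFrame with columns
    experiment_id, chamber_id, role.
    """
    if n_experiments < 1:
        raise ParameterError("n_experiments must be >= 1")
    params = params or ChromatogramClassParams()
    rng = np.random.default_rng(seed)
    heavy_ids = [f"H{23 + 2 * i}" for i in range(params.n_heavy_compounds)]
    heavy_ret = {cid: 23.0 + 2.0 * i for i, cid in enumerate(heavy_ids)}
    # fixed compound composition of the heavy signature, shared by all samples
    heavy_w = rng.dirichlet(np.full(params.n_heavy_compounds, 5.0))
    noise_cv = 0.8 * (1.0 - params.heavy_correlation)

    worker_roles = ["worker_brood"] * params.n_brood + ["worker_nonbrood"] * (
        3 - params.n_brood
    )
    rows = []
    labels = []
    for e in range(n_experiments):
        exp = f"exp{e:03d}"
        light_total = params.light_scale * rng.lognormal(0.0, 0.3)
        heavy_total = params.heavy_scale * rng.lognormal(0.0, 0.3)
        chambers = (
            [("entrance", "entrance"), ("queen", "queen")]
            + [(f"worker{i + 1}", role) for i, role in enumerate(worker_roles)]
            + [("arena1", "arena"), ("arena2", "arena")]
        )
        for chamber_id, role in chambers:
            labels.append({"experiment_id": exp, "chamber_id": chamber_id, "role": role})
            light_raw = light_total * _gamma_around(
                rng, params.light_means[role], params.cv
            )
            heavy_raw = heavy_total * _gamma_around(
                rng, params.heavy_means[role], params.cv
            )
            light_parts = np.array(LIGHT_WEIGHTS) * light_raw
            for cid, area in zip(LIGHT_COMPOUNDS, light_parts):
                rows.append(
                    {
                        "experiment_id": exp,
                        "chamber_id": chamber_id,
                        "compound_id": cid,
                        "retention_min": LIGHT_COMPOUNDS[cid],
                        "area": float(area),
                    }
                )
            comp_noise = _gamma_around(
                rng, np.ones(params.n_heavy_compounds), noise_cv
            )
            heavy_parts = heavy_w * comp_noise * heavy_raw
            for cid, area in zip(heavy_ids, heavy_parts):
                rows.append(
                    {
                        "experiment_id": exp,
                        "chamber_id": chamber_id,
                        "compound_id": cid,
                        "retention_min": heavy_ret[cid],
                        "area": float(area),
                    }
                )
    peaks = PeakTable(frame=pd.DataFrame(rows))
    return peaks, pd.DataFrame(labels)


# ---------------------------------------------------------------------------
# Deposition
# ---------------------------------------------------------------------------


def simulate_deposition(
    ant_counts,
    m_ant: float,
    sigma_ant: float,
    distribution: str = "gamma",
    seed: int = 0,
    queen_fractions=None,
) -> pd.DataFrame:
    """Per-chamber total signal as a sum of N i.i.d. nonnegative deposits.

    Each chamber with (integer) ant count N receives the sum of N per-ant
    deposits with mean `m_ant` and s.d. `sigma_ant`, drawn from a gamma
    (default; supports s.d. > mean) or lognormal distribution. Returns a
    DataFrame with columns chamber_id, n_ants, total_signal, queen_fraction.
    """
    if m_ant <= 0:
        raise ParameterError(f"m_ant must be positive, got {m_ant}")
    if sigma_ant < 0:
        raise ParameterError("sigma_ant must be nonnegative")
    if distribution not in ("gamma", "lognormal"):
        raise ParameterError(f"unknown distribution {distribution!r}")
    counts = np.asarray(ant_counts, dtype=int)
    if (counts < 0).any():
        raise ParameterError("ant counts must be nonnegative")
    rng = np.random.default_rng(seed)
    if queen_fractions is None:
        qf = np.zeros(len(counts))
    else:
        qf = np.asarray(queen_fractions, dtype=float)
        if qf.shape != counts.shape:
            raise ParameterError("queen_fractions must match ant_counts in length")
    totals = np.empty(len(counts))
    for i, n in enumerate(counts):
        if n == 0:
            totals[i] = 0.0
        elif sigma_ant == 0:
            totals[i] = n * m_ant
        elif distribution == "gamma":
            shape = (m_ant / sigma_ant) ** 2
            scale = sigma_ant**2 / m_ant
            totals[i] = rng.gamma(shape, scale, size=n).sum()
        else:
            s2 = np.log1p((sigma_ant / m_ant) ** 2)
            mu = np.log(m_ant) - s2 / 2.0
            totals[i] = rng.lognormal(mu, np.sqrt(s2), size=n).sum()
    return pd.DataFrame(
        {
            "chamber_id": [f"ch{i:04d}" for i in range(len(counts))],
            "n_ants": counts.astype(float),
            "total_signal": totals,
            "queen_fraction": qf,
        }
    )
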