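"""Floor-shuffle permutation test.

After a nest's floor segments are shuffled into a new nest, each candidate
one-to-one assignment sigma from floor segments to new locations is scored by
how well the colony's post-shuffle occupancy matches its pre-shuffle
occupancy transported by sigma. The per-ant kernel is the overlap
coefficient sum_j min(p_before(j), p_after(sigma(j))) (default) or the
total-variation complement; the assignment score is the mean over ants. The
realized (experimental) assignment is ranked among all K! candidates, giving
an empirical p-value with resolution 1/K!, and experiments are combined
either by exact convolution of the summed-score null or by Fisher's rule.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, SizeError

__all__ = [
    "FloorAssignment",
    "PermutationScan",
    "assignment_score",
    "permutation_scan",
    "combine_experiments",
    "per_ant_score_histogram",
]

log = logging.getLogger(__name__)

KERNELS = ("overlap", "tv_complement")

# Enumerating K! assignments (and 24^ceil(m/2) partial sums when combining)
# is exact but exponential; cap K at 8 as documented.
MAX_SEGMENTS = 8


@dataclass(frozen=True)
class FloorAssignment:
    """Bijection from floor-segment ids to new nest-location ids."""

    mapping: tuple

    def __init__(self, mapping) -> None:
        if isinstance(mapping, dict):
            items = tuple(sorted(mapping.items()))
        else:
            items = tuple(sorted(tuple(kv) for kv in mapping))
        object.__setattr__(self, "mapping", items)
        segs = [s for s, _ in items]
        locs = [l for _, l in items]
        if len(set(segs)) != len(segs) or len(set(locs)) != len(locs):
            raise ParameterError("assignment is not a bijection")

    def as_dict(self) -> dict:
        return dict(self.mapping)

    def __getitem__(self, segment):
        return self.as_dict()[segment]

    @property
    def segments(self) -> list:
        return [s for s, _ in self.mapping]

    @property
    def locations(self) -> list:
        return sorted(l for _, l in self.mapping)


@dataclass
class PermutationScan:
    """All K! assignment scores for one experiment plus the realized rank."""

    scores: pd.Series  # index: tuple of location ids in segment order
    realized: FloorAssignment
    realized_score: float
    rank: int
    empirical_p: float
    per_ant_scores: pd.DataFrame  # ants x assignments
    segments: list
    locations: list


def _check_profiles(before: pd.DataFrame, after: pd.DataFrame, strict: bool):
    common = before.index.intersection(after.index)
    missing = before.index.symmetric_difference(after.index)
    if len(missing):
        msg = f"{len(missing)} ant(s) present in only one phase"
        if strict:
            raise ParameterError(msg)
        log.warning("%s; excluded", msg)
    if len(common) == 0:
        raise ParameterError("no ant is present in both phases")
    b = before.loc[common]
    a = after.loc[common]
    for name, df in (("before", b), ("after", a)):
        arr = df.to_numpy(float)
        if (arr < -1e-9).any() or np.abs(arr.sum(axis=1) - 1.0).max() > 1e-6:
            raise ParameterError(f"{name}-profiles are not probability vectors")
    return b, a


def _pairwise_kernel(b: np.ndarray, a: np.ndarray, kernel: str) -> np.ndarray:
    """M[ant, j, k]: the kernel's per-coordinate term between before-segment j
    and after-location k. Both kernels are coordinate-separable."""
    if kernel == "overlap":
        return np.minimum(b[:, :, None], a[:, None, :])
    if kernel == "tv_complement":
        return -0.5 * np.abs(b[:, :, None] - a[:, None, :])
    raise ParameterError(f"unknown kernel {kernel!r}; choose from {KERNELS}")


def _kernel_offset(kernel: str) -> float:
    return 1.0 if kernel == "tv_complement" else 0.0


def assignment_score(
    before: pd.DataFrame,
    after: pd.DataFrame,
    sigma: FloorAssignment,
    kernel: str = "overlap",
    strict: bool = False,
) -> float:
    """Mean-over-ants similarity between after-profiles and sigma-transported
    before-profiles; 1 iff every ant's occupancy is exactly transported."""
    b, a = _check_profiles(before, after, strict)
    segs = list(b.columns)
    mapped = [sigma[s] for s in segs]
    per_ant = _pairwise_kernel(
        b.to_numpy(float), a[mapped].to_numpy(float), kernel
    )
    # transported coordinates sit on the diagonal j == k after reordering
    scores = np.einsum("ajj->a", per_ant) + _kernel_offset(kernel)
    return float(scores.mean())


def permutation_scan(
    before: pd.DataFrame,
    after: pd.DataFrame,
    realized: FloorAssignment,
    kernel: str = "overlap",
    strict: bool = False,
) -> PermutationScan:
    """Score all K! segment-to-location assignments and rank the realized one.

    Rank counts every assignment scoring >= the realized score (ties counted
    conservatively), so empirical_p = rank / K! is at least 1/K!.
    """
    b, a = _check_profiles(before, after, strict)
    segments = list(b.columns)
    locations = list(a.columns)
    k = len(segments)
    if k != len(locations):
        raise ParameterError("before and after profiles span different region counts")
    if k > MAX_SEGMENTS:
        raise SizeError(
            f"K={k} segments require {math.factorial(k)} assignments; exhaustive "
            f"enumeration is capped at K={MAX_SEGMENTS} (a sampling mode is not provided)"
        )
    M = _pairwise_kernel(b.to_numpy(float), a.to_numpy(float), kernel)
    offset = _kernel_offset(kernel)
    perms = list(itertools.permutations(range(k)))
    per_ant = np.empty((M.shape[0], len(perms)))
    for i, perm in enumerate(perms):
        per_ant[:, i] = M[:, range(k), perm].sum(axis=1) + offset
    scores_arr = per_ant.mean(axis=0)
    index = [tuple(locations[j] for j in perm) for perm in perms]
    scores = pd.Series(scores_arr, index=index, name="score")

    realized_key = tuple(realized[s] for s in segments)
    if realized_key not in scores.index:
        raise ParameterError("realized assignment does not match the profile regions")
    realized_score = float(scores[realized_key])
    rank = int((scores_arr >= realized_score - 1e-12).sum())
    return PermutationScan(
        scores=scores,
        realized=realized,
        realized_score=realized_score,
        rank=rank,
        empirical_p=rank / len(perms),
        per_ant_scores=pd.DataFrame(per_ant, index=b.index, columns=index),
        segments=segments,
        locations=locations,
    )


def _half_sums(score_arrays) -> np.ndarray:
    total = np.zeros(1)
    for arr in score_arrays:
        total = np.add.outer(total, arr).ravel()
        if total.size > 20_000_000:
            raise SizeError("too many experiments for exact convolution")
    return total


def combine_experiments(scans, method: str = "sum_convolution") -> dict:
    """Combine per-experiment permutation scans into one global p-value.

    sum_convolution: the null draws one of the K! scores uniformly and
    independently per experiment; the p-value is the exact probability that
    the summed score reaches the realized sum (computed by meet-in-the-middle
    enumeration of the product distribution, no distributional assumption).
    fisher: chi-squared combination of the per-experiment empirical p-values.
    """
    scans = list(scans)
    if not scans:
        raise ParameterError("need at least one permutation scan")
    if method == "fisher":
        ps = [s.empirical_p for s in scans]
        stat, p = stats.combine_pvalues(ps, method="fisher")
        return {"p_value": float(p), "statistic": float(stat), "method": method}
    if method != "sum_convolution":
        raise ParameterError(f"unknown combination method {method!r}")
    arrays = [s.scores.to_numpy(float) for s in scans]
    realized_sum = float(sum(s.realized_score for s in scans))
    half = len(arrays) // 2
    left = _half_sums(arrays[:half]) if half else np.zeros(1)
    right = np.sort(_half_sums(arrays[half:]))
    # count pairs with left + right >= realized_sum; small slack keeps the
    # realized atom itself in the tail despite float summation order
    tol = 1e-9 * max(1.0, abs(realized_sum))
    idx = np.searchsorted(right, realized_sum - tol - left, side="left")
    count = int((right.size - idx).sum())
    total = left.size * right.size
    return {
        "p_value": count / total,
        "realized_sum": realized_sum,
        "n_experiments": len(scans),
        "method": method,
    }


def per_ant_score_histogram(
    before: pd.DataFrame,
    after: pd.DataFrame,
    realized: FloorAssignment,
    kernel: str = "overlap",
) -> dict:
    """Per-ant scores under the realized assignment versus all others pooled."""
    scan = permutation_scan(before, after, realized, kernel=kernel)
    realized_key = tuple(realized[s] for s in scan.segments)
    correct = scan.per_ant_scores[realized_key]
    others = scan.per_ant_scores.drop(columns=[realized_key])
    return {
        "correct": correct.to_numpy(float),
        "random": others.to_numpy(float).ravel(),
    }
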