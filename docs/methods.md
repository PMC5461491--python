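# Methods

This note documents the models behind `antsigns`, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
numerical conventions. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Occupancy profiles and fidelity statistics

Tracking samples are assigned to regions by boundary-inclusive
point-in-polygon tests (shapely); a point on a shared chamber boundary goes
to the chamber with the lexicographically smallest id, a deterministic
convention that only matters for a measure-zero set of positions. Samples
outside every chamber are labelled `arena` if inside the arena polygon,
otherwise `outside`.

An ant's occupancy vector is the share of samples per chamber. By default
the denominator is the ant's **in-nest** time, so before/after-manipulation
vectors are comparable probability vectors even when nest attendance
changes; total-time shares are available via `renormalize_in_nest=False`
since published fidelity figures do not always say which denominator they
use. Ants with no in-nest sample in the analysis window are excluded and
logged, never silently dropped.

An *excursion* is a maximal run of samples outside the preferred chamber
bounded by samples inside it. Runs shorter than 2 samples are treated as
tracking flicker (at 8 Hz, single-frame misassignments near boundaries are
common); the debounce length is a parameter. The fidelity summary keeps
ants whose in-nest fraction reaches a threshold (default 0.75).

The exit–return test scans each ant's chamber/arena visit sequence for
nest → arena → nest episodes and counts an episode a success when the first
chamber re-entered equals the last chamber left. The p-value is the exact
binomial upper tail (k-or-more) at the uniform null `1/K`. Episodes, not
ants, are the unit; an ant with several excursions contributes several
trials.

Chamber roles: the entrance is the chamber whose centroid is nearest the
door (ties broken lexicographically and flagged); the queen's chamber is
the one holding the queen more than half her time (none → flagged,
unassigned); remaining chambers are worker chambers, split into brood and
non-brood at a mean brood count of one item.

## The floor-shuffle permutation test

Segments `{Q,1,2,3}` are mapped to locations `{N,S,E,W}` by a bijection;
the experiment realizes one assignment, and all `K!` candidates are scored

    S^sigma = mean_a sum_j min(p_a_before(j), p_a_after(sigma(j))).

The overlap coefficient is the default per-ant kernel because it satisfies
the documented score axioms: values in [0, 1]; 1 exactly when an ant's
after-vector is its before-vector transported by sigma (equal time
fractions included); 0 exactly when the supports are disjoint. The
total-variation complement `1 - 0.5 * sum_j |p - q∘sigma|` is offered as
`tv_complement`; it shares the range and identity axioms but is nonzero
for disjoint supports unless both vectors are degenerate.

The realized assignment's rank counts every assignment scoring at least as
high (ties conservative), so the empirical p is at least `1/K!` and at one
experiment's resolution cannot beat 1/24 for K=4. Exhaustive enumeration is
capped at K = 8 (40 320 assignments).

Experiments are combined by **exact sum-convolution**: under the global
null each experiment contributes one of its K! scores uniformly at random,
independently; the combined p is the probability that the summed score
reaches the realized sum. This is computed by meet-in-the-middle
enumeration (two halves of at most `24^ceil(m/2)` partial sums), which is
exact and assumption-free; a relative tolerance of 1e-9 on the threshold
keeps the realized atom inside its own tail despite floating-point
summation order. Fisher's chi-squared combination of the empirical p-values
is provided as an alternative; with per-experiment p's granular at 1/24 it
is approximate, and neither method is claimed to be the one used in any
particular published analysis.

## Synthetic generators

All generators take an explicit seed and are byte-deterministic given it.

**Tracks.** Each ant has a home chamber and follows a per-frame chain: keep
the current chamber with probability `1 - lambda`, otherwise re-draw from
the stationary law (home with probability `fidelity`, remaining mass
uniform over the other chambers). This "stay-or-redraw" construction hits
any stationary home occupancy in [0, 1] exactly with a single dwell
parameter (`mean_dwell_s`, default 5 s at 8 Hz); a pure
leave-uniformly-to-others chain cannot reach fidelities below 1/K.
Positions are uniform in the occupied chamber polygon. Real trajectories
have continuous motion, wall-following and arena foraging trips; none of
that is emulated, so the generator validates occupancy statistics, not
movement models.

**Floor shuffle.** Before-profiles are Dirichlet vectors with concentration
`c = 20` split as `c*fidelity` on the home segment and the rest uniform, so
the expected home share equals `fidelity` (0.71 by default, the scale of
published in-nest fidelity). After the shuffle an ant follows its floor
with probability `follow_strength` (home moves to `sigma_true(home)`),
otherwise it re-concentrates on a uniformly random location —
`follow_strength = 0` is exactly the permutation test's null, under which
the realized assignment's rank is uniform on `{1..K!}` by symmetry.

**Chromatograms.** Each experiment yields 7 samples: 2 arena, 1 entrance,
1 queen, 3 worker (2 brood + 1 non-brood by default, matching the observed
~2-of-3 prevalence). Normalized feature targets per class are drawn from
gamma distributions with CV 0.25 around class means; the two printed
worker-chamber heavy means (brood 0.19, non-brood 0.11) anchor the heavy
scale, while the remaining class means (queen 0.45, entrance 0.06; light:
entrance 0.50, queen 0.10, workers 0.13; arena light-rich, heavy-poor) are
package defaults chosen to reproduce the qualitative class separation of
real feature plots — they are configurable and are not measurements. Each
class's internal means sum to ~1, consistent with the normalization
contract. Light totals decompose over C17/C19/C21 with fixed weights;
heavy totals decompose over `n_heavy_compounds` fixed Dirichlet weights
times per-sample gamma noise whose CV is `0.8 * (1 - heavy_correlation)`,
so `heavy_correlation -> 1` makes every compound proportional to the heavy
total.

**Deposition.** A chamber with N ants accumulates the sum of N i.i.d.
nonnegative deposits with mean `m_ant` and s.d. `sigma_ant`; gamma by
default (at the ratio sigma/m = 3 the shape is 1/9 — most ants deposit
almost nothing, a few deposit a lot, which is the regime of interest),
lognormal as an alternative. `n_ants` is stored real-valued since real
records are time-averaged counts, but the generator uses integer counts.

## Chromatogram features and classification

The light/heavy boundary sits at the heneicosane retention time and the
boundary peak is counted **light** by default (heneicosane is one of the
three Dufour's-gland alkanes), with a flag to move it since the defining
texts are ambiguous. "Internal chambers" are entrance + queen + 3 workers;
arena samples are divided by the same per-experiment divisor but excluded
from the normalizing sum, which keeps internal features on the simplex and
lets arena points exceed it.

The pairwise SVMs use scikit-learn's `SVC(kernel="linear")` with C = 1.0
(the regularization used in the original analyses is unknown; C is
exposed). No feature scaling is applied beyond the per-experiment
normalization — both features already live on commensurate O(1) scales.
Vote ties are broken by the largest sum of signed distances to the tied
classes' separators, then lexicographically, and flagged.

Cross-validation folds are whole experiments (grouped leave-one-out):
samples of one experiment share a normalization divisor and must never
straddle the split. Folds whose training split loses a class are skipped
with a warning rather than scored against an untrainable ensemble.

Two accuracies are reported. Plain accuracy is the headline number.
Balanced accuracy (macro-averaged recall) is the *chance-calibrated* one:
for any predictor independent of the labels its expectation is exactly
`1/n_classes`, whereas plain accuracy drifts to the majority-class share
under the tasks' imbalanced compositions (4:3, 3:1:1, 3:1:1:2 per
experiment). Chance-level checks therefore use balanced accuracy.

## Deposition fits

The mean line is plain OLS with a free intercept (the passive model implies
zero intercept; `force_origin` enforces it, and the slope is insensitive to
the choice on well-spread counts). The noise law uses `n_bins = 5`
equal-count bins (each bin needs >= 3 records); per-bin residual s.d. is
regressed through the origin on sqrt(mean bin count). Equal-count binning
keeps per-bin estimator variance comparable; the bin count trades bias
(few bins) against noisy s.d. estimates (many bins) and is configurable.
No robust or weighted regression is attempted — the documented estimator is
plain least squares at both stages.

## Problem sizes and numerical conventions

Simulation-based checks use deliberately scaled study sizes chosen once:
2 000 replicates of 16-ant colonies for the null-rank calibration, 19
experiments (133 samples) for classifier runs, 60–100 ants x 1 000–2 400
frames for track recovery, and 400 chambers (counts 1..40 x 10) for the
deposition fit, where the sigma/m estimator's spread is a few percent —
comfortably inside the ±10%/±20% recovery checks. Monte-Carlo assertions
use 3-standard-error bands.

Exact binomial quantities go through scipy's regularized-beta
implementation (double precision); the signed-rank test enumerates all 2^n
sign patterns with midranks on ties and drops zero differences with a
warning (a convention, not the only one). Readers parse floats in
round-trip mode so write-then-read is the identity.

## Known limitations

- The generators validate the statistics the analyses consume, not the
  underlying biology: no movement dynamics, no queen/worker behavioural
  asymmetry, no refuse-pile samples, no colony-to-colony chemical
  specificity.
- Published data-derived figures (overall fidelity, combined permutation
  p-values, real classification accuracies) depend on unreleased raw
  recordings and are not reproduced here; the package reproduces the
  closed-form statistics exactly and the estimation procedures on synthetic
  data with known ground truth.
- Decision boundaries depend on the unknown original solver/regularization;
  quantitative boundary positions will differ from published figures even
  when accuracies agree.
- The permutation machinery is exhaustive-only (K <= 8); no sampling
  fallback is provided.
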