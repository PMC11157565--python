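# Methods

`swarmselect` implements a two-stage hybrid feature-selection procedure for
regression on high-dimensional small-sample (HDSS) tables — the regime of
untargeted metabolomics, where a few dozen samples carry hundreds to tens
of thousands of ion-abundance features. Stage 1 is a filter–wrapper pass
that discards irrelevant and part of the redundant features; Stage 2 is a
multi-objective particle swarm that searches subsets of the surviving
candidates, returning a Pareto front over (subset size, prediction error)
rather than a single subset.

## Stage 1: mRMR ranking and forward search

**Mutual-information estimate.** Relevance and redundancy are measured by
mutual information, estimated with the histogram plug-in

I(x; y) = Σ_cells p̂(x, y) · ln( p̂(x, y) / (p̂(x) p̂(y)) ),

in nats, over nonzero joint cells. Continuous variables are discretized
into equal-width bins; integer-coded variables with ≤ 20 levels keep their
native levels. The automatic bin count follows a joint-occupancy rule,
k = max(2, ⌈√(n/5)⌉) bins per variable, which keeps the expected count per
joint cell near five. The more common per-marginal rule k = ⌈√n⌉ puts more
joint cells than samples at n ≈ 50–60 (8×8 = 64 cells), at which point the
plug-in estimate is dominated by its bias ((r−1)(c−1)/2n ≈ 0.4 nats) and
variance, and relevant features become statistically indistinguishable
from noise features; we verified this empirically before fixing the
occupancy rule as the default. The bin count is configurable
(`n_bins`) for users who want a different operating point.

**Ranking.** Features are ordered by the classical greedy max-relevance
min-redundancy scheme: the first pick maximizes I(f, y); each later pick
maximizes I(f, y) − (1/|S|)·Σ_{s∈S} I(f, s) over unselected features, S
being the selected set. Ties break toward the lower column index, making
the ranking deterministic. A one-shot relevance-only mode
(`relevance_only=True`) and |Pearson|/|Spearman| baselines are provided
for comparison.

**Forward search.** Prefixes of the ranking of sizes step, 2·step, …, m
(default step = 1% of m, minimum 1) are scored by k-fold cross-validated
PLS regression RMSE; the prefix with the smallest CV RMSE becomes the
candidate set. Ties prefer the smaller prefix. Because the full feature
set is always among the evaluated prefixes, the candidate's CV RMSE never
exceeds the full-set baseline.

**PLS engine and cross-validation.** Folds are formed by one seeded
shuffle followed by contiguous splits, fixed for the whole run; fold RMSEs
are averaged (a pooled-residual mode exists behind `pooled`). PLS is fit
with 2 components by default — a small-n-safe choice — with the component
count capped at each training fold's usable rank. Standardization uses
training-fold statistics only, so no information leaks from held-out
folds. The fits use an in-package single-target NIPALS implementation
that follows the standard centering/scaling conventions (mean and ddof-1
standard deviation, zero deviations treated as one); it agrees with
scikit-learn's `PLSRegression` to machine precision (tested) and is about
two orders of magnitude faster per fit, which matters because a swarm run
performs tens of thousands of fold fits.

## Stage 2: Pareto-archive particle swarm (CMOPSO)

Both objectives are minimized: f1 = subset size, f2 = the subset's CV RMSE
on the same fixed folds as Stage 1, so f2 is a deterministic function of
the subset (dominance comparisons would otherwise be corrupted by fold
noise); subset evaluations are memoized within a run.

**Encoding.** Particles live in [0, 1]^D, one dimension per candidate
feature, and decode to the set of dimensions whose position exceeds a
threshold (default 0.6). An empty decode is repaired to the argmax
dimension so f1 ≥ 1 always. Velocity and position follow the classical
updates v′ = w·v + c1·r1·(pbest − x) + c2·r2·(leader − x), x′ = x + v′,
with fresh per-dimension uniforms r1, r2, velocities clamped to ±0.5
(half the position range) and positions clipped to [0, 1] with the clipped
component's velocity zeroed.

**Schedules.** The distinguishing ingredient is the coefficient schedule:
nonlinearly decreasing inertia w(t) = (w_max − w_min)(t/T − 1)² + w_min
(0.9 → 0.4 by default) and linear acceleration ramps with the cognitive
factor c1 falling 2.75 → 1.25 and the social factor c2 rising 0.5 → 2.25,
so early iterations explore independently and late ones converge toward
the archive. A literal alternative for the c2 line
(c2 = c2f + (c2f − c2i)·t/T) is available behind `literal_c2`; it
decreases to −1.25, which contradicts the documented 0.5 ∼ 2.25 operating
range, so the increasing ramp is the default. The plain-MOPSO baseline
(`optimizer="mopso"`) runs the identical loop with constant w = 0.9 and
c1 = c2 = 2.0.

**Archive and leaders.** The external archive (capacity 50 by default)
holds pairwise non-dominated solutions. Exact duplicates (same objectives
and feature set) collapse; equal objective vectors with different subsets
are distinct solutions and both stay. Over capacity, the entry with the
smallest crowding distance is removed one at a time with recomputation;
ties drop the later-inserted entry. Crowding distance is the normalized
gap-sum over objectives with a distinct-value-neighbor convention: tied
points share a distance and any point attaining a per-objective extreme is
infinite. This is identical to the NSGA-II stable-sort formulation on
fronts with distinct values but is permutation-equivariant under ties,
which the stable-sort version is not. Leaders are drawn per particle per
iteration by adaptive-grid roulette: the archive's objective bounding box
(inflated by 10%) is divided into a 20×20 grid and a cell is chosen with
probability inversely proportional to its occupancy, then a uniform
member of that cell — favouring sparse regions of the front. A particle's
personal best is replaced when the new point dominates it, kept when
dominated, and replaced with probability ½ when mutually non-dominated.
There is no mutation/turbulence operator; the schedules are the diversity
mechanism.

Default run parameters: T = 300 iterations, 100 particles, archive 50,
grid 20. Tests and the acceptance script use scaled-down problem sizes
(T = 100, 40 particles on 60×500 inputs; T ≤ 50 for structural checks),
chosen so the whole suite completes in minutes while leaving the dynamics
qualitatively unchanged.

## Synthetic data

The generator emulates the structure of wide metabolomics regression
tables: n ≪ m; a small relevant core (i.i.d. standard normal) with linear
effects on the response, default effect sizes ramping 1.0 → 2.0 (strong,
unambiguous standardized effects); redundant features as round-robin
noisy copies of relevant parents (default jitter SD 0.3, parent–copy
correlation ≈ 0.96, the "tight technical duplicate" end of what
correlated ions exhibit); independent standard-normal noise features; and
Gaussian response noise (default SD 0.5). What it does **not** emulate:
missingness mechanisms, heteroscedastic intensity noise, retention-time
drift, non-linear responses, or correlated noise blocks — passing tests
therefore demonstrate correctness of the machinery and recoverability
under a clean linear-Gaussian ground truth, not performance on real
LC–MS data.

One consequence worth stating plainly: with parent–copy correlation 0.96
and n = 60, which of a parent and its copy carries more estimated mutual
information with the response is close to a coin flip, and the greedy
redundancy charge then pushes the loser far down the ranking. Recovery
experiments that insist on the *parents specifically* (rather than
parent-or-copy) therefore fail at a substantial rate at Stage 1, even
though the optimizer recovers planted signal reliably when the candidate
set contains it (the optimizer-only recovery study passes 10/10). This is
a structural property of greedy mRMR under near-duplicate features, not a
defect of the implementation, and is visible in the acceptance report's
`recovery_rate_pct` versus `optimizer_recovery_rate_pct`.

## Determinism and numerical choices

All randomness flows from one integer seed: the pipeline spawns child
seeds (NumPy `SeedSequence`) for the fold shuffle and the swarm, so an
identical config reproduces an identical result bit-for-bit, including
the serialized front CSV. Other conventions: MI clipped at zero against
round-off; constant features get correlation 0 (ranked last) with a
warning; a constant vector has MI 0 by the zero-entropy convention;
candidate sets of size 1 skip the swarm with a forced single-entry front;
PLS component caps are logged once per distinct cap. Multiple response
columns are processed one per run — fronts for different responses are
not comparable, so no joint mode is offered.

## Known limitations

- Histogram-MI ranking is the weakest link at n ≲ 60: its variance
  dominates feature separation long before the wrapper or the optimizer
  become limiting. The correlation filters are often the stronger Stage-1
  choice for roughly linear responses.
- The min-RMSE end of the front is selected on cross-validated error over
  thousands of candidate subsets and therefore carries winner's-curse
  optimism; treat reported front RMSEs as model-selection scores, not
  unbiased generalization estimates.
- The optimizer's budget (T × nPop evaluations) must grow with the
  candidate-set size; with D ≳ 100 and small budgets the front is
  exploratory rather than converged.
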