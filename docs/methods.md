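# Methods

`timemotion` analyses continuous direct-observation (time-motion) event logs
of clinical work, of the kind produced by multidimensional work-observation
methods: every task a clinician performs is recorded as a timestamped
interval carrying four dimension labels — *what* task, *where*, *how* it was
conducted, and with *whom* — together with interruption linkage and
overlapping intervals for multitasking. This note documents the models,
conventions, numerical choices and limitations behind each module.

## Time model and interval algebra

Timestamps are stored at one-second resolution and every interval is
half-open `[start, end)`. Two consequences drive everything downstream:
durations are exact integer seconds (no floating-point tolerance anywhere in
the interval engine), and adjacent tasks — one ending exactly when the next
starts — do not overlap.

Time on a slice ("drug-related documentation", "gathering information on
computer", …) is the *union* of the matching intervals within each session,
summed across sessions. Union semantics prevent double-counting when two
matching tasks overlap; summation across sessions reflects that wall-clock
overlap between different physicians' sessions is distinct observation time.
Because of multitasking, slice proportions are subadditive only per slice:
the sum over a family of category slices can legitimately exceed 100% of
observation time.

Production code uses sorted-merge unions, a two-pointer intersection and a
sweep-line concurrency segmentation, all O(n log n). The test suite re-derives
every operation from per-second boolean arrays — the brute-force oracle is
kept out of the production path on purpose.

## Estimators

* **Proportions of time.** The overall denominator is *scheduled session
  time* (total observation time), which may include seconds with no recorded
  task. Slice-specific ("group-specific") denominators use the denominator
  slice's own task time, and the numerator is the within-session intersection
  of numerator and denominator slices.
* **Multitask fraction** of a slice: seconds inside the slice's intervals
  during which the session's overall concurrency (counting all tasks, not
  just matching ones) is at least two, divided by the slice's task time.
* **Interruption rate**: interruptions are themselves task records
  (`is_interruption=True`) linked to the task they interrupt, whose interval
  must contain the interruption's start second. The overall rate divides the
  interruption count by total observation hours; slice-specific rates count
  interruptions starting while a slice-matching task (other than the
  interruption itself) is active, divided by slice task time. Whether tasks
  were interrupted is also reported instance-based (share of task instances
  hit at least once), which is deliberately distinct from the time-based
  rates.
* **Unknown / outside-department time** stays in the overall denominator;
  excluding it is not supported because the slice tables would no longer be
  self-consistent.

Display rounding is half-up to one decimal for percentages and minutes and
two decimals for agreement scores; machine-readable outputs keep full
precision, and all tests compare unrounded values.

## Resampling inference

Fourteen of the 31 physicians in the motivating study contributed two
sessions, so sessions of one physician are not independent. The resampling
unit is therefore the **physician** (configurable to session): the cluster
bootstrap resamples physicians with replacement to the original cluster
count, carrying all their sessions and records, and forms **percentile**
confidence intervals (default 10,000 replicates, level 0.95). Replicates on
which a statistic is undefined are dropped and counted; more than 10%
dropped aborts with an error. BCa was considered and rejected: the percentile
method is the simplest defensible choice and the replicate machinery does not
preclude adding BCa later.

The Monte Carlo group test permutes physicians' group labels (affiliation or
experience) preserving the empirical group sizes — including the 3:1
medical-to-surgical design — and recomputes the difference of group-wise
statistics (group-specific denominators arise naturally because each group's
statistic is evaluated on its own sessions). The two-sided p-value uses the
add-one formula `(1 + #{|T_perm| ≥ |T_obs|}) / (1 + B)`, so p ∈ (0, 1].

Statistics that are ratios of sums over clusters (time proportions, event
rates, session means — everything the pipeline reports) expose per-cluster
sufficient statistics; resampling then reduces to summing component rows,
which is exactly equivalent to recomputing on the rebuilt dataset (unions are
per-session and unaffected by surrounding clusters) and makes thousands of
replicates cheap. Arbitrary `statistic_fn(dataset) → float` callables are
supported through a slower rebuild path; a test asserts both paths produce
identical replicate values. All resampling is driven by a single seed;
per-call seeds are derived deterministically by hashing call identifiers, and
results are bit-reproducible for a fixed seed.

## Inter-rater agreement

Agreement between two observers of the same session is scored on aligned
one-second windows. Each window carries, per dimension, the *set* of labels
of tasks active during any part of the window (set-valued under
multitasking); uncovered windows get an idle sentinel so both sequences are
total over the common span.

The coefficient is **iota**, a multivariate generalisation of Cohen's kappa:
with per-window distance d(i) = Σ over dimensions of δ(Aᵢ, Bᵢ), observed
disagreement Dₒ is the mean distance over the n aligned windows, expected
disagreement Dₑ is the mean over all n² cross pairs (window i of observer A
against window j of observer B — Cohen-style per-observer marginals rather
than pooled Scott/Fleiss marginals, matching the "generalisation of Cohen's
kappa" framing), and the score is 1 − Dₒ/Dₑ. The set distance is
**1 − Jaccard similarity**, chosen because it degrades exactly to 0/1
mismatch for singleton labels: for a single dimension with singleton labels
iota reduces *identically* to Cohen's kappa, and that reduction is enforced
by tests. Dₑ is computed from value counts of the distinct label sets, so
cost is O(n + u²) rather than O(n²); the O(n²) double loop survives as a test
oracle. Dₑ = 0 (both observers constant and identical) makes the score
undefined and is signalled explicitly rather than returned as NaN.

Which dimensions enter the joint score is a caller choice (default: all
four); per-dimension kappas are reported alongside.

## Synthetic data generator

The generator is the stand-in for raw observation logs that studies of this
kind typically cannot deposit. It emulates, per physician and session:

* **Task sampling.** Categories are drawn with probability proportional to
  budget/mean-duration, so each category's expected share of *session* time
  equals its configured budget; durations are exponential with per-category
  means (minimal-assumption default; the machinery is distribution-agnostic).
  With probability `multitask_probability` the next task starts before the
  current one ends, with overlap uniform over the current task's duration;
  otherwise an exponential idle gap follows. The gap mean is solved in closed
  form from the budget sum, the mean task duration and the multitask
  probability, including a correction for the task truncated at session end
  (without it realized budgets run ≈1% low on two-hour sessions). Budgets may
  sum to more than 1 when multitasking is frequent enough; infeasible
  combinations raise a configuration error. Realized per-key budgets are
  recorded alongside the dataset as ground truth.
* **Interruptions.** A Poisson count at the configured rate per session hour,
  with event times placed uniformly over task-covered seconds. Placing events
  on covered time (rather than thinning events that land on idle seconds)
  keeps the realized overall rate unbiased for the configured intensity and
  guarantees every interruption has a resolvable target task. Interruption
  records carry their own what-category from a configurable interrupter
  distribution (default dominated by professional communication), so their
  time contributes to those categories *on top of* the configured budgets.
* **Patients.** New and follow-up counts per session are Poisson with
  configured means (default 2.0 and 0.7).
* **Groups.** Affiliations follow the 3:1 medical-to-surgical composition
  exactly (shuffled assignment, at least two physicians per group so group
  tests remain defined); experience is balanced 1:1.
* **Paired observer logs.** Observer B is a perturbed copy of the input log:
  task boundaries jittered by rounded Gaussian noise, labels confused per
  dimension with configured probabilities (respecting subcategory validity
  when the what-label changes), tasks dropped with a miss probability
  (dropping a task drops its interruptions), and interruption starts
  re-clamped into their target's interval so the perturbed log remains
  structurally valid.

A study-emulation preset ships with budgets set to the published per-category
time shares, per-category mean durations back-derived from published task
counts and hours, 4 interruptions/hour and 46 two-hour sessions (~92 h). It
is a demonstration preset: it reproduces headline magnitudes, not published
confidence-interval bounds.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: within-physician day effects and diurnal workload
variation, duration distributions heavier-tailed than exponential,
correlation between multitasking and category, interruption clustering
(bursts), and any dependence of patient counts on workload.

## Verification design and problem sizes

* Interval, concurrency and windowing operations are checked exactly against
  per-second arrays on 1,000 randomly generated sessions.
* Parameter recovery uses 200 two-hour sessions with a drug-related budget of
  0.18 and interruption intensity 4/h; tolerances (±0.018 on the proportion,
  ±0.47/h on the rate) were pre-computed as |bias| + 5 SD from 60 replicate
  simulations of that exact design.
* Bootstrap coverage is assessed on 500 simulated datasets of 40 single-session
  physicians at 500 replicates each, against 0.95 ± 3 binomial SE; the
  permutation test's size on 500 null datasets of 24 physicians at 199
  permutations, against 0.05 ± 3 binomial SE. These sizes keep the
  calibration suite to a few minutes while leaving the binomial bounds
  meaningful.
* Determinism is asserted at the byte level on rendered reports and generated
  CSV files.

## Known limitations

* No multi-rater (>2 observers) agreement; the windowing assumes paired
  observers of the same session.
* No parametric confidence intervals and no multiple-testing correction
  (none is applied in the motivating design).
* The interval engine is integer-second; sub-second timestamps are rejected
  at parse time rather than rounded silently.
* Slice-specific interruption rates attribute an interruption to the task(s)
  active at its start second; an interruption landing on two overlapping
  slices counts once per slice but once in the overall count.
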