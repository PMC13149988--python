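# Methods

## Sequence segmentation and schedule replay

A unit sequence is a maximal run of lever presses in which every
press-to-press gap is at most the pause threshold (default 3.0 s, strictly:
a gap of exactly 3.0 s does not split) and no head entry falls strictly
between two presses. Termination is recorded as `head_entry`, `pause`, or
`session_end` (a run cut by the end of the session is retained). The pause
is measured press-to-press, not press-to-any-event.

Press frequency is `(n_presses − 1) / duration` — the rate of inter-press
events. This convention makes "4 presses within 1 s" correspond to a ≥3 Hz
measured rate under the nominal 4 Hz schedule and is exact for metronomic
pressing. Single-press sequences have duration 0 and NaN frequency; they
are excluded from frequency-based statistics and from clustering (the
exclusion is explicit and logged via the returned index list).

Schedule replay reconstructs reward times from press times alone. FR1
rewards every press; NTC-FR4 every `ratio`-th press since the last reward.
TC-FR4 rewards press *k* when the most recent `ratio` presses since the
last reward span at most the time limit; after a reward the window
restarts, so presses consumed by one reward never count toward the next.
The restart is an interpretation of per-trial reward delivery; the sliding
window before the first reward means a slow start does not block a later
fast quadruple.

Rewarded status of a sequence is "any reward in [first press, termination
boundary)", with the boundary being the head-entry time, the next press, or
the session end, plus rewards coinciding exactly with the last press.

## Efficiency score

`S(x) = 2·φ(x|μ,σ)·Φ(x|μ,α)` with `φ = (2π)^(−1/2)·exp(−(x−μ)²/(2σ²))` and
`Φ = ½[1+erf(α(x−μ)/√2)]`; `efficiency(x_LEV, x_Hz) = 100·S(x_LEV)·S(x_Hz)`.

Two features are deliberate and load-bearing: φ carries **no 1/σ
prefactor**, and the CDF argument is **α(x−μ) without division by σ**. S is
therefore a positive unimodal score, not a normalized skew-normal density.
Defaults μ=2, σ=4, α=0.5, scale=100 live in `EfficiencyParams`, never in
code.

On the integer grid 1..12 × 1..12 the unique argmax is (4, 4). On a
continuous axis the 1-D maximum of S sits near x ≈ 4.12; the package
asserts only the integer-grid optimum and leaves the continuous offset as a
property of the printed formula. Numerically, Φ underflows to exactly 0 in
double precision once α(x−μ)/√2 < −6 (x ≲ −15 at defaults); positivity is
guaranteed on the kinematic domain (counts and rates ≥ 0) and tested there.

## Ward clustering

Features are presses/sequence, frequency/sequence, inter-sequence interval
(the first sequence, which has none, receives the session median;
configurable). Euclidean distance across a count, a rate, and a time is
unit-inconsistent, so features are z-scored per column by default; raw mode
exists for literal replication. Zero-variance columns are left unscaled
with a warning rather than producing NaNs.

The agglomeration is the Lance–Williams recurrence on squared Euclidean
distances,

    d²(u, i∪j) = [(nᵢ+nᵤ)d²(u,i) + (nⱼ+nᵤ)d²(u,j) − nᵤ d²(i,j)] / (nᵢ+nⱼ+nᵤ),

with each step merging the pair of minimal Ward cost (= d²/2, the increase
in within-cluster sum of squares) and ties broken toward the smallest
cluster-index pair, making the merge sequence deterministic given input
order. Heights follow the scipy convention (√d²), so the tree is directly
comparable to `scipy.cluster.hierarchy.linkage(·, "ward")`; the test suite
checks both that equivalence and merge-by-merge equality with an exhaustive
brute-force minimum-variance oracle on all instances up to 7 points.

Semantic classes: C1 = highest mean frequency cluster; C3 = higher mean
press count of the remaining two; C2 = the rest. An exact tie in either
statistic raises rather than guessing. Complete = C1 ∧ rewarded ∧
frequency strictly > 4 Hz; incomplete = C3 ∧ unrewarded.

Short/long duration bands take the lowest and highest 30% of the duration
distribution by stable rank (exactly `round(0.3·N)` each for distinct
durations); if the two cut values collide — e.g. all durations equal —
everything is labeled middle, never both short and long.

## Calcium processing

ΔF/F₀ = 100·(F − F₀)/F₀. The default baseline is a running 10th-percentile
filter over a 60 s window followed by a boxcar of the same width; it tracks
slow multiplicative drift while ignoring sparse transients. A low-order
polynomial fit to sub-threshold samples (below median + 1 robust SD) is the
alternative. Running-percentile baselines carry a small additive offset
under fast drift, so transient amplitudes should be read as peak minus
local pre-transient level; measured that way the generator's injected
amplitudes are recovered within 5% noiselessly.

Event detection thresholds both the height and the local prominence
(window ±5 s) of ΔF/F₀ maxima at `min_prominence` robust-noise units
(1.4826·MAD), default 3.5, with a 0.3 s minimum separation. Prominence
alone — with scipy's default unbounded base search — flags extreme noise
excursions; the added height requirement keeps the false-positive rate on
pure noise below 1 event/100 s at 5 MAD units. Both knobs are exposed, not
hidden.

Alignment snaps anchors floor-to-sample and slices half-open windows;
anchors whose window leaves the trace are dropped and logged. Event
probability is, per peri-anchor bin, the fraction of trials with ≥1 event.
Action-locked peaks are normalized by the peak of the same statistic over a
deterministic, evenly spaced anchor grid inside spontaneous epochs (all
times ≥10 s from any press, configurable margin). Population synchrony is
the mean off-diagonal Pearson coefficient of 10 s press-centered windows,
averaged across presses; zero-variance windows contribute NaN pairs that
are excluded and logged.

## Onset classification and associations

The dominant peak is the global maximum of the trial-averaged,
sequence-initiation-aligned curve within [−0.5, 5] s, ties toward the
earlier latency. Instant-onset: latency within ±0.5 s (inclusive).
Delayed-onset: latency in (0.5, 5] s. The significance gate compares the
peak against the 95th percentile of per-shuffle *maxima* over the same
window, where each of ≥100 shuffles circularly shifts all anchors by one
uniform offset; a pointwise band would flag the maximum of a null curve
with probability far above 5%. The gate is on by default and switchable.
The three labels partition the population; unclassified cells are excluded
from group averages but always counted.

Single-trial peak latency is the time of the largest-amplitude *detected*
event in (0.5, 5] after sequence initiation, absent when no event falls in
the window. Duration–latency and efficiency–activity associations are
ordinary least squares (slope, R², slope p) plus two-tailed Spearman rank
correlation, with pairwise deletion of absent values and explicit errors on
degenerate designs. "Session-normalized" population activity divides each
cell's single-trial peak by that cell's maximum trial peak in the session
and averages over cells.

## Synthetic sessions

The generator emulates the statistical structure the analyses assume, not
the animal or the optics. Behavior: sequences drawn from three latent
classes — fast-confined (log-normal inter-press intervals, mean 0.20 s,
4–6 presses), slow-confined (0.55 s, 3–5), slow-elongated (1.00 s, 6–10) —
with mixing proportions 0.46/0.295/0.245, inter-sequence gaps
exponential with mean 8 s floored at 3.5 s (always above the 3 s pause
threshold, so generated sequences segment exactly), head entries after 70%
of runs, and rewards placed exactly where schedule replay grants them.
Press-rate magnitudes are order-of-magnitude plausible choices, documented
here as assumptions. The suppression flag scales run length ×1.8 and
inter-press intervals ×1.6 — a phenotype-level model of interneuron
inactivation (more presses, elongated timing, lower efficiency), not a
biophysical one.

Calcium: raw = 100·drift·(1 + (signal + noise)/100), where drift is a ±5%
sinusoid over the session, noise is white Gaussian in ΔF/F₀-% units, and
signal sums unit-peak double-exponential transients (rise 0.1 s, decay
0.6 s — a GCaMP6f-like surrogate; config, not constants). Instant cells
fire at run start + base latency (|base| ≤ 0.5 s) + jitter; delayed cells
at base + coupling × run duration + jitter; tiled cells at a cell-specific
fraction of the run duration. Per-run emission is Bernoulli(reliability);
background transients are Poisson. One integer seed feeds spawned
per-component streams, so behavior and calcium are independently
reproducible and everything is bit-deterministic under a fixed seed.

What the generator does *not* emulate — bleaching, spatial footprints and
crosstalk, sensor nonlinearity, bursts of multiple transients per run,
non-stationary behavior within a session, between-animal variability — 
bounds what passing tests show: they validate the estimators against data
satisfying the model's assumptions, not robustness to real-data pathology.

## Problem sizes and numerical choices

Recovery experiments use sessions of 80–400 sequences and up to eight
cells at 10 Hz; the duration–latency recovery uses 400 sequences × 50
seeds with inter-trial gaps ≥ 6 s and duration support under ~5 s so the
(0.5, 5] single-trial search window is identifiable — with short gaps that
window can capture the *next* trial's response and bias the null slope.
Ward clustering is O(N²) memory and O(N³) via vectorized scans, adequate
for the few hundred sequences per session this pipeline targets. All
windows are half-open, anchor snapping floors to the sample grid, and the
correlation matrix is symmetric with unit diagonal by construction.

## Known limitations

* The efficiency formula's continuous optimum (~4.12) differs from the
  integer-grid optimum (4); only the latter is asserted.
* `label_complete_incomplete` requires k=3 clustering; other k values skip
  semantic labels.
* The percentile baseline biases ΔF/F₀ by a small additive offset under
  strong fast drift; amplitudes should be read relative to the local
  pre-event level.
* Replay assumes rewards coincide with press times (delivery latency below
  one behavioral-log tick).
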