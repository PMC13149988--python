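# leverseq

Analysis of operant lever-press action sequences and simultaneously
recorded single-cell calcium activity.

In temporally constrained fixed-ratio tasks (TC-FR4: four presses that must
fall within a time limit — 1 s for the "4 Hz" schedule), mice organize
pressing into discrete bouts. `leverseq` implements the full analysis chain
for such sessions:

* **Unit-sequence (SEQ) segmentation** — a sequence is a run of consecutive
  presses terminated by a head entry or a pause longer than 3 s; each
  sequence carries press count, duration, press frequency
  ((n−1)/duration), inter-sequence interval, and reward status obtained by
  replaying the schedule logic (FR1, NTC-FR4, or TC-FR4 with a restarting
  four-press window).
* **Sequence efficiency** — a skewed-Gaussian score
  `S(x) = 2·φ(x|μ,σ)·Φ(x|μ,α)` with
  `φ = (2π)^(−1/2)·exp(−(x−μ)²/(2σ²))` and
  `Φ = ½[1 + erf(α(x−μ)/√2)]`, combined over press count and frequency as
  `efficiency = 100·S(x_LEV)·S(x_Hz)`. With the defaults μ=2, σ=4, α=0.5
  the score over integer grids peaks at **4 presses at 4 Hz** — the optimum
  of the 4 Hz schedule.
* **Kinematic clustering** — Ward-linkage agglomerative clustering
  (Euclidean metric, z-scored features) of press count, frequency, and
  inter-sequence interval into three classes: C1 (fast, confined), C2, C3
  (slow, elongated); "complete" sequences are rewarded C1 sequences above
  4 Hz, "incomplete" are unrewarded C3 sequences.
* **Calcium analysis** — ΔF/F₀ against a running low-percentile baseline,
  MAD-thresholded transient detection, peri-event alignment, event
  probability curves, action-locked peaks normalized to spontaneous
  activity, and pairwise-correlation population synchrony over 10 s
  press-centered windows.
* **Onset classification** — cells whose sequence-aligned average peaks
  within ±0.5 s of initiation are *instant-onset*; 0.5–5 s after
  initiation, *delayed-onset*; peaks that fail a circular-shuffle
  max-statistic gate are *unclassified*. Trial-level regressions link
  single-trial peak latency to sequence duration and population activity
  to sequence efficiency.
* **Synthetic sessions** — a seeded generator emulating the task structure
  (three latent kinematic classes, schedule-consistent rewards, GCaMP6f-like
  transients for instant / delayed / tiled cell archetypes) with full
  latent ground truth, used by the test suite for oracle and recovery
  checks.

## Worked example

```python
from leverseq import PipelineConfig, run_pipeline, summarize_session

bundle = run_pipeline(PipelineConfig(scenario="tc_fr4_4hz", seed=7, n_shuffles=100))
print(summarize_session(bundle))
```

```
session: synth-TC-FR4-1201125462
sequences: 100

class summary:
class_label  n  mean_presses  mean_frequency_hz  mean_duration_s  mean_efficiency  frac_rewarded  percent
         C1 68         4.574              3.885            1.092           26.843          0.618   68.000
         C2 10         4.600              2.684            2.025           24.870          0.400   10.000
         C3 22         8.318              1.092            7.061            6.474          0.000   22.000

completeness:
  complete       37  (37.0%)
  incomplete     22  (22.0%)
  neither        41  (41.0%)

onset classes:
  instant          3
  delayed          5
  unclassified     0

population synchrony (mean off-diagonal r): 0.1119

associations:
  duration_latency: slope=0.4972 R2=0.9535 p=2.14e-58 rho=0.903 n=87
  efficiency_activity: slope=0.0038 R2=0.2782 p=1.72e-08 rho=0.374 n=100
```

Reading the output: the 100 simulated sequences fall into a fast/confined
class C1 (3.9 Hz mean, mostly rewarded, high efficiency), a small
intermediate C2, and a slow/elongated C3 (never rewarded under the 1 s
limit, low efficiency). 37 sequences are "complete" (rewarded, >4 Hz, C1)
and all 22 C3 sequences are "incomplete". The duration–latency regression
recovers the generator's 0.5 s/s coupling between sequence duration and
the delayed cells' response latency (slope 0.497), and session-normalized
population activity increases with sequence efficiency.

The same run is available from the shell:

```bash
leverseq run --scenario tc_fr4_4hz --seed 7 --out out/
leverseq score-map --out map.csv   # prints: argmax at (4 presses, 4 Hz) = 35.096
```

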