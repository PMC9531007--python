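# contextprofile

Unsupervised anomaly detection for sensor-based remote health monitoring,
built around the **Contextual Matrix Profile (CMP)** and its multidimensional
extension. The target setting is a household instrumented with passive
infrared (PIR) motion sensors (bathroom, bedroom, kitchen, lounge, hallway)
whose occupant — typically a person living with dementia — may experience
adverse events such as urinary tract infections (UTI) or hospitalizations.
Those events leave traces in daily movement patterns (night-time bathroom
visits, suppressed activity) long before anyone annotates them, so the
package scores each block of days by how unlike the patient's own history it
is, with no training labels.

## The method

For a daily feature series *x* of length *n*, all length-*m* subsequences are
compared by the z-normalised Euclidean distance
d(a, b) = ‖(a − μ_a)/σ_a − (b − μ_b)/σ_b‖, with trivial self-matches
(|i − j| < m/2) excluded. Subsequence start positions are tiled into
disjoint *contexts* of *c* consecutive starts, and the CMP cell

&nbsp;&nbsp;&nbsp;&nbsp;CMP[i, j] = min { d(a, b) : a ∈ context i, b ∈ context j }

is the block minimum of the distance matrix — denoised, configurable in
granularity, and resistant to an anomaly masking its duplicate. For the 11
engineered daily features (night/evening room counts, room dwell durations,
day-to-day 1-Wasserstein change of each room's hourly activity histogram),
the per-feature CMPs are stacked into an F × C × C tensor, each cell is
sorted across the feature axis, and layer *k* of the *k*-dimensional CMP
holds the mean of the k + 1 smallest distances per cell. The anomaly score
of context *i* is the (equal or inverse-hop weighted) average of its layer-k
distances to strictly past contexts; scores are flagged by sliding-window
robust-z / IQR / quantile rules and validated against weak labels inside a
−10/+7-day soft buffer. The sorted feature order of the stack doubles as an
explanation: the modal feature in dimension 0 is the patient's leading
digital biomarker.

Because the cohort that motivated this design is not public, the package
ships a seeded generative simulator (Poisson visits on circadian hourly rate
profiles, lognormal day-to-day noise, burst-expanded firings) that injects
UTI-like episodes (night bathroom rate ×3 for 3–8 days) and
hospitalization-like episodes (all activity ×0.1 for 2–10 days) with ground
truth.

## Worked example

```bash
python examples/detect_and_evaluate.py
```

simulates 6 patients × 365 days (2 UTI-like + 1 hospitalization-like episode
each), scores them with the equal-weighted multidimensional CMP at k = 1,
thresholds with robust z = 1.65 in a 7-day window, and prints:

```
mean recall:        83.3%
mean alerts raised: 21.2 (5.8% of observed days)
patients with >1/3 of events recalled: 6/6

cohort digital-biomarker ranking (median share of top slots):
bathroom_em          0.486
kitchen_em           0.177
bedroom_em           0.123
bathroom_le          0.119
...
```

Read: on average 83% of injected episodes are caught by at least one alert
inside the soft buffer, at ~23 alerts per patient-year (a single-digit alert
rate), and the feature most often responsible for the smallest cross-context
distance is midnight–6 AM bathroom activity — the nocturia signature of UTI.
Other examples cover the simulator (`simulate_cohort.py`), feature
engineering (`daily_features.py`), a single CMP (`contextual_matrix_profile.py`)
and multidimensional scoring with automatic k (`multidimensional_scoring.py`).

A thin CLI mirrors the stages for shell use:

```bash
contextprofile simulate --patients 10 --days 365 --seed 1 --out run/
contextprofile run --out run/ --model mdcmp-equal --k 1 \
    --method robust_z --window 7 --threshold 1.65
```

Every stage persists its artifact (events, features, scores, alerts,
evaluation, biomarker ranking) as CSV next to a resolved `config.yaml`;
reruns with the same seed are byte-identical.

## Layout

- `src/contextprofile/` — library: `synth`, `streams`, `features`, `cmp`,
  `multidim`, `entropy`, `scoring`, `thresholds`, `evaluation`, `config`,
  `pipeline`, `cli`
- `examples/` — runnable narrative scripts, one per capability
- `docs/methods.md` — model assumptions, parameter choices, limitations
- `tests/` — pytest suite with brute-force oracles for every core operation
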