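# Methods

## Problem and model

The package detects anomalous stretches of days in a patient's household
movement record, unsupervised and causal: at any day, only history up to that
day informs the score. The core object is the Contextual Matrix Profile
(CMP) of a daily feature series.

**Distance.** Two length-*m* subsequences are compared by the Euclidean
distance of their z-normalisations (population standard deviation). This
makes the comparison scale- and offset-free: what is matched is the *shape*
of a few days of behaviour, not its level. Degenerate windows follow the
matrix-profile ecosystem conventions — two constant windows are at distance
0, a constant against a non-constant window at √m (the norm of any
z-normalised vector). An exclusion zone |i − j| < ⌈m/2⌉ around the distance
matrix diagonal is masked to +∞ so a subsequence cannot match its own
neighbourhood; it is applied uniformly (also inside same-context blocks)
because adjacent contexts share m − 1 days. A `none` policy is
config-selectable for the cross-context reading.

**Contexts.** Subsequence start positions are tiled into disjoint blocks of
*c* consecutive starts; trailing starts that do not fill a block are dropped
so all cells aggregate equally many pairs. CMP[i, j] is the minimum finite
distance over the c × c block; a fully masked block is +∞ and is skipped by
scoring. Defaults m = 3 days, c = 3 subsequences: one scored segment per 3
days, each spanning 5 calendar days — granular enough to localise a 3–8-day
episode, coarse enough to denoise single odd days.

**Multidimensional CMP.** Per-feature CMPs (the 11 features below) are
stacked into an F × C × C tensor, sorted ascending per cell along the feature
axis (ties broken by lexicographic feature name for reproducible
attribution; +∞ sorts last), and layer k holds the per-cell mean of the
k + 1 smallest distances. Layer 0 is the cross-feature minimum, layer F − 1
the plain mean; layers are cellwise non-decreasing in k by construction.
Per-cell sorting means the *identity* of the contributing features may
change from cell to cell — the point of the construction: whichever couple
of behaviours is most aberrant in a segment drives that segment's score.

**Choosing k.** `k="auto"` computes the median of each layer's finite cells
(exclusion-zone cells excluded so they cannot move the result) and takes the
knee of this non-decreasing curve: both axes min-max normalised, knee =
first index maximising y − x, the max-distance-from-chord form of the
kneedle procedure at sensitivity 1. A flat or linear curve has no knee; the
fallback (and the fixed setting used throughout the evaluation defaults) is
k = 1, i.e. the two best features per cell.

**Scoring.** The anomaly score of context i is the mean of its finite
layer-k distances to strictly past contexts j < i — equal-weighted by
default, or inverse-hop weighted (weight 1/(i − j)). Context 0 is unscored.
Scores are dated by the context's last covered day. Univariate model tags
(sum, mean, median, max, apen, fuzzyen) instead score each feature's own CMP
and fuse per context; the entropy tags weight features by the inverse
approximate/fuzzy entropy of their raw daily series (trailing N = 500 days,
computed once per patient), flooring near-zero entropies at 1e-6 so a flat
feature dominates without producing NaN.

**Entropies.** ApEn(m_e, r) uses hard Chebyshev template matching with
self-matches included, Φ^m − Φ^{m+1}; FuzzyEn uses mean-subtracted templates,
exponential membership exp(−(d/r)^n) with gradient n = 2, self-matches
excluded and N − m templates for both lengths, −ln(φ^{m+1}/φ^m). Defaults
N = 500, r = 0.2 SD, m_e = 7. The tolerance is r·SD of the series, floored
at 1e-6 for flat series (where both statistics are exactly 0). The gradient
n is exposed in config; 2 is the common choice in the fuzzy-entropy
literature.

**Thresholding.** Each scored context is tested against all scores dated in
its trailing window (t − w, t], itself included, w ∈ {7, 14, 21, 30, 60, 90}
days. Robust z flags when 0.6745(x − median)/MAD exceeds the threshold
(1.65, 1.8, 3, 4); IQR flags above Q3 + thr·(Q3 − Q1) (1.0, 1.2); quantile
flags above the empirical q-quantile (0.95–0.98). Quartiles/quantiles use
linear interpolation between order statistics (the numpy default), fixed for
bit-reproducibility. Windows with fewer than 3 scores never flag — MAD and
IQR are not meaningful on fewer points and the series start would otherwise
alert spuriously. A zero-MAD window falls back to a conservative
median-exceedance test (logged).

**Evaluation.** An alert matches a label if its date lies in the closed
buffer [label − 10, label + 7] days — weak labels have imprecise onsets, and
early detection is the clinical goal. One alert may validate several labels
and vice versa (a label is recalled once). Reported: per-patient recall %,
alerts raised, alert rate % over observed (non-empty) days, precision %
(read relatively: unlabelled true anomalies — visitors, sensor faults —
depress it), and cohort unweighted means plus the number of patients with
recall strictly above one third. Patients with no labels are excluded from
recall aggregates; patients with no alerts from the precision mean.

**Biomarkers.** The default per-patient contribution of a feature is its
share of dimension-0 slots over finite upper-triangle cells ("top1"), i.e.
how often it produced the smallest cross-context distance; the modal such
feature is the patient's top biomarker (ties lexicographic). The
alternative "leq_k" metric (share of all slots in dimensions ≤ k) is
config-selectable but over-credits degenerate near-constant features: their
distances are exactly zero almost everywhere under the flat-window
convention, so they always occupy *some* low dimension by tie even though a
zero distance contributes nothing to the anomaly score. Cohort ranking is
the per-feature median contribution across patients.

## Synthetic cohort

The generator stands in for a private remote-monitoring cohort and produces
the study conditions the pipeline assumes rather than a fitted replica of
any real household.

Per patient: for each (day, location, hour), the number of *visits* is
Poisson(base_rate × day_factor × episode_multiplier); the day factor is
lognormal with σ = 0.15 and mean 1, shared across locations within a day
(the person's overall activity level that day); each visit receives a
uniform minute within its hour and is expanded into 1 + Poisson(2)
consecutive firings so that run-collapsing in ingestion is exercised
non-trivially. Base hourly profiles (visits/hour) are chosen once for
circadian plausibility: bathroom bimodal morning/evening with a
nocturia-scale night base (0.15/h ⇒ ~0.9 night visits), bedroom night-loaded,
kitchen meal peaks, lounge a daytime plateau, hallway flat transit. Episodes
are placed uniformly at random with ≥ 14 clean days between them: UTI-like
episodes multiply the night (00:00–06:00) bathroom rate by 3 and the night
bedroom rate by 1.5 for 3–8 days; hospitalization-like episodes multiply all
rates by 0.1 for 2–10 days. One label per episode at its start date.
Everything is a pure function of (seed, patient index).

What the simulator does **not** model: carers, pets and visitors as distinct
agents; door/appliance/physiological modalities; seasonal or weekly
structure; sensor dropouts and clock drift; gradual behavioural drift.
Passing recovery tests therefore show that the pipeline detects the two
injected episode archetypes under realistic Poisson noise — not that it
attains any particular recall on real households.

## Feature engineering

Consecutive firings from the same sensor are collapsed to runs; counts are
run (visit) counts by default because burst length is hardware chatter
rather than behaviour (`counts="raw"` preserves the literal firing-count
alternative). Dwell at a run's location is next run's first firing minus
this run's last firing, split across midnights, capped at 1440 min/day, with
zero tail dwell for the final run (`duration="span"` selects the common PIR
alternative, next-first minus this-first). Circadian windows are half-open
wall-clock intervals: early morning [00:00, 06:00) of the day, late evening
[18:00, 24:00) of the *previous* day. The day-to-day change feature is the
first-order Wasserstein distance (summed |CDF difference|, unit ground
distance between adjacent hours) between consecutive days' 24-bin hourly
run histograms; a day with no activity at a location maps to the uniform
histogram, so a dead day reads as maximally spread — the hospitalization
signature. Days with no events at all are flagged missing and zero-filled
(the calendar must be contiguous for the CMP); evaluation denominates alert
rates by observed days only. The dwell rule looks one firing ahead, so the
current day's duration is provisional until the next firing arrives — at a
live streaming edge the last day's features can still change, which is why
the causality guarantee is stated at the level of the daily feature series.

## Numerical choices and scaled-down problem sizes

- CMP distances are computed by vectorised z-normalisation + `scipy` cdist;
  the brute-force definition is the contract, and tests require entrywise
  agreement within 1e-8 (the block minimum amplifies no error).
- Entropy implementations are checked against O(N²) double-loop references
  within 1e-10 up to N = 300.
- The episode-recovery evaluation runs 10 patients × 365 days with 2
  UTI-like + 1 hospitalization-like episodes each — enough contexts (121 per
  patient) for stable medians while a full run stays in seconds; the
  package's own defaults (15 × 624) reproduce the cohort scale of interest.
- `optimal_k` degenerates gracefully: all-constant layer medians, or any
  curve without an interior bend, return the k = 1 fallback.

## Known limitations

- z-normalised distance is amplitude-blind: a uniformly elevated but
  equally-shaped week looks normal. Detection of level shifts rides on shape
  breaks (onsets, offsets) and on the Wasserstein and duration features.
- Count features at low rates are heavily quantised; exact shape ties are
  common, which is why tie handling and the flat-window conventions are
  spelled out and tested.
- Robust z over a 7-day window sees only ~3 context scores; with MAD that
  small-sample the rule is deliberately conservative below 3 scores and
  falls back to median-exceedance at MAD = 0.
- No alert cool-down or deduplication: consecutive anomalous contexts each
  alert, matching the day-denominated alert-rate accounting.
- Cross-feature correlation is not modelled in scoring or in the simulator.
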