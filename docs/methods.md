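# Methods

## Model

Each 4-category ordinal item is modelled by the pair (P, r): the upper three
categories *some*, *much*, *most* carry probabilities P, Pr, Pr² (a geometric
progression with common ratio r) and *rarely* absorbs the remainder,
1 − P(r² + r + 1). The model is marginal per item; no dependence between items
is modelled. Admissibility requires P > 0, r > 0 and P(r² + r + 1) ≤ 1 — the
last constraint is forced by non-negativity of the "rarely" probability and is
enforced at `ModelParams` construction. P = 0 is excluded (r would be
unidentifiable); P exactly at the bound (p_rarely = 0) is allowed.

Closed forms used throughout:

* expected item score: P(3r² + 2r + 1) under Likert (0-1-2-3) weights,
  P(r² + r + 1) under binary (0-1-1-1) weights; the difference P(2r² + r) is
  non-negative, so binary totals never exceed Likert totals;
* log-linearity: log p_some, log p_much, log p_most are collinear with slope
  log r;
* crossing point: for fixed r, the line segments joining (0, p_rarely) to
  (1, p_some) for every admissible P pass through
  x = (r²+r+1)/(r²+r+2), y = 1/(r²+r+2), hence x + y = 1. The category axis
  convention is rarely=0, some=1, much=2, most=3.

## Estimators

**Ratio estimator** (the descriptive workhorse): P̂ = n_some/n_total and
r̂ = (n_much/n_some + n_most/n_much)/2, the mean of the two successive
frequency ratios. The defining text for this estimator is ambiguous as
typeset; the mean-of-ratios reading is the only one that yields a ratio
estimate of a common ratio, and is what this package implements. Zero-count
conventions: n_some = 0 leaves both parameters undefined; n_much = 0 with
n_most > 0 leaves r̂ undefined (mass beyond an empty middle category);
n_much = n_most = 0 gives r̂ = 0. Undefined estimates are reported and skipped
(not imputed) when averaging parameters within an age group. r̂ is *not*
clamped to the validity region — it is a descriptive statistic.

**MLE**: maximizes the multinomial log-likelihood over the validity region in
the reparameterization (u, r), u = P(r²+r+1) ∈ (0,1), which makes the
constraint automatic. Numerically: Nelder-Mead multi-start (from the ratio
estimate and from (0.1, 0.5); xatol 1e-12), followed by a stationarity polish —
in (u, r) the score equations separate into u* = (n₁+n₂+n₃)/n and a quadratic
(2−q)r² + (1−q)r − q = 0 with q = (n₂+2n₃)/(n₁+n₂+n₃), whose positive root is
the unique interior critical point; it is adopted when not worse than the
numeric optimum beyond float noise. This makes the MLE exact (≪1e-9) on counts
lying inside the model family. The MLE is undefined when all mass is in
"rarely".

**Log-linear slope**: the 3-point OLS slope of log frequency against category
index over (some, much, most), which reduces to (log f_most − log f_some)/2;
undefined when any of the three counts is zero. Parallelism verdict: slope
spread (max − min) ≤ 0.15 natural-log units by default. The threshold is a
package default (the parallel-lines claim in the source analysis is visual);
it is configurable everywhere it is used.

## Scoring

Subscales: depressive mood {3,6,9,10,14,17,18}, somatic/retarded
{1,2,5,7,11,13,20}, interpersonal {15,19}, positive affect {4,8,12,16}; the
first three form the 16 negative items. Positive items are reverse-scored
(s → 3 − s) before totalling; binary recoding (score ≥ 1 → 1) is applied
*after* reversal by default, since the binary method targets symptom presence
and reversal is what maps a positive item onto the distress scale. The
pre-reversal ordering is available (`binary_totals(..., reverse_first=False)`);
the two differ only on the 4 positive items, never on the 16-item totals.

## Pipeline

Exclusion rules run in a fixed order — uniform response pattern (all 20 raw
codes 0, or all 3), then missing key variables, then age above the cap
(default 89) — and each row is attributed to the first rule it trips, making
the exclusion report reproducible. The uniform-pattern rule reads raw codes,
not reverse-scored ones ("rarely throughout" or "most throughout" regardless
of item direction). Age bins are the eight inclusive decades 12–19 … 80–89.
The Likert-vs-binary trajectory comparison is restricted to ages ≤ 79 by
default and contrasts the 70–79 group with the pooled (respondent-weighted)
30–39/40–49/50–59 groups. Group mean parameters are unweighted means over the
16 per-item estimates; crossing-point residuals evaluate each item's
rarely→some relative-frequency segment at the crossing abscissa implied by the
group mean r.

## Synthetic data generator

The generator emulates the survey shape the analysis assumes: eight age bins,
uniform integer ages within bins, 16 negative items drawn independently per
respondent from the bin's (P, r), 4 positive items drawn from a free 4-vector
of scored-value probabilities and stored in raw coding (raw = 3 − scored), and
an injected round(invalid_fraction × n) subset of all-0/all-3 responders
(default 2%).

Default scenario (illustrative choices, not estimates from any dataset —
the source analysis prints its fitted parameters only as figures): per-bin
mean r = (0.45, 0.42, 0.34, 0.33, 0.33, 0.38, 0.52, 0.55) — a U across age —
and mean P = (0.20, 0.21, 0.21, 0.21, 0.20, 0.18, 0.16, 0.19) — comparatively
flat, declining through 50–79 with its minimum at 70–79 and an uptick at
80–89. These magnitudes keep expected Likert item scores in a plausible
0.3–0.6 band and were fixed analytically so that the documented qualitative
contrasts hold at the distribution level: at 70–79, P(3r²+2r+1) exceeds the
pooled 30–59 value by ≈0.043 per item while P(r²+r+1) falls short by ≈0.012,
producing the Likert-up/binary-down reversal. Items within a bin share r —
the shared ratio is precisely what makes their log-scale lines parallel — and
differ only through mean-zero jitter (±0.01) on P, drawn once from a fixed
internal seed so the scenario is deterministic. Positive items use the scored
distribution (0.35, 0.35, 0.20, 0.10), constant across bins (plateau-shaped).

What the generator does **not** emulate: stratified community sampling,
nonresponse, item-level missingness patterns, or any dependence between items.
Passing tests therefore demonstrate correctness of the estimators and pipeline
under the model's own assumptions, not robustness to correlated items or
informative missingness in real surveys.

## Numerical choices and problem sizes

Closed-form identities are asserted at 1e-12 and linear-system/crossing
results at 1e-10; these are simple arithmetic and need no looser bands.
Parameter-recovery checks use n = 10,000 draws per (P, r) cell over
P ∈ {0.1, 0.2, 0.3} × r ∈ {0.25, 0.5, 0.75} with tolerances |P̂−P| < 0.02,
|r̂−r| < 0.05. Trajectory analyses run at 2,500 respondents per bin (20,000
total), where the reversal contrasts are several Monte-Carlo standard errors
wide; the parallelism verdict is exercised at 10,000 per bin, where the
slope-spread noise floor sits below the 0.15 threshold. All simulations are
seeded and reproducible.

## Known limitations

* The ratio estimator has no standard errors or confidence intervals here,
  matching its descriptive role; no goodness-of-fit test is provided.
* The MLE's boundary cases (all upper mass in "most", q → 2) have no finite
  maximizer; the optimizer returns a large-r approximation.
* Real-data features outside the model (item dependence, differential item
  functioning by age, missingness mechanisms) are out of scope.
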