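# Methods

`semforage` analyses verbal-fluency response logs as a foraging process in
semantic memory. This note documents the models, the conventions behind each
computed measure, the synthetic-cohort generator, and the numerical choices.

## The scoring model

A fluency session is a sequence of single-word responses to a polysemous cue,
each labeled with the cue meaning it refers to. Responses are classified as
**clustering** (same meaning as the previous response) or **switching**
(different meaning); the first response of a cue is **initial** and carries
no transition label.

Per response we compute:

- **IRT** (inter-response time, s). Spoken mode: onset of the response minus
  offset of the previous one; undefined for the first response. Typed mode:
  previous validation keypress to first keypress of the current response,
  plus a thinking-time correction `max(0, measured_typing − n_chars /
  fastest_cps)`, where `fastest_cps` is the participant's maximum typing
  speed over responses longer than four characters. The typed first response
  has an IRT from trial start; it enters marginal values but never the
  transition-typed statistics.
- **IRS** (inter-response similarity): cosine of the word-embedding vectors
  of consecutive words; undefined when either word lacks a vector (misses
  are counted and reported).
- **IRTr, IRSr**: the ratio of IRT (IRS) to the participant's *per-cue
  marginal value*, the arithmetic mean of that cue's defined IRTs (IRSs).
  Because the denominator is the mean of the same values, the per-cue mean
  IRTr is exactly 1 — a structural identity the tests assert at 1e−9. The
  *long-term* IRT/IRS reported per participant is the mean of the per-cue
  marginals (response → cue → participant averaging is used everywhere).
  IRSr is left undefined when the cue's marginal IRS is within 1e−6 of zero.
- **Speed**: fast if IRTr < 1, slow if IRTr ≥ 1. The boundary is assigned to
  "slow" so the partition is exhaustive; on continuous data the boundary has
  measure zero.
- **Switch-relative positions**: for each switching response S, the up-to-two
  clustering responses immediately before it are −2, −1 and the up-to-two
  immediately after (before any further switch) are +1, +2. A clustering
  response squeezed between two switches keeps both roles (+k of the earlier
  switch, −k of the later one); statistics operate on the long anchor table,
  one row per (switch, position).

Under the marginal value theorem (MVT), a forager should leave a semantic
patch when its local return rate falls to the environment-wide average:
clustering responses should be fast (IRTr < 1) and switching responses slow
(IRTr > 1). Crossing speed with transition yields four response types;
fast switching and slow clustering are the MVT-deviant patterns of interest.

## Statistical battery

- **Position tests**: paired Wilcoxon signed-rank of the switching IRTr
  (IRSr) against the clustering value at each position, across participants,
  optionally restricted to fast or slow governing switches. The exact null
  distribution is used for up to 25 untied pairs, the normal approximation
  with continuity correction beyond; zero differences are dropped before
  ranking (standard signed-rank convention). The reported statistic is W⁺,
  the sum of positive-difference ranks.
- **Ramping test**: paired Wilcoxon of IRTr at position −1 vs −2 — does
  retrieval slow down as the forager approaches a switch?
- **Optimality regression**: OLS of fluency on the pre-switch gap
  |pre-switch IRT − long-term IRT|. A negative slope means participants who
  leave clusters near their marginal value retrieve more items. R² is the
  squared Pearson correlation (asserted to 1e−10); F = R²(n−2)/(1−R²).
- **IRT→IRS mixed model**: IRS ~ IRT + response rank with crossed random
  intercepts for participant and cue, fitted by REML (BFGS, then L-BFGS,
  then Powell; OLS fallback with a flag if none converges). The reported R²
  is marginal (fixed-effects variance over total).
- **Correlation battery**: Spearman correlations (mid-rank ties, pairwise
  deletion) of response-type counts against executive/creativity scores,
  Benjamini–Hochberg-adjusted within the declared family; two-sided by
  default with a one-sided replication mode.

## Connectome-based predictive modeling

Edges are the strict upper triangle of symmetric, unit-diagonal
connectivity matrices (symmetrized by averaging when asymmetry ≤ 1e−6,
rejected otherwise). In each leave-one-out fold, edges whose Pearson
correlation with behavior passes p < α (default 0.01; implemented as a
critical |r| threshold, exactly equivalent for continuous data) form
positive and negative masks; per-subject mask strengths (edge-weight sums)
and mean framewise displacement enter an OLS model fitted on the training
subjects and evaluated on the held-out one. Folds in which both masks are
empty predict from intercept and motion alone and are flagged. Prediction
quality is the Spearman ρ of predicted vs observed; the final masks are the
intersection of the fold masks. The permutation test reruns the entire
cross-validated pipeline under shuffled behavior, with
p = (1 + #{ρ_null ≥ ρ}) / (n_perm + 1) (default 1000 permutations).
Per-fold selection statistics are derived from full-cohort column sums, so a
fold costs two matrix–vector products over the edge matrix rather than a
centered copy (which would be prohibitive at atlas scale).

## Mediation

Single-mediator mediation with all variables z-scored once on the full
sample: a from m~x, (b, c′) from y~m+x, c from y~x; indirect = a·b, and
c = c′ + a·b holds exactly for nested OLS (asserted at 1e−10). The
confidence interval is the percentile interval (default 95%, 5000 resamples)
of the indirect effect over bootstrap resamples of the standardized rows;
degenerate resamples are redrawn (at most 10 rounds). The percentile — not
bias-corrected — interval is used, matching the 2.5th/97.5th-percentile
convention of the analysis this implements.

## The synthetic-cohort generator

### Semantic space

Each cue has `n_meanings` abstract meanings; meaning centroids are drawn on
the unit sphere and member words are centroid + isotropic noise,
renormalized. Words are eccentricity-graded: noise scales from 0.5× to 1.5×
`within_sd` across a meaning's pool, so low-index words are prototypical.
With `within_sd = 0` all words of a meaning coincide (within-meaning cosine
exactly 1); within-meaning similarity exceeds between-meaning similarity for
any `within_sd < 0.5`.

### The foraging agent

Within a cluster the agent's IRTs are lognormal with arithmetic mean
`mu_cluster · ramp^(position−1)` (patch depletion) and log-scale SD
`noise_sd`. Its marginal-value estimate is the running mean of the IRTs
emitted so far (it cannot know the final long-term IRT mid-trial). Before
each retrieval it compares the *prospective* next within-cluster IRT with
`threshold_frac ×` the running mean: above threshold it switches (IRT =
`mu_cluster` + `switch_cost`), below it continues. Two deviations are
injected per decision: with probability `p_fast_switch` a below-threshold
decision becomes a switch at within-cluster speed with no travel cost
(over-exploration), and with probability `p_slow_cluster` an above-threshold
decision persists in the depleted cluster, paying the switch-scale retrieval
cost while keeping the meaning (over-exploitation). Words are retrieved
central-first (with mild stochastic skipping) and without replacement, which
couples retrieval depth to falling similarity — the generative source of
the negative IRT→IRS relation the mixed model recovers.

`threshold_frac` (default 0.85) makes the agent leave slightly before its
marginal value. This mirrors the empirical pattern that mean pre-switch IRT
ratios sit below 1, and it gives the zero-noise policy a strict margin: with
no noise and no deviants, every clustering IRT lies below the final cue mean
and every switch IRT above it, so the scored pattern "switching IRTr > 1 >
clustering IRTr" holds for *every* response, exactly.

Default policy (chosen once to match the spoken-mode study conditions:
1-minute trials, ~15 responses per cue, long-term IRT ≈ 3.5–4 s, ~14% fast
switching and ~20% slow clustering):

| parameter        | default | units | role |
|------------------|---------|-------|------|
| `mu_cluster`     | 2.0     | s     | first within-cluster IRT after a switch |
| `switch_cost`    | 3.0     | s     | travel cost between clusters |
| `ramp`           | 1.3     | —     | depletion growth per within-cluster item |
| `p_fast_switch`  | 0.15    | —     | over-exploration rate |
| `p_slow_cluster` | 0.20    | —     | over-exploitation rate |
| `noise_sd`       | 0.25    | log s | lognormal IRT noise |
| `trial_duration` | 60      | s     | time budget per cue |
| `threshold_frac` | 0.85    | —     | fraction of the running mean that triggers a switch |

The ramp magnitude is a free parameter (no published value constrains it);
1.3 was chosen so cluster runs last 2–4 items with a clear −2 → −1 ramp.
Offsets are onset + 0.4 s of articulation; the separation is irrelevant to
downstream statistics, which only use IRT differences.

### Cohort structure

Latent brain factors u (one per MVT-deviant pattern) drive planted
connectivity edges (`±beta · z(u)` on disjoint upper-triangle edge sets over
a N(0, `edge_noise_sd`) background, unit diagonal). Search-pattern traits
m = a_true·u + √(1−a_true²)ε set each participant's deviant rates
(`p_fast_switch + p_fs_slope · m`, clipped); participants also vary in time
scale (lognormal, `scale_sd`) and threshold fraction (`kappa_sd`).
Creativity scores are built from the *true* deviant counts — CAT accuracy
from fast switches, AUT fluency/uniqueness from slow clustering — as
b_true·z(count) + c′_true·z(strength) + noise, with noise sized so the
count→creativity R² is ≈ 0.1–0.2, comparable to the modest correlations such
studies report. Executive scores load on the slow-switch count. Defaults:
86 participants, 3 cues, 200 nodes, beta = 0.3, a_true = 0.4, b_true = 0.3.

### What the generator does and does not emulate

It reproduces the statistical skeleton the analysis assumes: MVT-consistent
timing with tunable deviations, meaning-clustered embeddings, edge-level
brain–behavior effects with a motion nuisance, and a mediated
brain → search-pattern → creativity chain. It does **not** emulate real
lexical statistics or polysemy (meanings are abstract clusters), dynamic
drift of the marginal value over a trial, BOLD time series (matrices are
generated directly), or response-level semantics of creativity scoring.
Switch rates run somewhat above the empirical ~30% of responses. Passing
recovery tests therefore certifies the pipeline's correctness and
calibration on data satisfying its assumptions — not the cognitive validity
of those assumptions on human data.

## Recovery-experiment design and problem sizes

- **Deviant-rate recovery** runs at `noise_sd = 0` with 200 sessions per
  rate: only the zero-noise policy makes the scored classes coincide exactly
  with the generating events (at rate 0 the binomial interval is the single
  point 0, so any noise leakage would be a false failure). Binomial
  denominators are the generator's recorded decision-opportunity counts.
- **Mediation recovery** uses 300 participants × 49 cues with homogeneous
  exposure (`scale_sd = kappa_sd = 0`, `p_fs_slope = 0.07`): the mediator is
  a count, so its reliability as a proxy for the latent trait (~0.95 under
  these conditions, ~0.8 with default heterogeneity) bounds the recoverable
  a-path. Estimates are averaged over three replicate cohorts to keep
  sampling noise (per-cohort correlation SD ≈ 0.05) well inside the ±0.1
  recovery band. Bootstrap-CI coverage is measured on 100 replicates of the
  latent mediated triple at 500 resamples.
- **CPM calibration** uses 30 subjects × 20 nodes with 199 permutations and
  200 null replicates; power uses planted beta = 1.0 over five positive and
  two negative edges.

## Numerical choices

- Exact Wilcoxon only for untied |differences| (the exact signed-rank null
  assumes distinct ranks); ties at n ≤ 25 fall back to the corrected normal
  approximation.
- Edge selection thresholds on |r| > r_crit(α, n−2), algebraically identical
  to p < α and cheaper inside the permutation loop.
- All randomness flows through `numpy.random.Generator`; the pipeline
  derives per-stage child seeds from the master seed via `SeedSequence`
  spawn keys with a fixed stage registry, so adding a stage never perturbs
  earlier stages' streams. Identical seeds give byte-identical outputs.
- Degenerate inputs raise typed errors (`DataError`, `FormatError`,
  `NumericError`, `DegenerateTestError`) naming the offending row, word, or
  column; cues with no defined IRT and participants with no switches are
  dropped/flagged with warnings rather than silently imputed.

## Known limitations

- The exact Wilcoxon path requires untied magnitudes; heavily discretized
  data always use the approximation.
- The crossed-random-intercept model can fail to converge on small cohorts;
  the OLS fallback is flagged but changes the variance-component story.
- The CPM permutation test reruns the full LOO pipeline and scales linearly
  in permutations × subjects; atlas-scale runs (200 nodes, 86 subjects,
  199 permutations) take ~30 s on one CPU.
- Mediation assumes the usual single-mediator OLS structure; no sensitivity
  analysis for unobserved confounding is provided.
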