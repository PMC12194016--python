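# Methods

## Timing decomposition

Every item log is an ordered click stream with one terminal event
(submit, or timeout at the item's time limit, default 90 s).  ToT is the
terminal-event time.  Consecutive click pairs split into interrule gaps
(rules differ) and intrarule gaps (same rule), so that

    first_click + Σ inter_gaps + Σ intra_gaps + (terminal − last_click) = ToT

holds exactly for every log (a tested invariant).  Items with fewer than
two rules carry no information about processing structure and are
excluded from analysis.

**Interrule aggregation.**  The per-item interrule value is the summed
between-rule gap time divided by a configurable denominator: observed
transitions (default), number of rules, or rules − 1.  Per-transition is
the default because it is the only choice that does not inflate when
extra rule jumps multiply the transition count; the alternatives are one
flag away (`ExtractionConfig.inter_denominator`).

**Onset residualization.**  The first-click time confounds global
orientation with the first rule's planning gap.  The onset is computed
as the residual of an OLS regression of first-click time on the item's
interrule time, pooled over all participant-items, recentred by the
grand mean of the first-click time so it keeps the seconds scale and a
positive mean.  The construct (orientation time purged of planning time)
requires the first-click time to be the response; the opposite direction
— the literal reading of the published analysis sentence, which is
ambiguous — is available via `onset_direction="inter_on_first"`, and
per-item rather than pooled regressions via
`pool_residualization="per_item"`.  A constant predictor degenerates to
centring with a warning.  Residuals are orthogonal to the predictor by
construction (|r| < 1e-8, tested).

## Scores

* Rule-jump score: executed between-rule transitions minus (rules − 1);
  negative values are possible for abandoned items and are kept, since
  they still order participants by jump economy.
* Test score: count of exactly-correct final selections over analysed
  items (toggle-replay semantics decide the final selection).
* Acceleration ΔM: head ⌊n/3⌋ minus tail ⌊n/3⌋ item means in
  administration order (7 vs 7 items for the 22-item bank), middle
  discarded.
* RtD slope: within-participant OLS slope of item ToT on sample-
  estimated difficulty 1 − P; both variables are z-scored within the
  participant by default so the slope is the correlation and is
  comparable across participants (raw-seconds slopes optional).  The
  published analyses do not state the scaling; scale-free is the safer
  default for between-person comparison.
* IAP: an item is an incomplete attempt when termination occurs before
  every rule received at least one click on its symbol group.  Global
  IAP is the participant mean; current IAP is the group-mean-centred
  remainder (mean 0 per participant by construction).
* Classical item statistics: P (column mean), item-rest Pearson r,
  Cronbach's α in the variance form k/(k−1)(1 − Σσ²ᵢ/σ²_total); α equals
  the covariance-form computation to 1e-12 (tested).

## Statistical stage

* **Quadratic ToT effect.**  z(score) ~ z(ToT) + z(ToT)² with all
  columns standardized, so coefficients are standardized βs; F-change
  against the linear model on (1, n−3) df.
* **Clustering.**  Ward linkage on Euclidean distance over z-standardized
  (score, interrule) — the Ward.D2 convention, i.e. merge heights are
  √(2·ΔSSE), which scipy implements; heights match an exhaustive O(n³)
  agglomeration oracle on small instances (tested exactly).  k is chosen
  by maximum average silhouette over k ∈ [2, 10]; if every candidate
  silhouette is below 0.25 the solution is flagged weak and k = 1 is
  admissible.  A participant bootstrap (default 100 resamples) records
  the silhouette distribution and pairwise co-assignment agreement with
  the full-sample labels.  The downstream strategy dichotomy (group
  comparisons, mediation, hierarchical regression) always uses the
  two-cluster cut of the tree: the substantive hypotheses concern two
  strategy groups, and the selected k is reported alongside as a
  structure diagnostic.  The higher-scoring cluster is labelled
  structured.
* **Mediation.**  Recursive path model x → {m1, m2} → y on standardized
  variables, estimated equation-by-equation by OLS (intra ~ inter;
  jumps ~ inter; score ~ inter + intra + jumps).  The mediator residual
  covariance is fixed to zero — the single over-identifying restriction
  (df = 1) — and the fit indices derive from the ML discrepancy between
  the implied and sample correlation matrices: χ² = (n−1)·F_ML (the n−1
  convention), RMSEA = √(max(χ²−df,0)/(df(n−1))), CFI against the
  independence baseline, SRMR as the RMS of the standardized residual
  matrix (diagonal included).  Freeing the residual covariance yields
  the saturated model (χ² = 0, df = 0), a config flag.  total = direct +
  a₁b₁ + a₂b₂ is an exact OLS identity and is asserted to 1e-8.
  Indirect-effect CIs are percentile bootstrap over participant
  resamples (default B = 1000); point estimates do not depend on the
  bootstrap seed.
* **Hierarchical regression.**  score ~ ToT, then + onset + inter +
  intra, all standardized.  Unique R² is the drop in full-model R² when
  a predictor is removed (squared semipartial); VIF = 1/(1−R²ⱼ); exact
  collinearity aborts with the offending predictor(s) named.  F-change
  on (3, n−5) df.
* **IAP mixed model.**  response ~ global IAP + current IAP with crossed
  random intercepts for participant and item, fitted by REML
  (statsmodels MixedLM, variance-component formulation; lbfgs with a
  powell fallback); Wald p-values for fixed effects.  Non-convergence
  raises rather than returning silently.
* **Incremental validity.**  Nested OLS ΔR² with F-change on (1, n−3)
  df; an addition that is an exact linear function of the covariate
  returns ΔR² = 0.
* Cohen's d uses the pooled SD even next to the Welch t, matching common
  reporting practice in this literature.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes —
not the cognitive process itself (no diffusion/IRT response-time
model).  Per participant: a strategy class (structured with probability
0.56), ability θ ~ N(+0.8, 0.8²) (structured) or N(−0.8, 0.8²)
(unstructured), a general log-normal pace factor with class-specific SD
(0.08 structured, 0.30 unstructured — the unstructured class is markedly
more heterogeneous in tempo), and latent RtD slope and IAP propensity.
Per item, rules are processed in order; before each rule a planning gap
is drawn log-normally with location log(16 s) − 0.14·θ (structured) or
log(4.5 s) (unstructured), declining geometrically with test position at
a rate that grows with θ only in the structured class; onset locations
start at 19 s, decline with position, and shorten with θ for everyone;
within-rule gaps (1.3 s scale) are scaled by the participant's gap
latent (coupling 0.25); extra rule jumps arrive Poisson with log-rate
−1.2/−0.1 (structured/unstructured) plus 0.25·z(gap latent) and are
realised as instantaneous excursions — a toggle plus immediate
toggle-back on an earlier rule's unused symbol — so they perturb jump
and transition counts without changing the final selection; each rule is
solved with probability logistic(θ − b − 0.2·jumps − 0.5·[unstructured]),
the last term representing goal-management failure on multi-rule items;
rule difficulties are N(−0.70, 0.5²).  Abandonment (probability = the
Beta(0.2, 20) IAP propensity) attempts only a prefix of the rules and
times out; the whole item's gap budget is multiplied by
(1 + RtD·difficulty); all events past the 90-s limit are censored and
replaced by a timeout terminal.  The first click occurs at onset + first
planning gap, so first-click times are genuinely confounded and the
onset residualization has something to recover (tested: the residualized
onset correlates more strongly with the latent onset than the raw
first-click time does).

Log-normal families are used throughout because response-time components
are positive and right-skewed and only location/scale information is
available for the real data.  Default values were calibrated once so
that cohort descriptives reproduce the qualitative pattern of the
published clusters — unstructured: low score with a floor effect, short
interrule gaps, more jumps, wide ToT spread; structured: the reverse,
with an inverted-U between score and ToT across the mixture — at
pattern level only, never value-matched.  What passing tests show is
therefore that the pipeline recovers structure of this kind when it is
present; they cannot show that real click streams contain it, nor
calibrate effect sizes for real data.  Features of real data the
generator does not emulate: post-error checking, within-item strategy
switches, fatigue beyond geometric practice decline, and symbol-level
motor variation.

## Problem sizes and numerics

Validation runs use the study's design sizes where that is cheap
(cohorts of 200 × 22; mediation recovery at n = 5000; the crossed mixed
model at 200 × 22) and scaled-down replicate counts where many refits
are needed (e.g., 100 null replications at 40 × 8 for the mixed-model
p-value calibration, 20 cohort seeds for recovery medians).  Determinism
is enforced by routing all randomness through named substreams of one
root seed; pipeline outputs are byte-identical across runs with the same
seed.  Degenerate inputs (constant predictors, zero-variance items,
all-identical feature rows, items without clicks) are either handled
with a documented fallback and warning or rejected with a specific
error, as listed per function in the API docstrings.

## Known limitations

* The onset residualization direction and pooling level in the source
  analyses are ambiguous; both are config switches, defaults documented
  above.
* The mediation model is exactly the 4-variable recursive path model; no
  latent variables, no FIML for missing data.
* Silhouette-based k selection on elongated clusters can prefer k = 3;
  the strategy dichotomy therefore pins the two-cluster cut (see above).
* External validation against a second test score is supported as a
  library call (`incremental_r2`) but no second-test data generator is
  bundled.
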