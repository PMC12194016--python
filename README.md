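# matrixlft

Process-data analysis for **construction-based figural matrix tests**:
decompose click-stream time on task into its cognitive components, score
the structuredness of item processing, and run the statistical battery
that links both to test performance.

In a construction-based matrix test (e.g., the DESIGMA) the participant
composes the answer by clicking symbols in a construction kit; every
symbol belongs to a symbol group, and every group realises one logical
rule (addition, subtraction, intersection, ...).  The timestamped click
log therefore segments each item's total **time on task** (ToT) into
three *log-file times* (LFTs):

* **onset time** — global orientation before the first rule is engaged.
  The raw first-click time confounds this with the first rule's planning
  time, so the onset is the residual of the first-click time after
  regressing out the interrule time (recentred to the seconds scale);
* **interrule time** — gaps between clicks on *different* rules, read as
  the construction of a rule-specific solution plan (the high-demand
  cognitive component);
* **intrarule time** — gaps between clicks within the *same* rule, the
  behavioural execution of the plan,

plus the **rule-jump score** (executed minus necessary between-rule
transitions, necessary = number of rules − 1), the acceleration of each
measure across the test (first-third minus last-third mean, ΔM), and two
motivation indicators: the **RtD slope** (intraindividual regression of
item time on item difficulty 1 − P) and the **IAP** (incomplete attempt
propensity, split into a participant-level global part and an item-level
centred current part).

The statistical stage implements: the quadratic ToT effect
(score ~ z(ToT) + z(ToT)²), Ward/Euclidean agglomerative clustering of
standardized (score, interrule time) with silhouette-based selection of
k and a participant bootstrap, Welch t comparisons with Cohen's d, a
4-variable parallel mediation path model (interrule → {intrarule,
rule jumps} → score) with ML fit indices (χ², CFI, RMSEA, SRMR) and
percentile-bootstrap indirect effects, a hierarchical regression (ToT
only vs ToT + LFTs) with unique R² and VIFs, a linear mixed model with
crossed random intercepts (participant, item) for the IAP, and nested
incremental-validity comparisons.

Because the raw study data are not bundled, the package ships a
synthetic cohort generator that plants exactly the structure the
analysis assumes (a structured/unstructured strategy mixture,
ability-dependent planning gaps, a mediation channel, abandonment and
difficulty-sensitive time investment, 90-s right-censoring) together
with its ground truth, so every stage is testable end to end.

## Worked example

```bash
matrixlft run --out report --seed 7 --bootstrap 300 --cluster-bootstrap 30
```

simulates a default cohort (200 participants × 22 multi-rule items),
extracts features and writes `report/` with CSV tables, `report.md` and
a manifest.  The summary from this exact command:

```
- Cronbach's alpha (score): 0.91
- Quadratic ToT effect: beta_quad = -0.27 (p = 0.000), R2_quad = 8.00%,
  delta R2 vs linear = 6.70% (F(1, 197) = 14.35, p = 0.000)
- structured vs unstructured on score: t(141.22) = 14.92, p = 0.000, d = 2.08
- structured vs unstructured on inter: t(139.82) = 25.05, p = 0.000, d = 3.50
- structured vs unstructured on rule_jump_score: t(194.77) = -15.91, p = 0.000, d = -2.24
- structured, inter: dM = 1.78 (p = 0.000), r with score = 0.40 (p = 0.000)
- unstructured, inter: dM = 0.09 (p = 0.420), r with score = 0.01 (p = 0.919)
```

Reading: the score is internally consistent (α = .91); score and mean
ToT show the inverted-U (negative quadratic β); the higher-scoring
cluster plans longer between rules (d = 3.50) and jumps less
(d = −2.24); and only in that structured cluster does the *interrule*
acceleration across the test correlate with performance (r = .40 vs
.01) — the planted signature that the interrule gaps carry the
cognitive component.

The same stages are available as `matrixlft simulate`, `extract`,
`analyze` and `report`, and as plain library calls
(`generate_cohort`, `build_feature_table`, `ward_cluster`,
`mediation_path`, ...).  On-disk formats are documented in
`docs/schemas/`; the model and its assumptions in `docs/methods.md`.

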