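# Methods notes

This note records the modelling conventions, generator assumptions, numerical
choices and known limitations behind `opheno`.  Nothing here is an empirical
claim beyond what the test suite and `scripts/acceptance.py` compute.

## Schedule state machines

Sessions are walked in continuous time (seconds from session start) over an
ordered press stream; presses with equal timestamps are processed in input
order (stable).  Conventions that the literature leaves open and that we fix:

- **Time-outs** are half-open intervals `[t_pellet, t_pellet + 10 s)`; a
  press exactly at time-out end is countable.  Presses inside a time-out or
  the pellet-free period are recorded with `countable = false` but are never
  discarded.
- **FR session structure.**  The stated session composition (25 min + 10 min
  + 55 min) is arithmetically inconsistent with the stated 1-h session
  length, so the default long protocol is 25/10/25 min (1 h) and the short
  protocol 55/10/55 min (2 h); all three period durations are configurable,
  and zero-length free/second periods model a single continuous pellet
  period.  The ratio counter persists across the pellet-free period.
- **Progressive ratio.**  One continuous period, requirement escalating along
  the fixed 35-step series; a 10-s time-out follows each pellet; session ends
  at the 5-h cap or 1 h after the last lever response.  Breaking point with
  zero completed ratios is defined as 0.
- **Shock session.**  FR5 blocks; 4th countable press → shock only, 5th →
  shock + pellet + time-out.  If the 5th response does not occur within 60 s
  of the 4th, the counter resets to zero, and the 4th press of the new block
  again delivers a shock (literal reading of the schedule being
  "reinitiated"; the alternative — no repeated shock — is not modelled).
- Presses at or beyond session end are dropped with a warning.

Each machine is checked event-for-event against an independently written
brute-force walk (interval-membership bookkeeping, prefix recounting) on
hundreds of random streams per run.

## Synthetic cohort generator

Each virtual mouse is a latent trait vector: active/inactive Poisson press
rates (presses/min), a pellet-free rate multiplier (persistence factor), a
motivation cap (largest PR requirement it will complete), a per-shock
continuation probability, and an FR1 learning gain.  Traits are sampled
lognormally (mean-parameterised) except the continuation probability, which
is logistic-normal; a group is a set of (location, scale) pairs.  Group-level
biology (genotype, circuit manipulations) is represented **only** as trait
distribution shifts.

Press emission is open-loop for FR sessions (a piecewise Poisson process,
independent of pellet delivery) and closed-loop where behaviour must react to
events: the PR policy quits when the requirement exceeds the motivation cap,
and the shock-session generator stops pressing permanently after the first
shock the mouse does not tolerate (absorbing suppression — the simplest
mechanism that yields a graded shock count).

Default trait locations (control: active rate 6/min, persistence factor
0.35, motivation cap 60, shock continuation 0.35; vulnerable: 7/min, 1.1,
400, 0.80) are free parameters — per-session press-rate distributions are
not published — chosen so that control mice earn tens of pellets per 1-h FR5
session and vulnerable shifts are large, planted effects.  They are fixed
once here and not tuned per analysis.

What the generator does **not** emulate: within-session satiation and
circadian drift, inter-session autocorrelation beyond the FR1 learning ramp,
correlated criteria in control animals (real criteria correlate; a
`correlation` knob exists in the null-score generator but independence is
the default because it admits the analytic check below), cue-light effects,
and any pharmacology.  Passing tests therefore validate the pipeline's
logic and statistics, not the biological realism of any particular cohort.

## Classification conventions

- Criterion flag: score **≥** control 75th percentile ("equal or beyond");
  a strict `>` mode exists.  Percentiles use linear interpolation between
  order statistics (NumPy's default inclusive convention).
- Persistence aggregates the 3 pre-PR sessions by arithmetic mean.
- Acquisition: some 3 consecutive sessions with <20 % deviation of each
  session's reinforcers from the triple mean, ≥75 % active-lever responding,
  and ≥5 reinforcers per session.
- Exclusion: a mouse is excluded iff it responded (≥1 reinforcer) in <25 %
  of FR5 sessions **and** never met acquisition (conjunction, literal
  reading of the rule; "responded" as ≥1 reinforcer is an interpretation).
- Thresholds are always computed on the control group only.

**Discreteness.**  The analytic control addicted fraction, 15.625 %, holds
for continuous independent criteria.  Breaking points live on the 35-value
series and shock counts are small integers, so percentile ties under the ≥
convention flag more than 25 % of controls per criterion; mechanistically
simulated control cohorts therefore classify ~20–25 % addicted rather than
15.6 %.  This is a property of the published rule applied to discrete
scores, not an implementation artefact.  The calibration check consequently
runs on `simulate_null_scores`, a first-class continuous null population
(lognormal persistence and motivation, gamma compulsivity), and lands within
binomial error of 15.625 %.

## Statistics

Mann–Whitney U is reported with the min-U convention and a two-sided p
(exact for small tie-free samples via SciPy, normal approximation with tie
correction otherwise).  The classification chi-square is a 1-df
goodness-of-fit of observed addicted/non-addicted counts against expected
counts under the control proportion; Yates correction is off by default
(flag available).  No multiple-testing correction is applied by default; a
Bonferroni helper exists.  Stars follow the 0.05/0.01/0.001 convention.  In
replicate studies where a 50-mouse control group can produce a degenerate
0 % addicted proportion, the proportion is clipped to 1/(2n) before the
chi-square (Haldane-style continuity), a convention of the study harness
rather than of the test itself.

## Differential-expression stage

- **Size factors**: median over all-positive genes of the count/geometric
  mean ratio, rescaled to geometric mean 1 (so factors are comparable across
  cohorts); estimation is scale-equivariant, and an optional pseudocount
  handles matrices with no universally expressed gene.
- **Dispersion**: per-gene method of moments on normalized counts, pooled
  within conditions (n−2 df), floored at 1e-8, with **no information sharing
  across genes** — a deliberate desk-scale simplification; parity with any
  specific DE package is a non-goal.
- **Test**: exact conditional test of the two raw condition sums given their
  total, each sum moment-matched to a negative binomial.  Plugging in the
  noisy per-gene dispersion makes this anticonservative at small n (genes
  with underestimated dispersion dominate the p < 0.01 tail, inflating it to
  2–3 %), so the p-value is averaged over the sampling distribution of the
  variance estimate — scaled inverse-chi-square with n−2 df, evaluated at 16
  fixed mid-point quantiles (deterministic quadrature; set
  `variance_quadrature=1` for the plain plug-in test).  This is the same
  logic that turns a z-test into a t-test, and restores ~1 % type-I error at
  the 1 % level with 5 samples per group.
- **Selection filter**: |FC| > 1.5 in either direction (the printed
  threshold is directionless), raw p < 0.01, and mean *normalized* counts >
  40 in either condition.  Fold changes are raw normalized-mean ratios (no
  shrinkage).  BH adjustment at FDR 0.1 is reported alongside but the
  published filter uses raw p.
- **PCA**: top-500 variance genes of log2(normalized + 1), sample-centred
  SVD; deterministic up to sign.
- Simulated matrices are NB with variance mu + alpha·mu², lognormal base
  means, per-sample depth factors and planted fold changes; dispersion 0.05
  (typical for brain bulk RNA-seq) and 5 samples/group are the default study
  conditions.

## Determinism and problem sizes

A single master seed is expanded through NumPy `SeedSequence` into per-mouse
substreams, so cohorts are reproducible independent of iteration order; the
CLI pipeline is byte-identical across runs at a fixed seed (the run manifest
carries wall-clock provenance and is excluded from that comparison).
Replicate studies use desk-scale sizes chosen for quick laptop runs: 2×1000
mice for control calibration, 100 replicates of 50/50 cohorts (FR5 reduced
to the 3 scored pre-PR sessions) for planted-effect recovery, 2000
Mann–Whitney null replicates, and 3000–5000-gene matrices for the DE stage.

## Known limitations

- The schedule machines model lever/pellet/shock contingencies only; cue
  lights and box hardware are represented at most as log markers.
- The generator's traits map one-to-one onto the three criteria; real
  behaviour couples them (e.g., press rate affects both persistence and
  shock exposure) — only that coupling induced through the schedules is
  present.
- The DE stage tests two conditions with no covariates, interactions or
  paired designs.
- Repeated-measures and two-way ANOVAs used for session-curve analyses are
  out of scope; standard statistics packages cover them.
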