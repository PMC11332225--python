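# Methods

This note documents the models, conventions and numerical choices behind
`srttlearn`, and what the synthetic-data tests do and do not establish about
real data.

## Task and design conventions

The SRTT is an 8-choice cued keypress task. Blocks hold 48 presses; in
sequential runs the stimuli cycle the fixed pattern 4-7-3-8-6-2-5-1 (six
repetitions per block, each block starting at the first element, so the six
8-press repetition windows coincide with sequence traversals — a requirement
for the per-repetition micro measures). Pseudorandom runs contain each
location exactly once per 8-trial window with no consecutive repeats, window
and block boundaries included.

Session 1 (both designs): familiarization (1 block, never analyzed),
pre-learning random (4), training (16), post-learning test (4), post-learning
random (4). The consolidation design adds sessions at ~5 h and ~24 h, each
with 4 sequential retest and 4 random retest blocks. Group labels use
contiguous age brackets (7–<13, 13–<18, 18–35, 55–75); ages 36–54 are
rejected by the validator because neither window was sampled.

## Preprocessing

- **Exclusion**: RT outside mean ± k·SD (default k = 3) of its own 48-press
  block. The bounds are computed once from all 48 presses (correct and
  incorrect; sample SD) — no iterative re-trimming — so flagging is
  idempotent. Whether the original criterion used correct-only presses is
  not determinable from the measure definitions; using all presses is the
  recorded default and the window is switchable via `k`.
- **Aggregation**: block mean RT over included correct presses (missing when
  none); accuracy = % correct of included presses. Excluded presses leave
  both RT and accuracy aggregation.
- **Normalization**: every block measure is divided by the participant's
  mean over the four session-1 pre-random blocks; accuracy is normalized by
  the same rule. Participants without a complete usable pre-random run are
  dropped with a logged reason. A `raw_mode` flag passes raw values through
  the norm fields for non-normalized re-analysis.

## Measures and sign conventions

For an RT outcome, lower is better; verbal definitions of "difference"
measures are therefore sign-ambiguous. This package orients **every** measure
so that positive = better performance:

- learning magnitude `LM = (R̄ − S̄)/R̄` (sequence faster than random → +);
- micro-online `rep1(n) − rep6(n)`; micro-offline `rep6(n) − rep1(n+1)`;
- macro-offline `test − retest` (faster at retest → +);
- ΔLM = retest LM − session-1 LM.

Group-difference statistics (F, p, |g|, R²) are invariant to this choice.
Repetition means average trial-level normalized RT over the included correct
presses of each 8-press window; empty windows propagate missingness (how the
original analysis handled such windows is unstated; propagation is the
conservative choice). LM is computed on speed by default; the accuracy
variant exists but is not part of the reference battery.

## Synthetic cohort generator

The generator is specified on the normalized scale (1 = pre-learning
baseline). Familiarization and pre-random blocks sit exactly at baseline;
from training onset the expected normalized RT of repetition `r` in a block
is

    h = exp( −A_g (1 − e^(−r_g t)) − [seq] A_s (1 − e^(−r_s b))
             + δ (r − 1) − j J )

with `t` the cumulative analyzed block since training onset (training 1–16,
test 17–20, post-random 21–24), `b` the cumulative sequential block
(training 1–16, test 17–20), `J` the completed rest intervals since training
onset, `δ` a linear within-block drift (positive = slowing, a reactive-
inhibition stand-in) and `j` the per-rest micro-offline jump. Counting rest
intervals cumulatively across the session's runs (rather than per run) keeps
the post-test at the training plateau instead of jumping back by 15·j.
Retest runs are frozen at their session-1 counterpart state — four retest
blocks are treated as expression of the consolidated memory, not further
learning — and shifted by the session gain **on the normalized scale**:

    expected_norm = h − gain_5h·[session 2] − gain_24h·[session 3]

so the macro-offline measures recover the planted gains exactly in the
noise-free limit (the package's closed-form oracle, `expected_norm_rt`).
Observed RTs are lognormal, `rt = baseline_rt · expected_norm · e^N(0,σ)`
(RTs are positive and right-skewed, which makes the 3-SD rule bite
realistically); with probability `outlier_rate` a trial is multiplied by
Uniform(3, 8). Accuracy is Bernoulli; wrong responses are uniform over the
seven non-target keys.

Per-participant parameters are drawn from group-level normal distributions
(clipped to validity bounds) using a child random stream derived from the
master seed and participant index, so cohorts are bit-reproducible. The
group **means** are fabrications chosen to reproduce the qualitative lifespan
pattern: slower baselines in children (650 ms) and older adults (550 ms)
than adolescents/young adults (480/420 ms); smaller sequence-specific
amplitude in children (0.06 vs 0.09–0.10); larger offline gains in children
(0.05 / 0.12 normalized units at 5 h / 24 h) than young adults (0.00 / 0.05)
and a 24 h deficit in older adults (−0.02); slightly larger rest-interval
jumps in children. Between-subject SDs (0.03 for the sequence amplitude,
0.06 for the offline gains) were set so that group contrasts land in the
range of standardized effect sizes typical of lifespan SRTT cohorts (|g|
roughly 0.5–2.5) rather than being trivially separable. Defaults for the
within-block dynamics (δ = 0.002/repetition, j = 0.004–0.006/rest) have no
quantitative empirical anchor and stay config-exposed. Accuracy ~0.94–0.96,
lognormal σ ~0.12–0.15 and 2% contamination yield stable ~95% accuracy and
trial-exclusion rates of 1–3%, the order observed in web-acquired SRTT data.

A continuous-age mode draws ages uniformly on 7–35 and plants
`seq_amp(age) = 0.12 − 0.00039 (age − 24)²` (floored at 0.005; the floor
never binds on 7–35). Because the learning magnitude is, at fixed age, a
monotone transform of `seq_amp`, the planted peak age transfers exactly to
the LM trajectory; the curvature sits below the quadratic coefficient scale
that lifespan LM fits report, so trajectory-recovery tests are conservative.

**What the generator does not emulate**: psychologically mechanistic RT
distributions (no drift-diffusion), post-error slowing, fatigue beyond the
linear drift, learning within the pre-random baseline, continued learning at
retest, or item-level sequence knowledge. Passing recovery tests therefore
shows the *pipeline arithmetic and statistics* are sound under a realistic
noise model — not that these parametric forms describe real participants.

## Statistics

- **One-way ANOVA**: classical SS decomposition; η² = SSB/SST with a 95% CI
  by noncentral-F inversion (λ bounds via Steiger's method, mapped through
  η² = λ/(λ+N)).
- **Mixed ANOVA**: one between (group) × one within factor, complete
  balanced-within designs only (incomplete participants are listwise-deleted
  upstream, mirroring run-wise exclusion of unusable data). The F table
  comes from pingouin; Greenhouse-Geisser ε multiplies the within and
  interaction dfs when Mauchly's test rejects at α = 0.05 (for m = 2 levels
  sphericity holds and ε = 1 analytically). Unbalanced group sizes use the
  standard cell-means partitioning. A within factor with one level
  degenerates to the one-way ANOVA.
- **Pairwise**: Tukey HSD from the studentized-range distribution (pooled
  MSW); Hedges' g = J·d with J = 1 − 3/(4·df − 1) and a noncentral-t CI.
- **Bayes factors**: t statistics get the exact JZS BF10 (Cauchy prior,
  scale √2/2, one-dimensional quadrature over the inverse-gamma mixing
  variable). ANOVA effects and regression blocks use the BIC approximation
  BF10 = exp((BIC_reduced − BIC_full)/2); repeated-measures models carry a
  subject random intercept (ML fit) in both the full and reduced models, so
  the ANOVA null is the subject random effect alone. BIC Bayes factors agree
  with default g-prior implementations at the evidence-category level, not
  digit-for-digit; the JZS t-test BF is exact.
- **Moderated regression**: OLS of a macro-offline gain on the mean
  micro-offline gain with dummy-coded groups (young adults as reference) and
  group × micro interactions; the interaction-block BF compares the model
  with and without all interaction terms.
- **Reporting**: dfs are the conventional (k−1, N−k) etc.; effects with
  0.05 < p < 0.1 are flagged as non-significant trends.

## Age trajectories and power

Five candidate forms (linear, quadratic, power a·x^b, single and double
exponential) are fitted within each sampled age window separately (7–35 and
55–75; never jointly across the unsampled gap). Polynomials are solved in
closed form; nonlinear forms use multi-start least squares (moment-based
starts from log/log-linear regressions where signs permit, plus random
starts from documented ranges, fixed seed; exponent arguments are clipped at
±700 to avoid overflow). Selection minimizes the Gaussian AIC
`n·ln(RSS/n) + 2(p+1)` — the error variance counts as a parameter, the same
convention for every form, so rankings are comparable — with ties broken
toward fewer parameters. A form that converges from no start is excluded
from selection rather than failing the fit. AIC rankings are invariant to
adding a constant to y only for forms with an intercept-like parameter
(linear, quadratic); the power/exponential forms are not translation
equivariant. The quadratic's vertex −b/(2c) is reported as the peak age.

Power uses the noncentral F distribution: λ = f²N for one-way designs;
repeated-measures designs multiply by m/(1+(m−1)ρ) for between effects and
m/(1−ρ) for within/interaction effects, with dfs (k−1, N−k) and
((k−1)(m−1), (N−k)(m−1)) respectively. λ = 0 returns power = α exactly
(scipy's noncentral F is unreliable at zero noncentrality). The
interaction convention is the primary path for repeated-measures
sample-size planning; the between-effect formula is available. Sample-size
search walks N upward in multiples of k (equal groups).

## Problem sizes in the validation studies

The calibration and recovery studies generate only the runs their measure
consumes (e.g. pre-random + post-test + retest for macro gains), which
changes nothing about the measure's sampling distribution but keeps many
replicates cheap: type-I calibration uses 500 cohorts of 27/group with all
group parameters set to the young-adult means; gain recovery uses 20 default
cohorts of 27/group; trajectory recovery uses 50 continuous-age cohorts of
n = 98. The full-pipeline runtime check analyzes a complete 108-participant
consolidation cohort (233k keypresses) end to end.

## Known limitations

- The mixed ANOVA covers exactly one between and one within factor; no
  linear mixed-effects (REML) machinery, by design.
- BIC Bayes factors are approximations; evidence categories, not digits,
  are the contract.
- The double-exponential form is weakly identified on 29-point windows and
  occasionally out-competes a true quadratic by AIC (~7% of simulated
  cohorts) — a property of AIC with flexible non-nested families, not a
  defect of the fitter.
- The validator checks structural invariants, not behavioral plausibility
  (it will accept, e.g., constant 1 ms RTs).
- No loader for external repository layouts; data must be mapped to the
  documented CSV schema (one row per keypress, lower-snake-case columns).
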