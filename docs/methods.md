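# Methods

## Generative observer

A session is a sequence of trials with signed stimulus strength `x`
(motion coherence in percent; negative leftward, positive rightward). The
observer holds two latent functions:

- decisions: `P(right | x) = λ/2 + (1 − λ)·Φ((x − μ)/σ)` with lapse rate
  λ (default 0, so the model the fits assume is exactly the model
  simulated);
- confidence: `P(low | x) = f + a·exp(−(x − μ_c)²/(2σ_c²))`, a raised
  Gaussian with floor `f` and amplitude `a`, `f + a ≤ 1`.

Choices and confidence are independent Bernoulli draws given those
probabilities. This is deliberately the simplest observer that makes the
diagnostic logic exact; see *Limitations* for what it leaves out.

### Mechanisms

- **Sensory shift** δ: both functions translate, `μ → μ + δ`,
  `μ_c → μ_c + δ`. A rightward adaptor is represented by δ > 0: it raises
  the PSE (ambiguous tests are seen as moving leftward), the classic
  contrastive aftereffect.
- **Decision bias** (γ, b): `p′ = (1 − γu)·p + γu·b`, where
  `u(x) = exp(−(x − μ_c)²/(2σ_c²))` is the uncertainty bell normalized to
  peak 1 and `b ∈ {0, 1}` is the default direction. The exact functional
  form of a "bias that scales with uncertainty" is underdetermined by a
  verbal description; this mixture was chosen because it (i) leaves the
  confidence distribution exactly unchanged, (ii) shifts decisions in
  proportion to low confidence, and (iii) produces the expected asymmetric
  decision functions. Normalizing `u` to peak 1 decouples bias strength (γ
  alone) from the observer's confidence calibration (`a`, `f`).
- **Serial observer**: per trial, a sensory-shift component of magnitude
  `delta_1back` whose sign follows the previous stimulus direction (PSE
  convention: rightward antecedent ⇒ positive PSE shift, i.e. contrastive),
  applied to both functions; plus a decision-bias component whose default
  repeats the direction of the stimulus two back (assimilative), with
  compliance `gamma_2back`, decisions only. The bias gate uses the
  *shifted* bell — the default rule operates on whatever currently counts
  as ambiguous. The first one/two trials of a block run the missing lag
  component in its neutral state.

### Designs

Three presets mirror the study conditions this package models:
`exp1`/`exp2` use 11 levels (±30, ±20, ±10, ±6, ±3, 0) × 10 repeats × 2
half-block conditions = 220 trials; `exp3` uses 8 levels (±30, ±15, ±5,
±1; 0 excluded so every antecedent has a direction) × 55 repeats = 440
trials. Conditions reverse at the block midpoint; order within each
half-block is a uniform random permutation. One master seed governs a run;
per-subject streams are spawned from it, so any subject is individually
reproducible.

### Cohort distributions

Observer parameters for simulated cohorts are drawn from truncated normals
matching the baseline group statistics of the modelled task: `μ ~
N(−0.43, 1.60)`, `σ ~ N(6.32, 4.31)` truncated at 2, `μ_c ~ N(−0.51,
1.03)`, `σ_c ~ N(5.37, 1.90)` truncated at 1.5 (all in coherence %). The
confidence amplitude and floor are not identifiable from published group
summaries; they default to `a ≈ 0.8`, `f ≈ 0.05` (an observer who reports
low confidence on ~85% of fully ambiguous trials and ~5% of easy ones),
with small between-subject spread. Default manipulation magnitudes — shift
±10%, cue compliance γ = 0.8, serial `delta_1back` = 3%, `gamma_2back` =
0.3 — produce group effects of the same order as the empirical ones
(ΔPSE ≈ 20, ≈ 14, ≈ 6, ≈ 5 respectively).

## Fitting

Both response functions are fit by binomial maximum likelihood on
per-level counts (MLE rather than least squares: it weights unequal trial
counts correctly and is the standard reading of "psychometric function
fit"). Optimization is deterministic: a fixed coarse grid over the
location/scale parameters is scanned vectorized, the three best starts are
polished by bounded local search (L-BFGS-B for the 2-parameter decision
fit; SLSQP for the 4-parameter confidence fit, which carries the linear
constraint `f + a ≤ 1`; the solution is projected back onto the constraint
to remove SLSQP's tolerance-level violation), and ties are broken toward
the smallest |μ|. Bounds: `μ, μ_c ∈ [−60, 60]`, `σ, σ_c ∈ [0.5, 60]`,
`a ∈ [0.01, 1]`, `f ∈ [0, 0.5]`. The fitted decision model has no lapse
term (documented limitation: a true lapse inflates σ̂ slightly but leaves
μ̂ nearly unbiased by symmetry).

**Peak detection.** A raised Gaussian fit to a flat confidence profile is
degenerate: the optimizer can park a narrow bell between sampled levels
with arbitrary amplitude. The fit is therefore marked non-converged unless
it beats a flat constant-rate model by a likelihood-ratio margin exceeding
the χ²(3) 95% point — "no detectable uncertainty peak" — in addition to
requiring fitted amplitude > 0.05.

**Adequacy screen** (per subject; mirrors excluding participants whose
judgements "could not be adequately modelled"): non-convergence of either
fit, |PSE| or |peak| beyond the largest stimulus level, σ or σ_c beyond
the full 60% stimulus range, or amplitude < 0.05. Subjects failing the
screen are dropped from cohort analyses and listed with reasons in the
report.

## Aftereffect estimation and diagnosis

`Δ = right-context estimate − left-context estimate`, separately for the
decision PSE (ΔPSE) and the confidence peak (ΔCONF). Under this convention
a contrastive aftereffect (adaptation, 1-back) is positive and an
assimilative one (congruent cue, 2-back repetition) negative; magnitudes
are reported as |Δ| where a summary calls for them. n-back splits assign
trial *t* by the sign of the stimulus at *t − k* within the same block
only, dropping the first *k* trials per block. A baseline estimate of
exactly 0 joins the positive group in sign-split analyses (measure-zero
event; fixed for determinism).

The diagnosis computes three one-sample JZS Bayes factors — on ΔPSE, on
ΔCONF, and on the per-subject difference ΔPSE − ΔCONF — and labels the
group: *perceptual* (BF_dec > 3, BF_conf > 3, BF_diff < 1), *decisional*
(BF_dec > 3, BF_conf < 1, BF_diff > 3), *indeterminate* (BF_dec < 3),
otherwise *mixed*. The 3/1 cutoffs are the conventional
moderate-evidence/null boundaries and are keyword-configurable. At
single-session trial counts (220/subject) the difference BF is noisy, so a
true sensory-shift cohort occasionally lands in *mixed*; this is a
property of the evidence thresholds, not of the estimator (the equivalence
|mean ΔPSE − mean ΔCONF| → 0 holds as repeats grow, and is tested at 10³
repeats/level). A degenerate delta vector with zero variance is assigned
BF 0 (all-zero: no evidence of any shift) or ∞ (constant nonzero shift)
rather than erroring.

## Inferential statistics

Two-tailed t-tests from summary statistics (one-sample/paired:
`t = m/(s/√n)`, df = n − 1; independent: pooled-variance). Cohen's d uses
the paired convention `d = t/√n` (independent: `t·√(1/n₁ + 1/n₂)`); its
95% CI inverts the noncentral-t CDF for the noncentrality parameter
(bracketed expanding search + Brent root-finding, robust to the
far-tail NaNs of `nct.cdf`) and rescales to d units.

The JZS Bayes factor is the Rouder-style default for t-tests:

```
BF10 = ∫ T(t; ν, √N_eff·δ)·Cauchy(δ; 0, r) dδ / T(t; ν, 0)
```

with `r = 0.707`, `N_eff = n` (paired) or `n₁n₂/(n₁+n₂)` (independent).
The substitution `δ = r·tan θ` maps the prior to a uniform density on
(−π/2, π/2); adaptive quadrature then evaluates the integral at relative
tolerance 10⁻⁸. An independent brute-force trapezoid evaluation on
δ ∈ [−20, 20] with 10⁵ points (`bf10_jzs_trapezoid`) serves as a
cross-check and agrees to 4 significant figures on all reference values.
Sign conventions for printed d values vary across sources; comparisons are
by magnitude.

## What the synthetic data does and does not show

The generator emulates: the three designs' level grids, repeat counts and
half-block condition reversal; binary choice + binary confidence;
between-subject parameter spread matched to published baseline summaries;
and the three mechanisms (shift, uncertainty-gated bias, lagged serial
combination). It does **not** emulate: lapses mid-session or attention
drift, learning/fatigue nonstationarity, response-hand or cue-side
counterbalancing, adaptation dynamics (18 s vs 6 s top-ups are collapsed —
timing enters no computation), reaction times, or graded confidence.
Passing recovery and dissociation tests therefore shows the *pipeline* is
correct and the *diagnostic logic* is sound under its own assumptions; it
cannot show that real observers satisfy those assumptions (e.g. that
confidence is immune to response bias in humans).

## Numerical and design choices

- Probabilities are clipped to [10⁻¹⁰, 1 − 10⁻¹⁰] inside likelihoods;
  degenerate all-left/all-right profiles are flagged non-converged rather
  than fit.
- Problem sizes in the test suite: 200 sessions for decision-PSE recovery
  (mean signed error < 0.3%), 10-subject cohorts at 10³ repeats/level for
  the shift-equivalence bound, 15/22-subject cohorts at the preset designs
  for the dissociation and serial checks — sizes chosen to put Monte-Carlo
  error well inside the asserted bounds.
- CSV is the only trial interchange format; reports are JSON; runs are
  fully determined by a YAML `RunConfig` plus seed (replays are
  byte-identical apart from the timestamp).

## Known limitations

- The decision-bias mixture is one admissible realization of an
  uncertainty-scaled bias; other forms (e.g. criterion shifts in an SDT
  observer) would produce qualitatively similar but not identical
  asymmetries. The slight slope increase near peak uncertainty is noted
  qualitatively, not targeted quantitatively.
- Group-level diagnosis assumes exchangeable subjects; no hierarchical
  shrinkage of per-subject fits.
- Bayes factors are two-sided only; no one-tailed variants, no multiple-
  comparison correction (none is applied in the modelled analysis).
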