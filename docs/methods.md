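# Methods

This note documents the models, defaults and numerical choices behind
`predinf`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task model

The environment is a circular prediction task: on trial *t* an outcome
angle X_t is drawn from a Gaussian with SD σ around a hidden mean μ_t on a
circle of 360 integer points. With per-trial hazard H the mean is re-drawn
uniformly from the circle's integer points (a change-point, CP). Defaults:
200 trials, H = 0.125, σ = 12°, four blocks of 50 trials, ±10 points per
catch/miss, confidence slider anchored randomly at 25 or 75.

Conventions chosen where the task leaves detail open:

- Trial 1 initialises a run; CPs can occur from trial 2 onward, giving
  199 × 0.125 ≈ 24.9 expected CPs per session, matching the folk figure of
  "about 24" for this design.
- "U(1, 360)" is read as uniform over the circle's 360 integer points.
  Outcomes are drawn continuously, then rounded to the nearest integer
  degree (display resolution) and wrapped to [0, 360). Bucket positions
  are kept continuous.
- The bucket's angular half-width is not part of the published task
  parameters; it controls hit probability and is exposed in `TaskConfig`
  (`bucket_halfwidth`, default 20°, giving roughly 70–80% hits for a
  well-adapted agent at σ = 12°).
- Blocks are logging-only; the self-timed breaks have no model effect.

All public angles are degrees in [0, 360); signed differences live on
(−180, 180] with antipodal pairs mapped to +180. Radians appear only
inside the Von Mises likelihood.

## Reduced Bayesian learner

The learner maintains a point belief B and relative uncertainty τ ∈ (0, 1).
On error δ (signed, wrapped):

- change-point probability:
  Ω = H·U / (H·U + (1−H)·N(δ; 0, σ²/(1−τ))), with U = 1/360. Computed in
  log densities, so large |δ| at small predictive variance cannot
  underflow.
- learning rate: α = Ω + (1−Ω)τ; belief update B ← B + αδ (wrapped).
- uncertainty update:
  s² = Ω σ² + (1−Ω) τ σ² + Ω(1−Ω) (δ(1−τ))², then τ ← s²/(s²+σ²).
  Closed forms used as test oracles: Ω = 0 gives τ/(τ+1) (and from τ = ½,
  k quiet steps give 1/(k+2)); Ω = 1 gives ½.

Initialisation: τ₁ = 0.5 — the value the recursion itself produces after a
certain change, i.e. a single observation pins the mean no better than half
the predictive variance — and B₁ anchored at the first observation (first
outcome in normative mode, first bucket in conditioned mode). The
likelihood is a Gaussian on the wrapped error rather than a Von Mises: at
σ = 12° the wrap-around mass beyond |δ| = 180° is negligible, and the
Gaussian keeps the uncertainty recursion in closed form. The environment
has no drift term (hazard-only), so none is modelled; RU here conflates
estimation uncertainty with no drift component.

Two driving modes: *normative* (the learner's own errors) and *conditioned
on participant* (δ = the participant's error at their bucket), the latter
producing the trial-wise CPP/RU regressors. In this fixed-H, fixed-σ design
CPP is nearly a deterministic monotone function of |PE|, so the two are
strongly collinear by construction — the reason the confidence models enter
them in separate variants.

## Synthetic participants

The generator is the package's stand-in for human cohorts; its defaults are
fixed once and define the conditions under which all qualitative claims are
tested.

A *noisy-normative* agent runs the learner online on its own errors and
updates its bucket by λ·α + (1−λ)·base_lr times the error, plus Gaussian
motor noise; confidence is a clipped linear function of the learner's
certainty, 100·(1−τ_t)·(1−Ω_{t−1}) — any monotone-in-certainty proxy would
do; this one is fixed for reproducibility — plus noise, left at the random
anchor with a small sticking probability. Degenerate policies
(`always_update`, `never_update`, `random`, `anchor_sticky`) provide exact
oracles for the derived measures and planted defects for the exclusion
screens.

Population defaults (mean ± SD, truncated to valid ranges): λ 0.8 ± 0.15,
base_lr 0.4 ± 0.2, motor noise 8 ± 4°, confidence intercept 95 ± 8,
uncertainty slope 0.75 ± 0.2, confidence noise 8 ± 4, anchor-sticking
probability 0.05 ± 0.05. Traits are drawn once per participant; each
session perturbs them by N(0, 0.3 × population SD) ("session drift") and
plays a fresh environment. These values were chosen to give plausible task
behaviour (hit rates well above chance, confidence spanning the scale,
clear CP dynamics) and meaningful between-participant variance; they are
not fit to any dataset.

What the generator does *not* emulate: reaction times, practice/attention
effects, learning across sessions, non-Gaussian trait distributions, and —
importantly — the large stable individual differences in *baseline*
(stable-phase) learning rate seen in humans. In the default population the
stable-phase LR variance between agents is small relative to motor noise,
so split-half and ICC estimates for off-CP learning rates are low in
simulation even though the same machinery returns high values for
confidence and for the CP-trial learning rate. Passing tests therefore
validate the estimators and pipeline, not any claim about the reliability
values of real human data.

## Behavioural measures and screens

PE, action-update and LR are computed with the signed circular difference;
an unsigned "linear" variant (shortest absolute distances) is available as
a robustness alternative. LR is undefined where PE = 0 and on the last
trial.

The validity mask for learner-based analyses removes PE = 0 trials and
trials whose LR exceeds the pooled 99th percentile — applied to the signed
LR's upper tail only ("exceeds" read as one-sided), pooled across
participants within a session. With fewer than 100 pooled values the
percentile is refused and only the PE = 0 rule applies.

Confidence-quality screens per participant × session: (i) anchor-default
rate over the first 50 trials > 0.70 (informational reset flag only),
(ii) anchor-stay rate > 0.60 over all trials (drop), (iii) Pearson
correlation between the trial's random anchor and logged confidence > 0.5
(drop; an undefined correlation from constant confidence fires the flag by
convention), (iv) mean confidence after hits significantly *lower* than
after misses (drop) — implemented as a one-sided Welch t test at α = 0.05,
a deliberate choice where "significantly lower" is otherwise unspecified.

CP alignment collects a measure at offsets −4…+4 around each CP, truncating
windows at neighbouring CPs so no trial is attributed across another CP.
Per participant, the median (default; mean and a [0, 1]-restricted mean are
available) is taken across CPs per offset; derived scores are the
stable/unstable phase averages (offsets −2,−1 / +1,+2) and the CP
adaptation (offset 0 minus the mean of +1…+4). "Bounded mean LR" restricts
to trials with LR ∈ [0, 1] rather than clipping. The group-level CP effect
is a Welch two-sample t test across participants of the offset-0 summaries
against the post-CP summaries (an unpaired test is used deliberately; its
degrees of freedom can exceed n − 1).

## Regressions

*Circular update model* (per participant × session, valid trials only):
update_t ~ VonMises(β_PE·PE + β_CPP·PE·CPP_c + β_RU·PE·RU_c +
β_Hit·PE·Hit_c, κ), interactions mean-centred within participant, no
intercept (updates are error-driven). Estimation is MAP with independent
N(0, 5²) priors on each coefficient ("width 5" interpreted as the prior SD
on degree-scale coefficients) and a flat prior on log κ. The optimiser
runs Nelder–Mead then BFGS from ≥ 3 starts (an OLS warm start with a
moment-matched κ, zeros, and random perturbations), keeps the best
optimum (objective tolerance 1e-6), and reports standard errors from the
central-difference Hessian at the optimum. The objective is verified in
tests against a brute-force density summation and reduces to wrapped least
squares as κ → ∞; with prior width → ∞ it converges to the MLE.

*Confidence models* (OLS, lagged): confidence at *t* on z-scored |PE|, CPP,
RU (standardised within participant × session) and binary Hit at *t* − 1,
in `pe_model` / `cpp_model` / `combined` variants; the combined design's
condition number is reported. Standardisation of outcome and continuous
predictors is what makes coefficient magnitudes comparable across
participants. Zero-variance regressors are dropped with a warning.

*Action–confidence coupling*: the confidence reported at trial *t* follows
the update u_{t−1} that produced the current bucket position, so confidence
is regressed on |u_{t−1}|. Because the model direction and scaling both
appear in the literature, three scalings are emitted: predictor-
standardised (primary; confidence units per SD of |update|), fully raw
(per degree) and fully standardised.

Group-level inference is a two-sided one-sample Student t test of
per-participant coefficients against zero (single group vs zero, so no
Welch variant applies).

## Psychometrics

*Split-half*: for trial-level measures the data are split by odd/even
trials; for CP-aligned measures the split is at the level of whole CP
segments (a CP trial through the trial before the next CP; the leading
pre-CP run is segment 0), alternating segments between halves so each half
keeps ≥ ⌊k/2⌋ CPs. Offset windows are always drawn from the full trial
sequence — the split is over CPs, not trials — since pre-CP offsets
necessarily reach into the neighbouring segment. Halves are correlated
across participants (Pearson), corrected with Spearman–Brown; 95% CIs are
built on the Fisher-z scale of the half correlation with the endpoints
Spearman–Brown transformed (the CI method is a package choice). Negative
corrected values are reported as computed, with a warning.

*ICC*: ICC(2,1) and ICC(3,1) from the two-way ANOVA mean squares, with
participant/session/error variance components (expected-mean-square
solutions, clipped at zero, as percentages) and F-based CIs (exact for
(3,1), the McGraw–Wong approximation for (2,1)); both estimates and the
(2,1) CI are cross-checked against `pingouin.intraclass_corr` in tests.

*Category labels*: internal consistency below 0.5 "low", 0.5–0.7
"moderate", above 0.7 "good"; ICC below 0.5 "low", 0.5–0.75 "moderate",
above 0.75 "good". Boundary values take the lower interval's label.

*CP-count curves*: reliability is recomputed restricting every
participant × session to its chronologically first m CP segments
(deterministic, mirroring "reduced task length"), m from 6 (fewer gives
unstable splits) to full length; at full length the curve equals the
unrestricted estimate exactly.

*Correlation power*: `required_n_correlation` returns the smallest N whose
test of ρ = 0 reaches the target power. Three methods: `exact` integrates
the exact sampling density of r under a bivariate normal (Gauss
hypergeometric form, log-domain, `scipy.integrate.quad`) over the t-test
critical region; `nct` is the noncentral-t point-biserial computation that
standard power software applies to correlation tests (noncentrality
ρ√N/√(1−ρ²)); `fisher_z` is the closed-form normal approximation. The
methods differ by a few participants — at ρ = 0.272, α = 0.01 two-tailed,
power 0.90 they give 194, 190 and 195 respectively — and the `nct` value is
the one matching published power-software output, so it is what the
acceptance script reports; the exact method is the more conservative
choice for new study planning.

## Pipeline and problem sizes

The analysis drivers default to a 60-participant, two-session cohort
(seed 7) — large enough for stable group tests and meaningful reliability
estimates while keeping the full pipeline, including ~720 regression fits
for the coefficient-reliability block, to a couple of minutes. The test
suite uses a 20-participant shared cohort for model-level checks and a
300-agent single-session cohort for the group-dynamics checks. All
randomness flows from explicit seeds through `numpy.random.SeedSequence`
spawning, so every artefact is bit-reproducible.

## Known limitations

- The synthetic population is a convenience model: reliabilities computed
  on it characterise the estimators, not human data (see above).
- The Gaussian-on-wrapped-error likelihood in the learner is an
  approximation that would degrade for outcome SDs approaching the
  circle's scale.
- The exclusion screens assume the anchor and hit columns are trustworthy;
  no attention-check modelling is included.
- ICC CIs use the standard F approximations; they are not exact for the
  (2,1) form and can be slightly liberal at small n.
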