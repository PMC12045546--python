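# Methods

`reconpref` simulates and analyses a preference-elicitation interview for
nine post-mastectomy health states (implant-based and tissue-based
reconstruction at excellent/good/fair/poor quality, plus no
reconstruction), with death as the scale's lower anchor.  This note
documents the model, its parameters, the design choices taken where the
design was genuinely open, and what the synthetic experiments do and do
not demonstrate.

## Latent utility model

Each respondent holds a latent utility u(s) ∈ [0, 1] per state, with
u(death) = 0 exactly, built as

```
u(s) = base(s) + Σ effects(s) / 100 + ε(s),    ε(s) ~ N(0, σ_latent²),
```

clipped to [0, 1].  The default `base(s)` values sit close to the median
standard-gamble utilities a 40-woman interview cohort reported (implant
0.99/0.96/0.94/0.93, tissue 0.97/0.95/0.935/0.92, none 0.86): two values
are nudged off the published medians so that the noiseless ordering
excellent > good > fair > poor is strict within each modality and no two
cards tie exactly, which downstream ordering invariants require.

Covariate **effects** are specified in VAS points (0–100) per covariate
unit — the scale on which such study reports print regression
coefficients — and divided by 100 to act on the latent scale.  They
target option groups (`any` = all eight reconstruction states, `implant`,
`tissue`, `none`, or a single state) and sum when a state is hit by
several (e.g. an implant state receives the `any` and the `implant`
BREAST-Q effects).  Continuous covariates are centred at their configured
means so that the base utilities remain cohort means; categorical effects
are level indicators.  The default effect set is the published
multivariable VAS panel: BREAST-Q breast +0.29 (`any`) and +0.46
(`implant`), BREAST-Q outcome −0.25 (`none`), ASI-R behaviour +4.20
(`any`), ASI-R self-evaluation −6.96 (`any`) and −6.04 (`tissue`), and
obesity −16.15 (`implant`) / +10.59 (`tissue`).

Two behavioural perturbations reproduce interview findings:

- **Unexpected rankings** (default fraction 0.45): with that probability
  the respondent's excellent card in a random modality swaps utilities
  with that modality's fair or poor card.  This is implemented as an
  excellent↔{fair, poor} swap rather than an adjacent-quality swap
  because the study's operational definition of "unexpected" — a
  fair/poor outcome in the top 3 or an excellent outcome in the bottom 3
  — is then triggered deterministically on a clean deck, making the
  configured fraction recoverable from the data.  Note that under the
  full default configuration the *realised* flag rate (≈ 90%) exceeds
  the configured fraction, because the study-scale covariate effects and
  the latent noise themselves reorder decks (obesity alone pushes all
  implant states below tissue-poor).
- **Equipoise** (default fraction 0.25, strength 0.9): all non-excellent
  states are compressed 90% of the way toward their common mean,
  mimicking respondents who value one or two excellent options and are
  nearly indifferent among the rest.

### Cohort covariates

Continuous covariates (age, ASI-R total and subscales, BREAST-Q breast
and outcome) are clipped normals at the published mean/SD, clipped at the
published min/max.  Clipping at asymmetric bounds biases the mean (about
−0.35 y for age), so the sampler calibrates the pre-clip mean by a scalar
root solve on the censored-normal mean; the realised expectation then
matches the configured target.  Categoricals (race, ethnicity, marital
status, education, indication, laterality, BMI category, assessment
timing) follow the published proportions; covariates are sampled
independently, as the source study reports no covariance structure.

Every participant owns private RNG streams keyed by
`(seed, participant_index, stage)` with stages covariates / profile /
gamble choices / instruments, so cohorts are bit-reproducible and stable
under subsetting or reordering.

## Respondent choice model

A gamble offer compares the certainty of state c against a lottery
giving best state b with probability p and worst state w otherwise.  The
respondent evaluates

```
Δ = w(p)·u(b) + (1 − w(p))·u(w) − u(c)
```

where w(p) = p^γ / (p^γ + (1−p)^γ)^(1/γ) is the inverse-S probability
weighting function (γ = 1, the default, is the expected-utility
respondent).  With `choice_noise` τ = 0 the gamble is chosen iff Δ > 0
(exact indifference resolves to the certainty, making the noiseless
switch point deterministic); with τ > 0 the gamble is chosen with
logistic probability 1/(1 + e^(−Δ/τ)).  The default τ = 0.02 makes a
0.05-utility advantage chosen consistently (92%) while near-indifferent
offers are noisy, a moderate level of choice consistency for an
instrument respondents sometimes find difficult.

## Titration and chaining

Titration offers p = 1, 1 − s, 1 − 2s, … (default step s = 0.05,
matching the 95%-then-90% interview script) and stops at the first
certainty choice; the indifference probability is the midpoint of the
one-step bracket, so a noiseless respondent's estimate is within s/2 of
the true relative utility v = (u(c) − u(w))/(u(b) − u(w)).  Boundary
conventions: certainty at the very first offer yields 1 − s/2 flagged
`high` (v ≥ 1); never switching by p = 0 yields s/2 flagged `low`
(v ≤ 0).  Degenerate traces are flagged and kept, never dropped — the
analysis layer owns exclusion policy.

The chained gamble titrates each intermediate state against the
respondent's (best, worst) pair (P1ᵢ), then the worst state against
(best, death) (P2), composing u(stateᵢ) = P1ᵢ + (1 − P1ᵢ)·P2 with
u(best) ≡ 1 and u(death) ≡ 0.  Anchors are the *participant's own* best
and worst non-death states, identified from the noiseless latents with
ties broken by deck order; death enters only in the anchoring stage.  As
the step shrinks, composed utilities converge to u(s)/u(best).

## Instruments

**Ranking** sorts the latent utilities perturbed by rating noise
(σ = `vas_noise_sd`/100); values within a configurable epsilon share a
midrank.  **VAS** min–max rescales the noisy latents over the presented
card set to [0, 100] and snaps to a grid (default 2.5 — quarter-point
medians in published summaries suggest such grids).  Anchoring reproduces
the documented behaviour: the best card at exactly 100 and the worst at
exactly 0 without death, and compression of reconstruction states toward
100 once death anchors the bottom.  A degenerate all-equal profile is
rated 50 everywhere rather than dividing by zero.

`vas_rate(..., anchor=False)` returns the *unanchored* thermometer
reading 100·u(s) instead.  Re-anchoring is a per-respondent monotone
transformation that destroys cross-respondent comparability of VAS
points: a regression of anchored ratings on covariates estimates the
generating effects only up to each respondent's (max − min) rescaling
factor, which itself depends on the covariates.  The package therefore
uses anchored ratings everywhere a respondent-facing table is involved,
and unanchored ratings in the effect-recovery validation, where the
generating slopes must be identified.

## Analysis pipeline

A participant's **option-group score** is the mean (configurable to
median) of the group's states — all 8 reconstruction states for `any`,
the 4 per modality, the single no-reconstruction state — computed
listwise: a participant missing any state of a cell is excluded from
that cell and the exclusion count logged.  Summary cells report median,
IQR, quartiles and n; empty cells are missing, never zero.

Tests: Spearman rank correlations (VAS-with-death vs chained utility per
cell), two-sided Wilcoxon signed-rank contrasts (reconstruction vs none,
implant vs tissue, per instrument) with zero differences dropped, and
Kruskal–Wallis comparisons of implant/tissue scores across BMI
categories.  Small samples get exact p-values computed in-package:
Spearman and Kruskal–Wallis by full permutation enumeration (pooled
n ≤ 8), and the signed-rank test (n ≤ 25) from the exact distribution of
the rank sum built by convolution over doubled midranks, which unlike
the textbook exact distribution tolerates tied magnitudes.  Larger
samples use scipy's asymptotics (t approximation; chi-square; normal
with tie and continuity corrections).  If every value is tied the tests
report the degenerate H = 0, p = 1 rather than dividing by zero, and a
constant vector leaves Spearman's rho missing with a warning.

Regressions follow the study's recipe per instrument × option group
(12 models): a univariate screen retains candidates with p < 0.2
(categoricals tested jointly as indicator sets; zero-variance covariates
excluded with a warning), then backward elimination from the full
screened model removes, at each step, the covariate block whose removal
most reduces AIC, stopping when no removal helps; AIC ties are broken by
dropping the block with the larger p-value, and blocks contributing no
column rank are dropped with a warning before selection.  Outcomes stay
on their native scales (VAS 0–100, utility 0–1), confidence intervals
are Wald-type at 95%, and no multiple-testing adjustment is applied,
matching the source analysis's conventions.  Candidate covariates are
the psychosocial scores plus engineered clinical contrasts
(cancer-in-one-breast, BMI category with normal as reference, bilateral
plan, post-mastectomy timing, and sociodemographic indicators); race is
left out of the default set because its minority levels hold a single
participant each at n = 40.

## Validation experiments and their problem sizes

The experiments in `reconpref.validation` (run by the test suite and
`scripts/acceptance.py`) were sized to give tight checks at interactive
runtimes on a single CPU:

- **Titration sweep** — 1,000 random noiseless triples per step; the
  midpoint estimator's error is bounded by s/2 by construction, and the
  sweep confirms the bound is tight.
- **Chained vs direct** — 500 noiseless expected-utility profiles
  jittered around the default base utilities (the instrument's operating
  range); every composed utility agrees with a single direct
  (best, death) titration within one step.  The worst-case algebraic
  bound is 1.5·s (three independent bracketing errors), so agreement
  within s is a property of the operating range, not of arbitrary
  profiles.
- **Zero-noise concordance** — 50 respondents with rating, choice and
  behavioural noise all off, on clip-free base utilities.  Rank vs VAS
  is exactly −1 for every respondent.  VAS vs chained utility is
  evaluated only for respondents whose minimum pairwise relative-utility
  gap exceeds the titration step: a gamble titrated in decrements of s
  has resolution s, and states closer than that are ties as far as the
  instrument is concerned.  Two design points matter here: the *default*
  base utilities hug the ceiling, so study-scale effects saturate
  several states at latent 1.0 and create exact ties the gamble resolves
  degenerately while the VAS does not; and the equipoise perturbation
  manufactures sub-resolution near-ties on purpose.  Both are excluded
  from this check by design, and documented as such.
- **Screen null rate** — 1,000 replicates of a pure-noise covariate at
  n = 500; retention sits at the nominal 20% within binomial error.
- **Effect recovery** — 200 replicates at n = 2,000: cohort → latent
  profiles → unanchored VAS → group scores → screen → backward AIC.
  The recovery config lowers the base utilities (implant 0.70…0.52,
  tissue 0.68…0.50, none 0.35) so that effects never hit the [0, 1]
  clip, and disables the behavioural perturbations, which are deliberate
  nonlinearities orthogonal to the linear structure under test.
  Because group scores average states receiving different effect sums,
  coverage is assessed against *implied* per-group slopes (e.g.
  BREAST-Q breast on the implant score = 0.29 + 0.46 = 0.75/point; the
  obesity effect on the implant score is −16.15 exactly).  Every
  generating effect is retained in ≥ 90% of replicates and the Wald CIs
  cover the implied slopes at ≈ 95%.

## What the synthetic cohort does not show

The generator emulates marginal covariate distributions, additive
group-level effects, and a handful of documented response behaviours.
It does not model covariate correlations (none are published), item-level
psychometrics of ASI-R/BREAST-Q, interviewer effects, learning or fatigue
across the 90-minute protocol, ordering bias between the without-death
and with-death passes, or the photographic stimuli that real respondents
actually judged.  Passing tests therefore demonstrate that the
*machinery* — elicitation, composition, and statistics — is correct and
well calibrated against known truth; they are not evidence about real
patients, and the default-cohort medians resemble, but do not reproduce,
any study's data.

## Known limitations

- The titration schedule is a fixed-decrement ladder; adaptive bisection
  is out of scope.
- Anchored VAS effects are attenuated/rescaled relative to generating
  truth by construction (see above); users regressing anchored ratings
  should interpret coefficients as within-scale, not latent, effects.
- With strong positive effects several states can saturate at latent
  1.0, creating ties; the elicitation then assigns the tied non-best
  states 1 − s/2 of the way to the anchor, a convention, not a
  measurement.
- Backward-AIC inference is reported without post-selection adjustment,
  as in the emulated analysis; coverage statements hold for strongly
  identified effects.
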