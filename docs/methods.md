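# Methods

`labourprogress` models the progress of the first stage of labour as a
continuous-time Markov chain on cervical dilatation and asks how well
reference labour curves — the WHO partograph alert and action lines, and
customised percentile curves per obstetric subgroup — discriminate between
women who do and do not go on to a severe adverse birth outcome. Because
individual-level intrapartum data of this kind are not publicly deposited,
the package ships a calibrated synthetic cohort generator so that the whole
pipeline is runnable and testable end to end.

## The progressive dilatation model

Each centimetre of cervical dilatation from 2 to 10 cm is a transient state
and childbirth is an absorbing state. The chain is progressive and
unidirectional: from state *i* the only move is to *i*+1, at transition
intensity λᵢ (units 1/hour), so the generator matrix Q is upper-bidiagonal
with Q[i,i] = −λᵢ, Q[i,i+1] = λᵢ and a zero absorbing row. Dilatation is
panel data — observed only at irregular examination times — so an
observation pair (s_a, t_a) → (s_b, t_b) contributes the transition
probability P_{s_a s_b}(t_b − t_a) to the likelihood, and repeated equal
dilatations at successive exams are ordinary diagonal contributions, not
errors. A series containing a dilatation regression is a data error and is
rejected with the offending series named.

The first-passage time from 4 cm to d cm is hypoexponential with rates
λ₄ … λ_{d−1}. Transition probabilities are computed in closed form from the
partial-fraction expansion of the hypoexponential CDF when the rates are
well separated; when near-ties make those weights numerically unusable
(|w| > 10⁶, including the exactly-tied Erlang case) the computation falls
back to uniformization of the sub-chain, truncated where the discrete
absorption probability saturates, with the Poisson tail folded in
analytically. The two routes agree with the matrix exponential to ~1e−10
and are cross-checked against `scipy.linalg.expm` in the tests.

### Birth observations

The recorded birth time is treated as one more panel observation: the final
interval contributes a transition into the absorbing state, not an
exact-event density. This is the simplest form consistent with data that
are "repeated assessments". It has a known cost: because the observation
time coincides with the transition, the last intensity (10 cm → birth) is
biased upward (about +20% in simulation at n = 2000). The percentile curves
use only λ₄ … λ₉, which are unaffected (they recover within a few percent),
so downstream results do not inherit the bias. Caesarean section truncates
a woman's series at the decision time; her exam pairs still contribute, but
no absorbing transition is recorded for her.

### Estimation

Intensities are estimated by maximum likelihood over log-rates with
L-BFGS-B, three starts (one moment-based initialisation — spanning
transitions over a uniform allocation of interval time — plus two jittered
restarts), projected-gradient tolerance 1e−5 and a forward-difference
gradient. A tolerance much below 1e−5 is under the numeric-gradient noise
floor for log-likelihoods of magnitude ~10⁴ and only produces line-search
thrash. Log-rates are box-bounded to mean sojourns between one minute and
~1000 hours per centimetre; the bound is a plausibility constraint that
also keeps the uniformization fallback cheap. Non-convergence is flagged on
the result, never raised.

The model support is trimmed from below: every state from 4 cm up must be
spanned by at least `min_transitions` (default 5) observed state-change
intervals, otherwise the fit fails naming the state. States 2–3 cm are
fittable by the library when data support them, but the pipeline anchors
fitting at 4 cm: below 4 cm only the admission exam is ever observed, which
leaves λ₂ and λ₃ essentially unidentified (their MLE can run to the
boundary), and no curve or classifier uses them.

### Percentile curves and crossing

A customised labour curve for subgroup g and percentile p maps each
dilatation d ∈ {5,…,10} to q_p(4→d), the p-th quantile of the fitted
first-passage time from 4 cm, found by bisection of the hypoexponential CDF
(absolute tolerance well below 1e−6 h). Curves are strictly increasing in d
and in p by construction. Following convention, curves are fitted on women
*without* a severe adverse outcome, one chain per analysis subgroup.

A woman's time origin is her first exam at ≥ 4 cm. If that anchor is above
4 cm, her elapsed times are offset by the curve's own q_p(4→anchor), i.e.
she is compared with a reference labour that reached her anchor dilatation
at percentile speed. She crosses the curve when, at any later exam showing
dilatation d, the offset elapsed time strictly exceeds q_p(4→d); equality
is not a crossing. Crossing is evaluated only at observed exam points — no
interpolation — matching how a partograph is read. One consequence worth
noting: a repeated post-anchor dilatation (still at d cm at a later exam)
counts as crossing every percentile curve, because the woman is then
observably behind any reference that had already passed d.

## Partograph lines

The alert line rises 1 cm/h from the anchor exam (first observed dilatation
≥ 4 cm, plotted on the line even when above 4 cm — there is no re-anchoring
rule) and caps at 10 cm; the action line is the alert line shifted 4 h
right, imposing no deficit before the lag has elapsed. Crossing requires an
exam strictly below the line; on-line observations are "not crossed"
because the line itself is the boundary of normal progress. Line analyses
require at least two exams between 4 cm and childbirth; women with fewer
are not evaluable (NaN), handled pairwise per classifier. Action-line
crossing implies alert-line crossing for any series; this and the other
order properties (translation invariance; adding an exam can only create a
crossing) are property-tested.

## Diagnostic accuracy

Each classifier is consolidated into a 2×2 table against severe adverse
outcomes. Statistics: sensitivity, specificity, ±likelihood ratios,
diagnostic odds ratio and Youden's J = sens + spec − 1, which equals the
vertical distance of the classifier's ROC-space point above the chance
diagonal. Confidence intervals: Wilson score for proportions (via
statsmodels), Woolf's log method for the DOR, Simel's log method for the
LRs, and a normal approximation for J with Var(J) = Var(sens) + Var(spec).
These choices reproduce the published interval values this package is
validated against (the printed +LR upper bound differs from the Simel
computation in the last digit; point estimates are the authority). When any
cell is zero, ratio statistics (only) apply the Haldane–Anscombe 0.5
correction to all cells.

## Robson stratification

Classification order: non-cephalic presentations pool into one excluded
group (6/7/9); then preterm (< 37 completed weeks at childbirth) assigns
group 10; then a previous caesarean assigns group 5 (defined at term, so
preterm previous-caesarean women fall in group 10); finally parity × onset
splits groups 1–4. The eligible population (singletons in labour) cannot
reach group 8 or pre-labour caesarean; multiple pregnancy raises rather
than classifying. Groups 1–5 and 10 split by augmentation into the 12
modelled analysis subgroups; pooled non-cephalic women keep their
alert/action classification but are never curve-modelled.

## The synthetic cohort generator

The generator emulates the statistical structure of a large multicentre
intrapartum cohort from low-resource settings. Configured marginals
(defaults): 2.2% severe adverse outcomes, 35.1% augmentation, 13.2%
caesarean section, 89.9% spontaneous onset, 40.8% nulliparity, 5.4%
previous caesarean among parous women, 98.6% cephalic presentation, 4.5%
preterm, admission at ≤ 6 cm, and 2.22 (SD 1.02) cervical assessments
between 4 and 10 cm.

Mechanism, per woman:

- **Covariates** are drawn at the configured marginals (parity beyond
  nulliparity is geometric, capped at 8; term gestational age is normal
  around 39.3 weeks, clipped to 37–42; preterm uniform 34–37).
- **Latent trajectory**: the progressive chain is simulated forward from
  the admission dilatation with subgroup-specific base intensities scaled
  by a per-woman gamma frailty (shape 4, mean 1) — a single multiplier on
  all her rates. Base intensities rise with dilatation (0.65/h at 2 cm to
  2.6/h for the second stage, reference subgroup) and are scaled down for
  nulliparous, induced and augmented subgroups, so nulliparous groups are
  slower than multiparous ones. The absolute scale was calibrated once so
  that roughly half of evaluable labours cross the alert line, as observed.
- **Exams**: the number of assessments between 4 and 10 cm is
  1 + Binomial, moment-matched to mean 2.22 / SD 1.02 (the +1 floor
  reflects that a woman observed in the active phase has at least one exam
  there). Exams are placed roughly evenly through the active window with
  jitter — providers re-examine at intervals, not at uniformly random
  moments. An admission exam at t = 0 is always charted, and full
  dilatation is charted when reached.
- **Caesarean section** truncates the trajectory at a decision time drawn
  uniformly in the 40–95% span of the latent labour; the decision time then
  stands as the operative birth time, keeping the absorbing state
  well-defined.
- **Outcome**: severe adverse outcome is Bernoulli with logit linear in the
  standardised log-frailty (the "slow-labour score"), odds multiplier 1.3
  per SD of slowness. The intercept is solved numerically (quadrature over
  the frailty distribution) so the marginal rate equals the configured
  baseline exactly. The multiplier was calibrated once so the customised
  curve-crossing classifiers land in the weak-association band (diagnostic
  odds ratios roughly 1.3–1.6) with Youden J below 10%; slowness is
  deliberately a weak predictor.

Determinism: a fixed config and seed reproduce the cohort byte-for-byte.

### What the generator does and does not emulate

It reproduces the marginal rates above, the sparse-panel observation
process, subgroup speed differences and a weak slowness–outcome
association. It does **not** simulate fetal heart rate, moulding, caput,
meconium or fever; neonatal care pathways; referral; or informative exam
timing (in reality providers examine slow labours more often). The
single-frailty mechanism under-produces extreme delays, so action-line
crossing (~7%) is lower than in real cohorts (~15%). Passing tests
therefore certify the analysis machinery and its calibration targets, not
clinical realism beyond those targets.

### Stochastic headline quantities

With a 2.2% event rate at n = 10 000 (~220 events), each classifier's J
carries a sampling SD of ≈ 3.5 percentage points (the alert line's own
published J interval spans 0.8–14.9%). The "maximum J across the six
percentile classifiers below 10%" summary therefore holds in expectation
and for most seeds, but individual seeds can exceed it through outcome-draw
luck alone; this is a property of the study conditions, not of the
implementation.

## Problem sizes and defaults

Default analyses use n = 10 000 women, six percentiles (50–95), at least
two active-phase exams for line analyses, fits on outcome-free women with
at least 5 observed transitions per state from 4 cm, and 3 optimizer
starts. A full generate-fit-classify-evaluate run completes in well under a
minute on one core; parameter-recovery simulations use 2 000 women with
half-hourly inspections.

## Known limitations

- The homogeneous chain is fitted to frailty-heterogeneous data, so fitted
  marginal intensities are population summaries, not the generator's base
  rates; this mirrors the real analysis situation and is why parameter
  recovery is validated on homogeneous simulations.
- Exact birth times bias λ₁₀ upward under the panel treatment (see above).
- No misclassification/hidden states, no covariate effects on intensities
  beyond subgroup stratification, no time-inhomogeneity.
- CIs beyond those listed (e.g. exact binomial) are out of scope.
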