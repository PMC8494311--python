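# Methods

## Observer models

All models operate in log-odds (natural logarithm). A trial supplies
the logits `L_p` (prior cue: the fisherman's lake preference) and `L_s`
(likelihood cue: the red-fish proportions); each cue takes one of nine
probability levels 0.1–0.9 and the two response options are
complementary, so only the left-lake probability is represented.

Simple Bayes adds the logits. Weighted Bayes passes each through the
sigmoid `F(L, w) = ln((w e^L + 1−w)/((1−w) e^L + w))`, which is the
posterior logit of a signal transmitted through a channel of
reliability `w`: `F(·, 1)` is the identity, `F(·, 0.5)` is the zero
map, and for `w < 1` the output saturates at `±ln(w/(1−w))`. The two
circular-inference variants add reverberated copies of the cues before
the final weighting: in CII the pooled term
`I = F(a_p L_p, w_p) + F(a_s L_s, w_s)` corrupts both channels, making
each cue's influence depend on the other; in CINI each channel only
overcounts itself, keeping the cue contributions additive. Setting both
`a = 0` recovers WB and additionally `w = 1` recovers SB, giving the
nested reduction chain the test suite checks to 1e-10.

`F` is evaluated as a difference of `logaddexp` terms so that |L| up to
~700 neither overflows nor loses the saturation level, and the `w = 1`
limit is exact. Weights below 0.5 (true scale) are rejected rather than
clipped: a weight under 0.5 would invert a cue, which the model family
does not contemplate.

### Parameters and scaling

True ranges are `w ∈ [0.5, 1]` and `a ∈ [0, 60]`; 60 is a nominal
ceiling far above anything this design elicits. Parameters are stored
and reported rescaled to [0, 1] (`(w−0.5)/0.5`, `a/60`) and mapped back
to the true scale only inside the prediction functions. All defaults,
fits and recovery statistics use the rescaled convention.

Every model is antisymmetric under joint cue negation
(`L_c(−L_p, −L_s) = −L_c(L_p, L_s)`) and monotone in each cue; both
properties are enforced as structural tests, and antisymmetry is what
licenses the symmetric-trial averaging below. One subtlety: CII and
CINI coincide not only at `a = 0` but on any trial where the pooled
interference term `I` is exactly zero — e.g. mirrored cues under
channel-symmetric parameters — so their divergence is conditioned on
`I ≠ 0`, not merely on `a > 0`.

## Trial design

`build_trial_set` covers every cell of the 9×9 grid at least once and
spreads the surplus (130 − 81 = 49 trials at the default length) over a
seeded choice of distinct cells, then shuffles the order. The exact
composition of the original 130-trial session is not public; this
balanced construction is a documented stand-in that preserves the grid,
the trial count and randomized order. Stimulus rendering and
presentation timing are out of scope.

## Response generation

A simulated response is the model prediction plus Gaussian noise in
logit space (`L_c = pred + N(0, σ)`), mapped to a confidence and
clipped to `[ε, 1−ε]` with ε = 0.01, i.e. |logit| ≤ ln 99 ≈ 4.6. How
edge clicks were handled in the original scale is not documented; the
clipping bound is this package's stand-in for a response scale of
finite resolution, and it is configurable. The fitting stage applies
the same cap to its predictions so that generation and inference share
one observation model (see Fitting).

Reaction times are log-normal with median 2 s scaled by
`exp(−0.1·|prediction|)` (confident trials answered faster, the
empirical direction) and log-scale SD 0.4. They exist to exercise the
speed–accuracy term of the mixed-effects stage, not to model decision
dynamics.

## Synthetic cohorts

A cohort draws, per participant: generating parameters (rescaled
w ~ U(0.3, 1.0), a ~ U(0, 0.3), bracketing the fitted values this
design produces — the largest reported non-rescaled reverberation is
about 29 of 60, i.e. ≈ 0.48 rescaled), logit noise SD ~ U(0.5, 1.5),
integer AQ (truncated normal, mean 22.9, SD 6.5 on [0, 50]; the ASD
subgroup instead mean 28.0, SD 8.0) and PDI (mean 6.1, SD 3.1 on
[0, 21]) trait totals, and a diagnosis label (ASD/ND/other in roughly
the study's 21/61/94-of-176 proportions). Trait–parameter couplings
default to zero — the null cohort, whose role is type-I calibration —
and can be set per (parameter, trait) pair as a slope on the
standardized trait, with out-of-box values clipped and logged.

What the generator does **not** emulate: item-level questionnaires,
learning or drift across the session, lapses and attention failures,
response granularity beyond the clipping bound, and any true
trait–parameter structure. Passing tests on these cohorts therefore
show that the pipeline is correct and calibrated under its own
assumptions, not that those assumptions hold of real participants.

A quality-control helper flags flat responders (confidence SD < 0.05)
and midpoint-heavy responders (> 30% of clicks within 0.02 of 0.5) as a
stand-in for the study's undocumented exclusion rules; exclusion is
opt-in.

## Fitting and model comparison

Under logit-Gaussian noise, least squares on `L_c` is maximum
likelihood. The forward model caps its predictions at the response
scale's edge (±ln 99 in logit units, matching the ε = 0.01 clipping of
observed confidences) before computing residuals: a model is not
penalized for predicting beyond what the scale can express, and
noiseless synthetic data is fit exactly. The cap is configurable and
never binds for SB, whose predictions stay within ±2 ln 9 on the grid.
Models are scored with
`BIC = n ln(σ²) + k ln(n)` where `σ²` is the residual MSE and
k = 0/2/4/4 (the noise SD is not counted as a free parameter). A
perfect fit floors the MSE at 1e-12 with a warning. Optimization is
L-BFGS-B in the rescaled unit box from the deterministic start grid
{0.25, 0.75}^k plus 8 seeded uniform restarts, followed by a
derivative-free Powell polish of the three best candidates — once the
reverberated signal saturates on every grid logit the objective is
nearly flat along `a` and gradient steps stall, while Powell's line
searches still walk those directions. Ties within 1e-9 resolve to the
smallest `a_p + a_s`, then lexicographically, preferring the
least-reverberant explanation and making refits bit-reproducible.
Heavy-multistart spot checks (64 extra restarts) change no model
attribution, so the default start set is treated as sufficient on this
design.

Group-level comparison is done both ways: summed ΔBIC against a
configurable baseline (CII by default), and random-effects Bayesian
model selection — the variational Dirichlet scheme over per-participant
log evidences approximated as −BIC/2, with a uniform Dirichlet(1)
prior, tolerance 1e-6 on the concentration updates, and exceedance
probabilities from 10⁶ seeded Dirichlet draws. The per-participant
attribution matrix `u` is exposed alongside the population
frequencies: with a single decisive participant the attribution
approaches the softmax of the evidences while the expected population
frequency only reaches `(1+u)/(K+1)` — the two quantities are easy to
conflate.

## Recovery validation

Parameter recovery draws generating sets (from the default ranges or by
resampling a fitted table), simulates the 130-trial design, refits, and
reports Pearson and Kendall correlations (Pearson is outlier-sensitive
for the skewed reverberation estimates, hence both) plus the recovered
cross-parameter correlation matrix. At noise SD 1 the weights recover
excellently (r ≥ 0.85 enforced) and the reverberations positively but
moderately — the expected split on 130 trials, where noise and
overcounting trade off.

Model recovery simulates from CINI and from CII, fits both, and assigns
by lower BIC (equal k, so this is an MSE comparison); exact ties —
possible only at the shared a = 0 boundary — are credited to the
generator and counted. At the validation scale (200 simulants per
model, noise SD 1, seed 1) the confusion matrix is:

```
          recovered
simulated  CINI  CII
   CINI     161   39     (80.5%)
   CII       18  182     (91.0%)
```

85.75% correct on average. The residual asymmetry is a property of the
stand-in generating distribution: uniform reverberation draws up to 0.3
(rescaled) produce more strongly separable simulants than a fitted
sample concentrated at small reverberation would, and the original
study's generating draws are not public. The average rate is the robust
quantity; per-row rates move by several points across seeds and
generating choices.

## Trait statistics

The model-free stage regresses absolute confidence `|c − 0.5|` on
absolute likelihood `|like − 0.5|`, prior congruency
`|prior − 0.5|·sgn[(prior − 0.5)(like − 0.5)]` (zero when the prior is
0.5), their interaction and reaction time, in five mixed-model variants
that progressively add AQ/PDI main effects and interactions.
Participants enter as a random factor with intercept and slopes for the
two cue regressors, falling back (flagged) to intercept-only on
singular fits; traits are mean-centred before interacting; models are
fitted by maximum likelihood (statsmodels MixedLM) so BICs are
comparable, with the model's degrees of freedom counted as fixed
effects + unique random (co)variances + the residual.

Associations use Kendall τ-b (integer trait totals guarantee ties) with
the usual tie-corrected two-sided p, and Mann–Whitney U with
`f = U/(n_x n_y)`, the tie-corrected probability that a random member
of the first group exceeds one of the second (f = 0.5 ⇒ no
difference; `f(x,y) + f(y,x) = 1`). Extreme groups are the bottom/top
15% of the sample by AQ with threshold ties included on the extreme
side; the ASD vs ND contrast uses the stated labels, and the low-AQ ND
subgroup is emitted for the supplementary-style contrast. The battery
(8 correlation tests, 8 group tests) is Benjamini–Hochberg-adjusted
within each table; raw p-values are always reported alongside. The
named correction procedure behind the original adjustment is not
stated; BH is this package's documented choice. Across 500 seeded null
cohorts of 60 participants every battery test rejects at 3–7% at
nominal α = 0.05.

Symmetric-trial averaging exploits model antisymmetry: a trial and its
mirror (both cue probabilities complemented) are combined as
`(L_c(t) − L_c(t'))/2`, halving response-noise variance while leaving a
model-consistent responder unchanged. Output is indexed by the 45 grid
cells with non-negative summed logits; a missing mirror keeps the
available side and is flagged.

## Problem sizes and numerical choices

Validation scales were set to keep every stage comfortably
reproducible on a single CPU: 200 simulants per generating model for
model recovery, 200 (and 50 noiseless) for parameter recovery, 500
cohorts of 60 for type-I calibration, 10⁶ Dirichlet draws for
exceedance probabilities. Equivalence and reduction tests use 1e-10;
optimizer ties 1e-9; logit round-trips 1e-12. Seeds parameterize every
random draw, and all high-level entry points are pure functions of
their seed.

## Known limitations

- The balanced trial set, clipping rule, QC rule, generating-parameter
  distribution and BH adjustment are documented stand-ins for
  undisclosed details of the original study; conclusions that depend on
  their fine structure (notably per-row model-recovery rates) should be
  read with that in mind.
- Bayes-factor columns of the original result tables are out of scope;
  the battery's schema reserves the column but never fills it.
- Mixed-model p-values come from the asymptotic Wald t of MixedLM;
  small cohorts with rich random structures can be anticonservative.
- Recovery is validated for the circular models only; SB/WB are not
  competitive on this task and are excluded, as in the original
  validation.
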