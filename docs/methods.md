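# Methods

## The model

`milksession` models the milk yield of a dairy cow at the resolution of the
individual milking session rather than the day. Three ingredients generate
the lactation curve mechanistically.

**Alveolar population kinetics.** The udder is treated as a single
compartment with a fixed population of alveoli, each in one of three
states: non-activated, activated (secreting), or inactivated. With
activation rate λ_A and inactivation rate λ_R (both per hour, constant over
the lactation), the state proportions follow first-order kinetics from
N_I(0) = 1:

    N_I(t) = exp(−λ_A t)
    N_A(t) = λ_A/(λ_A − λ_R) · [exp(−λ_R t) − exp(−λ_A t)]
    N_R(t) = 1 − N_I(t) − N_A(t)

Time t is hours since lactation onset, which precedes the first milking by
an estimated latency δ. The rise and slow decline of N_A(t) *is* the
lactation curve: its peak at t* = ln(λ_A/λ_R)/(λ_A − λ_R) falls near day 30
at the reference estimates. When |λ_A − λ_R| < 1e−10·λ_A the confluent
limit N_A = λ_A t·exp(−λ_A t) is used, because the optimizer may pass
through that region.

**Secretion.** Milk produced on the interval between sessions k−1 and k is
linear in the activated proportion: Y_P(k) = PL(k)·∫ N_A(x) dx over the
interval. At twice-daily milking the udder stays far from capacity, so the
saturating form (a maximum volume approached exponentially) linearizes and
only the product PL = V_max·P_max is identifiable; V_max and P_max are
deliberately absent from the parameterization. PL(k) is piecewise constant
over *segments* of the lactation; β(k) = PL(k)/PL_max ∈ (0,1] is the
secretion proportion, an umbrella for event-driven influences (diet,
grazing, udder state) that the smooth kinetics do not capture.

**Retention and carryover.** A session extracts all available milk except a
retained fraction π(k): Y_R(k) = π(k)(Y_P(k) + Y_R(k−1)) and
Y_E(k) = (1−π(k))(Y_P(k) + Y_R(k−1)), with Y_R(0) = 0. Carryover couples
successive sessions and is the mechanistic source of yield
autocorrelation. π is a baseline value with per-session overrides for
sessions with extreme retention (milking incidents).

## The variance model

The measured yield is Y_M(k) = Y_E(k)·exp(ε) with ε ~ (0, CV_M²),
CV_M = 0.025 fixed a priori (recording-equipment precision, small-ε
approximation E e^ε ≈ 1). First and second moments propagate through the
retention recursion with S(k) = E(Y_P(k)) + E(Y_R(k−1)):

    Var(Y_E(k)) = S π(1−π) + (1−π)² [Var(Y_P(k)) + Var(Y_R(k−1))]
    Var(Y_R(k)) = S π(1−π) + π²     [Var(Y_P(k)) + Var(Y_R(k−1))]

and Var(Y_P) = V_PL + V_PA with

    V_PL = PL_max·Δt·m̄·β(1−β)            (secretion-proportion term)
    V_PA = (PL_max β)²·Δt·φ·m̄(1−m̄)       (activated-alveoli term)

where m̄ is the interval-averaged activated proportion and φ ∈ (0,1] is a
dispersion factor absorbing the underdispersion caused by interdependence
among alveoli. Total session variance decomposes exactly into five named,
non-negative components:

    Var(Y_M) = V_mes + V_ret + V_rec + V_pro + V_alv

with V_mes = E(Y_E)²CV_M², V_ret = Sπ(1−π), V_rec = (1−π)²Var(Y_R(k−1)),
V_pro = (1−π)²V_PL and V_alv = (1−π)²V_PA. The carryover component V_rec
carries the coefficient (1−π)² — the coefficient of Y_R(k−1) in Y_E — so
that the decomposition sums identically to the propagated variance and
matches a Monte-Carlo simulation of the generative process (both are
tested); the π² weight belongs to the Y_R recursion instead. Covariance
between Y_P(k) and Y_R(k−1) is taken as zero, as the recursions assume.

When exact milking times are unknown (schedule-only mode), the schedule is
rebuilt from nominal interval lengths (14 h before a morning session, 10 h
before an evening one) and a sixth component is added,

    V_tim = (1−π)²·[PL(k)·N_A(t(k))]²·Var_T ,

the first-order (delta-method) propagation of interval-length uncertainty
with Var_T = 0.25 h².

**A deliberate consequence of the kg-scale binomial terms.** V_ret and
V_PL have the dimension of kg (a count-like binomial variance applied to
kilograms). At the reference parameter scale this makes per-session
retention noise large (sd ≈ 0.8 kg on a retained amount of ≈ 0.6 kg),
which in turn induces a genuine negative lag-1 covariance between
successive extractions, Cov(Y_E(k), Y_E(k+1)) = π(1−π)²(Var(A) − S) < 0
for A = Y_P + Y_R(k−1). Standardized residuals of the session-independent
likelihood therefore show mild negative autocorrelation (ρ₁ ≈ −0.1) on
data generated by this very model, and portmanteau p-values are not
uniform under the null. This is an internal property of the variance
specification, not an implementation artifact; see Limitations.

## Estimation

Standardized residuals (Y_O − E(Y_M))/√Var(Y_M) are standard normal under
a correct model, so parameters are estimated by maximizing the Gaussian
log-likelihood with both the mean and the variance model evaluated at the
candidate parameters. Positive parameters (δ, λ_A, λ_R, PL) are optimized
as θ = exp(α) and unit-interval parameters (π, φ) as θ = exp(−exp(α)),
over unconstrained α. The optimizer is BFGS with finite-difference
gradients (relative likelihood-change and gradient tolerances 1e−9 / 1e−6,
with a restart if a line search stalls and a derivative-free warm-up if a
cold start makes no progress). Physical working-scale ranges
(δ ∈ [1, 1000] h, λ_A ∈ [1e−4, 0.1] /h, λ_R ∈ [1e−9, 1e−3] /h, PL ∈
[1e−3, 1e3] kg/h) are enforced as smooth quadratic penalties so the search
cannot drift onto the flat saturated plateaus of the transforms.

Starting values: δ = 72 h, λ_A = 5e−3, λ_R = 5e−5, π = 0.05,
PL = (max session yield)/10 h, φ = 0.5 — order-of-magnitude defaults that
proved robust in testing.

**Identifiability.** Swapping (λ_A, λ_R) and rescaling PL by λ_A/λ_R
leaves the mean trajectory exactly invariant; only the variance model
breaks the tie, weakly. Activation is the fast process (days) and
inactivation the slow one (the whole lactation), so the likelihood rejects
the λ_R ≥ λ_A branch (smooth penalty rising from λ_R/λ_A = 0.8).

**Uncertainty.** The covariance of the working-scale estimates is the
inverse numerical Hessian (central differences) of the negative
log-likelihood at the optimum; 95% intervals are formed on the working
scale and back-transformed, exploiting the asymptotic normality of ML
estimators. A singular Hessian falls back to a pseudo-inverse; intervals
whose standard error is not finite are reported as unavailable.

## Conditional-element discovery (two-stage workflow)

Two kinds of lactation-period structure are discovered from the residuals
of an initial constant-PL, constant-π fit:

* **Extreme-retention sessions** — residuals with two-sided normal tail
  probability below 0.001. A positive spike immediately following a
  flagged negative spike is attributed to the carryover rebound of the
  preceding high-retention session (the retained milk is extracted one
  session later) and is not given its own override. Flagged sessions share
  one extreme-π parameter in the refit.
* **Secretion-rate segments** — changepoints in the mean and variance of
  the residual sequence, located by an exact penalized segmentation (PELT
  with the Gaussian mean+variance cost). The penalty is the asymptotic
  critical value of the maximal likelihood-ratio statistic for a single
  mean/variance change (Gumbel limit with p = 2 changing parameters), so
  the α = 0.05 default controls the family-wise false-alarm rate at about
  5% on white noise (verified by simulation). Minimum segment length: 30
  sessions (≈ 15 days) — β regimes span weeks to months, and shorter
  segments would fit noise.

A single detection pass is not enough, for a measurable reason: the
constant-parameter fit absorbs most of a monotone β staircase into an
inflated λ_R, muting the residual steps to ~0.1–0.3 sd, and adding one
boundary at a time barely improves the likelihood because λ_R only relaxes
once several boundaries enter jointly. The workflow therefore

1. screens liberally (changepoint candidates at α = 0.5 on the current
   residuals, re-detected *within* each fitted segment on later rounds)
   and seeds a provisional sieve grid of boundaries (spacing 60 sessions),
2. refits jointly and iterates detection/refit up to three rounds,
3. polishes each boundary position by profile likelihood on a coarse
   5-session lattice within ±30 sessions (a finer search would chase
   noise),
4. confirms each boundary with a Wald test on the adjacent log-PL
   difference at 5% and refits on the confirmed segmentation, accepting
   the merge only if each removed boundary costs at most its χ²₁ 5%
   critical value of log-likelihood.

The liberal screening level applies only to *candidates*; the reported
segmentation is what survives confirmation, and the stand-alone detector
keeps its α = 0.05 calibration.

## The synthetic-lactation simulator

The model specifies first and second moments, not distributions. The
simulator uses positivity-respecting families matched to those moments:
Y_P(k) is Gamma with the model's interval mean and variance; the retained
fraction is Beta with mean π(k) and variance
π(1−π)·E(A)/(Var(A)+E(A)²) — exactly the value that reproduces both
retention recursions above when the fraction is drawn independently of
the available milk A; measurement error is log-normal with sd CV_M.
Sample moments across replicates agree with the propagated moments to
Monte-Carlo error (tested at 1e5 replicates), and with every noise source
zeroed the draw reproduces the deterministic mean model exactly.
Schedules alternate intervals with means 14 h (evening→morning) and 10 h
(morning→evening) and sd √0.25 h, truncated positive; 305 days (610
sessions) is the default lactation length, a conventional figure since
the data the defaults derive from do not state one.

**Reference preset.** The defaults are the estimates from a second
lactation of a healthy Montbéliarde cow: δ = 70.98 h, λ_A = 64e−4 /h,
λ_R = 45e−6 /h, baseline π = 0.04 with extreme π = 0.28 at sessions 33
and 36, PL segments (1.41, 1.32, 1.16, 1.02, 0.90) kg/h, φ = 0.54,
CV_M = 0.025, Var_T = 0.25 h². The segment *boundaries* are not part of
those estimates and had to be chosen. Because β captures event-driven
regimes rather than the smooth decline (which λ_R already models), the
preset places a long plateau over peak and mid lactation followed by
progressively shorter late-lactation regimes (segment starts at fractions
0, 0.30, 0.65, 0.80, 0.90 of the session count). An equal-length
placement was rejected on identifiability grounds: a uniform monotone
staircase is statistically collinear with exp(−λ_R t) at this noise level
— no residual-based detector could have discovered such segments, which
would contradict the premise that β regimes are observable departures.

**What the simulator does not emulate.** Real lactations have
quarter-level heterogeneity, occasional missed or pooled milkings, drift
in measurement precision, health events that perturb both mean and
variance, and day-to-day diet effects smoother than a step function.
Passing recovery tests on this generator therefore demonstrates internal
consistency of model + estimator, not field validity.

## Diagnostics and the Wood baseline

Residual normality is tested against N(0,1) directly (residuals are
standardized by construction; no moments are re-estimated), and serial
correlation with the Box–Pierce portmanteau statistic at lag
min(20, K/4) by default (degrees of freedom not reduced for estimated
parameters). Daily means and variances are the sums of each calendar
day's sessions — valid exactly when session residuals are uncorrelated —
and the peak of the daily curve is read from a 7-day centered moving
average because raw daily values are noisy. The variance-explained ratio
is the summed model variance over the summed squared raw residuals (≈ 1
for a well-specified model).

Wood's classical daily curve a·x^b·e^(−cx) is fitted by nonlinear least
squares (log-linear regression provides starting values; day index starts
at 1; totals use daily summation). Its closed-form peak is at day b/c.
On data generated by the session-level physiology, Wood residuals are
strongly autocorrelated — carryover and the session-level variance
structure violate the independent-error assumption — which is the
baseline's documented defect.

## Known limitations

* **Post-selection deflation of φ.** When the segmentation is discovered
  from the data, boundary count and position selection absorb residual
  variance and the dispersion estimate is biased low (median ≈ 0.35–0.46
  across simulated replicates versus 0.54 truth; the identical estimator
  with the true structure supplied recovers φ with median ≈ 0.51). No
  degrees-of-freedom correction is applied because the effective selection
  dimension is not honestly quantifiable.
* **Over-segmentation of the reported count.** The liberal screening that
  makes the continuous parameters recoverable typically leaves 5–9
  confirmed segments where 5 were implanted; redundant boundaries are
  nearly harmless for the estimands (the extra segments carry near-equal
  PL) but inflate the count.
* **Residual autocorrelation under the model's own noise scale.** See the
  variance-model section: the kg-scale binomial terms make retention noise
  large enough to induce ρ₁ ≈ −0.1 in the standardized residuals of data
  the model itself generates, so Box–Pierce p-values are anti-conservative
  under that generative null.
* **Mild residual non-normality under the generative families.** The same
  large retention noise forces the Beta retention fraction into a strongly
  skewed corner (cv > 1, skewness ≈ 2), so standardized residuals of
  simulated lactations carry slight skewness; per-lactation KS tests
  usually pass, but KS p-values are not exactly uniform across replicates.
  With field-scale (smaller) retention noise the families are
  near-symmetric and the effect vanishes.
* **Extreme-retention detection power.** At the reference variance scale a
  π = 0.28 session shifts its residual by only ≈ 2.3–3 sd, so flagging at
  the 0.001 threshold succeeds in well under half of simulated replicates;
  with smaller (field-realistic) residual variance the same spike exceeds
  3.5 sd and is flagged reliably.
* The udder is one compartment; quarters are summed before modelling.
  λ_A, λ_R, π and CV_M are constant over the lactation by assumption.
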