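# Methods

## The model

`hpaxis` implements a joint nonlinear mixed-effects model of the
hypothalamic-pituitary-adrenal (HPA) axis coupled to hydrocortisone
pharmacokinetics, for simulating healthy subjects, congenital adrenal
hyperplasia (CAH) patients of graded severity, and oral/IV hydrocortisone
regimens.

**ACTH turnover.** ACTH concentration A (pmol/L) follows a turnover model
with zero-order baseline secretion and first-order elimination,

    dA/dt = Base*Kout + s(t) * S(t) - Kout*A,

where `S(t)` is the circadian pulsatile secretion — the sum of two
bell-shaped surge functions

    S_i(t) = SA_i / (((t - Pt_i)/SW_i)^n + 1),   n = 4,

a narrow morning surge (SA1 = 1300 pmol/h at 70 kg, SW1 = 0.606 h, peak
06:18) and a broad midday surge (SA2 = 50 pmol/h, SW2 = 2.33 h, peak
11:48). Because simulations span several days and Eq. above is aperiodic,
the surge is extended periodically by summing the day images at offsets
−24/0/+24 h; the polynomial tails are not negligible (≈11 pmol/h each
12 h from the morning peak), which matters for the nocturnal ACTH floor
(see *Known limitations*).

**Feedback.** The multiplier `s(t)` on the pulsatile secretion is the
sigmoidal inhibition by unbound cortisol Cu,

    s = 1 - Imax * Cu^γI / (IC50^γI + Cu^γI),

with Imax fixed at 0.999 (full suppression possible), IC50 = 4.60 nmol/L
unbound (≈160 nmol/L total) and γI = 5.33. The zero-order baseline
secretion is never suppressed. Dexamethasone (DEX) is modeled as a binary
window during which `s = 1 - I_DEX = 0` regardless of cortisol.

**Cortisol production.** ACTH drives adrenal cortisol production through a
sigmoidal Emax model, `activity * Emax * A^γE/(EC50^γE + A^γE)`, with
Emax = 5400 nmol/h, EC50 = 6.63 pmol/L, γE = 2.94. `activity` ∈ [0, 1] is
the remaining 21-hydroxylase activity: 1 healthy, 0.2 mild CAH, 0 severe
CAH.

**Kinetics and binding.** Cortisol/hydrocortisone disposition is a
two-compartment model acting on unbound drug (CL = 106 L/h, Vc = 2.15 L,
Q = 89.9 L/h, Vp = 61.7 L at 70 kg; unbound elimination rate CL/Vc =
49.3 h⁻¹). The central state is the *total* cortisol amount; the unbound
concentration is the closed-form positive root of the binding equation

    Ctot = Cu + Bmax*Cu/(Kd + Cu) + NS*Cu

(saturable corticosteroid-binding globulin, Kd = 9.71 nmol/L, plus linear
albumin binding, NS = 4.15). Bmax is not part of the published parameter
table; the default 424.1 nmol/L is calibrated so that Cu = 4.60 nmol/L
corresponds to ≈160 nmol/L total, and it is an ordinary configurable
parameter. The peripheral compartment stores unbound-equivalent amounts;
binding is central only.

**Absorption.** Oral immediate-release granules enter through an analytic
transit-chain input `F*D*Ktr*(Ktr t)^Ntr e^(-Ktr t)/Γ(Ntr+1)`,
`Ktr = (Ntr+1)/MTT`, feeding a depot absorbed at Ka = 24 h⁻¹ with
F = 0.344. The mean transit time follows a dose power law
`MTT = 0.868 h * (dose/5 mg)^0.179` (0.57 h at 0.5 mg, 1.11 h at 20 mg).
Doses convert as 1 mg = 2759 nmol (MW 362.46 g/mol). IV boluses add
directly to the central compartment.

**Covariates and variability.** SA1 scales with body weight as
`(BW/70)^6.53`; clearances by `(BW/70)^0.75`, volumes by `(BW/70)^1`.
Between-subject variability is log-normal on SA1, Kout, Base, EC50 (with
the Base-EC50 pair drawn jointly), Ntr, F, CL and Vp; between-occasion
variability on MTT; residual error is proportional (53.7% ACTH, 39.5%
cortisol; unbound cortisol reuses the cortisol sigma). The printed CV% are
interpreted as 100·ω (log-scale SD). The printed Base-EC50 covariance
(0.0686) together with the printed SDs implies a correlation of 1.01; the
covariance is projected to |ρ| = 0.999 with a logged warning. Sampled F is
clipped at 1.

## Numerical choices

* ODE integration uses `scipy.integrate.odeint` (LSODA) with a
  numba-compiled right-hand side; the pure-Python `hpa_ode_rhs` is the
  reference implementation and the two are tested for exact agreement.
  Dose times and DEX-window edges are integration restarts. Defaults
  rtol 1e-8 / atol 1e-10 with max step 0.25 h (so the 0.6 h-wide morning
  surge can never be stepped over) for reported simulations; fitting uses
  rtol 1e-6 / atol 1e-8.
* Simulations start from ACTH at Base and empty cortisol compartments and
  discard a 72 h warm-up, which brings the healthy trajectory within 1e-4
  of its periodic attractor (slowest mode ≈ Kout).
* The binding inversion is the closed-form quadratic root written in a
  cancellation-free form; the round trip is exact to machine precision.
* Event tables carry clock-plus-day time so circadian semantics stay
  explicit; "pre-dose" samples default to 0.05 h before the dose.

## Estimation

The desk-scale estimator emulates the three-step workflow:

1. **Step 1 (PK)** uses only DEX-suppressed periods. DEX clamps ACTH at
   `Base`, so endogenous production reduces to a constant input `b`
   estimated per subject (anchored to the pre-dose cortisol level with a
   log-normal prior, SD 0.75 ≈ γE·ω_Base); each period then starts from an
   analytic pre-dose steady state and integrates only the observation
   window. Fixed effects (F, CL, Vc, Q, Vp, MTT_ref, dose exponent, Ntr)
   and every subject's random effects (etas on F/CL/Vp/Ntr, one MTT IOV
   eta per occasion, log b) are estimated *jointly* by penalized
   Gauss-Newton (`scipy.optimize.least_squares`, trf, sparse finite-
   difference Jacobian; eta priors enter as residual rows). Residual
   scales are frozen at the current iterate and refreshed once (IRLS):
   scaling by current predictions inside a pure least-squares cost rewards
   overprediction, scaling by observations the reverse.
2. **Step 2 (endogenous)** fits the ACTH secretion, production and
   feedback fixed effects plus per-subject etas (SA1, Kout, Base, EC50,
   with the correlated Base-EC50 prior) on the endogenous 24 h profiles
   and the DEX-only period, with each subject's PK frozen at its Step-1
   individual estimates. Same joint scheme; endogenous periods use the
   full model with a 24 h warm-up (start anchored 24 h before the first
   sample; all transient modes decay faster than 0.6 h⁻¹, so the warm-up
   error is ≲1e-5).
3. **Step 3 (joint)** re-estimates all free fixed effects together on the
   complete dataset from the Step-2 values, with random effects frozen at
   their posterior modes and error scales frozen at the step start, then
   refines the endocrine block against the *exact* proportional-error
   −2 log-likelihood (whose log-variance term the least-squares surrogate
   lacks): a derivative-free polish alternated with posterior-mode eta
   refreshes, plus a one-dimensional profile scan along the
   (Emax, EC50, γE) ridge. The reported step objective is the exact
   likelihood of the best candidate, so it never exceeds its starting
   value.

Parameters fixed by convention are never estimated: n, I_DEX, Imax, NS,
Kd, Bmax, the allometric exponents, the BW-SA1 exponent, and Ka (the data
cannot distinguish large Ka values; it is held at its initial value and
excluded from recovery claims, as are the weakly identified Ntr, γI and
SA2/SW2 whose information content at n = 13 endogenous subjects is low).
Variance components are held fixed at their configured values throughout.
`map_fit` exposes the per-subject posterior-mode (EBE) problem directly
(multi-start Levenberg-Marquardt on the penalized residuals, best solution
by the exact −2 log-likelihood + prior objective), and
`profile_or_bootstrap_se` provides case-resampling bootstrap intervals for
the pooled PK fixed effects by re-running the pooling stage on resampled
subjects.

Known identifiability limits at this design and noise level: the
production triple (Emax, EC50, γE) is informed mainly through the
combination `Emax/EC50^γE` because healthy ACTH rarely exceeds EC50; the
joint posterior-mode objective is nearly flat over EC50 ± ~30% (the large
ACTH residual error lets the subject-level etas absorb the difference), so
single-dataset EC50 estimates can sit ±30% from truth even when the
optimizer has converged — a full marginal (FOCE-type) likelihood would be
needed to concentrate it further. Ka, Ntr, γI, SA2 and SW2 are weakly
identified and documented as excluded from recovery claims.

## The virtual-trial generator

`synthetic_data` reproduces the statistical structure the analysis
assumes: trial 1 (default n = 16) with four DEX-suppressed periods and
single 0.5/2/5/10 mg oral doses at 07:00, total cortisol pre-dose,
half-hourly to 8 h and hourly to 12 h, pre-dose ACTH; trial 2 (default
n = 13-14) with an endogenous period (hourly ACTH and total cortisol
15:00→15:00, unbound cortisol at 22:00/07:00/09:00) plus DEX-only,
DEX + 20 mg oral and DEX + 20 mg IV periods sampled 0.25-12 h post 07:00
with pre-dose and 2 h unbound samples. Periods are one week apart
(washout); each oral period is an IOV occasion. DEX dosing times are not
modeled explicitly — with the all-or-none suppression model only the
window matters, and it opens 12 h before the 07:00 period start.
Covariates are uniform over the observed cohort ranges (BW 64.7-102 kg,
age 21-60 y) because only medians and ranges are published. The pre-dose
ACTH exclusion rule (> 20 pg/mL, MW 4541.1 g/mol for the unit conversion)
is applied to the generated tables; a deliberately non-suppressed subject
can be injected to exercise it.

What the generator does *not* emulate: assay quantification limits
(LLOQ/BLQ), dropout or missing samples, ultradian pulsatility,
cortisone-cortisol interconversion, and any model misspecification —
passing recovery tests therefore demonstrates the estimator is consistent
with its own generating model at the published design and variability, not
that the published parameters are correct for real patients.

## Known limitations

* The polynomial surge tails keep the nocturnal ACTH floor at
  `Base + tails/Kout ≈ 1.7 pmol/L`, ~33% above Base: "baseline equals the
  nocturnal minimum" holds only approximately in this model class.
* Typical-subject pulse suppression exceeds 95% only while unbound
  cortisol exceeds ~8 nmol/L (total ≳233 nmol/L), roughly 05:00-14:30 with
  a short morning dip; total cortisol stays above the IC50-equivalent
  (~160 nmol/L) from ~04:00 to ~17:30, where suppression is ≥50%.
* With `activity = 0` there is no feedback at all and the morning ACTH
  peak is the full surge response (~1040 pmol/L), ~177-fold above the
  healthy typical peak.
* Estimation problem sizes (iteration caps, 24 h fitting warm-up,
  rtol 1e-6) are chosen for desk-scale studies of tens of subjects; they
  are package defaults, all overridable.
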