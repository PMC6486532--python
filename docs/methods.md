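# Methods

## Model

`irtmarkov` implements a joint longitudinal item-response-theory /
continuous-time Markov model for daily ordinal questionnaire data, of the
kind produced by a 14-item COPD symptom e-diary (9 items scored 0–4, 5
items scored 0–3, a day is either fully completed or fully missing).

**Measurement model.** Each item *j* follows a graded response model: with
latent disease severity *D*, the cumulative category probabilities are

    P(Y_j >= k | D) = expit( a_j (D - b_{j,k}) ),   k = 1..K_j-1,

with discrimination `a_j > 0` and non-decreasing difficulties `b_{j,k}`.
Differencing gives the exact-category law (the *steady state* of the item).
Severity drifts linearly, `D_i(t) = d0_i + slope_i * t/365`; `d0_i ~ N(0,1)`
(variance fixed for identifiability), `slope_i ~ N(slope_mean, slope_sd^2)`
in latent units per year.

**Serial dependence.** Scores of one item form a birth–death continuous-time
Markov chain over the categories.  The whole rate structure is tied to the
steady state through a single dependence parameter, the mean equilibrium
time (MET): for every adjacent category pair,

    lambda_up(k)  = 1 / ( MET * (1 + p_k / p_{k+1}) ),
    lambda_down(k) = lambda_up(k) * p_k / p_{k+1},

so `lambda_up + lambda_down = 1/MET` for every pair and detailed balance
makes the steady state stationary.  A chain's first observation follows the
steady state; after every observation the state distribution is reset to a
point mass at the observed score and propagated through `P = expm(Q dt)`
over the elapsed day gap (missing days simply lengthen one interval).
MET carries a log-normal subject effect, `MET_i = MET_pop(t) e^eta`,
`eta ~ N(0, omega^2)` — the standard pharmacometric "exponential" IIV model,
chosen because it guarantees positivity.  The population MET profile is
constant, linear (`met0 + met_tslope * t`) or power (`met0 (1+t)^met_tslope`);
the single coefficient field changes meaning with the mode.

Items are conditionally independent given the subject's random-effect
vector `(d0, slope, eta)`, which is assumed mutually independent.

## Numerics of the kernel

Every generator built here is reversible, so
`M = diag(sqrt(pi)) Q diag(1/sqrt(pi))` is symmetric and the kernel is
evaluated through the (batched) symmetric eigendecomposition — numerically
exact even in the stiff regime `dt >> MET`, where scaling-and-squaring expm
accumulates round-off above 1e-6.  Steady-state probabilities are floored
at 1e-12 before rate ratios are formed (logistic probabilities are never
exactly zero; the floor only matters at extreme severities).  Within one
inter-observation interval, `D` and MET are frozen at the interval's left
endpoint (piecewise-constant approximation; daily sampling makes
within-interval drift negligible — a `midpoint` evaluation option exists for
sensitivity checks).  Degenerate inputs: a 4-category item simply has no
fifth state (no rates to it); a numerically non-positive kernel entry
reports `-inf` log-likelihood rather than raising.

One caveat worth knowing: "dt of a few hundred MET reaches the stationary
law" holds only without probability bottlenecks.  A stationary law with a
tiny *interior* category mixes across that category at a rate far slower
than 1/MET, so the equilibrium limit is approached at the bottleneck rate,
not the MET rate.  Realistic item parameters (cut-point gaps around 1
latent unit) are nowhere near this regime.

## Estimation

The marginal likelihood integrates the conditional likelihood over the
(standardised) random effects.  The default is a Laplace approximation:

* inner problem — per subject, the mode of `loglik(eta) - |eta|^2/2` is
  found by damped Newton iterations, batched across all subjects; gradients
  of the conditional log-likelihood are analytic throughout (logistic
  chain rules plus the eigendecomposition form of the Frechet derivative of
  the matrix exponential; the derivative with respect to log MET reduces to
  `-dt (M P)_rc / P_rc` because M scales as 1/MET).  The inner negative
  Hessian comes from finite differences of the analytic gradient
  (step 1e-4), with eigenvalue clipping for safety; inner tolerance 5e-5 on
  the gradient, warm-started across outer iterations.
* outer problem — L-BFGS-B on an unconstrained scale (log a, first
  cut-point plus log-increments, log met0, log SDs; increments keep the
  difficulty ordering by construction).  The gradient is the analytic
  conditional-likelihood gradient at the mode (envelope theorem) plus the
  explicit parameter-dependence of the log-determinant term, computed as
  directional second differences of the analytic parameter-gradient along
  the inner-Hessian eigenvectors (`tr(H^-1 dH/dtheta)` with the `1/w`
  weights folded into the perturbation sizes).  The only omitted piece is
  the coupling through the inner-mode shift, which we measured at well
  under one OFV-gradient unit on validation fixtures; without the explicit
  log-determinant part the optimiser exhibits stall points and a
  systematic upward bias of the discriminations, so it is always included.
  The optimiser is restarted (memory cleared) from any stall point; an
  optional `refine` phase performs Newton steps with fully
  finite-differenced gradients and resolves optima below 0.1 OFV units on
  small problems.

Adaptive Gauss–Hermite quadrature (nodes centred at the Laplace mode and
scaled by its Hessian; >= 7, default 15 nodes per active dimension) serves
as the accuracy oracle; on small fixtures Laplace agrees with 15-node AGHQ
to well within 0.5 log-units per subject.  OFV is reported as -2 log
marginal likelihood and nested models are compared by chi-square on their
OFV difference (3.84 at one degree of freedom for p < 0.05).

Initial values come from per-item collapsed fits: each item's categories
are merged to 3 in up to three overlapping schemes (0|1|rest, low|mid|high,
rest|next-to-top|top), each collapsed item is fitted as a small mixed model
(baseline severity integrated by 8-node Gauss–Hermite — the discrimination
is only identified through between-subject heterogeneity) using the
analytic 3-state kernel (spectral projectors of the 3x3 generator), and the
cut-point estimates are mapped back, averaging where two schemes estimate
the same cut-point; the initial MET is the mean of the collapsed-fit METs.

Standard errors come from a finite-difference Hessian of the OFV, inverted
with modified-Cholesky-style eigenvalue regularisation (flat directions of
the soft discrimination/difficulty ridge yield large, not degenerate, SEs)
and mapped to the natural scale by the delta method.

## Simulator

The simulator is the model run forward: steady-state draw at a subject's
first observed day, kernel-row draws thereafter.  Ensembles advance all
subjects and items on the daily grid at once and delete unobserved days,
which is equivalent in law (Chapman–Kolmogorov) to gap-lengthened kernels
up to the piecewise-constant parameter approximation.

The study-like fixture emulates the structure of a year-long observational
COPD diary: 14 items on the two scales; ~28% of subjects stop filling in
the diary before the end (uniform dropout day); whole-day gap episodes
(Poisson count, geometric lengths, mean 3 days) reproducing a median of
~13 missing days per subject at year scale; age ~ N(67, 8^2) in 42–85 and
54% male.  Missingness is non-informative — independent of the latent
state — so passing tests say nothing about informative dropout.  The
default population uses a linear MET profile rising 1.2 -> 5.1 days over
the year, progression 0.007 latent units/year with 122 %CV, omega = 0.3,
and a synthetic but realistic item catalogue (a in [1, 2.5], cut-points
spread over [-2, 3]); the published instrument's estimated parameters are
not publicly deposited, so no claim of parameter-level realism is made.
The compact 5-item validation population (`example_population`) uses
a = 1.0..2.5, cut-points in [-2, 2.2], constant MET 2 d, omega 0.3,
slope 0.2 ± 0.1 per year.

## Diagnostics

* **VPCs** simulate replicates on the observed design (fresh random
  effects each) and compare observed statistics with 2.5–97.5 percentile
  bands: per-score proportions per 28-day bin (pooled or per item),
  conditional transition proportions `P(current | previous, bin)`, and
  2.5/50/97.5 percentiles of the 0–100 scaled total.  Cells whose band and
  observation are identically degenerate (statistics never realized, e.g.
  far-off-diagonal jumps) are excluded from coverage summaries.  Default
  1000 replicates; validation uses 200 for speed.
* **Residuals**: IPRED is the probability-weighted expected score given
  the previous observation and elapsed time (steady state for first
  observations); RES = observed - IPRED.  The item correlation map shows
  Pearson correlations of paired residuals off-diagonal and, on the
  diagonal, observed-minus-simulated lag-1 autocorrelation over
  consecutive calendar days only.
* **Fisher information** per item is the expected information of the
  steady-state categorical likelihood, `I(D) = sum_k (p_k')^2 / p_k`
  (equal to the expected negative curvature of the log-likelihood;
  verified against finite differences at 1e-6 relative).  Population
  summaries evaluate it at standard-normal severity quantiles (5/50/95 by
  default) at baseline; information scales with `a^2`, so item rankings
  are not invariant to rescaling discriminations.

## Total scores and exacerbation events

The raw daily total (maximum 51 on the standard catalogue) is scaled to
0–100 linearly by default; the instrument's proprietary scoring table can
be plugged in as a lookup and is honoured bit-exactly.  A symptom-defined
exacerbation is a rise of the scaled total over a rolling baseline of at
least 12 points on each of 2, or at least 9 points on each of 3,
*calendar-adjacent* data days (a missing day breaks the run; a zero
baseline can never produce an event; the event's onset day is the day the
qualifying run completes).  Baselines reset every 28 days: block 1 uses
the mean total of study week 1; later blocks the mean of the last 7 days
of the previous block when at least 4 of them have data, else the previous
baseline carries forward.  Detection continues after an event, but
cumulative incidence curves count first events only.  Only the increment
over baseline matters, so adding a constant to scores and baselines leaves
events unchanged (except through the zero-baseline rule).

## Validation scales and known limitations

Validation jobs are sized to run on one CPU in minutes: the parameter
recovery study uses 100 subjects x 5 items x 100 complete days (three
replicates in the test suite, one in the acceptance script), VPC
self-coverage uses 28 subjects x 112 days x 14 items with 200 replicates
and 14-day bins (coverage pooled over informative cells only: degenerate
cells and physically near-impossible distant-jump transition cells are
excluded), and the exacerbation contrast 120 subjects x 84 days.  At this scale MET
recovers within a few percent and discriminations within ~10%; cut-points
carry 2-SE-level uncertainty, and one replicate in three shows a
correlated latent-scale wobble on several cut-points — the soft
discrimination/difficulty ridge is the model's weakly identified
direction at these sample sizes.

Known limitations: one latent dimension (residual item correlations within
symptom domains are visible in the correlation map, not modelled);
non-informative missingness only; the Laplace objective carries the usual
small-sample bias for ordinal data; Box–Cox MET-IIV and covariate effects
are out of scope (the literal Exponential MET-IIV reading is available in
the simulator behind a flag, not used by estimation).
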