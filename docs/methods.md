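# Methods

This note records the model, the procedure each module implements, the
defaults and why, the numerical choices, and what the simulations do and do
not establish.

## Outcome model and scenarios

A patient carries three independent binary biomarkers (default prevalence
0.3 each), giving 8 profiles. Binary response is generated from a logistic
model with intercept `mu`, treatment main effects `theta_k`, biomarker main
effects `beta_j` and treatment-by-biomarker interactions `gamma_kj` — 16
coefficients in total. All effects are additive on the log-odds scale, so a
patient positive for several biomarkers accumulates every applicable
interaction.

The scenario library fixes `mu = logit(0.3)` (30% control response) and
`beta = 0` (no prognostic main effects) and varies the interaction
structure: a beneficial interaction is `logit(0.6) − logit(0.3) = 1.2528`
(response doubles to 60% in the affected subgroup), a detrimental one is
`logit(0.11) − logit(0.3) = −1.2434` (response falls to 11%). Scenario 4's
"moderate benefit in all subgroups" is not pinned down numerically by the
published description; we default to `theta_1 = 0.63` (half the beneficial
interaction), configurable. Scenarios 7 and 8 reuse the two printed
magnitudes. These three choices are inferences, not published values.

Accrual is deterministic and uniform: patient *i* of *N* arrives at
`duration · i / N` months (default 350 over 36). Determinism isolates
Monte-Carlo noise in outcomes and randomisation; a Poisson accrual process
would add variance without changing means. Outcomes become observable
exactly `delay` months after recruitment (default 6).

## Interim Bayesian analysis

At each interim the 16-coefficient logistic model is fitted to the patients
whose outcomes have matured. Priors: flat on [−10, 10] for every
coefficient; in the linked design, additionally N(1, 1) on the three linked
interactions `gamma_kk`. The allocation consumes the superiority
probabilities `p_k(b) = P(theta_k + sum_j b_j gamma_kj > 0 | data)`.

The posterior computation is importance sampling from a Laplace proposal:

1. maximise the log-posterior under the box bounds (L-BFGS-B; informative
   priors contribute quadratic penalties);
2. form the Laplace curvature: the inverse of (Fisher information + prior
   precision + curvature floor), where the floor `12 / width² ≈ 0.03` is
   the precision of a Gaussian moment-matched to the uniform box prior (a
   ridge is escalated tenfold on top in the rare event the matrix is still
   not positive definite);
3. draw `n_draws` (default 4000) samples from a hybrid proposal:
   coordinates whose mode is pinned at a box bound, or whose Laplace
   spread sits at the floor (the data leave them essentially flat), are
   proposed uniform over the box — their posterior marginals are
   near-uniform or bound-hugging shapes a mode-centred Gaussian covers
   badly — while the informed coordinates are drawn from the Gaussian
   Laplace block;
4. attach self-normalised importance weights `posterior / proposal`
   (draws outside the box get zero weight, which enforces the box prior
   exactly) and estimate each superiority probability as the weighted
   frequency of the contrast exceeding zero. If the effective sample size
   of the weights falls below `n_draws / 100` the estimate falls back to
   unweighted Gaussian draws clipped to the box (logged).

The reweighting step matters: the plain normal approximation misses the
skewness of small-sample logistic posteriors by up to ±0.04 on individual
superiority entries, while the reweighted estimator agrees with a long,
convergence-checked ensemble-MCMC reference to within ±0.013 on a
200-patient fixture (the test suite re-runs this comparison). The uniform
component matters under prior-data conflict (a linked arm that is actually
harmful): there, several interaction coefficients are typically pinned at a
bound and a pure-Gaussian proposal degenerates to effective sample sizes
below 10. Early interims (~41 matured outcomes for 16 parameters) still
run at effective sample sizes of a few hundred — noisy, but unbiased in a
way plain Laplace is not.

## Allocation rule

Initial stage, linked designs (LB, PT): equal probability over control and
the arms linked to the patient's positive biomarkers; all-negative patients
are randomised 1/4 to every arm. NLB and ER: 1/4 everywhere.

After the first interim with any matured outcomes, the adaptive designs
(LB, NLB) set, for each profile *b*, experimental weights

    w_k = p_k(b)^h(t),   h(t) = a (t/N)^s

with recruitment fraction `t/N` and defaults `a = 3`, `s = 0.5`, and a
control weight

    w_0 = max_k(w_k) · exp(eta (n* − n_0) / (n_b + 1)),   eta = 1.25

where `n*` is the count on the best-recruited experimental arm for this
profile, `n_0` the control count and `n_b` the profile total. The row
(w_0, w_1, w_2, w_3) is normalised. Superiority probabilities are frozen
between interims; the control weight is recomputed after every recruit from
live counts, so control exposure tracks the best-recruited arm (control
matching) without needing outcome data between interims. PT and ER never
adapt.

The increasing exponent is the one genuinely open design choice. Published
BAR procedures of this family sharpen allocation as the trial matures —
near-balanced early (protecting the interim model from starving arms it
still knows little about), strongly concentrated late. We validated the
(a, s) and eta defaults against the published operating-characteristic
table: with them, the simulator reproduces the family-wise error rates of
both adaptive designs to within about 0.02 and their powers to within
about 0.03;
a constant exponent of 1 ("allocation directly proportional to the
posterior probabilities") inflates the linked design's family-wise error
rate by ~0.08 and is therefore not the default, though
`BarTuning(power_scale=c, power_shape=0)` recovers any constant-exponent
rule.

Tie-breaking for `n*` is immaterial (only the count enters the formula).
If every `w_k` is zero (degenerate posteriors), allocation falls back to
equal mass over control plus the arms with positive superiority, and the
event is logged. An optional `min_prob` floor exists but defaults to 0.

## Trial engine

Interims trigger on recruitment counts: the first at 100 recruits, the rest
equally spaced over the remainder (rounding half up; 350/100/4 interims
gives 100, 163, 225, 288). An interim with zero matured outcomes skips the
refit and keeps the current allocation (logged). Recruitment never pauses,
so recruit times are identical across variants for a fixed seed; patient
randomness is split into independent substreams (profiles, outcomes,
assignments, posterior draws), which lets variants share patient-level
randomness for variance-reduced comparisons. Everything is deterministic
given (seed, design, scenario); a replay helper recomputes every patient's
allocation row from the recorded posterior history as an audit.

## Final analysis

Classical ML fit of the same 16-coefficient model on the complete data,
using a dense Newton solver (the fit is 350×16; a solver call is ~0.2 ms,
which is what makes 10 000-replicate studies cheap). Separation is routine
— adaptive starvation and 32 (arm × profile) cells guarantee empty or
one-sided cells — and is detected as non-convergence, divergence of a
coefficient past ±12, or a singular information matrix; the fit then
switches to Firth bias-reduced logistic regression (Jeffreys penalty via
the hat-matrix diagonal, Newton with step-halving on the penalised
log-likelihood to prevent oscillation on near-separated data). Columns with
no data at all are dropped; contrasts touching them score 0 and never
reject. Wald statistics use the inverse (penalised) Fisher information;
rejection is one-sided in the benefit direction at 1.5 (one-sided
p ≈ 0.067) with no further multiplicity adjustment — the design
deliberately tolerates a family-wise error rate near 0.4, appropriate for
phase II screening where rejections feed confirmatory trials rather than
licensing.

## Monte-Carlo studies

`run_oc` estimates the 12 recommendation probabilities plus "recommend any"
over independent replicate trials. Replicate seeds are
`SeedSequence(seed, spawn_key=(replicate_id,))`, so results are independent
of worker scheduling and split runs pool exactly. Default replicate counts
follow the published study sizes (2 500 for the BAR designs, 10 000 for the
others); the test suite and acceptance script scale some BAR runs down
(500–800) where the widened tolerances permit. `allocation_trajectory`
averages the live allocation row of a chosen profile at every recruitment
index; `prevalence_sweep` varies B1 prevalence over 0.10–0.50 (step 0.025
by default); `sensitivity_grid` exposes the number of stages, the linked
prior mean and the recruitment rate (accrual duration = N / rate, delay
fixed).

## What the synthetic data do and do not emulate

The generator reproduces the study conditions: independent biomarkers at
fixed prevalence, a correctly specified logistic outcome model, uniform
accrual, a fixed outcome delay, complete outcome ascertainment. It does not
emulate biomarker assay error or missingness, patient dropout, drifting
recruitment rates, prognostic biomarker effects (`beta` is estimated but
zero in every library scenario), biomarker–biomarker interactions, or
model misspecification. Passing tests therefore demonstrate the operating
characteristics of the designs under the stated simulation model, not
robustness of the designs to violations of it.

## Numerical choices and degenerate inputs

* Logistic solvers: Newton tolerance 1e-8 (ML) / 1e-6 (Firth), step cap 5,
  ML divergence bound ±12, Firth step-halving up to 12 halvings.
* Laplace/IS: L-BFGS-B with analytic gradients, ftol 1e-12; curvature
  floor 0.03; ESS fallback threshold `n_draws / 100`; 4000 draws.
* Interim schedule rounding: half up; configurable only through the
  schedule function.
* Zero matured outcomes at an interim: skip the refit (the initial rule
  continues to apply).
* A totally failed final fit (ML and Firth both non-convergent) yields an
  empty-fit sentinel: all 12 statistics 0, nothing rejected, logged. This
  did not occur in any of the ~10^5 simulated trials run during
  development after the Firth line search was added.
* Prevalence 0 or 1 is allowed in the generator (degenerate profiles) but
  not in sweep grids.

## Known limitations

* The allocation functional form is a reconstruction validated against
  published aggregate results; per-patient allocation paths may differ from
  the original procedure even where operating characteristics agree.
* The interim posterior is importance-corrected Laplace, not exact MCMC;
  its accuracy contract (±0.02 on superiority probabilities vs a long MCMC
  reference at 200 patients) is enforced by test, but accuracy at the first
  interim (~41 outcomes) is looser.
* Scenario-2 powers of the two BAR designs run ~0.03 below the published
  values (within the stated reproduction tolerance); the family-wise error
  rates and the unlinked-effect powers match to ~0.02.
* Early stopping, time-to-event endpoints, intermediate endpoints,
  biomarker hierarchies and multi-treatment linkage are out of scope.
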