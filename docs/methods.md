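# Methods

## Model

A multistate process on states 1..S with transitions g = 1..G, each a
directed pair (i, j).  Under the clock-reset convention the time axis of
every sojourn restarts at 0 on state entry, and transition g has intensity
λ_g(t) = λ_g0(t)·exp(βᵀZ_g) with t the time since entering the origin
state.  Data are long format: one record per patient-at-risk-for-
transition, so a patient occupying state i contributes one record for
every transition leaving i, all sharing the sojourn interval; the
transition actually taken carries status 1.  The membership indicator
I_gi marks whether patient i ever contributed a record to transition g.

The expanded design encodes the covariate-to-transition mapping: each
design column is a baseline covariate restricted to a set of transitions
(value there, zero elsewhere).  Mapping one column to several transitions
shares the coefficient; distinct columns per transition give
transition-specific effects.  A single coefficient vector β of length p
therefore covers the whole process.

All transitions pool into one partial likelihood.  For each event record
(g, k),

    ℒ_gk(β) = Z_gkᵀβ − log Σ_{l ∈ R(t_gk)} exp(Z_glᵀβ),

where the risk set R(t) contains the records of transition g with
entry < t ≤ exit.  Ties are handled Breslow-style: tied events share the
full risk-set denominator, and a record exiting exactly at an event time
is in that event's risk set regardless of its own status.  Censored
records enter only through risk sets — the event sum never includes them.

Score and Hessian are the standard weighted-mean and weighted-covariance
forms: each event contributes U_gk = Z_gk − (Σ Q_l Z_l)/C with
Q_l = exp(Z_lᵀβ), C = Σ Q_l, and minus the Q-weighted covariate
covariance over its risk set, so the Hessian is symmetric negative
semidefinite and the log partial likelihood concave.  The cumulative
baseline hazard per transition is Nelson–Aalen: jumps 1/C at event times,
estimated only after convergence; no influence quantity depends on it.

## Estimation

Newton–Raphson from β₀ = 0 with step-halving whenever a step would lower
the likelihood; convergence when the max-abs score component falls below
1e-8 (at most 50 iterations, then an error — never a silent partial
result).  The variance V = −ℒ̈⁻¹ is obtained by solving against the
symmetrized Hessian, then symmetrized again; a singular Hessian (collinear
design within the risk-set structure, or a likelihood with no curvature)
raises immediately.  With p = 0 the fit degenerates to the null model and
only the baselines are meaningful.

## Case-deletion (global) diagnostics

The patient score Uᵢ = Σ_g U_gi·I_gi sums the patient's own event
contributions; a patient's appearances in other patients' risk sets are
deliberately excluded — that omission is precisely what the one-step
approximation β̂₍ᵢ₎ ≈ β̂ − V·Uᵢ trades against an exact refit.  The
likelihood displacement LDᵢ = 2[ℒ(β̂) − ℒ(β̂₍ᵢ₎)] always evaluates the
full-data likelihood, with β̂₍ᵢ₎ from either the one-step formula or an
exact refit (all records of patient i removed, warm-started at β̂; the
answer is start-point independent because the objective is concave).  The
one-step generalized Cook distance is Dᵢ = UᵢᵀVUᵢ/p.  Only whole patients
are deleted: removing a single transition would change the parameter
space and represent patients inconsistently.

## Case-weight (local) diagnostics

Curvature matrix B = Δᵀℒ̈⁻¹Δ via linear solves (never explicit inverses);
B is negative semidefinite, so tr B ≤ 0 and the index curvatures
Bᵢ = |bᵢᵢ/tr B| sum to one.  The conformal normal curvature
B_h = |hᵀBh|/|tr B| is bounded in [0, 1] for every unit direction and is
invariant to reparameterizations of β (verified in the tests by rescaling
covariate columns).  hmax is the unit eigenvector of the symmetrized B
with largest-magnitude eigenvalue, sign fixed so its largest entry is
positive; ties break deterministically toward the lowest eigen-index.
A unit is flagged when Bᵢ strictly exceeds mean(B) + 2·sd(B), with the
sample (n−1) standard deviation.

The three schemes:

* **Scheme I** (r = N records): weight each log-likelihood component,
  null weights all one.  Δ columns follow transition-major record order;
  an event column is v_gk·U_gk with v_gk = 1 − exp(Z_gkᵀβ̂)/C_gk, a
  censored record keeps a zero column (it is still a component of ω).
  This closed form keeps only own-record terms; the exact mixed partial
  would also carry cross-risk-set terms because the weights sit inside
  the risk-set sums.  Both are implemented — `delta_scheme1` is the
  canonical closed form, `delta_scheme1_full` the full-derivative
  diagnostic — and they are *not* asserted equal.
* **Scheme II** (r = G transitions): component weights 1 + (N_g/N)·ω_g
  with null ω = 0; Δ column g is (N_g/N)·Σ U_gk.  Validated against
  finite-difference mixed partials of the perturbed likelihood.
* **Scheme III** (r = M patients): weights ω_k on every component of
  patient k, null all one; Δ column i is exactly the patient score Uᵢ.
  Hence p·Dᵢ = ΔᵢᵀVΔᵢ = |bᵢᵢ|: the per-patient curvature and the
  one-step Cook distance rank and flag identically — this identity is
  enforced to 1e-10 in the tests.

M is taken as the number of distinct patient ids (in file order); for the
breast-cancer graph, where everyone starts in state 1, this coincides
with N₁.

## Synthetic cohorts

The generator emulates the breast-cancer study conditions: the 5-state
graph, a tumor-size-like covariate (Gamma, mean 25 mm, sd 12.5 mm) and a
binary grade-like marker, both shared across all transitions with true
log hazard ratios 0.03 per mm and 0.4; constant baseline rates per
transition (0.0005–0.02 per month) chosen so first events land a few
years after surgery; administrative censoring at 180 months plus an
independent exponential censoring clock (rate 1/360 per month), giving
roughly one-third censoring.  Sojourns are competing independent latent
clocks (exponential by default, per-transition Weibull shapes available),
minimum taken, clock reset on entry.  Default cohort size is n = 300.

Contamination injects the influential-case patterns the diagnostics
target: multiplying a covariate by 6 (pushing typical tumors past
100 mm), shrinking the sojourn ending in the patient's first event to 5%
(fast progression), or inflating post-relapse sojourns.  Contaminated
patients are drawn among those with at least one event, since a fully
censored patient has Uᵢ = 0 and is invisible to every case-weight
measure — matching the motivating cases, which are patients who
progressed.  Contaminated ids are returned as ground truth.

What the generator does *not* emulate: covariate-dependent censoring,
measurement error, time-varying effects, non-proportional hazards, missing
data, or the empirical transition frequencies of any real registry.
Passing tests therefore demonstrate correctness of the estimators and
diagnostics under a well-specified proportional-hazards process, not
robustness to model misspecification in real cohorts.

## Data-preparation rules

Times are months, stored as reals.  Simultaneous local and distant
relapses are resolved by assuming local-before-distant progression and
adding 0.1 months to the distant-relapse time (idempotent); a local
relapse recorded after a distant one is dropped.  Covariate truncation
(e.g. recoding sizes above 80 mm to 80 mm) is monotone and idempotent and
returns a new dataset.  Zero-length at-risk intervals, unknown transition
ids and duplicate (id, transition) pairs are rejected at read time with
row numbers.

## Numerical choices and problem sizes

Degenerate inputs: an event with an empty risk set signals broken data
preparation and raises; tr B = 0 (zero Δ) is reported as all-zero
curvatures with a warning rather than NaNs; flagging needs r ≥ 2.
Finite-difference validations exploit that the perturbed likelihoods are
linear in ω, so the ω-difference is exact and only the β-difference is
approximate.  Test and validation problem sizes — 50 random datasets with
n ≤ 30 for derivative checks, n = 200 for the one-step-vs-exact and
Cook/curvature identities, n = 300 with 100 replicates for detection
power, n = 500 with 200 replicates for coverage — were chosen as the
smallest scales at which the corresponding asymptotic properties are
clearly expressed.

## Known limitations

Breslow ties only (no Efron option); no stratified baselines beyond
per-transition, no time-varying coefficients, no robust/sandwich
variance, no interval censoring; no covariate- or censoring-perturbation
schemes; no group deletion.  The one-step quantities degrade for patients
with very large leverage — exactly the cases the exact-refit mode exists
for.
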