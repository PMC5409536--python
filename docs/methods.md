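# Methods

## Model

A single receptor is exposed to a mixture of ligand species, here two: a
cognate species (binding rate k_c per unit concentration, unbinding rate
r_c) and a non-cognate one (k_nc, r_nc). Binding is diffusion-limited, so
k_c ~ k_nc; the species are distinguished by their off-rates, with the
convention r_c < r_nc (the cognate ligand stays bound longer). The receptor
alternates between unbound intervals τᵘ ~ Exponential(k_c c_c + k_nc c_nc)
and bound intervals whose species is drawn with probability proportional to
k_i c_i and whose duration is Exponential(r_i). The data are the interval
sequences {τᵢᵇ, τᵢᵘ}, i = 1..n; the final unbound interval wraps around,
combining the lead-in before the first binding with the tail after the last
unbinding. Rates are assumed known; the concentrations (c_c, c_nc) are the
unknowns.

The probability density of a trace factorizes over events:

    P ∝ ∏ᵢ exp(-τᵢᵘ Σ k_j c_j) · D(c, τᵢᵇ),
    D(c, τ) = Σ_j k_j c_j r_j exp(-r_j τ).

## Maximum-likelihood estimator

The log-likelihood (dropping the combinatorial normalization, whose
concentration derivatives vanish in the stationarity conditions used here) is

    log P = -Tᵘ Σ k_j c_j + Σᵢ log D(c, τᵢᵇ),   Tᵘ = Σ τᵢᵘ.

Multiplying the two stationarity equations by the respective concentration
estimates and adding gives the exact identity

    k_c c_c* + k_nc c_nc* = n / Tᵘ,

i.e. the total on-rate is fixed by the mean unbound interval. The solver
exploits this: the problem is reduced to a one-dimensional concave
maximization along the constraint line, parameterized by the cognate
on-rate fraction f = k_c c_c / (n/Tᵘ) ∈ [0, 1]. The derivative in f is
monotone, so a bracketed Brent root-find (relative tolerance 1e-8, 200
iteration cap) either finds the interior optimum or the sign test selects a
boundary endpoint (one concentration exactly zero), which is then the exact
single-species maximizer. D is always evaluated through log-sum-exp: bound
intervals with τ·r_nc of several hundred occur routinely and would underflow
a direct evaluation.

Error bars come from the observed information: the Hessian of log P is
minus a sum of rank-one outer products of (k_j r_j e^{-r_j τ})/D, so every
entry is negative and the matrix is negative semidefinite; its negative
inverse at the optimum is the per-trace covariance (the Cramér-Rao scale).
At a boundary optimum the asymptotic theory does not strictly apply; the
package reports the curvature-based covariance evaluated at the constrained
optimum (well-defined there, since D > 0 for all events when the other
concentration is positive) and sets a `boundary` flag so downstream
consumers can treat it as a one-sided approximation. The public `hessian`
operation refuses boundary points outright.

Scaled errors are reported as E = n σ²(ĉ)/c², the squared coefficient of
variation per binding event; E = 1 is the single-ligand benchmark. Two
definitions are computed over replicate ensembles: (a) the mean
inverse-Hessian variance (the default, used by all headline numbers) and
(b) the ensemble variance of the estimates (a consistency cross-check; the
two agree within sampling error, and (b) can never fall significantly below
(a) by the Cramér-Rao bound). The correlation ρ between the two estimates
comes from the averaged inverse-Hessian covariance. E uses the true
concentrations in the denominator when the truth is known (simulation
studies) and the estimates otherwise.

## Threshold (long-event) estimator

Bound intervals with τᵇ ≥ Tc (ties count as long) are attributed to the
cognate ligand. With n_l such events,

    c_cᵃ  = n_l e^{r_c Tc} / (k_c Tᵘ),
    c_ncᵃ = (n - n_l e^{r_c Tc}) / (k_nc Tᵘ),

which preserves the total-on-rate identity exactly for every trace and
cutoff. In finite samples c_ncᵃ can be negative; it is returned unclipped
(with a flag) so that the bias/variance algebra of ensemble statistics is
preserved, and clipping is available as an explicit option.

Closed-form error model (using ⟨Tᵘ⟩ = n/(k_c c_c + k_nc c_nc), unbound
intervals being independent):

    ⟨c_cᵃ⟩  = c_c + (k_nc c_nc / k_c) e^{-(r_nc - r_c) Tc}         (bias ↓ in Tc)
    σ²(c_cᵃ) = ⟨c_cᵃ⟩ (c_c + k_nc c_nc/k_c) e^{r_c Tc} / n          (variance ↑ in Tc)

The variance form is derived from Poisson statistics of the rare long
events; in fact it holds more broadly, because the sub-Poisson (binomial)
correction to var(n_l) cancels exactly against the fluctuation of Tᵘ in the
denominator — which is why the unit tests see agreement well outside the
nominal rare-event regime. The loss L = variance + bias² trades the two off;
setting dL/dTc = 0 (with ⟨c_cᵃ⟩ ≈ c_c near the optimum) gives the
closed-form optimal cutoff

    Tc* = log( 2 Tᵘ (r_nc/r_c - 1) k_nc² c_nc² / (k_c c_c) ) / (2 r_nc - r_c).

Tc* depends on the unknown concentrations only logarithmically, so a fixed
reference cutoff is practical: T0 is Tc* evaluated at the reference
on-rates k_c c_c = k_nc c_nc = 1/2 with ⟨Tᵘ⟩ = n, which simplifies to
T0 = log(n (r_nc/r_c - 1)) / (2 r_nc - r_c). Note that T0 grows
logarithmically with the number of events n: fixed-cutoff efficiency ratios
quoted at one sequence length shift slightly at another (see Limitations).
The non-cognate loss is obtained from the exact linear constraint in the
regime where n_l variability dominates: bias_nc = -(k_c/k_nc) bias_c,
σ²(c_ncᵃ) = (k_c/k_nc)² σ²(c_cᵃ). A soft validity check warns when
r_nc·Tc < 3 (long events no longer predominantly cognate).

## Kinetic-proofreading readout

Two messengers downstream of the receptor implement the threshold estimator
chemically: B is produced at rate k_B whenever the receptor is bound, A at
rate k_A only once the current binding has outlasted the proofreading delay
Tc; both decay in first order (r_A, r_B). Time-averaging the gated
production over the binding statistics gives

    Ā = [Σ_j (k_j c_j/r_j) e^{-r_j Tc}] / Q · k_A/r_A,
    B̄ = [Σ_j (k_j c_j/r_j)] / Q · k_B/r_B,      Q = 1 + Σ_j k_j c_j/r_j.

B̄ saturates at k_B/r_B; below saturation X = B̄/(k_B/r_B - B̄) recovers
Σ k_j c_j/r_j exactly, and together with the cognate-only reading of Ā
(valid for Tc ≫ 1/r_nc) the pair inverts to (c_c, c_nc) in closed form.
When the occupancy ϵ = B̄/(k_B/r_B) is small the inversion linearizes to

    c_c^KPR  = Ā e^{r_c Tc} r_c r_A/(k_c k_A),
    c_nc^KPR = (r_nc/k_nc)(r_B B̄/k_B - Ā e^{r_c Tc} r_A/k_A),

the chemical analog of the threshold estimator; the subtraction is the
incoherent-feedforward node. ϵ is always reported so users can judge the
linearization (the exact-vs-linear discrepancy is bounded by ~2ϵ).

A multi-step proofreading cascade makes the delay random with variance
σ²_Tc. Averaging the survival probability e^{-r_c Tc} over the delay and
expanding to second order renormalizes the effective cutoff to
T̄c - r_c σ²_Tc/2; Monte-Carlo validation draws per-event Erlang delays with
matched mean and variance (only these two moments enter the formulas — the
Erlang is a modeling choice representing a chain of exponential proofreading
steps, and the expansion requires the delay spread to be modest,
r_c σ_Tc ≲ 0.3, and the delay distribution not to reach down to times where
non-cognate events survive). The relative readout noise of the proofread
branch,

    σ²_A/Ā² = Q e^{r_c Tc - r_c² σ²_Tc/2} / (k_c c_c (1/r_c + 1/r_A)),

is Poisson shot noise of the rare long events (arrival rate
k_c c_c e^{-r_c Tc}/Q per unit time) filtered by the burst duration 1/r_c
and the messenger memory 1/r_A; intrinsic production noise is neglected, as
it is suppressed by large k_A. The trace-driven stochastic simulator
(`trace_sim.simulate_messengers`, an exact SSA over the gated occupancy
timeline) validates both the means and this variance.

## Sequestration circuit

For similar ligands (r_c ≲ r_nc) a different architecture estimates the
cognate concentration alone: an activator A (production drive β_A, after an
extra proofreading delay Tc) and an inhibitor I (drive β_I, no extra delay)
degrade in first order and sequester each other at rate r_AI:

    dA/dt = β_A - r_A A - r_AI A I,
    dI/dt = β_I - r_I I - r_AI A I.

The drives are occupancy-weighted productions analogous to Ā and B̄. With
the matched-gain tuning k_A = k_I e^{r_nc Tc}, the difference β_A - β_I has
a numerator proportional to k_c c_c (e^{(r_nc-r_c)Tc} - 1) — independent of
c_nc to machine precision — so sequestration strips the non-cognate
contribution from the A branch. The steady state solves a quadratic
(eliminating I through its exact balance I_ss = β_I/(r_I + r_AI A_ss)); the
package always uses the general positive root and checks its residual to
1e-9, with the r_A = r_I, degradation ≪ sequestration limit form provided
separately. A warning (not an assumption) flags parameter sets where
r_A/(r_AI A_ss) > 0.1. The circuit is antagonistic: with c_c > 0, A_ss
decreases as c_nc rises (the non-cognate ligand occupies the receptor
without adding to the matched difference), while with c_c = 0,
A_ss = I_ss = sqrt(k_I k_nc c_nc / (r_AI (k_nc c_nc + r_nc))) grows with
c_nc — a weak ligand activates alone but antagonizes a strong agonist.

ODE trajectories use an implicit adaptive integrator (Radau, rtol 1e-9,
atol 1e-12): the sequestration term is stiff for large r_AI.

## Synthetic data: what it does and does not emulate

The generator *is* the model: memoryless two-state receptor kinetics with
exponential intervals, known rates, fixed concentrations, one receptor.
Consequences for interpreting green tests: they certify the estimators and
circuit algebra under the model's own assumptions, not robustness to
receptor internalization, diffusive ligand depletion or rebinding, rate
misspecification, time-varying concentrations, or correlations among
multiple receptors — all of which real membranes have and none of which is
modeled. Traces are parameterized by the number of events n (total time is
derived); a fixed-duration variant exists but truncates the final interval
and is not used in the replicated studies.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed; sweeps derive
per-replicate generators from `SeedSequence((master_seed, point_index,
replicate))`, so tables are bit-reproducible. The replicated studies run at
desk scale: 500 traces × 3,000 events for the fixed-cutoff comparison, 300 ×
3,000 for the single-ligand limit, 300 × 10,000 for the near-degenerate
regime. These sizes were chosen because every reported quantity is a mean
or ratio whose Monte-Carlo error at this replication (relative s.e. of a few
percent) is already well below the effects being measured; a full-scale
configuration is a `SweepConfig` away.

## Numerical choices

- log-sum-exp for all D evaluations (τ·r products up to ~800 occur).
- Brent root-find on the monotone 1-d likelihood derivative; bracket
  [1e-12, 1]; boundary detected by derivative sign at the endpoints.
- Ties at the threshold count as long (τᵇ ≥ Tc).
- Negative c_ncᵃ unclipped by default; clipping opt-in.
- Hessian finite-difference validation uses steps of 1e-5 on the analytic
  gradient (second differences of the log-likelihood itself lose too much
  precision at realistic n).
- Radau for the stiff sequestration ODEs; steady-state tests integrate to
  t ≫ 1/r_A and compare at 1e-6 relative.

## Limitations

- The ML solver handles exactly two species (the constraint-line reduction
  is one-dimensional); the likelihood, gradient and Hessian accept any
  number.
- The fixed reference cutoff T0 depends on the sequence length n, so the
  fixed-cutoff efficiency ratios are not universal constants: at
  r_c/r_nc = 0.1 with equal on-rates the cognate ratio is ≈ 1.46 at
  n = 30,000 but ≈ 1.30 at n = 3,000 (both computable with this package).
- The readout-noise formula is leading-order in the rare-long-event limit;
  simulations match it to ~tens of percent, not exactly.
- The sequestration analysis is mean-field: no copy-number noise in A and I.
- Three-or-more-ligand threshold/readout schemes are out of scope.
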