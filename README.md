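# ligandsense

Inference of **multiple ligand concentrations from a single receptor's
binding/unbinding time series**, with the biochemical readout circuits that
can implement the computation.

Cell-surface receptors are usually cross-reactive: a cognate ligand and
non-cognate ones bind the same receptor with similar (diffusion-limited)
on-rates k and are distinguished only by their unbinding rates r. Mean
receptor occupancy then reports a single weighted sum of concentrations and
the individual concentrations are unidentifiable. The precise *temporal
sequence* of stochastic binding and unbinding events, however, contains much
more: the unbound-interval statistics pin down the total on-rate, and the
bound-interval durations reveal the mixture composition. This package is for
quantitative/systems biologists who want to compute how accurately that
works and what simple signaling circuits achieve it.

## What it computes

For a two-state receptor in a mixture with concentrations c_c, c_nc, a
trace of n bound/unbound intervals {τᵢᵇ, τᵢᵘ} has likelihood

    P ∝ ∏ᵢ e^{-τᵢᵘ (k_c c_c + k_nc c_nc)} (k_c c_c r_c e^{-r_c τᵢᵇ} + k_nc c_nc r_nc e^{-r_nc τᵢᵇ})

- **`trace_sim`** — exact simulation of traces from this generative model,
  and exact stochastic simulation of trace-driven messenger birth-death
  processes.
- **`ml_inference`** — maximum-likelihood estimates (c_c*, c_nc*), which
  satisfy k_c c_c* + k_nc c_nc* = n/Tᵘ exactly; inverse-Hessian
  (Cramér-Rao) covariance; scaled errors E = n σ²(ĉ)/c² and estimate
  correlation ρ. E = 1 is the single-ligand benchmark.
- **`approx_estimator`** — the biochemically implementable threshold
  estimator c_cᵃ = n_l e^{r_c Tᶜ}/(k_c Tᵘ) counting bound intervals longer
  than a cutoff Tᶜ, its analytic bias/variance/loss, the closed-form optimal
  cutoff, and the fixed reference cutoff T0.
- **`kpr_readout`** — the two-branch kinetic-proofreading circuit (a gated
  and an ungated messenger) whose mean levels invert to the concentrations;
  renormalization of random proofreading delays; readout noise.
- **`sequestration`** — the activator/inhibitor mutual-sequestration
  circuit that isolates a cognate ligand from a similar non-cognate one and
  reproduces ligand antagonism.
- **`experiments`** — seeded, replicated sweeps comparing all of the above,
  with tidy TSV/JSON reports.

## Worked example

```python
from ligandsense import LigandMixture, sample_trace, solve_ml
from ligandsense.approx_estimator import approx_estimate, reference_cutoff

mix = LigandMixture.two_species(k_c=1.0, r_c=0.1, c_c=0.3,
                                k_nc=1.0, r_nc=1.0, c_nc=0.7)
trace = sample_trace(mix, n_events=5000, seed=11)

fit = solve_ml(trace, mix)
print(f"ML estimates: c_c = {fit.c_hat[0]:.3f}, c_nc = {fit.c_hat[1]:.3f}")
print(f"scaled errors E = {fit.scaled_errors(mix.c).round(2)}, rho = {fit.rho:.2f}")

T0 = reference_cutoff(mix, trace.n)
approx = approx_estimate(trace, T0, mix)
print(f"threshold estimator at T0 = {T0:.2f}: n_l = {approx.n_l}, "
      f"c_c^a = {approx.c_hat_a[0]:.3f}, c_nc^a = {approx.c_hat_a[1]:.3f}")
```

prints

```
ML estimates: c_c = 0.325, c_nc = 0.679
scaled errors E = [5.34 1.71], rho = -0.24
threshold estimator at T0 = 5.64: n_l = 917, c_c^a = 0.324, c_nc^a = 0.681
```

One receptor recovers *both* concentrations from 5,000 binding events: the
minority slow ligand to ~3% relative error (E_c ≈ 5 means its variance is
five times the single-ligand limit σ² = c²/n), the majority fast ligand to
~2%. The threshold estimator — which a kinetic-proofreading circuit can
implement — lands within a fraction of a standard error of the full ML
solution here, using only the count of 917 long binding events at the fixed
cutoff T0.

The same functionality is exposed on the command line:

```sh
ligandsense simulate --rates rates.json --n-events 5000 --seed 11 --out trace.tsv
ligandsense ml-fit --trace trace.tsv --rates rates.json
ligandsense approx-fit --trace trace.tsv --rates rates.json --cutoff auto
ligandsense sweep --mode compare --config sweep.json --out table.tsv
```

See `docs/methods.md` for the estimator derivations, the proofreading and
sequestration circuit algebra, numerical choices, and known limitations.

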