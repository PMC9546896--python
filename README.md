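# tslopt — spin-lock-time schedule design for multi-exponential T1ρ relaxometry

Quantitative T1ρ mapping of articular cartilage acquires one image volume
per spin-lock time (TSL) and fits a relaxation model voxel by voxel. Every
extra TSL costs roughly 3.2 minutes of scan time, so the question this
package answers is: **given a budget of K acquisitions, which spin-lock
times best constrain the model parameters?** It is aimed at MRI physicists
designing T1ρ protocols and at anyone reproducing or extending the
underlying simulation methodology.

## The method

Signals are modeled as bi-exponential,

    s(t) = A [ f·exp(−t/T1ρs) + (1−f)·exp(−t/T1ρl) ],

or stretched-exponential,

    s(t) = A exp( −(t/T1ρ*)^β ),   0 < β ≤ 1,

with complex amplitude `A` and complex white Gaussian noise. For a schedule
`t = [t_1 … t_K]` the Fisher information matrix is

    I(t, θ) = (1/σ²) Σ_k J(t_k, θ)ᵀ J(t_k, θ),

and its inverse `V = I⁻¹` carries the Cramér–Rao lower bounds (CRLB) on the
diagonal. Because the bounds depend on the unknown tissue parameters,
schedules are scored by averaging over draws θ_s taken uniformly from a
constraint box of physiologically expected values:

* CRLB cost:   `mean_s Σ_i w_i · V(t, θ_s)_ii`
* MCRLB cost:  `mean_s Σ_i w_i · sqrt(V(t, θ_s)_ii) / |θ_s,i|`  (equal *relative* precision)

with weights `w = [0, 0.3, 0.4, 0.3]` (bi-exponential, ordered A, f, T1ρs,
T1ρl) and `w = [0, 0.9, 0.1]` (stretched, ordered A, T1ρ*, β). The discrete
TSL grid runs 0.5–5 ms in 0.5 ms steps and 6–55 ms in 1 ms steps; the
optimizers are exhaustive multiset enumeration (small K) and Pareto
Optimization for Subset Selection (POSS). Candidate schedules are validated
by a paired Monte Carlo harness: synthesize noisy curves at SNR 30, fit
them with bound-constrained complex-valued nonlinear least squares, and
compare mean normalized absolute errors (MNAE). Model choice per voxel uses
the small-sample corrected Akaike criterion (AICc).

## A worked example

```bash
python examples/03_monte_carlo_comparison.py
```

compares the published 6-TSL MCRLB-optimized schedule `[0.5 2.2 6 21 22 55]`
against the linearly spaced baseline `[0.5 11 22 33 44 55]` on 400 paired
bi-exponential draws at SNR 30 and prints:

```
   schedule  combined_nae
    mcrlb-6      0.274145
linspaced-6      0.393828
```

The combined NAE is the weighted average of the per-parameter MNAEs; the
optimized schedule cuts the error by ~30 % at the same scan time, chiefly by
sampling the short-TSL region where the fast compartment decays
(`t1rho_short` MNAE 0.32 vs 0.62). The other examples cover schedule
optimization, single-curve fitting, phantom mapping, and AICc model
selection; a thin CLI (`tslopt optimize|simulate|fit|metrics`) wraps the
same functions for shell use.

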