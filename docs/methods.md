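# Methods

## Signal models and noise

Three decay models of the spin-lock time `t` (all times in milliseconds):
mono-exponential `A·e^{−t/T1ρ}`, bi-exponential
`A·[f·e^{−t/T1ρs} + (1−f)·e^{−t/T1ρl}]`, and stretched-exponential
`A·exp(−(t/T1ρ*)^β)`. The amplitude is complex; all other parameters are
real. The stretched model's `t = 0` value and Jacobian row are defined as
limits (`s → A`, row `[1, 0, 0]`) rather than evaluated, avoiding `0^β` and
`log 0` for β < 1.

Noise is complex white Gaussian; **SNR is defined as |A| divided by the
per-component standard deviation**, so SNR 30 at unit amplitude means
σ = 1/30 in each of the real and imaginary channels. Reported error
magnitudes scale directly with this convention.

The constraint box (defaults used everywhere):

| parameter | min | max | units |
|---|---|---|---|
| A | 0 | 1e10 | a.u. |
| f | 0.05 | 0.95 | — |
| T1ρs | 1 | 10 | ms |
| T1ρl | 30 | 90 | ms |
| T1ρ* | 10 | 90 | ms |
| β | 0.4 | 1 | — |

The ranges represent expected values in knee cartilage; the disjoint
T1ρs/T1ρl ranges also remove the label-swapping ambiguity of the
bi-exponential model.

## Schedule scoring

The Fisher information of a schedule is `I = (1/σ²) Σ_k JᵀJ` with the
analytic real Jacobians; the amplitude enters as one real degree of freedom
(data are phase-aligned before fitting, and the amplitude's weight is zero
in both criteria, so the distinction is immaterial to the optimization).
The CRLB cost averages weighted diagonal entries of `V = I⁻¹` over
parameter draws; the MCRLB cost averages `sqrt(V_ii)/|θ_i|`, which targets
equal relative precision and keeps the large absolute bounds of the long
relaxation times from dominating.

Choices a reader should know about:

* **Parameter draws.** Uniform over the box with the amplitude fixed at 1.
  A uniform amplitude over (0, 1e10) would only rescale each draw's
  contribution (the bounds of the remaining parameters scale as 1/A²) while
  adding enormous variance; unit amplitude matches the pre-fit signal
  normalization. Default S = 500 draws; one fixed draw set is shared by all
  candidate schedules in a run, making the cost surface deterministic given
  the seed.
* **σ during optimization** is 1. Scaling σ by c multiplies the CRLB cost
  by c² and the MCRLB cost by c and changes no ranking.
* **Degenerate draws.** An FIM whose condition estimate (‖F‖₁·‖F⁻¹‖₁ in the
  batched evaluator, 2-norm `np.linalg.cond` in the scalar path) exceeds
  1e12 is skipped and the average renormalized over survivors; a schedule
  with no survivors scores +∞. Propagating +∞ instead would let one
  near-singular draw veto an otherwise good schedule, which contradicts the
  purpose of averaging. Schedules with fewer distinct TSLs than model
  parameters are singular for every draw and are thereby excluded
  automatically.
* **Flatness.** The cost surfaces are very flat near the optimum: neighboring
  grid choices for the interior TSLs differ by well under 1 % of the cost.
  Optimal interior TSLs should therefore be read as basins (±1–2 grid
  nodes), and small changes in the draw set can move the argmin a node or
  two — worth remembering when comparing runs with different seeds.

## Optimizers

The TSL grid is `{0.5:0.5:5} ∪ {6:1:55}` (60 nodes); a 0.1 ms fine variant
of the short segment is provided as a preset. Schedules are multisets:
repeats are allowed and do occur (a repeated TSL is signal averaging at
that point).

`exhaustive_search` enumerates all `C(n+K−1, K)` multisets (refused above
1e7) with the per-draw node information blocks precomputed, batching the
matrix inversions; it is the oracle for small K. `poss_optimize` is an
evolutionary bi-objective (cost, multiset size) search: per-node counts are
mutated ±1 with probability 1/n per node, and an archive keeps the best
solution per size (the Pareto front has exactly one point per size because
cost is monotone under appending). The archive is seeded with the empty
schedule and with the linearly spaced size-K baseline — without a feasible
anchor every sub-P-sized solution has infinite cost and the search would
wait on a rare multi-node mutation. Default 2·10⁵ iterations,
deterministic given the seed. POSS matches the exhaustive optimum on every
small instance we test; on large instances it carries no optimality
guarantee.

The acquisition-time model charges each TSL `shots × (TSL + imaging +
recovery)` with defaults 128 shots, 486.4 ms imaging, 1000 ms recovery —
3.17 min per data matrix at TSL = 0.5 ms, 3.29 min at 55 ms.

## Fitting

The estimator is bound-constrained nonlinear least squares on the
complex-valued data, `θ̂ = argmin_{θ∈Θ} Σ_k |x(t_k) − s(t_k, θ)|²`. Curves
are normalized to unit peak magnitude (the factor is restored into Â) and
phase-aligned by the shortest-TSL sample, after which the model is real and
the imaginary channel contributes only a constant to the objective. This is
the statistical advantage of complex fitting: the informative channel
carries Gaussian noise, whereas magnitude data are Rician-distributed and
bias a plain least-squares fit near the noise floor. A magnitude-fitting
baseline (no Rician correction) is provided for comparison.

The minimizer is a projected Levenberg–Marquardt scheme — damped
Gauss–Newton steps from the normal equations, projection onto the box
after each step, per-curve adaptive damping. Stopping follows two rules:
2500 iterations, or normalized step `‖Δθ‖/(‖θ‖+1e−12) < 1e−9` (applied to
the proposed, damped step: once no admissible move of that size remains,
the iteration is done). A proposed step with zero objective decrease counts
as a rejection; accepting such steps creates accept/reject limit cycles on
the flat valleys typical of multi-exponential objectives. The solver is
batched — thousands of curves advance simultaneously with all linear
algebra vectorized over the batch — which is what makes the Monte Carlo
study affordable on one CPU. Multi-start (default 5: box center plus a
fixed Halton set of interior points, with the amplitude axis narrowed to
the data scale) guards against multimodality; on noisy bi-exponential
curves the best-of-5 objective is within noise of best-of-10. At high SNR
the estimator attains the Cramér–Rao bound (empirical variance ratios
0.91–0.97 in our checks), so residual errors reflect the information
content of the schedule, not the solver.

## Monte Carlo harness and phantom

`run_mc` draws tissue parameters uniformly from the box (A = 1), shares the
same draws across all schedules (paired design — schedule contrasts are
then deterministic functions of the seed set and far lower-variance than
independent draws), synthesizes noisy curves per schedule from named seed
substreams, fits every curve, and reports per-parameter MNAE
(`mean |θ−θ̂|/|θ|`), the standard deviation of the estimates, and the
weighted combined NAE. Defaults: 2000 replicates per schedule, SNR 30 —
the problem size used throughout the reported simulations.

The synthetic phantom is a deterministic 64×64 blockwise image with six
regions spanning the box. Three regions probe component separability: the
nearly merged corner (T1ρs ≈ 10, T1ρl ≈ 30) plus an interior
close/separated pair sharing f and T1ρs. Note one subtlety: in the corner
region the box constraint truncates the normalized errors (estimates cannot
err below T1ρl = 30), so the clean demonstration that merged components fit
worse is the interior pair. The generator emulates piecewise-constant
tissue with i.i.d. complex Gaussian noise; it does not emulate partial
volume, B0/B1 inhomogeneity, motion, coil sensitivity structure, or
k-space undersampling, so passing phantom tests demonstrate estimator
behavior, not acquisition robustness.

## Metrics and model selection

MNAE and the combined NAE are implemented as stated above; voxels with a
zero reference value are excluded (with a warning) rather than assigned
infinite error. Two deviation-ratio goodness metrics are available: the
default form `Σ(θ̂−θ̄)²/Σ(θ−θ̄)²` and the textbook coefficient of
determination `1 − SSE/SST` behind a flag; neither is used for acceptance
decisions. AICc is `2P + K·ln(SSE/K) + 2P(P+1)/(K−P−1)` with natural log,
K the number of complex samples, and P the named parameter count (mono 2,
stretched 3, bi 4 — the complex amplitude is not double-counted). It
requires K > P + 1; ties within 1e−9 (e.g. a stretched fit pinned at β = 1
duplicating mono) resolve to the smaller model.

## Known limitations

* The schedule-cost argmin is a basin, not a point; different draw sets can
  shift interior TSLs by a grid node or two (see Flatness above).
* The NLS estimator is biased near the box bounds; the CRLB is a bound for
  unbiased estimators, so matched-precision crossing points measured by MNAE
  can differ from what the bounds alone suggest.
* Magnitude fitting is provided only as the uncorrected baseline; a proper
  Rician likelihood is out of scope.
* SENSE reconstruction, coil handling, motion correction, and pulse-sequence
  simulation are out of scope; inputs are decay curves or image stacks that
  already exist.
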