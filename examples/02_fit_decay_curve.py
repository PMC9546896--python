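"""Fit a noisy complex decay curve with the bi-exponential model.

Synthesizes one voxel's signal at the published 6-TSL optimized schedule,
adds complex Gaussian noise at SNR 30, and runs the constrained NLS fit
(phase-aligned complex data, multi-start projected trust-region solver).
"""

import numpy as np

from tslopt import BiExpParams, NoiseSpec, Schedule, fit_magnitude, fit_nls, synthesize_curve

truth = BiExpParams(amplitude=1.0, fraction=0.5, t1rho_short=5.0, t1rho_long=60.0)
schedule = Schedule((0.5, 2.2, 6, 21, 22, 55), provenance="mcrlb")
curve = synthesize_curve(truth, schedule, NoiseSpec(snr=30, seed=7))

res = fit_nls(curve, "bi")
print("complex-valued NLS fit:")
print(f"  truth:    f={truth.fraction:.3f}  T1rho_s={truth.t1rho_short:.2f}  T1rho_l={truth.t1rho_long:.1f}")
print(f"  estimate: f={res.theta[1]:.3f}  T1rho_s={res.theta[2]:.2f}  T1rho_l={res.theta[3]:.1f}")
print(f"  SSE={res.sse:.4g}  iterations={res.iterations}  converged={res.converged}")

mag = fit_magnitude(curve, "bi")
print(f"magnitude-only baseline: f={mag.theta[1]:.3f}  T1rho_s={mag.theta[2]:.2f}  T1rho_l={mag.theta[3]:.1f}")

# The complex fit sees Gaussian noise in a single (real) channel after phase
# alignment; the magnitude baseline fits Rician-distributed data without
# correction and is typically less accurate at low SNR.
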