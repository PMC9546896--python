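"""Parameter mapping on a synthetic blockwise phantom.

Builds the default 64x64 six-region bi-exponential phantom (one region has
nearly merged compartments), synthesizes noisy data at SNR 30 for the
optimized 6-TSL schedule, fits voxelwise, and summarizes the error maps.
"""

import numpy as np

from tslopt import NoiseSpec, Schedule, evaluate_phantom, make_phantom

phantom = make_phantom("bi")
schedule = Schedule((0.5, 2.2, 6, 21, 22, 55), provenance="mcrlb")
out = evaluate_phantom(phantom, schedule, NoiseSpec(snr=30, seed=3))

names = ("amplitude", "fraction", "t1rho_short", "t1rho_long")
print("per-parameter MNAE over the phantom ROI:")
for name, v in zip(names, out["mnae"]):
    print(f"  {name:12s} {v:.3f}")
print(f"residual std: {out['residual_std']:.4f}")

w = np.array([0.0, 0.3, 0.4, 0.3])
combined = out["nae_maps"] @ w
for r in range(phantom.n_regions):
    sel = phantom.labels == r
    f, ts, tl = phantom.maps[sel][0][1:]
    print(f"region {r} (f={f:.2f}, T1rho_s={ts:.0f}, T1rho_l={tl:.0f}): combined NAE {np.nanmean(combined[sel]):.3f}")

# Regions whose short and long components sit close together are the hardest
# to separate; compare the interior close/separated pair (regions 4 and 5).
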