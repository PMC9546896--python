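"""Voxelwise model selection with the corrected Akaike criterion.

Fits the mono-, bi-, and stretched-exponential models to synthetic curves
of known origin and tallies which model AICc prefers. Lower AICc means a
better fit after penalizing parameter count (mono 2, stretched 3, bi 4).
"""

import numpy as np

from tslopt import DecayCurve, classification_percentages, select_model
from tslopt.models import signal_array

tsl = np.array([0.5, 2, 5, 9, 14, 20, 27, 35, 44, 55.0])
rng = np.random.default_rng(0)

labels = []
for i in range(40):
    theta = np.array([1.0, 0.5, 5.0, 60.0])  # well-separated bi-exponential
    x = signal_array("bi", tsl, theta) + (rng.normal(size=10) + 1j * rng.normal(size=10)) / 100
    label, scores = select_model(DecayCurve(tsl, x), n_starts=3)
    labels.append(label)
    if i == 0:
        print("AICc per model for the first voxel:")
        for m, s in sorted(scores.items(), key=lambda kv: kv[1]):
            print(f"  {m:9s} {s:8.2f}")

print("\nselected-model percentages over 40 voxels:")
for m, pct in classification_percentages(labels).items():
    print(f"  {m:9s} {pct:5.1f}%")

# At SNR 100 with 10 TSLs the true bi-exponential should win in most voxels;
# at lower SNR the 3-parameter stretched model often wins the AICc trade-off
# even for bi-exponential tissue - the same behavior reported in vivo.
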