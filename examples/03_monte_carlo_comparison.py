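"""Monte Carlo comparison of an optimized schedule against the linearly
spaced baseline (a desk-scale slice of the full simulation study).

Draws 400 tissue-parameter vectors uniformly from the constraint box,
synthesizes noisy curves at SNR 30 for both 6-TSL schedules from the same
draws (paired design), fits every curve, and reports the mean normalized
absolute error per parameter and the weighted combined error.
"""

from tslopt import NoiseSpec, Schedule, linspaced_schedule, run_mc

schedules = {
    "mcrlb-6": Schedule((0.5, 2.2, 6, 21, 22, 55), provenance="mcrlb"),
    "linspaced-6": linspaced_schedule(6),
}
report = run_mc("bi", schedules, noise=NoiseSpec(snr=30, seed=11), replicates=400)

print(report.table[["schedule", "parameter", "mnae", "std"]].to_string(index=False))
print()
print(report.combined[["schedule", "combined_nae"]].to_string(index=False))

# Expect the optimized schedule's combined NAE to be clearly lower than the
# baseline's at the same K — the central simulation claim. MNAE ~0.2-0.4 at
# SNR 30 is normal for bi-exponential parameters over the full box.
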