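"""Globally fit replicate folding transients to a shared rate constant.

Simulates three replicate fluorescence transients of a membrane protein
folding into liposomes (observed rate 14.9e-3 s^-1, 2% noise) and fits
them globally: one shared rate, per-replicate amplitudes and offsets.
"""

from foldkit import fit_exponential_global
from foldkit.synthetic import TransientSpec, generate_transients

transients = generate_transients(TransientSpec(
    rates=(0.0149,), amplitudes=(-5.0,), offset=7.0,
    noise_fraction=0.02, duration_s=600.0, sample_interval_s=1.0,
    n_replicates=3, seed=42, condition_label="liposomes alone"))

fit = fit_exponential_global(transients, n_exponentials=1)

print(f"shared rate constant k = {fit.k1 * 1e3:.2f} +/- "
      f"{fit.rate_stderr[0] * 1e3:.2f} x 10^-3 s^-1 (true: 14.90)")
for i, (amps, c) in enumerate(zip(fit.amplitudes, fit.offsets)):
    print(f"  replicate {i + 1}: amplitude {amps[0]:+.2f}, offset {c:.2f}")
print("The shared k is the observed folding rate; negative amplitudes mean "
      "fluorescence rises as the protein inserts and folds.")
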