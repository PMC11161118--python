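"""Characterize a single synthetic neuron with the six per-neuron measures.

Generates a slow, regular (clock-like) spike train plus its averaged
waveform, standardizes the ISI sequence to 225 intervals, and prints firing
rate, CV, APD and the three nonlinear measures.
"""

from spikeprofile import (
    bins_entropy,
    coefficient_of_variation,
    compute_isi,
    firing_rate,
    measure_apd,
    op_entropy,
    plzc,
    standardize_length,
)
from spikeprofile.synthetic import gen_renewal_train, gen_waveform

train = gen_renewal_train(rate=3.0, gamma_shape=25.0, n_spikes=400, seed=1)
wave = gen_waveform(apd_ms=2.4, seed=1)
isi = standardize_length(compute_isi(train), 225)

print(f"firing rate : {firing_rate(train, train.recording_window):.2f} Hz")
print(f"CV          : {coefficient_of_variation(isi):.3f}")
print(f"APD         : {measure_apd(wave):.2f} ms")
print(f"OP Entropy  : {op_entropy(isi, tiebreak_seed=1):.4f}")
print(f"Bins Entropy: {bins_entropy(isi):.4f}")
print(f"PLZC        : {plzc(isi, tiebreak_seed=1):.4f}")
print()
print("A regular 3 Hz train: CV well below 0.30 and a wide (>1.4 ms) spike")
print("are the classic putative-serotonergic signature.  OP Entropy stays")
print("near 1 because consecutive-interval rank order remains random even")
print("when the interval magnitudes are tightly concentrated.")
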