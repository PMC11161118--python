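"""Rule-based firing-pattern labels on three synthetic phenotypes.

Builds a theta-rhythmic train, a bursting train and an irregular (Poisson)
train, then prints the autocorrelogram rhythmicity label, burst report and
clock-like flag for each.
"""

from spikeprofile import (
    MeasureSet,
    autocorrelation_histogram,
    classify_clock_like,
    classify_rhythmicity,
    coefficient_of_variation,
    compute_isi,
    detect_bursts,
    firing_rate,
)
from spikeprofile.synthetic import gen_burst_train, gen_renewal_train, gen_rhythmic_train

trains = {
    "theta-rhythmic (6 Hz modulation)": gen_rhythmic_train(15.0, 6.0, 0.9, 120.0, seed=3),
    "bursting (4 bursts/s)": gen_burst_train(4.0, duration=120.0, seed=3),
    "irregular (Poisson)": gen_renewal_train(10.0, 1.0, 1200, seed=3),
}

for name, train in trains.items():
    ach = autocorrelation_histogram(train, bin_width=0.010, max_lag=1.0)
    rhythm = classify_rhythmicity(ach)
    bursts = detect_bursts(train)
    m = MeasureSet(
        fr_hz=firing_rate(train, train.recording_window),
        cv=coefficient_of_variation(compute_isi(train)),
        apd_ms=2.5,
    )
    freq = f", {rhythm.rhythm_freq_hz:.1f} Hz" if rhythm.rhythm_freq_hz else ""
    print(f"{name}:")
    print(f"  rhythmicity : {rhythm.label} ({rhythm.n_peaks} ACH peaks{freq})")
    print(f"  bursting    : {bursts.bursting} "
          f"({len(bursts.bursts)} bursts, "
          f"{100 * bursts.fraction_spikes_in_bursts:.1f}% of spikes)")
    print(f"  clock-like  : {classify_clock_like(m, rhythm)}")
    print()

print("Rhythmic firing shows equally spaced autocorrelogram peaks whose")
print("spacing inverts to the modulation frequency; bursting shows runs of")
print("sub-20 ms intervals with decaying amplitudes; the Poisson train is")
print("flat-ACH and neither bursts nor satisfies the clock-like rule.")
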