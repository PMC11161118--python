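# Methods

`spikeprofile` characterizes the basal discharge of single extracellularly
recorded neurons from their inter-spike-interval (ISI) sequences.  It was
built around the analysis of dorsal and median raphe (DRN/MRN) recordings —
slow clock-like serotonergic firing, theta-rhythmic firing, doublet/triplet
bursting, and irregular activity — but every operation is generic to point
processes.

## Measures

All nonlinear measures operate on a standardized ISI sequence of N = 225
intervals (the first 225 of each neuron, see *Standardization*).

**Firing rate (FR, Hz).** Spike count divided by the analysis window when a
window is given; `(n-1)/(t_last - t_first)` otherwise.  Windows under 60 s
are flagged as shorter than the usual stable-activity span.

**Coefficient of variation (CV).** Sample SD of the ISIs over their mean; 0
for clock-like regularity, ~1 for Poisson firing, above 1 for bursty
discharge.  Invariant to rescaling and to interval order.

**Action-potential duration (APD, ms).** The averaged extracellular spike is
mostly triphasic; APD is the span of its first two phases.  Onset is the
first departure from baseline sustained for 3 samples beyond 3 baseline SDs
(a lone noise excursion cannot fake an onset); each phase ends at a baseline
crossing, and APD runs from onset to the crossing that terminates phase two.
This is a deterministic surrogate for manual cursor placement; an
undetectable onset or missing second crossing yields NaN (undetermined)
rather than a guess.

**OP Entropy (permutation entropy).** The ISI sequence is split into
non-overlapping windows of D = 3 consecutive intervals; each window maps to
the lexicographic index of its rank permutation ((1,2,3) -> 0, (3,2,1) -> 5
— the labeling is arbitrary for entropy and frozen only for serialization).
A second encoding starting from the second interval doubles the pattern
count (75 + 74 = 149 symbols at N = 225, about 25 expected per pattern).
OP Entropy is the Shannon entropy of the pooled pattern distribution
normalized by log D!, so it lies in [0, 1].  It sees only local rank order:
it is invariant to any strictly increasing transform of the intervals and
blind to their magnitudes.

**Bins Entropy.** Shannon entropy of the ISI magnitude histogram with
Nb = 18 equal-width bins spanning [min, max] of the sequence, normalized by
log Nb.  Nb = 18 keeps the a-priori count per bin (225/18 = 12.5)
comparable to the count per ordinal pattern.  The per-neuron adaptive range
makes the measure scale-free; a constant sequence returns 0, not an error.
Exactly invariant under shuffling.

**LZ76 / PLZC.** Lempel-Ziv-76 exhaustive-history parsing splits a symbol
sequence into words, each the shortest prefix of the remainder not occurring
as a substring of the text preceding its final symbol; the final word counts
even when reproducible.  The word count `c` is normalized as
`C = c * log_alpha(T) / T` so random sequences sit near 1.  PLZC applies
this to the offset-0 ordinal-pattern sequence (T = 75 symbols, alphabet
D! = 6).  Only the single non-overlapping encoding is parsed: concatenating
the two offset readings would splice overlapping passes of the same data
and manufacture spurious words.

**Tie-break noise.** Ordinal patterns are undefined on ties, so a seeded
zero-mean Gaussian perturbation with SD = 1e-6 x SD(ISI) is added before
encoding — far below any physiological interval difference, sufficient to
make all values distinct with probability 1.  For a constant input (SD = 0)
the noise SD falls back to 1e-6 x |mean| so ties are still broken.  All
seeds are derived from the run's master seed and recorded.

### Entropy normalization

The two entropies are normalized Shannon entropies (log base = alphabet/bin
count).  Written with natural logs, `H = -sum p ln p / ln K`.  This is the
convention under which both measures live in [0, 1], with 1 for the uniform
distribution; it also makes OP Entropy and Bins Entropy directly
comparable despite their different alphabet sizes.

## Standardization, truncation and quality control

Neurons are analyzed at a common ISI length (default 225) so that entropy
and complexity estimates carry identical statistical power; neurons that
cannot supply it are skipped, not padded.  Truncation keeps the *first*
contiguous block of intervals: contiguity preserves the temporal structure
that OP Entropy and PLZC measure, which subsampling would destroy.  A
refractory check reports ISIs under 2 ms (possible contamination by a
second unit) but does not reject — it is a sorting-quality diagnostic, and
synthetic data may legitimately violate it.

## Surrogate testing

Shuffling the ISI values is an exact null for temporal order: the value
multiset — hence FR over the ISI span, CV and Bins Entropy — is preserved,
while any order structure is destroyed.  For an order-sensitive measure the
test draws `n = 100` uniform permutations, recomputes the measure with
fresh tie-break noise per surrogate (so the null includes encoding noise),
and reports the rank p-value `(1 + #{surrogate <= observed}) / (n + 1)`,
which can never be 0.  The default is one-sided lower-tail — temporal
structure can only reduce entropy/complexity relative to the exchangeable
null — with a two-sided option.  Testing a permutation-invariant measure is
refused with an explanation: its surrogate distribution is a point mass.

## Firing-pattern rules

These rules replace classifications traditionally made by eye; every
threshold is a configurable keyword with a frozen default, and the defaults
below were fixed by calibration on the synthetic generators.

**Rhythmicity.** The autocorrelation histogram (ACH; 10 ms bins to 1 s) is
Gaussian-smoothed (bandwidth 2 bins) and peaks are local maxima exceeding a
null band.  The default band is analytic and flat: a non-rhythmic train of
the same mean rate has a flat expected ACH with Poisson counting noise, so
the band is `mean + 3.5 * sqrt(mean * k)`, where `k` is the variance
shrinkage of the smoothing kernel.  Two or more peaks whose spacings
(including the first peak's lag from zero — rhythmic peaks sit at multiples
of the period) all fall within 20% of their median give `rhythmic`, with
frequency = 1/median spacing; exactly one peak gives
`excluded_single_interval` (a lone preferred interval, e.g. a dominant
doublet lag, is not a rhythm); zero peaks on a flat profile give
`non_rhythmic`; anything else is `excluded_undefined`.

A shuffled-ISI surrogate band (`shuffle_null_band`) is provided but is
deliberately not the default.  For a renewal train — i.i.d. intervals,
exactly the clock-like case — shuffling is distribution-preserving: the
surrogate ACH reproduces the very peaks under test, so that band has no
power against regular-renewal rhythmicity.  The flat-rate band detects both
renewal regularity and oscillatory modulation; the surrogate band remains
useful when the question is specifically "structure beyond the ISI
distribution".

**Bursts.** Maximal runs of consecutive ISIs under 20 ms are candidate
doublets/triplets; longer runs are split greedily into triplets then
doublets (leftover single spikes are not bursts).  With per-spike
amplitudes available, a candidate must have strictly decreasing amplitudes
— the classical signature distinguishing genuine bursts from chance short
intervals.  Without amplitudes, chance is controlled explicitly: the
short-ISI count must exceed twice the expectation of a rate-matched Poisson
train (a 10 Hz Poisson train has ~18% sub-20 ms intervals by chance alone).
A neuron is `bursting` when it has at least 3 bursts containing at least 1%
of its spikes and passes the applicable gate.

**Clock-like.** The classical putative-serotonergic rule: APD > 1.4 ms
(strict), CV < 0.30, a rhythmic ACH, and FR < 5 Hz (strict).  Without an
APD the outcome is undetermined, never False.

**Interval-histogram unimodality.** The smoothed IH's modes are local
maxima at least 5% of the global maximum that also rise 3 smoothed-Poisson
noise SDs above their reference valley; the second condition stops counting
wiggles on a plateau from reading as modes while keeping broad genuine
second modes (the burst signature) detectable.  Fewer than 5 occupied bins
is undetermined.

## Cohort statistics

Recordings are hierarchical — 1 to 7 neurons per animal — so neurons are
not exchangeable.  Group differences (e.g. DRN vs MRN) are tested by
permuting group labels across whole animals (all neurons of an animal move
together), with the difference of group means as statistic and a two-sided
rank p-value; each group must span at least two animals.  For contrasts
defined *within* animals (rhythmic vs non-rhythmic neurons of the same rat)
an animal-level permutation is undefined, and the pipeline falls back to
neuron-level permutation, recorded in the output's `permute_unit` column.
This permutation scheme stands in for multilevel (mixed-effects) model
fitting: it respects the random-effect structure without distributional
assumptions, at the price of not producing effect-size posteriors.

Measure redundancy is assessed for all 15 unordered pairs of the six
measures by least-squares fits on two scales: raw (linear) and log-log
(power law), keeping both and flagging as best whichever has the larger
|Pearson r|.  Because OP Entropy of near-random trains crowds against its
ceiling of 1, it enters power laws as `1 - H` before the log; all other
measures enter as `log x`; non-positive transformed pairs are dropped with
a logged count.  Raw per-pair p-values are primary; a Holm-corrected column
is emitted alongside as a clearly labeled extension.

## Synthetic study conditions

The generator module is first-class, tested code; its defaults define the
conditions under which the pipeline is validated.

* **Hierarchy.** 1-7 neurons per animal; animals assigned round-robin to
  nuclei; default class mixture mirroring the recorded populations (DRN:
  60% irregular, 26% rhythmic, 5% bursting, 9% clock-like; MRN: 58/21/21/0).
* **Durations.** Every cohort neuron spans at least 120 s and 320 spikes,
  matching the minutes-long basal recordings and 60-300 s stable analysis
  windows the pipeline assumes; ACH-based rhythmicity genuinely needs this
  much data even though the nonlinear measures use only 225 intervals.
* **Irregular firing** is a gamma renewal with shape 1 (Poisson-like),
  rates 3-20 Hz.  **Clock-like** firing is the same renewal with shape 25
  (CV = 0.2) at 2.5-4.5 Hz — the slow regular serotonergic signature, with
  the rate floor placed so a 1 s autocorrelogram window holds at least two
  periods — plus a wide-spike waveform (1.8-3.5 ms APD).
* **Rhythmic firing** is an inhomogeneous Poisson process with intensity
  `r (1 + m sin(2 pi f t))`, theta-band f in 4-9 Hz, depth 0.9, sampled
  exactly by thinning; depth 0 reduces to a homogeneous Poisson train.
* **Bursting** places doublets/triplets (intra-burst ISIs uniform in
  (0.3, 0.95) x 20 ms, amplitudes decaying geometrically by 30% per spike)
  on a gamma (shape 4) renewal of burst onsets: quasi-rhythmic burst
  emission puts the inter-burst mode of the interval histogram well away
  from the intra-burst peak, the classic bimodal signature.  Overlapping
  candidates are rejected, not merged, so ground truth stays unambiguous;
  an infeasibly high burst rate errors out.
* **Waveforms** are triphasic half-sine templates whose first two phases
  span the requested APD exactly, digitized at >= 20 kHz with faint
  Gaussian noise.

Every generator is bit-for-bit deterministic in (parameters, seed).  What
the generators do **not** emulate: slow nonstationarities and drift,
spike-sorting artifacts, serial ISI correlations beyond the modeled
rhythm/burst structure, rate-dependent waveform changes, and any coupling
between measures that real neurons may exhibit (e.g. the empirical CV-FR
power law arises only if regularity is made rate-dependent, as one
validation cohort does).  Passing tests therefore demonstrate correctness
of the measures and rules under controlled point-process conditions, not
fidelity to every property of raphe data.

## Numerical choices

* Histogram bins are half-open `(lo, hi]` with a 1e-9 relative edge
  tolerance; the Bins-Entropy histogram's last bin is right-closed.
* The rank p-value tie comparison uses a relative (1e-12) tolerance so
  permutation p-values are invariant under rescaling the measure.
* Per-neuron seeds derive from the master seed and a CRC-32 of the neuron
  id: reproducible end-to-end, independent across neurons, stable across
  runs and platforms.
* Validation sample sizes (20 seeded runs for classifier checks, 200 for
  null calibrations, 10,000 intervals for CV recovery) were chosen so the
  checked fractions have standard errors well inside the asserted margins.

## Known limitations

* The rhythmicity rule assumes an approximately stationary rate; slow
  drift inflates ACH mass at short lags and can push a train to
  `excluded_undefined`.
* Rhythm frequencies are quantized by the 10 ms ACH bin; frequencies above
  ~12 Hz need a finer `ach_bin_width` to resolve peak spacing.
* PLZC at T = 75 symbols is a short-sequence estimate; its normalization
  makes values comparable across neurons at fixed N but not across
  different N.
* The permutation group test reports a difference of means; it does not
  estimate variance components, and with very few animals per group its
  p-value resolution is limited by the number of distinct animal
  permutations.
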