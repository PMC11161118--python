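"""Rule-based firing-pattern labels: rhythmicity, bursting, clock-like.

These rules are objective stand-ins for classifications that are
traditionally done by eye on the autocorrelation histogram (ACH) and raw
traces; every threshold is a keyword argument with a frozen default.

Rhythmicity is decided from peaks of the smoothed ACH that exceed a null
band.  The default band is the analytic flat-rate (Poisson) band: a
non-rhythmic train of the same mean rate has a flat expected ACH, so peaks
are bins whose smoothed count rises significantly above that flat level.
A shuffled-ISI surrogate band is also provided (:func:`shuffle_null_band`)
but is *not* the default: for a renewal train (i.i.d. intervals — exactly
the clock-like case) shuffling the ISIs is distribution-preserving, so the
surrogate ACH reproduces the very peaks one is trying to detect and the
band test has no power against regular-renewal rhythmicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .core import (
    InsufficientDataError,
    InvalidParameterError,
    SpikeTrain,
    compute_isi,
)
from .measures import LagHistogram, MeasureSet, autocorrelation_histogram, smoothing_var_factor

__all__ = [
    "RhythmicityResult",
    "BurstReport",
    "Burst",
    "classify_rhythmicity",
    "shuffle_null_band",
    "detect_bursts",
    "classify_clock_like",
    "INTRA_BURST_ISI_MAX_S",
]

#: Maximum intra-burst interval: doublets/triplets ride on ISIs < 20 ms.
INTRA_BURST_ISI_MAX_S = 0.020

RHYTHMIC = "rhythmic"
NON_RHYTHMIC = "non_rhythmic"
EXCLUDED_SINGLE_INTERVAL = "excluded_single_interval"
EXCLUDED_UNDEFINED = "excluded_undefined"


@dataclass(frozen=True)
class RhythmicityResult:
    """Outcome of the ACH rhythmicity rule.

    ``rhythm_freq_hz`` is 1 / (median peak spacing) when rhythmic, else None.
    """

    label: str
    n_peaks: int
    rhythm_freq_hz: float | None = None
    peak_lags_s: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


@dataclass(frozen=True)
class Burst:
    """One detected doublet or triplet."""

    start_index: int
    size: int
    max_intra_isi_s: float
    amplitudes_decreasing: bool | None = None


@dataclass(frozen=True)
class BurstReport:
    bursts: tuple[Burst, ...]
    bursting: bool
    fraction_spikes_in_bursts: float
    rejected_candidates: int = 0


def classify_rhythmicity(
    ach: LagHistogram,
    null_band: np.ndarray | None = None,
    *,
    smooth_bins: float = 2.0,
    z: float = 3.5,
    spacing_tol: float = 0.20,
) -> RhythmicityResult:
    """Classify an ACH as rhythmic / non-rhythmic / excluded.

    The ACH counts are Gaussian-smoothed (bandwidth ``smooth_bins`` bins)
    and local maxima exceeding the null band are taken as peaks.  The
    decision mirrors the visual convention:

    * >= 2 peaks whose spacings (including the first peak's lag from zero,
      since rhythmic peaks sit at multiples of the period) all lie within
      ``spacing_tol`` of their median -> ``rhythmic`` with frequency
      1 / median spacing;
    * exactly 1 peak -> ``excluded_single_interval`` (a single predominant
      interval, e.g. a dominant doublet lag, is not rhythmicity);
    * 0 peaks with a flat profile -> ``non_rhythmic``;
    * anything else (irregular peaks, non-flat but peakless) ->
      ``excluded_undefined``.

    ``null_band`` is a per-bin threshold applied to the *smoothed* ACH;
    when None, the analytic flat-rate band
    ``mean + z * sqrt(mean * k)`` is used, where ``k`` is the variance
    shrinkage of the smoothing kernel (Poisson counting noise after
    smoothing).
    """
    counts = ach.counts.astype(float)
    if counts.size < 20:
        raise InsufficientDataError("ACH needs >= 20 bins for rhythmicity analysis")
    sm = gaussian_filter1d(counts, smooth_bins, mode="nearest")
    m = float(counts.mean())
    if null_band is None:
        band = np.full(counts.size, m + z * np.sqrt(max(m, 1.0) * smoothing_var_factor(smooth_bins)))
    else:
        band = np.asarray(null_band, dtype=float)
        if band.shape != counts.shape:
            raise InvalidParameterError("null_band must have one threshold per ACH bin")
    peaks, _ = find_peaks(sm, height=band, prominence=0.5 * (band - m).clip(min=0))
    peak_lags = (peaks + 0.5) * ach.bin_width
    n = int(peaks.size)
    if n == 0:
        flat = not bool(np.any(sm > band))
        label = NON_RHYTHMIC if flat else EXCLUDED_UNDEFINED
        return RhythmicityResult(label=label, n_peaks=0)
    if n == 1:
        return RhythmicityResult(
            label=EXCLUDED_SINGLE_INTERVAL, n_peaks=1, peak_lags_s=peak_lags
        )
    spacings = np.diff(np.concatenate([[0.0], peak_lags]))
    med = float(np.median(spacings))
    if med > 0 and np.all(np.abs(spacings - med) <= spacing_tol * med):
        return RhythmicityResult(
            label=RHYTHMIC, n_peaks=n, rhythm_freq_hz=1.0 / med, peak_lags_s=peak_lags
        )
    return RhythmicityResult(label=EXCLUDED_UNDEFINED, n_peaks=n, peak_lags_s=peak_lags)


def shuffle_null_band(
    train: SpikeTrain,
    bin_width: float = 0.010,
    max_lag: float = 1.0,
    n_shuffles: int = 50,
    seed: int | None = None,
    smooth_bins: float = 2.0,
    z: float = 2.0,
) -> np.ndarray:
    """Per-bin ``mean + z*SD`` band of smoothed ACHs of shuffled-ISI trains.

    Destroys ISI ordering while preserving the interval distribution.  Note
    the caveat in the module docstring: this band has no power against
    renewal (i.i.d.-ISI) regularity, for which shuffling is a null that
    contains the alternative.
    """
    isis = np.diff(train.timestamps)
    if isis.size < 2:
        raise InsufficientDataError("need >= 2 intervals to build a shuffle band")
    rng = np.random.default_rng(seed)
    t0 = train.timestamps[0]
    smoothed = []
    for _ in range(n_shuffles):
        ts = t0 + np.concatenate([[0.0], np.cumsum(rng.permutation(isis))])
        ach = autocorrelation_histogram(
            SpikeTrain(timestamps=ts), bin_width=bin_width, max_lag=max_lag
        )
        smoothed.append(gaussian_filter1d(ach.counts.astype(float), smooth_bins, mode="nearest"))
    arr = np.array(smoothed)
    return arr.mean(axis=0) + z * arr.std(axis=0, ddof=1)


def detect_bursts(
    train: SpikeTrain,
    intra_burst_isi_max: float = INTRA_BURST_ISI_MAX_S,
    min_bursts: int = 3,
    min_fraction: float = 0.01,
    chance_excess: float = 2.0,
) -> BurstReport:
    """Detect doublet/triplet bursts and decide whether the neuron bursts.

    Maximal runs of consecutive ISIs below ``intra_burst_isi_max`` define
    candidate bursts; runs longer than a triplet are split greedily into
    triplets then doublets (leftover single spikes are not bursts).  When
    per-spike amplitudes are available a candidate additionally requires
    strictly decreasing amplitudes — the classical signature of genuine
    bursts versus chance short intervals.  The neuron is flagged bursting
    when at least ``min_bursts`` bursts are found and they contain at least
    ``min_fraction`` of all spikes.

    Without amplitudes the short intervals alone cannot separate bursts
    from the chance doublets any fast irregular neuron produces (a 10 Hz
    Poisson train has ~18% sub-20 ms intervals), so the flag additionally
    requires the short-interval count to exceed ``chance_excess`` times the
    expectation of a rate-matched Poisson train.
    """
    isis = compute_isi(train).values
    short = isis < intra_burst_isi_max
    amp = train.amplitudes
    bursts: list[Burst] = []
    rejected = 0

    def consider(start: int, size: int) -> None:
        nonlocal rejected
        intra = isis[start : start + size - 1]
        dec: bool | None = None
        if amp is not None:
            a = amp[start : start + size]
            dec = bool(np.all(np.diff(a) < 0))
            if not dec:
                rejected += 1
                return
        bursts.append(
            Burst(
                start_index=start,
                size=size,
                max_intra_isi_s=float(intra.max()),
                amplitudes_decreasing=dec,
            )
        )

    i = 0
    n = short.size
    while i < n:
        if not short[i]:
            i += 1
            continue
        j = i
        while j < n and short[j]:
            j += 1
        run_spikes = (j - i) + 1  # run of (j - i) short ISIs spans this many spikes
        pos = i
        remaining = run_spikes
        while remaining >= 3:
            consider(pos, 3)
            pos += 3
            remaining -= 3
        if remaining == 2:
            consider(pos, 2)
        i = j

    spikes_in_bursts = sum(b.size for b in bursts)
    fraction = spikes_in_bursts / train.n_spikes
    above_chance = True
    if amp is None and isis.size > 0:
        rate = isis.size / float(isis.sum())
        expected_short = (1.0 - np.exp(-rate * intra_burst_isi_max)) * isis.size
        above_chance = short.sum() >= chance_excess * max(expected_short, 1.0)
    bursting = len(bursts) >= min_bursts and fraction >= min_fraction and above_chance
    return BurstReport(
        bursts=tuple(bursts),
        bursting=bursting,
        fraction_spikes_in_bursts=float(fraction),
        rejected_candidates=rejected,
    )


def classify_clock_like(
    m: MeasureSet,
    r: RhythmicityResult,
    *,
    apd_min_ms: float = 1.4,
    cv_max: float = 0.30,
    fr_max_hz: float = 5.0,
) -> bool | None:
    """Classical putative-serotonergic (clock-like) rule.

    True iff APD > 1.4 ms (strict), CV < 0.30, the ACH is rhythmic, and
    FR < 5 Hz (strict).  Returns None (undetermined) when no APD is
    available — a neuron without a waveform cannot be ruled in or out.
    """
    apd = m.apd_ms
    if apd is None or not np.isfinite(apd):
        return None
    return bool(
        apd > apd_min_ms and m.cv < cv_max and r.label == RHYTHMIC and m.fr_hz < fr_max_hz
    )
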