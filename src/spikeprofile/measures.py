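"""Classic electrophysiological measures: FR, CV, APD, interval and
autocorrelation histograms, and the interval-histogram unimodality check."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, peak_prominences

from .core import (
    ISISequence,
    InsufficientDataError,
    InvalidParameterError,
    SpikeTrain,
    WaveformTemplate,
)

__all__ = [
    "MeasureSet",
    "LagHistogram",
    "firing_rate",
    "coefficient_of_variation",
    "measure_apd",
    "interval_histogram",
    "autocorrelation_histogram",
    "unimodality_check",
]

#: Shortest analysis window (s) considered representative of stable basal
#: activity; shorter windows trigger a warning but are still measured.
MIN_STABLE_WINDOW_S = 60.0


@dataclass
class MeasureSet:
    """The six per-neuron measures plus tri-state classification flags.

    ``apd_ms`` is ``None`` when no waveform was available and ``nan`` when a
    waveform was given but no phases could be detected.  Flags are
    True/False/None (None = undetermined).
    """

    fr_hz: float
    cv: float
    apd_ms: float | None = None
    op_entropy: float | None = None
    bins_entropy: float | None = None
    plzc: float | None = None
    rhythmic: bool | None = None
    bursting: bool | None = None
    clock_like: bool | None = None
    unimodal_ih: bool | None = None


@dataclass(frozen=True)
class LagHistogram:
    """Histogram over positive lags with half-open bins (lo, hi].

    ``kind`` is ``"interval"`` (ISI magnitudes) or ``"autocorrelation"``
    (all ordered spike-pair lags).  Bin i covers (i*bin_width, (i+1)*bin_width].
    """

    kind: str
    bin_width: float
    max_lag: float
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("interval", "autocorrelation"):
            raise InvalidParameterError("kind must be 'interval' or 'autocorrelation'")
        c = np.asarray(self.counts, dtype=np.int64)
        if np.any(c < 0):
            raise InvalidParameterError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


def _bin_positive_lags(values: np.ndarray, bin_width: float, max_lag: float) -> np.ndarray:
    """Counts per half-open bin (lo, hi] for positive values up to max_lag."""
    n_bins = int(round(max_lag / bin_width))
    if n_bins < 1:
        raise InvalidParameterError("max_lag must cover at least one bin")
    v = values[(values > 0) & (values <= max_lag * (1 + 1e-12))]
    # ceil(v / w) - 1 places a value exactly on an edge into the lower bin,
    # i.e. bins are (lo, hi]; a tiny relative tolerance absorbs float error.
    idx = np.ceil(v / bin_width - 1e-9).astype(np.int64) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


def firing_rate(train: SpikeTrain, window: tuple[float, float] | None = None) -> float:
    """Mean firing rate in Hz.

    With an explicit ``window`` the estimate is (spike count inside) /
    (window duration); without one it is (n-1) / (t_last - t_first), the
    natural rate of the observed point process on its own span.  Windows
    shorter than 60 s are outside the usual stable-activity range and emit
    a warning.
    """
    ts = train.timestamps
    if window is None:
        if train.n_spikes < 2:
            raise InsufficientDataError("need >= 2 spikes for a firing rate")
        span = ts[-1] - ts[0]
        if span < MIN_STABLE_WINDOW_S:
            warnings.warn(
                f"analysis span {span:.1f} s is shorter than the 60 s "
                "stable-activity minimum",
                stacklevel=2,
            )
        return (train.n_spikes - 1) / span
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise InvalidParameterError("window must have positive duration")
    w0, w1 = train.recording_window
    if t0 < w0 - 1e-12 or t1 > w1 + 1e-12:
        raise InvalidParameterError("window must lie within recording_window")
    count = int(np.sum((ts >= t0) & (ts <= t1)))
    if count < 2:
        raise InsufficientDataError("fewer than 2 spikes inside window")
    if t1 - t0 < MIN_STABLE_WINDOW_S:
        warnings.warn(
            f"analysis window {t1 - t0:.1f} s is shorter than the 60 s "
            "stable-activity minimum",
            stacklevel=2,
        )
    return count / (t1 - t0)


def coefficient_of_variation(isi) -> float:
    """CV of the ISI sequence: sample SD / mean.

    0 for perfectly regular (clock-like) firing, ~1 for a Poisson process;
    invariant under rescaling all intervals by a positive constant and
    under any permutation of their order.
    """
    v = isi.values if isinstance(isi, ISISequence) else np.asarray(isi, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need >= 2 intervals for a CV")
    if np.any(v <= 0):
        raise InvalidParameterError("ISI values must be positive")
    mean = float(np.mean(v))
    return float(np.std(v, ddof=1) / mean)


def measure_apd(wave: WaveformTemplate, onset_sigma: float = 3.0) -> float:
    """Action-potential duration (ms): onset of phase 1 to end of phase 2.

    The averaged extracellular spike is mostly triphasic; its duration is
    conventionally the span of the first two phases.  Onset is the first
    departure from baseline sustained for 3 samples beyond
    ``onset_sigma`` x baseline SD; each phase ends where the trace crosses
    back through the baseline level, and the APD runs from onset to the
    crossing that terminates phase two.

    Returns ``nan`` (with a warning) when no phases are detectable, e.g. on
    pure noise.
    """
    v = wave.samples
    b0, b1 = wave.baseline_window
    base = v[b0:b1]
    mu, sigma = float(np.mean(base)), float(np.std(base))
    if sigma == 0.0:
        sigma = 1e-12
    dev = np.abs(v - mu) > onset_sigma * sigma
    # Sustained departure: 3 consecutive supra-threshold samples, so a lone
    # baseline noise excursion cannot fake an onset.
    run3 = dev[b1:-2] & dev[b1 + 1 : -1] & dev[b1 + 2 :]
    hits = np.flatnonzero(run3)
    if hits.size == 0:
        warnings.warn("no detectable departure from baseline; APD undetermined", stacklevel=2)
        return math.nan
    onset = b1 + int(hits[0])
    signs = np.sign(v[onset:] - mu)
    crossings = np.flatnonzero(np.diff(signs) != 0)
    if crossings.size < 2:
        warnings.warn("fewer than two baseline crossings; APD undetermined", stacklevel=2)
        return math.nan
    end_phase2 = onset + int(crossings[1]) + 1
    return (end_phase2 - onset) * wave.sample_period_ms


def interval_histogram(isi, bin_width: float, max_lag: float) -> LagHistogram:
    """Histogram of ISI magnitudes up to ``max_lag`` with (lo, hi] bins.

    Total counts equal the number of intervals not exceeding ``max_lag``.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be positive")
    v = isi.values if isinstance(isi, ISISequence) else np.asarray(isi, dtype=float)
    return LagHistogram(
        kind="interval",
        bin_width=bin_width,
        max_lag=max_lag,
        counts=_bin_positive_lags(v, bin_width, max_lag),
    )


def autocorrelation_histogram(
    train: SpikeTrain, bin_width: float = 0.010, max_lag: float = 1.0
) -> LagHistogram:
    """Autocorrelation histogram: all ordered spike-pair lags in (0, max_lag].

    Zero-lag self-pairs are excluded; only positive lags are kept (the ACH
    is symmetric by construction).  Periodic peaks indicate rhythmic firing;
    a flat profile is the signature of a homogeneous Poisson train.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be positive")
    ts = train.timestamps
    if ts.size < 2:
        raise InsufficientDataError("need >= 2 spikes for an ACH")
    n_bins = int(round(max_lag / bin_width))
    counts = np.zeros(n_bins, dtype=np.int64)
    hi = np.searchsorted(ts, ts + max_lag * (1 + 1e-12), side="right")
    for i in range(ts.size - 1):
        if hi[i] > i + 1:
            lags = ts[i + 1 : hi[i]] - ts[i]
            counts += _bin_positive_lags(lags, bin_width, max_lag)
    return LagHistogram(kind="autocorrelation", bin_width=bin_width, max_lag=max_lag, counts=counts)


def smoothing_var_factor(sigma: float) -> float:
    """Sum of squared Gaussian-kernel weights: the variance shrinkage that
    smoothing applies to independent per-bin counting noise."""
    half = max(1, int(np.ceil(4 * sigma)))
    delta = np.zeros(2 * half + 1)
    delta[half] = 1.0
    k = gaussian_filter1d(delta, sigma)
    return float(np.sum(k**2))


def unimodality_check(
    ih: LagHistogram,
    smooth_bins: float = 2.0,
    height_frac: float = 0.05,
    prominence_z: float = 3.0,
) -> bool | None:
    """Tri-state unimodality of an interval histogram.

    The counts are smoothed with a Gaussian kernel (bandwidth
    ``smooth_bins`` bins); a local maximum counts as a mode when its height
    is at least ``height_frac`` of the global maximum *and* it rises at
    least ``prominence_z`` smoothed-Poisson noise SDs above its reference
    valley (so counting wiggles on a plateau are not modes).  Exactly one
    mode -> True, two or more -> False, too little data (< 5 occupied bins)
    -> None.  A stand-in for visual classification; thresholds are
    configurable.
    """
    counts = ih.counts.astype(float)
    if int(np.sum(counts > 0)) < 5:
        return None
    sm = gaussian_filter1d(counts, smooth_bins, mode="nearest")
    floor = height_frac * float(sm.max())
    # Pad with zeros so a mode in the first or last bin is still a peak.
    padded = np.concatenate([[0.0], sm, [0.0]])
    peaks, props = find_peaks(padded, height=floor)
    if peaks.size:
        prom = peak_prominences(padded, peaks)[0]
        heights = props["peak_heights"]
        k = smoothing_var_factor(smooth_bins)
        noise_sd = np.sqrt(np.maximum(heights, 1.0) * k)
        peaks = peaks[prom >= prominence_z * noise_sd]
    n_peaks = int(peaks.size)
    if n_peaks == 0:
        return None
    return n_peaks == 1
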