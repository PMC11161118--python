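"""Domain types for single-unit spike-train analysis.

The package characterizes the basal discharge of single neurons recorded
extracellularly (here: dorsal and median raphe nuclei, DRN/MRN) from three
ingredients: the spike timestamps, the derived inter-spike-interval (ISI)
sequence, and the averaged extracellular action-potential waveform.  All
internal times are seconds; waveform durations are reported in milliseconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidParameterError",
    "SpikeTrainFormatError",
    "GenerationError",
    "InsufficientDataError",
    "SpikeTrain",
    "ISISequence",
    "WaveformTemplate",
    "RefractoryReport",
    "compute_isi",
    "standardize_length",
    "check_refractory",
    "DEFAULT_ISI_LENGTH",
]

#: Standardized ISI sequence length used throughout the analysis.  Every
#: neuron is truncated to the same number of intervals so that entropy and
#: complexity estimates share identical statistical power across neurons.
DEFAULT_ISI_LENGTH = 225


class InvalidParameterError(ValueError):
    """A generator or measure parameter is outside its valid domain."""


class SpikeTrainFormatError(ValueError):
    """An input file violates the spike-train format contract."""


class GenerationError(RuntimeError):
    """A synthetic generator could not satisfy its constraints."""


class InsufficientDataError(ValueError):
    """A spike train is too short for the requested operation."""


@dataclass(frozen=True)
class SpikeTrain:
    """Timestamped point process for one neuron.

    Parameters
    ----------
    timestamps:
        Spike times in seconds, strictly increasing.
    amplitudes:
        Optional per-spike amplitudes (relative units), same length as
        ``timestamps``.  Only burst detection consumes them.
    neuron_id, animal_id:
        Identifiers used for cohort bookkeeping and seed derivation.
    nucleus:
        Anatomical group label (``"DRN"``, ``"MRN"`` or ``"unknown"``).
    recording_window:
        ``(t_start, t_end)`` of the analysis window in seconds.  Defaults to
        the span of the timestamps.
    """

    timestamps: np.ndarray
    amplitudes: np.ndarray | None = None
    neuron_id: str = ""
    animal_id: str = ""
    nucleus: str = "unknown"
    recording_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.ndim != 1 or ts.size == 0:
            raise SpikeTrainFormatError("timestamps must be a non-empty 1-D array")
        d = np.diff(ts)
        if ts.size > 1 and not np.all(d > 0):
            bad = int(np.flatnonzero(d <= 0)[0]) + 1
            kind = "duplicate" if d[bad - 1] == 0 else "out-of-order"
            raise SpikeTrainFormatError(
                f"timestamps must be strictly increasing: {kind} value at row {bad}"
            )
        object.__setattr__(self, "timestamps", ts)
        if self.amplitudes is not None:
            amp = np.asarray(self.amplitudes, dtype=float)
            if amp.shape != ts.shape:
                raise SpikeTrainFormatError(
                    f"amplitudes length {amp.size} != number of spikes {ts.size}"
                )
            object.__setattr__(self, "amplitudes", amp)
        window = self.recording_window
        if window is None:
            window = (float(ts[0]), float(ts[-1]))
        else:
            window = (float(window[0]), float(window[1]))
            if window[0] > ts[0] or window[1] < ts[-1]:
                raise SpikeTrainFormatError(
                    "all timestamps must lie inside recording_window"
                )
        object.__setattr__(self, "recording_window", window)

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        t0, t1 = self.recording_window
        return t1 - t0

    def replace(self, **changes) -> "SpikeTrain":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ISISequence:
    """Ordered inter-spike intervals (seconds) for one neuron.

    The ISI sequence is the substrate of every order-sensitive measure in the
    package; its temporal order is meaningful and must not be disturbed
    except deliberately (shuffle surrogates).
    """

    values: np.ndarray
    neuron_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise InvalidParameterError("ISI values must be a non-empty 1-D array")
        if np.any(v <= 0):
            raise InvalidParameterError("ISI values must all be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class WaveformTemplate:
    """Averaged extracellular action-potential shape.

    ``samples`` is voltage in arbitrary units at a uniform sample period
    ``1 / sample_rate``; ``baseline_window`` is the (start, stop) index range
    of pre-spike baseline used to estimate noise level and offset.
    """

    samples: np.ndarray
    sample_rate: float
    baseline_window: tuple[int, int]

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1 or s.size < 8:
            raise InvalidParameterError("waveform needs >= 8 samples")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")
        b0, b1 = self.baseline_window
        if not (0 <= b0 < b1 <= s.size):
            raise InvalidParameterError("baseline_window out of range")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "baseline_window", (int(b0), int(b1)))

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.sample_rate


@dataclass(frozen=True)
class RefractoryReport:
    """Result of the refractory-period contamination check."""

    refractory_s: float
    count: int
    indices: np.ndarray = field(repr=False)
    clean: bool = True


def compute_isi(train: SpikeTrain) -> ISISequence:
    """Derive the inter-spike-interval sequence of a train.

    Raises
    ------
    InsufficientDataError
        If the train has fewer than 2 spikes.
    """
    if train.n_spikes < 2:
        raise InsufficientDataError("need >= 2 spikes to form an ISI sequence")
    return ISISequence(np.diff(train.timestamps), neuron_id=train.neuron_id)


def standardize_length(isi: ISISequence, n: int = DEFAULT_ISI_LENGTH) -> ISISequence:
    """Truncate an ISI sequence to its first ``n`` contiguous intervals.

    Truncation keeps the *first* contiguous block: contiguity preserves the
    temporal structure that ordinal-pattern entropy and Lempel-Ziv complexity
    measure, which subsampling would destroy.  The input is left untouched.

    Raises
    ------
    InsufficientDataError
        If the sequence is shorter than ``n``; record longer or lower ``n``.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if len(isi) < n:
        raise InsufficientDataError(
            f"ISI sequence has {len(isi)} intervals < requested {n}; "
            "record a longer train or lower the standardized length"
        )
    if len(isi) == n:
        return isi
    return ISISequence(isi.values[:n].copy(), neuron_id=isi.neuron_id)


def check_refractory(train: SpikeTrain, refractory_s: float = 0.002) -> RefractoryReport:
    """Report ISIs shorter than the absolute refractory period.

    A clean single unit cannot fire twice within the refractory period
    (about 2 ms); sub-refractory intervals indicate contamination by a second
    unit.  This is a report, not a rejection: synthetic or multi-unit data
    may legitimately violate it.
    """
    if refractory_s <= 0:
        raise InvalidParameterError("refractory_s must be positive")
    isis = np.diff(train.timestamps)
    idx = np.flatnonzero(isis < refractory_s)
    return RefractoryReport(
        refractory_s=refractory_s,
        count=int(idx.size),
        indices=idx,
        clean=bool(idx.size == 0),
    )
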