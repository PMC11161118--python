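"""Synthetic spike trains, waveforms, and hierarchical cohorts.

Four generator classes emulate the firing phenotypes found in raphe
recordings:

* ``renewal_gamma`` — gamma renewal process (i.i.d. gamma ISIs); its CV is
  ``gamma_shape**-0.5``, so shape 1 is Poisson-like/irregular firing.
* ``clock_like`` — the same renewal process with high shape (regular,
  CV <= 0.25) and a slow 1-5 Hz rate, plus a wide waveform: the classical
  putative-serotonergic signature.
* ``rhythmic_modulated`` — inhomogeneous Poisson process with intensity
  ``base_rate * (1 + mod_depth * sin(2 pi mod_freq t))`` generated by
  thinning; theta-band modulation frequencies (4-9 Hz) by default.
* ``bursting`` — renewal placement of doublets/triplets whose intra-burst
  ISIs stay below 20 ms and whose spike amplitudes decay geometrically.

Every generator is a pure function of (parameters, seed): identical inputs
give bit-for-bit identical output.  Cohorts reproduce the hierarchical
structure of the recordings: a variable number of neurons (1-7) per animal,
with per-nucleus mixtures of the four classes and ground-truth labels for
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    GenerationError,
    InvalidParameterError,
    SpikeTrain,
    WaveformTemplate,
)

__all__ = [
    "GeneratorSpec",
    "CohortSpec",
    "CohortData",
    "gen_renewal_train",
    "gen_rhythmic_train",
    "gen_burst_train",
    "gen_waveform",
    "gen_cohort",
    "PROCESS_KINDS",
    "DEFAULT_CLASS_MIXTURE",
]

PROCESS_KINDS = ("renewal_gamma", "rhythmic_modulated", "bursting", "clock_like")

#: Per-nucleus class proportions of the default synthetic cohort, mirroring
#: the reported composition of the two populations (DRN: ~26% rhythmic, 5%
#: bursting, ~9% clock-like; MRN: ~21% rhythmic, 21% bursting, no
#: clock-like).
DEFAULT_CLASS_MIXTURE: dict[str, dict[str, float]] = {
    "DRN": {"renewal_gamma": 0.60, "rhythmic_modulated": 0.26, "bursting": 0.05, "clock_like": 0.09},
    "MRN": {"renewal_gamma": 0.58, "rhythmic_modulated": 0.21, "bursting": 0.21},
}

#: Minimum spikes per cohort neuron: leaves headroom above the 226 spikes
#: needed for a standardized 225-interval ISI sequence.
_COHORT_MIN_SPIKES = 320

#: Minimum emulated recording duration (s).  Basal activity is recorded for
#: minutes and analyzed over 60-300 s stable windows; autocorrelogram-based
#: rhythmicity needs that much data even though the nonlinear measures use
#: only the first 225 intervals.
_COHORT_MIN_DURATION_S = 120.0


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic neuron.

    Only the fields relevant to ``process_kind`` are consumed; the rest keep
    their defaults.  ``amplitude_decrement`` is the fractional amplitude
    drop per within-burst spike; ``apd_ms`` parameterizes the waveform
    template paired with the train.
    """

    process_kind: str
    rate: float = 5.0
    gamma_shape: float = 1.0
    mod_freq: float = 6.0
    mod_depth: float = 0.9
    burst_size_range: tuple[int, int] = (2, 3)
    intra_burst_isi_max: float = 0.020
    amplitude_decrement: float = 0.3
    apd_ms: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.process_kind not in PROCESS_KINDS:
            raise InvalidParameterError(f"unknown process_kind {self.process_kind!r}")
        if self.rate <= 0 or self.gamma_shape <= 0:
            raise InvalidParameterError("rate and gamma_shape must be positive")
        if not 0 <= self.mod_depth <= 1:
            raise InvalidParameterError("mod_depth must lie in [0, 1]")
        if self.intra_burst_isi_max <= 0:
            raise InvalidParameterError("intra_burst_isi_max must be positive")
        lo, hi = self.burst_size_range
        if not (2 <= lo <= hi <= 3):
            raise InvalidParameterError("burst sizes must lie in {2, 3}")
        if not 0 <= self.amplitude_decrement < 1:
            raise InvalidParameterError("amplitude_decrement must lie in [0, 1)")

    def generate(
        self,
        min_spikes: int = _COHORT_MIN_SPIKES,
        min_duration: float = _COHORT_MIN_DURATION_S,
        **train_meta,
    ) -> SpikeTrain:
        """Generate a train of at least ``min_spikes`` spikes spanning at
        least ``min_duration`` seconds for this spec."""
        if self.process_kind in ("renewal_gamma", "clock_like"):
            n = max(min_spikes, int(np.ceil(self.rate * min_duration)) + 1)
            return gen_renewal_train(
                self.rate, self.gamma_shape, n_spikes=n, seed=self.seed, **train_meta
            )
        if self.process_kind == "rhythmic_modulated":
            duration = max(min_duration, 1.3 * min_spikes / self.rate)
            while True:
                train = gen_rhythmic_train(
                    self.rate, self.mod_freq, self.mod_depth, duration, seed=self.seed,
                    **train_meta,
                )
                if train.n_spikes >= min_spikes:
                    return train
                duration *= 1.5
        mean_size = 0.5 * (self.burst_size_range[0] + self.burst_size_range[1])
        duration = max(min_duration, 1.3 * min_spikes / (self.rate * mean_size))
        while True:
            train = gen_burst_train(
                self.rate,
                self.burst_size_range,
                self.intra_burst_isi_max,
                self.amplitude_decrement,
                duration,
                seed=self.seed,
                **train_meta,
            )
            if train.n_spikes >= min_spikes:
                return train
            duration *= 1.5


def gen_renewal_train(
    rate: float,
    gamma_shape: float,
    n_spikes: int,
    seed: int | np.random.Generator | None = None,
    **train_meta,
) -> SpikeTrain:
    """Gamma renewal train: i.i.d. gamma ISIs, mean 1/rate, CV = shape**-0.5."""
    if rate <= 0 or gamma_shape <= 0:
        raise InvalidParameterError("rate and gamma_shape must be positive")
    if n_spikes < 2:
        raise InvalidParameterError("n_spikes must be >= 2")
    rng = _rng(seed)
    isis = rng.gamma(gamma_shape, scale=1.0 / (rate * gamma_shape), size=n_spikes - 1)
    ts = np.concatenate([[0.0], np.cumsum(isis)])
    return SpikeTrain(timestamps=ts, **train_meta)


def gen_rhythmic_train(
    base_rate: float,
    mod_freq: float,
    mod_depth: float,
    duration: float,
    seed: int | np.random.Generator | None = None,
    **train_meta,
) -> SpikeTrain:
    """Sinusoidally rate-modulated Poisson train, generated by thinning.

    Candidate events are drawn from a homogeneous Poisson process at the
    peak intensity and kept with probability lambda(t) / lambda_max, which
    samples the inhomogeneous process exactly.  With ``mod_depth=0`` the
    output is a homogeneous Poisson (exponential renewal) train.
    """
    if base_rate <= 0 or mod_freq <= 0 or duration <= 0:
        raise InvalidParameterError("base_rate, mod_freq and duration must be positive")
    if not 0 <= mod_depth <= 1:
        raise InvalidParameterError("mod_depth must lie in [0, 1]")
    rng = _rng(seed)
    lam_max = base_rate * (1.0 + mod_depth)
    # Homogeneous candidates on [0, duration] via exponential gaps.
    n_expect = lam_max * duration
    ts: list[np.ndarray] = []
    t = 0.0
    while t < duration:
        gaps = rng.exponential(1.0 / lam_max, size=max(64, int(1.3 * n_expect)))
        cand = t + np.cumsum(gaps)
        ts.append(cand)
        t = cand[-1]
    cand = np.concatenate(ts)
    cand = cand[cand < duration]
    if mod_depth > 0:
        accept_p = (1.0 + mod_depth * np.sin(2 * np.pi * mod_freq * cand)) / (1.0 + mod_depth)
        keep = rng.random(cand.size) < accept_p
        cand = cand[keep]
    if cand.size < 2:
        raise GenerationError("fewer than 2 spikes generated; increase duration or rate")
    return SpikeTrain(timestamps=cand, recording_window=(0.0, duration), **train_meta)


def gen_burst_train(
    burst_rate: float,
    burst_size_range: tuple[int, int] = (2, 3),
    intra_burst_isi_max: float = 0.020,
    amplitude_decrement: float = 0.3,
    duration: float = 60.0,
    seed: int | np.random.Generator | None = None,
    **train_meta,
) -> SpikeTrain:
    """Train of doublets/triplets placed by a Poisson renewal of burst onsets.

    Burst onsets follow a gamma renewal (shape 4, mean gap 1/burst_rate):
    bursting neurons emit their doublets/triplets quasi-rhythmically, which
    puts the inter-burst mode of the interval histogram well away from the
    sub-20 ms intra-burst peak (the classic bimodal signature).  Within-burst
    ISIs are uniform on (0.3, 0.95) x ``intra_burst_isi_max`` (always below
    the threshold); spike amplitudes decay geometrically by
    ``amplitude_decrement`` within each burst.  Bursts that would overlap a
    previous burst (onset closer than two intra-burst intervals past its
    end) are rejected rather than merged, keeping ground truth unambiguous;
    if the requested rate forces more than half of the candidates to be
    rejected, generation fails with a diagnostic.
    """
    if burst_rate <= 0 or duration <= 0:
        raise InvalidParameterError("burst_rate and duration must be positive")
    lo, hi = burst_size_range
    if not (2 <= lo <= hi <= 3):
        raise InvalidParameterError("burst sizes must lie in {2, 3}")
    if intra_burst_isi_max <= 0 or intra_burst_isi_max > 0.020:
        raise InvalidParameterError("intra_burst_isi_max must lie in (0, 0.020] s")
    if not 0 <= amplitude_decrement < 1:
        raise InvalidParameterError("amplitude_decrement must lie in [0, 1)")
    gap_min = 2.0 * intra_burst_isi_max
    max_burst_span = (hi - 1) * intra_burst_isi_max
    if burst_rate * (max_burst_span + gap_min) > 0.5:
        raise GenerationError(
            f"burst_rate {burst_rate}/s is too high for non-overlapping bursts of "
            f"span <= {max_burst_span:.3f} s plus a {gap_min:.3f} s separation"
        )
    rng = _rng(seed)
    onset_shape = 4.0  # gamma shape of the burst-onset renewal
    spikes: list[float] = []
    amps: list[float] = []
    n_candidates = 0
    n_rejected = 0
    t = float(rng.gamma(onset_shape, 1.0 / (onset_shape * burst_rate)))
    prev_end = -np.inf
    while t < duration:
        n_candidates += 1
        if t <= prev_end + gap_min:
            n_rejected += 1
        else:
            size = int(rng.integers(lo, hi + 1))
            intra = rng.uniform(0.3, 0.95, size=size - 1) * intra_burst_isi_max
            times = t + np.concatenate([[0.0], np.cumsum(intra)])
            spikes.extend(times.tolist())
            amps.extend(((1.0 - amplitude_decrement) ** np.arange(size)).tolist())
            prev_end = float(times[-1])
        t += float(rng.gamma(onset_shape, 1.0 / (onset_shape * burst_rate)))
    if n_candidates and n_rejected / n_candidates > 0.5:
        raise GenerationError(
            f"{n_rejected}/{n_candidates} candidate bursts overlapped and were "
            "rejected; lower burst_rate"
        )
    if len(spikes) < 2:
        raise GenerationError("fewer than 2 spikes generated; increase duration or burst_rate")
    return SpikeTrain(
        timestamps=np.array(spikes),
        amplitudes=np.array(amps),
        recording_window=(0.0, max(duration, spikes[-1])),
        **train_meta,
    )


def gen_waveform(
    apd_ms: float,
    sample_rate: float = 20000.0,
    seed: int | np.random.Generator | None = None,
    amplitude: float = 1.0,
    noise_sd: float = 1e-4,
    baseline_ms: float = 2.0,
) -> WaveformTemplate:
    """Triphasic averaged-spike template whose first two phases span ``apd_ms``.

    A prominent positive half-sine (phase 1) is followed by a negative
    half-sine (phase 2) — together exactly ``apd_ms`` long — and a smaller
    positive third phase.  Gaussian noise of SD ``noise_sd`` (relative to a
    unit peak) emulates residual averaging noise.

    Raises
    ------
    InvalidParameterError
        If fewer than 8 samples would span the APD, or the sample rate is
        below the 20 kHz digitization floor.
    """
    if apd_ms <= 0:
        raise InvalidParameterError("apd_ms must be positive")
    if sample_rate < 20000.0:
        raise InvalidParameterError("sample_rate must be >= 20 kHz")
    dt_ms = 1000.0 / sample_rate
    n_apd = int(round(apd_ms / dt_ms))
    if n_apd < 8:
        raise InvalidParameterError(
            f"only {n_apd} samples span the APD; need >= 8 (raise sample_rate)"
        )
    rng = _rng(seed)
    n_base = int(round(baseline_ms / dt_ms))
    n1 = n_apd // 2
    n2 = n_apd - n1
    n3 = n1
    n_tail = int(round(1.0 / dt_ms))
    phase1 = amplitude * np.sin(np.pi * (np.arange(n1) + 0.5) / n1)
    phase2 = -0.7 * amplitude * np.sin(np.pi * (np.arange(n2) + 0.5) / n2)
    phase3 = 0.25 * amplitude * np.sin(np.pi * (np.arange(n3) + 0.5) / n3)
    v = np.concatenate([np.zeros(n_base), phase1, phase2, phase3, np.zeros(n_tail)])
    v = v + rng.normal(0.0, noise_sd * amplitude, size=v.size)
    return WaveformTemplate(samples=v, sample_rate=sample_rate, baseline_window=(0, n_base))


@dataclass(frozen=True)
class CohortSpec:
    """Hierarchical cohort layout: animals, neurons per animal, class mixture."""

    n_animals: int = 64
    neurons_per_animal_range: tuple[int, int] = (1, 7)
    class_mixture: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_MIXTURE.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise InvalidParameterError("n_animals must be >= 1")
        lo, hi = self.neurons_per_animal_range
        if not (1 <= lo <= hi):
            raise InvalidParameterError("neurons_per_animal_range must satisfy 1 <= lo <= hi")
        for nucleus, mix in self.class_mixture.items():
            if not mix:
                raise InvalidParameterError(f"empty class mixture for nucleus {nucleus!r}")
            for kind, p in mix.items():
                if kind not in PROCESS_KINDS:
                    raise InvalidParameterError(f"unknown process kind {kind!r}")
                if p < 0:
                    raise InvalidParameterError("mixture proportions must be >= 0")
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise InvalidParameterError(
                    f"class mixture for {nucleus!r} sums to {total}, not 1"
                )


@dataclass(frozen=True)
class CohortData:
    """Generated cohort: trains, per-neuron waveforms, and ground-truth manifest."""

    trains: tuple[SpikeTrain, ...]
    waveforms: dict[str, WaveformTemplate]
    manifest: pd.DataFrame


# Per-class parameter ranges of the default study conditions.  Rates cover
# the slow regular (clock-like) to fast irregular range seen in raphe
# recordings; clock-like rates start at 2.5 Hz so that a 1 s autocorrelogram
# window contains at least two periods of the regular rhythm.
_CLASS_PARAMS = {
    "renewal_gamma": dict(rate=(3.0, 20.0), gamma_shape=1.0, apd=(0.8, 2.5)),
    "clock_like": dict(rate=(2.5, 4.5), gamma_shape=25.0, apd=(1.8, 3.5)),
    "rhythmic_modulated": dict(rate=(8.0, 20.0), mod_freq=(4.0, 9.0), mod_depth=0.9, apd=(0.8, 2.5)),
    "bursting": dict(rate=(2.0, 6.0), apd=(0.8, 2.5)),
}


def _uniform(rng: np.random.Generator, bounds) -> float:
    lo, hi = bounds
    return float(rng.uniform(lo, hi))


def gen_cohort(spec: CohortSpec, min_spikes: int = _COHORT_MIN_SPIKES) -> CohortData:
    """Generate a labeled hierarchical cohort.

    Animals are assigned round-robin to the nuclei in the mixture; each
    animal contributes a uniform 1-7 (by default) neurons whose class is
    drawn from its nucleus mixture.  Every neuron carries its ground-truth
    class in the manifest and at least ``min_spikes`` spikes, so a
    standardized 225-interval ISI sequence always exists.
    """
    root = np.random.SeedSequence(spec.seed)
    nuclei = sorted(spec.class_mixture)
    trains: list[SpikeTrain] = []
    waveforms: dict[str, WaveformTemplate] = {}
    rows: list[dict] = []
    lo, hi = spec.neurons_per_animal_range
    animal_seeds = root.spawn(spec.n_animals)
    for a in range(spec.n_animals):
        rng = np.random.default_rng(animal_seeds[a])
        nucleus = nuclei[a % len(nuclei)]
        mix = spec.class_mixture[nucleus]
        kinds = sorted(mix)
        probs = np.array([mix[k] for k in kinds])
        animal_id = f"rat{a + 1:03d}"
        n_neurons = int(rng.integers(lo, hi + 1))
        for j in range(n_neurons):
            neuron_id = f"{animal_id}_n{j + 1}"
            kind = kinds[int(rng.choice(len(kinds), p=probs))]
            params = _CLASS_PARAMS[kind]
            apd_ms = _uniform(rng, params["apd"])
            gspec = GeneratorSpec(
                process_kind=kind,
                rate=_uniform(rng, params["rate"]),
                gamma_shape=float(params.get("gamma_shape", 1.0)),
                mod_freq=_uniform(rng, params["mod_freq"]) if "mod_freq" in params else 6.0,
                mod_depth=float(params.get("mod_depth", 0.9)),
                apd_ms=apd_ms,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            train = gspec.generate(
                min_spikes=min_spikes,
                neuron_id=neuron_id,
                animal_id=animal_id,
                nucleus=nucleus,
            )
            if train.amplitudes is None:
                train = train.replace(amplitudes=np.ones(train.n_spikes))
            waveforms[neuron_id] = gen_waveform(
                apd_ms, seed=np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
            )
            trains.append(train)
            rows.append(
                dict(
                    neuron_id=neuron_id,
                    animal_id=animal_id,
                    nucleus=nucleus,
                    true_class=kind,
                    n_spikes=train.n_spikes,
                )
            )
    manifest = pd.DataFrame(rows)
    return CohortData(trains=tuple(trains), waveforms=waveforms, manifest=manifest)
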