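"""End-to-end orchestration: cohort in, per-neuron profiles and cohort
statistics out.

``characterize_neuron`` computes the six measures, the classification
flags and the surrogate tests for one train; ``run_cohort`` maps it over a
cohort, then adds group comparisons and the pairwise redundancy matrix, and
writes everything as CSV/YAML/log files.  All randomness flows from one
master seed: per-neuron streams are derived by stable hashing of the neuron
id, so results are reproducible end-to-end yet independent across neurons.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import (
    INTRA_BURST_ISI_MAX_S,
    RHYTHMIC,
    BurstReport,
    RhythmicityResult,
    classify_clock_like,
    classify_rhythmicity,
    detect_bursts,
)
from .core import (
    DEFAULT_ISI_LENGTH,
    InsufficientDataError,
    SpikeTrain,
    WaveformTemplate,
    check_refractory,
    compute_isi,
    standardize_length,
)
from .io import load_manifest, load_spike_train, load_waveform
from .measures import (
    MeasureSet,
    autocorrelation_histogram,
    coefficient_of_variation,
    firing_rate,
    interval_histogram,
    measure_apd,
    unimodality_check,
)
from .ordinal import DEFAULT_D, DEFAULT_NB, DEFAULT_TIEBREAK_SCALE, bins_entropy, op_entropy, plzc
from .stats import MEASURE_COLUMNS, group_compare, redundancy_matrix, redundancy_table
from .surrogates import surrogate_test

__all__ = ["RunConfig", "NeuronProfile", "CohortReport", "characterize_neuron", "run_cohort",
           "run_cohort_from_manifest"]

logger = logging.getLogger("spikeprofile")


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of a characterization run, serialized with its outputs."""

    n_isi: int = DEFAULT_ISI_LENGTH
    D: int = DEFAULT_D
    nb: int = DEFAULT_NB
    n_surrogates: int = 100
    master_seed: int = 0
    tiebreak_scale: float = DEFAULT_TIEBREAK_SCALE
    ach_bin_width: float = 0.010
    ach_max_lag: float = 1.0
    ih_bin_width: float = 0.010
    ih_max_lag: float = 1.0
    refractory_s: float = 0.002
    rhythm_smooth_bins: float = 2.0
    rhythm_z: float = 3.5
    rhythm_spacing_tol: float = 0.20
    intra_burst_isi_max: float = INTRA_BURST_ISI_MAX_S
    burst_min_count: int = 3
    burst_min_fraction: float = 0.01
    clock_apd_min_ms: float = 1.4
    clock_cv_max: float = 0.30
    clock_fr_max_hz: float = 5.0
    n_permutations: int = 2000

    def neuron_seed(self, neuron_id: str) -> int:
        """Stable per-neuron seed: master seed mixed with a CRC of the id."""
        h = zlib.crc32(neuron_id.encode("utf-8"))
        return int((self.master_seed * 1_000_003 + h) % (2**31 - 1))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class NeuronProfile:
    """Full per-neuron characterization."""

    neuron_id: str
    animal_id: str
    nucleus: str
    measures: MeasureSet
    rhythmicity: RhythmicityResult
    bursts: BurstReport
    surrogate_p: dict[str, float]
    refractory_violations: int
    seed: int

    def to_row(self) -> dict:
        m = self.measures
        return dict(
            neuron_id=self.neuron_id,
            animal_id=self.animal_id,
            nucleus=self.nucleus,
            fr_hz=m.fr_hz,
            cv=m.cv,
            apd_ms=m.apd_ms if m.apd_ms is not None else np.nan,
            op_entropy=m.op_entropy,
            bins_entropy=m.bins_entropy,
            plzc=m.plzc,
            rhythmic=self.rhythmicity.label == RHYTHMIC,
            rhythm_label=self.rhythmicity.label,
            rhythm_freq_hz=self.rhythmicity.rhythm_freq_hz
            if self.rhythmicity.rhythm_freq_hz is not None
            else np.nan,
            bursting=self.bursts.bursting,
            clock_like=m.clock_like,
            unimodal_ih=m.unimodal_ih,
            surrogate_p_op=self.surrogate_p.get("op_entropy", np.nan),
            surrogate_p_plzc=self.surrogate_p.get("plzc", np.nan),
            refractory_violations=self.refractory_violations,
        )


def characterize_neuron(
    train: SpikeTrain,
    config: RunConfig = RunConfig(),
    waveform: WaveformTemplate | None = None,
) -> NeuronProfile:
    """Compute all measures, flags and surrogate tests for one neuron.

    The six measures are computed on the standardized ``n_isi``-interval
    sequence (FR over the train's recording window); rhythmicity and bursts
    use the full train.  Raises :class:`InsufficientDataError` when the
    train cannot supply ``n_isi`` intervals — callers decide whether to
    skip.
    """
    if train.n_spikes < config.n_isi + 1:
        raise InsufficientDataError(
            f"{train.neuron_id or 'train'}: {train.n_spikes} spikes < "
            f"{config.n_isi + 1} required for a standardized ISI sequence"
        )
    seed = config.neuron_seed(train.neuron_id)
    isi = standardize_length(compute_isi(train), config.n_isi)
    refractory = check_refractory(train, config.refractory_s)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short-window warnings are logged upstream
        fr = firing_rate(train, window=train.recording_window)
    cv = coefficient_of_variation(isi)
    apd = measure_apd(waveform) if waveform is not None else None

    ss = np.random.SeedSequence(seed)
    s_op, s_plzc, s_surr_op, s_surr_plzc = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(4)]
    h_op = op_entropy(isi, D=config.D, tiebreak_seed=s_op, tiebreak_scale=config.tiebreak_scale)
    h_bins = bins_entropy(isi, nb=config.nb)
    c_plzc = plzc(isi, D=config.D, tiebreak_seed=s_plzc, tiebreak_scale=config.tiebreak_scale)

    ach = autocorrelation_histogram(train, config.ach_bin_width, config.ach_max_lag)
    rhythm = classify_rhythmicity(
        ach,
        smooth_bins=config.rhythm_smooth_bins,
        z=config.rhythm_z,
        spacing_tol=config.rhythm_spacing_tol,
    )
    bursts = detect_bursts(
        train,
        intra_burst_isi_max=config.intra_burst_isi_max,
        min_bursts=config.burst_min_count,
        min_fraction=config.burst_min_fraction,
    )
    ih = interval_histogram(isi, config.ih_bin_width, config.ih_max_lag)
    unimodal = unimodality_check(ih)

    measures = MeasureSet(
        fr_hz=fr,
        cv=cv,
        apd_ms=apd,
        op_entropy=h_op,
        bins_entropy=h_bins,
        plzc=c_plzc,
        rhythmic=rhythm.label == RHYTHMIC,
        bursting=bursts.bursting,
        unimodal_ih=unimodal,
    )
    measures.clock_like = classify_clock_like(
        measures,
        rhythm,
        apd_min_ms=config.clock_apd_min_ms,
        cv_max=config.clock_cv_max,
        fr_max_hz=config.clock_fr_max_hz,
    )
    surrogate_p = {
        "op_entropy": surrogate_test(
            isi, "op_entropy", n=config.n_surrogates, seed=s_surr_op,
            D=config.D, tiebreak_scale=config.tiebreak_scale,
        ).p_value,
        "plzc": surrogate_test(
            isi, "plzc", n=config.n_surrogates, seed=s_surr_plzc,
            D=config.D, tiebreak_scale=config.tiebreak_scale,
        ).p_value,
    }
    return NeuronProfile(
        neuron_id=train.neuron_id,
        animal_id=train.animal_id,
        nucleus=train.nucleus,
        measures=measures,
        rhythmicity=rhythm,
        bursts=bursts,
        surrogate_p=surrogate_p,
        refractory_violations=refractory.count,
        seed=seed,
    )


@dataclass
class CohortReport:
    """In-memory results of a cohort run."""

    measures: pd.DataFrame
    comparisons: pd.DataFrame
    redundancy: pd.DataFrame
    skipped: pd.DataFrame
    config: RunConfig


_CONTRASTS = (
    # (column used to split, unit of permutation)
    ("nucleus", "animal"),
    ("rhythmic", "neuron"),
    ("bursting", "neuron"),
    ("clock_like", "neuron"),
)


def _cohort_comparisons(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Group comparisons of each measure for each available contrast."""
    rows = []
    rng_seed = np.random.SeedSequence(config.master_seed).spawn(1)[0]
    base = int(rng_seed.generate_state(1)[0] % (2**31 - 1))
    for ci, (split, unit) in enumerate(_CONTRASTS):
        if split not in df.columns:
            continue
        labels = df[split]
        if split != "nucleus":
            labels = labels.map(lambda v: "yes" if v is True else ("no" if v is False else None))
        mask = labels.notna()
        if labels[mask].nunique() != 2:
            continue
        for mi, measure in enumerate(MEASURE_COLUMNS):
            vals = df.loc[mask, measure].to_numpy(dtype=float)
            labs = labels[mask].to_numpy()
            animals = df.loc[mask, "animal_id"].to_numpy()
            finite = np.isfinite(vals)
            if finite.sum() < 6 or pd.unique(labs[finite]).size != 2:
                continue
            try:
                res = group_compare(
                    vals[finite],
                    labs[finite],
                    animals[finite],
                    n_perm=config.n_permutations,
                    seed=base + 1000 * ci + mi,
                    permute_unit=unit,
                    measure_name=measure,
                )
            except Exception as exc:  # e.g. single-animal group
                logger.warning("comparison %s/%s skipped: %s", split, measure, exc)
                continue
            rows.append(
                dict(
                    contrast=split,
                    measure=measure,
                    group1=res.group_names[0],
                    group2=res.group_names[1],
                    mean1=res.group_means[0],
                    mean2=res.group_means[1],
                    statistic=res.statistic,
                    p_value=res.p_value,
                    n_permutations=res.n_permutations,
                    permute_unit=res.permute_unit,
                )
            )
    return pd.DataFrame(rows)


def run_cohort(
    trains,
    config: RunConfig = RunConfig(),
    waveforms: dict[str, WaveformTemplate] | None = None,
    outdir: str | Path | None = None,
) -> CohortReport:
    """Characterize every train, then compute cohort statistics.

    Neurons that cannot supply the standardized ISI length are skipped with
    a logged reason (row accounting: valid + skipped = input size).  When
    ``outdir`` is given, writes measures.csv, comparisons.csv,
    redundancy.csv, skipped.csv, run_config.yaml and run.log.

    Raises
    ------
    InsufficientDataError
        If no neuron survives.
    """
    outdir_path: Path | None = None
    handler = None
    if outdir is not None:
        outdir_path = Path(outdir)
        outdir_path.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir_path / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    try:
        waveforms = waveforms or {}
        rows, skipped = [], []
        for train in trains:
            try:
                profile = characterize_neuron(
                    train, config, waveform=waveforms.get(train.neuron_id)
                )
            except InsufficientDataError as exc:
                logger.info("skipping %s: %s", train.neuron_id, exc)
                skipped.append(dict(neuron_id=train.neuron_id, reason=str(exc)))
                continue
            rows.append(profile.to_row())
            logger.info("characterized %s", train.neuron_id)
        if not rows:
            raise InsufficientDataError("no neuron provided enough spikes; nothing to report")
        measures = pd.DataFrame(rows)
        comparisons = _cohort_comparisons(measures, config)
        have_apd = measures["apd_ms"].notna().all()
        cols = MEASURE_COLUMNS if have_apd else tuple(c for c in MEASURE_COLUMNS if c != "apd_ms")
        redundancy = redundancy_table(redundancy_matrix(measures, columns=cols)) if len(
            measures
        ) >= 10 else pd.DataFrame()
        skipped_df = pd.DataFrame(skipped, columns=["neuron_id", "reason"])
        report = CohortReport(
            measures=measures,
            comparisons=comparisons,
            redundancy=redundancy,
            skipped=skipped_df,
            config=config,
        )
        if outdir_path is not None:
            measures.to_csv(outdir_path / "measures.csv", index=False)
            comparisons.to_csv(outdir_path / "comparisons.csv", index=False)
            redundancy.to_csv(outdir_path / "redundancy.csv", index=False)
            skipped_df.to_csv(outdir_path / "skipped.csv", index=False)
            config.to_yaml(outdir_path / "run_config.yaml")
        return report
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()


def run_cohort_from_manifest(
    manifest_path: str | Path,
    config: RunConfig = RunConfig(),
    outdir: str | Path | None = None,
) -> CohortReport:
    """Load a manifest CSV plus its spike/waveform files and run the cohort.

    Unreadable entries are logged and skipped; if every entry fails, an
    error is raised.
    """
    manifest_path = Path(manifest_path)
    df = load_manifest(manifest_path)
    base = manifest_path.parent
    trains, waveforms = [], {}
    failures = []
    for rec in df.to_dict("records"):
        try:
            train = load_spike_train(
                base / rec["spike_file"],
                neuron_id=str(rec["neuron_id"]),
                animal_id=str(rec.get("animal_id", "")),
                nucleus=str(rec.get("nucleus", "unknown")),
            )
            wf_file = rec.get("waveform_file")
            if isinstance(wf_file, str) and wf_file:
                waveforms[train.neuron_id] = load_waveform(base / wf_file)
            trains.append(train)
        except Exception as exc:
            logger.warning("manifest entry %s unreadable: %s", rec.get("neuron_id"), exc)
            failures.append(rec.get("neuron_id"))
    if not trains:
        raise InsufficientDataError("no readable manifest entries")
    return run_cohort(trains, config=config, waveforms=waveforms, outdir=outdir)
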