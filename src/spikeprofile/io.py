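"""Reading and writing spike trains, waveforms and cohort manifests.

All on-disk formats are plain text: spike files are single-column CSVs of
timestamps in seconds (optional second column: per-spike amplitude),
waveforms are two-column CSVs of (time_ms, voltage), manifests are CSVs with
one row per neuron.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SpikeTrain, SpikeTrainFormatError, WaveformTemplate

__all__ = [
    "load_spike_train",
    "save_spike_train",
    "load_waveform",
    "save_waveform",
    "load_manifest",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ("neuron_id", "animal_id", "nucleus", "spike_file")


def load_spike_train(
    path: str | os.PathLike,
    format: str = "csv_timestamps",
    units: str = "s",
    neuron_id: str = "",
    animal_id: str = "",
    nucleus: str = "unknown",
) -> SpikeTrain:
    """Load a spike train from a one-timestamp-per-row CSV.

    Parameters
    ----------
    units:
        ``"s"`` (canonical) or ``"ms"``; millisecond input is converted at
        load so that a single internal unit prevents silent 1000x errors.
    """
    if format != "csv_timestamps":
        raise ValueError(f"unsupported spike-train format: {format!r}")
    if units not in ("s", "ms"):
        raise ValueError("units must be 's' or 'ms'")
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter=",", ndmin=2, comments="#")
    except ValueError as exc:
        raise SpikeTrainFormatError(f"{path}: unparseable spike file ({exc})") from exc
    if data.size == 0:
        raise SpikeTrainFormatError(f"{path}: empty spike file")
    ts = data[:, 0]
    if units == "ms":
        ts = ts / 1000.0
    amp = data[:, 1] if data.shape[1] > 1 else None
    d = np.diff(ts)
    if ts.size > 1 and not np.all(d > 0):
        row = int(np.flatnonzero(d <= 0)[0]) + 2  # 1-based row of the offender
        kind = "duplicate" if d[row - 2] == 0 else "out-of-order"
        raise SpikeTrainFormatError(f"{path}: {kind} timestamp at row {row}")
    name = neuron_id or path.stem
    return SpikeTrain(
        timestamps=ts, amplitudes=amp, neuron_id=name, animal_id=animal_id, nucleus=nucleus
    )


def save_spike_train(train: SpikeTrain, path: str | os.PathLike) -> None:
    """Write a spike train to CSV at full float precision (round-trip safe)."""
    path = Path(path)
    if train.amplitudes is not None:
        data = np.column_stack([train.timestamps, train.amplitudes])
    else:
        data = train.timestamps.reshape(-1, 1)
    np.savetxt(path, data, delimiter=",", fmt="%.17g")


def load_waveform(
    path: str | os.PathLike, baseline_ms: float | None = None
) -> WaveformTemplate:
    """Load an averaged waveform from a (time_ms, voltage) CSV.

    The sample rate is inferred from the (uniform) time column.  The
    baseline window defaults to the samples before time zero; when the time
    axis starts at zero, ``baseline_ms`` must give the pre-spike span.
    """
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", ndmin=2, comments="#", skiprows=_header_rows(path))
    if data.shape[1] < 2:
        raise SpikeTrainFormatError(f"{path}: waveform CSV needs (time_ms, voltage) columns")
    t_ms, v = data[:, 0], data[:, 1]
    dt = np.diff(t_ms)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise SpikeTrainFormatError(f"{path}: waveform time axis is not uniform")
    sample_rate = 1000.0 / dt[0]
    if baseline_ms is None:
        n_base = int(np.sum(t_ms < 0))
        if n_base == 0:
            raise SpikeTrainFormatError(
                f"{path}: no pre-zero samples; pass baseline_ms explicitly"
            )
    else:
        n_base = int(round(baseline_ms / dt[0]))
    return WaveformTemplate(samples=v, sample_rate=sample_rate, baseline_window=(0, n_base))


def save_waveform(wave: WaveformTemplate, path: str | os.PathLike) -> None:
    """Write a waveform as (time_ms, voltage) with t=0 at baseline end."""
    n = wave.samples.size
    dt = wave.sample_period_ms
    t_ms = (np.arange(n) - wave.baseline_window[1]) * dt
    np.savetxt(
        Path(path),
        np.column_stack([t_ms, wave.samples]),
        delimiter=",",
        fmt="%.17g",
        header="time_ms,voltage",
    )


def _header_rows(path: Path) -> int:
    with open(path) as fh:
        first = fh.readline()
    head = first.lstrip("#").split(",")[0].strip()
    try:
        float(head)
        return 0
    except ValueError:
        return 1


def load_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Load a cohort manifest CSV and validate its required columns."""
    df = pd.read_csv(path, dtype={"neuron_id": str, "animal_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "spike_file"]
    if "spike_file" not in df.columns:
        missing.append("spike_file")
    if missing:
        raise SpikeTrainFormatError(f"manifest missing columns: {missing}")
    if df["neuron_id"].duplicated().any():
        dup = df.loc[df["neuron_id"].duplicated(), "neuron_id"].iloc[0]
        raise SpikeTrainFormatError(f"manifest has duplicate neuron_id: {dup}")
    return df
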