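"""Event-related spectral perturbation (ERSP) maps and ERD values.

The trial-averaged short-time Fourier power

    ERSP(f, t) = (1/n) * sum_k |F_k(f, t)|^2

is computed with a Hanning-tapered window of 256 samples (condition 1) or
512 samples (condition 2) at 200 window centers spanning the epoch, then
expressed in decibels relative to the per-frequency mean power over the
pre-onset baseline interval (divisive baseline normalization, the standard
ERSP convention).  An ERD value is the arithmetic mean of the dB map over a
rectangular frequency x time region:

    ERD_value = (1/N) * sum_{f in F} sum_{t in T} ERSP(f, t)

with N the number of time-frequency bins whose centers fall inside the
half-open rectangle.  Negative values are desynchronization (power loss
relative to baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .paradigm import (
    ConditionTiming,
    ROLE_CELLS,
    RoleLabel,
    SEQUENCE_NAMES,
    slot_window,
)
from .preprocessing import EpochArray

__all__ = ["TFMap", "ERDValue", "compute_ersp", "erd_value", "erd_by_role"]

#: Analysis band of the alpha/mu-ERD quantification (Hz).
ALPHA_BAND = (8.0, 13.0)

#: STFT window length in samples per pacing condition (at 200 Hz).
WINDOW_SAMPLES = {1: 256, 2: 512}


@dataclass
class TFMap:
    """Baseline-normalized time-frequency map (dB) of one electrode and task."""

    values: np.ndarray  # (n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray
    electrode: str
    task: str | None
    n_trials: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("axes must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")


@dataclass
class ERDValue:
    value: float  # dB
    band: tuple[float, float]
    interval: tuple[float, float]
    electrode: str
    role: RoleLabel | None
    n_bins: int


def compute_ersp(
    epochs: EpochArray,
    electrode: str,
    timing: ConditionTiming,
    n_windows: int = 200,
    freq_range: tuple[float, float] = (1.0, 30.0),
    task: str | None = None,
) -> TFMap:
    """Trial-averaged, baseline-normalized STFT power map of one electrode.

    Window centers are spaced evenly over the usable extent of the epoch
    (rounded to the nearest sample); the baseline is the per-frequency mean
    power over centers within the pre-onset baseline interval.
    """
    ch = epochs.channel_index(electrode)
    x = epochs.data[:, ch, :]
    wlen = WINDOW_SAMPLES[timing.condition]
    n_samp = x.shape[1]
    if n_samp < wlen:
        raise ValueError(
            f"epoch of {n_samp} samples shorter than the {wlen}-sample window"
        )
    half = wlen // 2
    centers = np.unique(
        np.round(np.linspace(half, n_samp - wlen + half, n_windows)).astype(int)
    )
    starts = centers - half
    window = np.hanning(wlen)

    segs = x[:, starts[:, None] + np.arange(wlen)] * window
    spec = np.fft.rfft(segs, axis=-1)
    power = (spec.real**2 + spec.imag**2).mean(axis=0)  # (n_centers, n_freqs)

    fs = epochs.fs
    freqs = np.fft.rfftfreq(wlen, 1.0 / fs)
    times = epochs.times[0] + centers / fs

    base_mask = (times >= -timing.baseline_length_s) & (times < 0)
    if not base_mask.any():
        raise ValueError("no window centers inside the baseline interval")
    baseline = power[base_mask].mean(axis=0)
    if np.any(baseline <= 0):
        bad = freqs[baseline <= 0]
        raise ValueError(f"zero baseline power at frequencies {bad}")
    values = 10.0 * np.log10(power / baseline)

    fmask = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    return TFMap(
        values[:, fmask].T,
        freqs[fmask],
        times,
        electrode,
        task if task is not None else _single_label(epochs),
        epochs.n_trials,
    )


def _single_label(epochs: EpochArray) -> str | None:
    labels = set(epochs.labels)
    return labels.pop() if len(labels) == 1 else None


def erd_value(
    tfmap: TFMap,
    band: tuple[float, float],
    interval: tuple[float, float],
    role: RoleLabel | None = None,
) -> ERDValue:
    """Mean dB over a half-open frequency x time rectangle of the map."""
    fmask = (tfmap.freqs >= band[0]) & (tfmap.freqs < band[1])
    tmask = (tfmap.times >= interval[0]) & (tfmap.times < interval[1])
    n_bins = int(fmask.sum() * tmask.sum())
    if n_bins < 1:
        raise ValueError(
            f"rectangle {band} Hz x {interval} s contains no map bins"
        )
    value = float(tfmap.values[np.ix_(fmask, tmask)].mean())
    return ERDValue(value, tuple(band), tuple(interval), tfmap.electrode, role, n_bins)


def erd_by_role(
    epochs: EpochArray,
    timing: ConditionTiming,
    band: tuple[float, float] = ALPHA_BAND,
) -> pd.DataFrame:
    """Alpha-band ERD value of every non-trivial sub-movement role.

    For each role (right/left-hand imagery in slot 2 or 3, labelled by its
    prior limb), the ERD value is taken at the role's designated electrode
    (C3 for right-hand, C4 for left-hand roles) over the role's slot window.
    Requires trials of all four sequence classes.
    """
    missing = [s for s in SEQUENCE_NAMES if s not in set(epochs.labels)]
    if missing:
        raise ValueError(f"missing task classes: {missing}")
    maps: dict[tuple[str, str], TFMap] = {}
    rows = []
    for label, seq_name, slot in ROLE_CELLS:
        electrode = "C3" if label.value.startswith("RH") else "C4"
        key = (seq_name, electrode)
        if key not in maps:
            maps[key] = compute_ersp(
                epochs.task(seq_name), electrode, timing, task=seq_name
            )
        interval = slot_window(timing, slot)
        erd = erd_value(maps[key], band, interval, role=label)
        rows.append(
            {
                "role": label.value,
                "sequence": seq_name,
                "slot": slot,
                "electrode": electrode,
                "band_lo": band[0],
                "band_hi": band[1],
                "t_start": interval[0],
                "t_end": interval[1],
                "value_db": erd.value,
                "n_bins": erd.n_bins,
            }
        )
    return pd.DataFrame(rows)
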