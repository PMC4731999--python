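"""Phase-locking value (PLV) analysis in the mu band.

Instantaneous phases come from the analytic signal (Hilbert transform) of
mu-band (8-13 Hz) filtered data; the single-trial PLV over a time interval is
the modulus of the temporal mean unit phasor of the phase difference,

    PLV = | < exp(j * (phi_x(t) - phi_y(t))) > |,

which is 0 for unrelated phases and 1 for perfect locking.  Trial-averaged
PLVs are computed per electrode pair (C3-FCz for the right hand, Cz-FCz for
the right foot, C4-FCz for the left hand) and per sub-movement slot, and
pooled into initial vs non-initial groups for the sequence-position contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .paradigm import (
    ConditionTiming,
    Limb,
    initiality_groups,
    limb_channel,
    slot_window,
)
from .preprocessing import EpochArray, bandpass

__all__ = [
    "MU_BAND",
    "PhaseSeries",
    "PLVResult",
    "instantaneous_phase",
    "plv_trial",
    "mean_plv",
    "initiality_contrast",
    "plv_pair",
]

MU_BAND = (8.0, 13.0)


def plv_pair(limb: Limb) -> tuple[str, str]:
    """Electrode pair used for one limb: its central electrode with FCz."""
    return (limb_channel(limb), "FCz")


@dataclass
class PhaseSeries:
    """Instantaneous phase of one channel, wrapped to (-pi, pi]."""

    phase: np.ndarray
    fs: float
    t0: float = 0.0
    channel: str | None = None

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.phase)) / self.fs


@dataclass
class PLVResult:
    pair: tuple[str, str]
    limb: Limb | None
    group: str | None  # "initial" / "noninitial" / None
    per_trial: np.ndarray
    mean: float


def instantaneous_phase(
    sig: np.ndarray, fs: float, t0: float = 0.0, channel: str | None = None
) -> PhaseSeries:
    """Analytic-signal phase of a band-limited signal.

    The Hilbert transform is taken on a reflection-padded extent and trimmed,
    guarding the ends against the transform's circularity.  Callers are
    expected to band-pass the signal first (the mu band here).
    """
    sig = np.asarray(sig, dtype=float)
    if sig.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if not np.any(sig):
        raise ValueError("phase of an all-zero signal is undefined")
    npad = min(len(sig) - 1, int(fs))
    padded = np.concatenate([sig[npad:0:-1], sig, sig[-2 : -npad - 2 : -1]])
    phase = np.angle(hilbert(padded))[npad : npad + len(sig)]
    return PhaseSeries(phase, fs, t0, channel)


def plv_trial(
    phase_x: PhaseSeries, phase_y: PhaseSeries, interval: tuple[float, float]
) -> float:
    """Single-trial PLV over the half-open interval [start, end) seconds."""
    if len(phase_x.phase) != len(phase_y.phase) or phase_x.fs != phase_y.fs:
        raise ValueError("phase series must share length and sampling rate")
    t = phase_x.times()
    mask = (t >= interval[0] - 1e-12) & (t < interval[1] - 1e-12)
    if not mask.any():
        raise ValueError(f"interval {interval} outside the phase series")
    dphi = phase_x.phase[mask] - phase_y.phase[mask]
    return float(np.abs(np.exp(1j * dphi).mean()))


def _phase_block(epochs: EpochArray, channel: str, band) -> np.ndarray:
    """Per-trial analytic phases of one channel (trials x samples)."""
    filt = bandpass(epochs, *band)
    x = filt.data[:, filt.channel_index(channel), :]
    npad = min(x.shape[1] - 1, int(epochs.fs))
    padded = np.concatenate(
        [x[:, npad:0:-1], x, x[:, -2 : -npad - 2 : -1]], axis=1
    )
    return np.angle(hilbert(padded, axis=-1))[:, npad : npad + x.shape[1]]


def mean_plv(
    epochs: EpochArray,
    pair: tuple[str, str],
    task: str,
    slot: int,
    band: tuple[float, float] = MU_BAND,
    timing: ConditionTiming | None = None,
) -> PLVResult:
    """Trial-averaged PLV of one electrode pair over one sub-movement slot.

    The whole epoch is filtered and Hilbert-transformed, then sliced to the
    slot window, so slot-edge transients do not bias the phase estimates.
    """
    timing = timing or epochs.timing
    if timing is None:
        raise ValueError("mean_plv needs condition timing (epochs.timing unset)")
    sub = epochs.task(task)
    interval = slot_window(timing, slot)
    t = sub.times
    mask = (t >= interval[0] - 1e-12) & (t < interval[1] - 1e-12)
    px = _phase_block(sub, pair[0], band)
    py = _phase_block(sub, pair[1], band)
    dphi = px[:, mask] - py[:, mask]
    per_trial = np.abs(np.exp(1j * dphi).mean(axis=1))
    return PLVResult(tuple(pair), None, None, per_trial, float(per_trial.mean()))


def initiality_contrast(
    epochs: EpochArray,
    limb: Limb,
    timing: ConditionTiming | None = None,
    band: tuple[float, float] = MU_BAND,
) -> tuple[PLVResult, PLVResult]:
    """Pooled per-trial PLVs of one limb's initial vs non-initial slots.

    Uses the limb's designated pair and concatenates per-trial PLVs across
    the limb's (sequence, slot) cells within each group, e.g. the right hand
    pools 2 initial cells (RRR/RLR slot 1) against 4 non-initial cells.
    """
    if not isinstance(limb, Limb):
        raise ValueError(f"invalid limb {limb!r}")
    timing = timing or epochs.timing
    pair = plv_pair(limb)
    initial, noninitial = initiality_groups(limb)
    results = []
    for group_name, cells in (("initial", initial), ("noninitial", noninitial)):
        pools = [
            mean_plv(epochs, pair, seq.name, slot, band, timing).per_trial
            for seq, slot in cells
        ]
        pooled = np.concatenate(pools)
        results.append(
            PLVResult(pair, limb, group_name, pooled, float(pooled.mean()))
        )
    return tuple(results)
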