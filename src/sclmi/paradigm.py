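"""Task paradigm for sequential compound limb motor imagery (SCL-MI).

Four drum-paced imagery sequences of three sub-movements each are used:
``RRR`` (right hand three times), ``RLR``, ``LFL`` and ``FRL``, where R/L/F
denote right hand, left hand and right foot.  Two pacing conditions exist:
condition 1 uses 1-s sub-movement slots inside an 8-s trial, condition 2 uses
2-s slots inside a 12-s trial.  Everything downstream (epoching, ERSP/ERD
quantification, PLV grouping) is expressed relative to imagery onset, i.e. the
moment the visual cue disappears.

This module is pure bookkeeping: sequence definitions, slot timing, the
sub-movement "role" taxonomy used by the prior-limb ERD analysis, and the
initial / non-initial grouping used by the phase-locking analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Limb",
    "SequenceClass",
    "SEQUENCES",
    "SEQUENCE_NAMES",
    "ConditionTiming",
    "condition_timing",
    "RoleLabel",
    "SubMovementRole",
    "role_of",
    "slot_window",
    "initiality_groups",
    "limb_channel",
    "TrialSchedule",
    "make_schedule",
]


class Limb(enum.Enum):
    """A limb taking part in a sequence."""

    RIGHT_HAND = "right_hand"
    LEFT_HAND = "left_hand"
    RIGHT_FOOT = "right_foot"


#: Contralateral (or midline, for the foot) sensorimotor electrode of each limb.
_LIMB_CHANNEL = {
    Limb.RIGHT_HAND: "C3",
    Limb.LEFT_HAND: "C4",
    Limb.RIGHT_FOOT: "Cz",
}


def limb_channel(limb: Limb) -> str:
    """Return the central electrode overlying the limb's representation area."""
    return _LIMB_CHANNEL[limb]


@dataclass(frozen=True)
class SequenceClass:
    """One imagery sequence: a name and an ordered triple of limbs."""

    name: str
    slots: tuple[Limb, Limb, Limb]

    def limb(self, slot: int) -> Limb:
        """Limb of slot 1, 2 or 3."""
        if slot not in (1, 2, 3):
            raise ValueError(f"slot must be 1, 2 or 3, got {slot}")
        return self.slots[slot - 1]


_R, _L, _F = Limb.RIGHT_HAND, Limb.LEFT_HAND, Limb.RIGHT_FOOT

SEQUENCES: dict[str, SequenceClass] = {
    "RRR": SequenceClass("RRR", (_R, _R, _R)),
    "RLR": SequenceClass("RLR", (_R, _L, _R)),
    "LFL": SequenceClass("LFL", (_L, _F, _L)),
    "FRL": SequenceClass("FRL", (_F, _R, _L)),
}

SEQUENCE_NAMES: tuple[str, ...] = tuple(SEQUENCES)


@dataclass(frozen=True)
class ConditionTiming:
    """Trial timing of one pacing condition, in seconds.

    ``imagery_onset_s`` is the cue offset measured from trial start; all
    analysis windows are expressed relative to that instant (time 0).
    """

    condition: int
    trial_length_s: float
    imagery_onset_s: float
    imagery_length_s: float
    slot_length_s: float
    baseline_length_s: float
    epoch_window_s: tuple[float, float]

    def __post_init__(self) -> None:
        if abs(self.imagery_length_s - 3 * self.slot_length_s) > 1e-9:
            raise ValueError("imagery length must equal three slot lengths")
        lo, hi = self.epoch_window_s
        if lo > -self.baseline_length_s or hi < self.imagery_length_s:
            raise ValueError("epoch window must span baseline and imagery")


_CONDITIONS = {
    1: ConditionTiming(1, 8.0, 3.0, 3.0, 1.0, 3.0, (-3.0, 5.0)),
    2: ConditionTiming(2, 12.0, 4.0, 6.0, 2.0, 4.0, (-4.0, 8.0)),
}


def condition_timing(condition: int) -> ConditionTiming:
    """Timing of pacing condition 1 (1-s slots) or 2 (2-s slots)."""
    try:
        return _CONDITIONS[condition]
    except KeyError:
        raise ValueError(
            f"condition must be 1 or 2, got {condition!r}"
        ) from None


def slot_window(timing: ConditionTiming, slot: int) -> tuple[float, float]:
    """Half-open time window ``[start, end)`` of a sub-movement slot.

    Times are relative to imagery onset, so slot 1 of either condition starts
    at 0.  Half-open intervals keep the three slots a tiling of the imagery
    period without double-counting boundary samples.
    """
    if slot not in (1, 2, 3):
        raise ValueError(f"slot must be 1, 2 or 3, got {slot}")
    L = timing.slot_length_s
    return ((slot - 1) * L, slot * L)


class RoleLabel(enum.Enum):
    """Sub-movement role in the prior-limb ERD analysis.

    ``RH_PH_k`` / ``RH_PF_k`` mean "right-hand imagery with prior hand / prior
    foot imagery" (and analogously ``LH_*`` for the left hand); roman numerals
    distinguish the distinct occurrences.  Only slots 2 and 3 carry roles; the
    first slot of a sequence has no prior sub-movement and foot slots are not
    analysed, both map to ``NONE``.
    """

    RH_PH_I = "RH_PH_I"
    RH_PH_II = "RH_PH_II"
    RH_PH_III = "RH_PH_III"
    RH_PF_I = "RH_PF_I"
    LH_PH_I = "LH_PH_I"
    LH_PH_II = "LH_PH_II"
    LH_PF_I = "LH_PF_I"
    NONE = "NONE"


@dataclass(frozen=True)
class SubMovementRole:
    label: RoleLabel
    electrode: str | None  # C3 for right-hand roles, C4 for left-hand roles


# Roman numerals are assigned in order of first occurrence scanning the
# sequences RRR, RLR, LFL, FRL with slot 2 before slot 3.
_ROLE_TABLE: dict[tuple[str, int], RoleLabel] = {
    ("RRR", 2): RoleLabel.RH_PH_I,
    ("RRR", 3): RoleLabel.RH_PH_II,
    ("RLR", 2): RoleLabel.LH_PH_I,
    ("RLR", 3): RoleLabel.RH_PH_III,
    ("LFL", 2): RoleLabel.NONE,  # foot slot: no role
    ("LFL", 3): RoleLabel.LH_PF_I,
    ("FRL", 2): RoleLabel.RH_PF_I,
    ("FRL", 3): RoleLabel.LH_PH_II,
}


def role_of(seq: SequenceClass | str, slot: int) -> SubMovementRole:
    """Role of slot 2 or 3 of a sequence in the prior-limb ERD analysis."""
    name = seq if isinstance(seq, str) else seq.name
    if name not in SEQUENCES:
        raise ValueError(f"unknown sequence {name!r}")
    if slot not in (2, 3):
        raise ValueError(f"roles attach only to slots 2 and 3, got slot {slot}")
    label = _ROLE_TABLE[(name, slot)]
    if label is RoleLabel.NONE:
        return SubMovementRole(label, None)
    electrode = "C3" if label.value.startswith("RH") else "C4"
    return SubMovementRole(label, electrode)


#: All non-NONE roles with their (sequence, slot) cell, in scan order.
ROLE_CELLS: tuple[tuple[RoleLabel, str, int], ...] = tuple(
    (label, name, slot)
    for (name, slot), label in _ROLE_TABLE.items()
    if label is not RoleLabel.NONE
)


def initiality_groups(
    limb: Limb,
) -> tuple[list[tuple[SequenceClass, int]], list[tuple[SequenceClass, int]]]:
    """Initial vs non-initial (sequence, slot) cells of one limb.

    The phase-locking analysis contrasts the first sub-movement of each
    sequence ("initial") against the second and third ("non-initial"),
    separately per limb.  E.g. the right hand occurs initially in RRR and RLR
    and non-initially in RRR (slots 2, 3), RLR (slot 3) and FRL (slot 2).
    """
    if not isinstance(limb, Limb):
        raise ValueError(f"invalid limb {limb!r}")
    initial: list[tuple[SequenceClass, int]] = []
    noninitial: list[tuple[SequenceClass, int]] = []
    for seq in SEQUENCES.values():
        for slot in (1, 2, 3):
            if seq.limb(slot) is limb:
                (initial if slot == 1 else noninitial).append((seq, slot))
    return initial, noninitial


@dataclass
class TrialSchedule:
    """Per-trial class labels and absolute trial-start times of one run.

    ``entries`` holds ``(trial_index, SequenceClass, trial_onset_s)`` with
    onsets spaced by ``timing.trial_length_s``; the imagery onset of a trial is
    ``trial_onset_s + timing.imagery_onset_s``.
    """

    entries: list[tuple[int, SequenceClass, float]]
    timing: ConditionTiming
    n_per_class: int

    def __post_init__(self) -> None:
        onsets = [t for _, _, t in self.entries]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [seq.name for _, seq, _ in self.entries]

    @property
    def duration_s(self) -> float:
        return len(self.entries) * self.timing.trial_length_s

    def imagery_onsets(self) -> np.ndarray:
        """Absolute imagery-onset times (s) of all trials."""
        return np.array(
            [t + self.timing.imagery_onset_s for _, _, t in self.entries]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": [i for i, _, _ in self.entries],
                "class": self.labels,
                "onset_s": [t for _, _, t in self.entries],
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path, condition: int) -> "TrialSchedule":
        frame = pd.read_csv(path)
        timing = condition_timing(condition)
        entries = [
            (int(r.trial_index), SEQUENCES[r["class"]], float(r.onset_s))
            for _, r in frame.iterrows()
        ]
        n_per_class = len(entries) // len(SEQUENCES)
        return cls(entries, timing, n_per_class)


def make_schedule(condition: int, n_per_class: int, seed: int) -> TrialSchedule:
    """Balanced pseudo-random trial schedule for one condition.

    Produces ``4 * n_per_class`` back-to-back trials whose class order is a
    seeded permutation, mimicking the randomized presentation of the paradigm.
    """
    timing = condition_timing(condition)
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.array(SEQUENCE_NAMES), n_per_class)
    labels = labels[rng.permutation(labels.size)]
    entries = [
        (i, SEQUENCES[name], i * timing.trial_length_s)
        for i, name in enumerate(labels)
    ]
    return TrialSchedule(entries, timing, int(n_per_class))
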