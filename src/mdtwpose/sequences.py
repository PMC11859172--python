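"""Domain containers for lower-limb joint-angle trials.

A trial is a matrix of sagittal-plane flexion-extension angles (degrees)
for six joints -- both knees, ankles and hips -- sampled nominally at
60 Hz. The fixed channel ordering mirrors the row layout used throughout
the pipeline and every serialization, so that left/right channels can
never be silently swapped.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Fixed channel order for the rows of every angle matrix.
CHANNELS: tuple[str, ...] = ("r_knee", "l_knee", "r_ankle", "l_ankle", "r_hip", "l_hip")
N_CHANNELS = len(CHANNELS)

#: Number of samples after time normalization.
TEMPLATE_LENGTH = 101

#: Canonical 12-class vocabulary, in the order used by every report.
CLASS_ORDER: tuple[str, ...] = (
    "DK",   # dorsiflexed kneeling
    "PK",   # plantarflexed kneeling
    "FS",   # flatfoot squatting
    "HS",   # heels-up squatting
    "CCS",  # sitting on a child-sized chair
    "ACS",  # sitting on an adult-sized chair
    "SK",   # supported kneeling (single- or double-arm)
    "STP",  # stooping
    "STD",  # standing
    "CLS",  # crossed leg sitting
    "SS",   # side sitting (incl. side leaning)
    "WLK",  # walking (single gait cycle)
)

#: Raw recording codes: the canonical twelve plus the three that are merged.
RAW_CLASS_CODES: tuple[str, ...] = CLASS_ORDER + ("SAK", "DAK", "SL")

#: Default grouping of kinematically similar classes for grouped reports.
DEFAULT_GROUPING: dict[str, str] = {
    "DK": "Kneeling", "PK": "Kneeling", "SK": "Kneeling",
    "FS": "Squatting", "HS": "Squatting",
    "ACS": "Chair Sitting", "CCS": "Chair Sitting",
    "CLS": "Floor Sitting", "SS": "Floor Sitting",
    "STP": "Stooping", "STD": "Standing", "WLK": "WLK",
}

NORMALIZATION_TOL = 1e-9


class SequenceError(ValueError):
    """Raised when a trial violates a structural invariant."""


@dataclass
class MovementSequence:
    """One six-channel joint-angle trial.

    Parameters
    ----------
    angles:
        ``(6, N)`` array of flexion-extension angles in degrees, rows
        ordered as :data:`CHANNELS` (flexion positive).
    label:
        Motion-class code, or ``None`` for an unlabelled trial.
    subject_id:
        Opaque subject identifier.
    sample_rate:
        Sampling rate in Hz before time normalization (nominal 60).
    time_normalized / scale_normalized:
        Normalization flags; a time-normalized trial has exactly
        :data:`TEMPLATE_LENGTH` samples, a scale-normalized trial has every
        non-constant channel spanning exactly [-1, 1].
    """

    angles: np.ndarray
    label: Optional[str] = None
    subject_id: str = ""
    sample_rate: float = 60.0
    time_normalized: bool = False
    scale_normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        a = self.angles
        if a.ndim != 2 or a.shape[0] != N_CHANNELS:
            raise SequenceError(
                f"angles must be ({N_CHANNELS}, N); got shape {a.shape}"
            )
        if a.shape[1] < 2:
            raise SequenceError(f"need at least 2 samples, got {a.shape[1]}")
        if not np.all(np.isfinite(a)):
            raise SequenceError("angle values must all be finite")
        if self.time_normalized and a.shape[1] != TEMPLATE_LENGTH:
            raise SequenceError(
                f"time-normalized trial must have {TEMPLATE_LENGTH} samples, "
                f"got {a.shape[1]}"
            )
        # span checks apply to sequences produced by scale_normalize (which
        # records its scope); directly constructed sequences assert their
        # own flags, e.g. synthetic fixtures probing scaling properties
        if self.scale_normalized and "scale_scope" in self.meta:
            if self.meta["scale_scope"] == "per_trial":
                lo, hi = a.min(), a.max()
                if hi - lo > NORMALIZATION_TOL and (
                    abs(lo + 1.0) > NORMALIZATION_TOL or abs(hi - 1.0) > NORMALIZATION_TOL
                ):
                    raise SequenceError(
                        f"trial-scaled angles span [{lo:.6g}, {hi:.6g}], expected [-1, 1]"
                    )
            else:
                for name, row in zip(CHANNELS, a):
                    lo, hi = row.min(), row.max()
                    if hi - lo > NORMALIZATION_TOL:  # non-constant channel
                        if abs(lo + 1.0) > NORMALIZATION_TOL or abs(hi - 1.0) > NORMALIZATION_TOL:
                            raise SequenceError(
                                f"scale-normalized channel {name} spans "
                                f"[{lo:.6g}, {hi:.6g}], expected [-1, 1]"
                            )

    # -- conveniences -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.angles.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.angles[CHANNELS.index(name)]
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; channels are {CHANNELS}") from None

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.sample_rate

    def copy(self, **changes) -> "MovementSequence":
        base = dataclasses.replace(self, **changes)
        base.angles = np.array(base.angles, copy=True)
        return base


@dataclass
class Template(MovementSequence):
    """A segmented, fully normalized ``6 x 101`` labelled exemplar."""

    template_id: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not (self.time_normalized and self.scale_normalized):
            raise SequenceError("a template must be time- and scale-normalized")
        if self.label not in CLASS_ORDER:
            raise SequenceError(
                f"template label {self.label!r} is not one of the 12 canonical classes"
            )
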