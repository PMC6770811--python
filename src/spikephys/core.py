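"""Core data types for extracellular single-unit recordings.

A recording is a :class:`SpikeTrain` (sorted spike timestamps over a known
span) annotated with :class:`Epoch` windows (background, innocuous/noxious
stimulus, drug conditions).  All times are in seconds; epoch membership is
half-open ``[onset, onset + duration)`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "Epoch",
    "BurstCriteria",
    "NeuronRecord",
    "NeuronMetrics",
    "EPOCH_LABELS",
    "SURGERY_GROUPS",
    "VECTOR_GROUPS",
    "ValidationError",
]

EPOCH_LABELS = ("background", "innocuous", "noxious", "drug_window")
SURGERY_GROUPS = ("sham", "SNL")
VECTOR_GROUPS = ("control_shRNA", "5HT2CR_shRNA", "none")


class ValidationError(ValueError):
    """Raised when a spike train, epoch, or cohort file violates an invariant."""


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike timestamps (seconds) over the span ``[t_start, t_stop]``.

    Parameters
    ----------
    timestamps
        Strictly increasing spike times in seconds.
    t_start, t_stop
        Recording span.  All timestamps must lie inside ``[t_start, t_stop]``.
    unit_id
        Opaque unit label carried through to result tables.
    """

    timestamps: np.ndarray
    t_start: float
    t_stop: float
    unit_id: str = ""

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        if ts.ndim != 1:
            raise ValidationError("timestamps must be a 1-d sequence")
        if not self.t_stop > self.t_start:
            raise ValidationError(
                f"t_stop ({self.t_stop}) must exceed t_start ({self.t_start})"
            )
        if ts.size:
            d = np.diff(ts)
            if np.any(d <= 0):
                i = int(np.argmax(d <= 0))
                raise ValidationError(
                    "timestamps must be strictly increasing; "
                    f"violation between entries {i} and {i + 1} "
                    f"({ts[i]:.6f} -> {ts[i + 1]:.6f})"
                )
            if ts[0] < self.t_start or ts[-1] > self.t_stop:
                raise ValidationError(
                    f"timestamps [{ts[0]:.6f}, {ts[-1]:.6f}] fall outside "
                    f"the recording span [{self.t_start}, {self.t_stop}]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def shift(self, dt: float) -> "SpikeTrain":
        """Translate the whole recording by ``dt`` seconds."""
        return SpikeTrain(self.timestamps + dt, self.t_start + dt,
                          self.t_stop + dt, self.unit_id)

    def slice(self, t0: float, t1: float) -> "SpikeTrain":
        """Restrict to the half-open window ``[t0, t1)``.

        The sliced train's span becomes ``[t0, t1]`` so that the silence
        observed between the window start and the first spike is preserved
        (it matters for burst detection at epoch boundaries).
        """
        ts = self.timestamps
        sel = ts[(ts >= t0) & (ts < t1)]
        return SpikeTrain(sel, t0, t1, self.unit_id)


@dataclass(frozen=True)
class Epoch:
    """A labeled time window of a recording.

    ``intensity_g``/``area_mm2`` carry the mechanical-stimulus calibration
    (100 g/6 mm^2 innocuous, 500 g/6 mm^2 noxious in the standard protocol);
    ``condition_tag`` distinguishes predrug/drug segments of one recording.
    """

    label: str
    onset: float
    duration: float
    intensity_g: Optional[float] = None
    area_mm2: Optional[float] = None
    condition_tag: str = ""

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise ValidationError(
                f"unknown epoch label {self.label!r}; allowed: {EPOCH_LABELS}"
            )
        if not self.duration > 0:
            raise ValidationError(f"epoch duration must be > 0, got {self.duration}")

    @property
    def t_stop(self) -> float:
        return self.onset + self.duration

    @property
    def is_stimulus(self) -> bool:
        return self.label in ("innocuous", "noxious")

    def overlaps(self, other: "Epoch") -> bool:
        return self.onset < other.t_stop and other.onset < self.t_stop


@dataclass(frozen=True)
class BurstCriteria:
    """Joint-ISI burst criterion: a burst begins at a spike preceded by at
    least ``min_silent_s`` of silence and followed by a spike within
    ``max_intra_isi_s``."""

    min_silent_s: float = 0.100
    max_intra_isi_s: float = 0.010

    def __post_init__(self) -> None:
        if not (self.min_silent_s > self.max_intra_isi_s > 0):
            raise ValidationError(
                "burst criteria require min_silent_s > max_intra_isi_s > 0, "
                f"got {self.min_silent_s} / {self.max_intra_isi_s}"
            )


@dataclass(frozen=True)
class NeuronRecord:
    """One recorded unit: spike train, epoch annotations, and group labels."""

    train: SpikeTrain
    epochs: tuple
    surgery: str = "sham"
    vector: str = "none"
    drug_protocol: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(self.epochs))
        if self.surgery not in SURGERY_GROUPS:
            raise ValidationError(
                f"unknown surgery group {self.surgery!r}; allowed: {SURGERY_GROUPS}"
            )
        if self.vector not in VECTOR_GROUPS:
            raise ValidationError(
                f"unknown vector group {self.vector!r}; allowed: {VECTOR_GROUPS}"
            )
        stims = [e for e in self.epochs if e.is_stimulus]
        for a, b in zip(stims, stims[1:]):
            if a.overlaps(b):
                raise ValidationError(
                    f"stimulus epochs overlap: {a.label}@{a.onset} / {b.label}@{b.onset}"
                )

    @property
    def group(self) -> str:
        """Composite analysis-group label, e.g. ``sham/control_shRNA``."""
        return f"{self.surgery}/{self.vector}"

    @property
    def condition_tags(self) -> tuple:
        seen: list = []
        for e in self.epochs:
            if e.condition_tag not in seen:
                seen.append(e.condition_tag)
        return tuple(seen)

    def epochs_for(self, condition_tag: str, label: Optional[str] = None) -> list:
        out = [e for e in self.epochs if e.condition_tag == condition_tag]
        if label is not None:
            out = [e for e in out if e.label == label]
        return out


@dataclass(frozen=True)
class NeuronMetrics:
    """Per-neuron, per-condition summary used for group statistics.

    ``mean_cv2`` is ``None`` when the scoring epoch contains fewer than two
    ISI pairs; such neurons are excluded listwise from CV2 group tests.
    """

    unit_id: str
    condition_tag: str
    background_hz: float
    net_innocuous_hz: float
    net_noxious_hz: float
    burst_rate_per_min: float
    mean_cv2: Optional[float]
    n_isi_pairs: int

    def __post_init__(self) -> None:
        if self.mean_cv2 is not None and not (0.0 <= self.mean_cv2 <= 2.0):
            raise ValidationError(
                f"mean CV2 must lie in [0, 2], got {self.mean_cv2}"
            )
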