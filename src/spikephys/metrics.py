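"""Per-neuron spike-train statistics.

Implements the standard single-unit battery for epoch-annotated recordings:

* firing rate per epoch (spikes/s) and peristimulus time histograms;
* net evoked activity — stimulus-epoch rate minus the mean background rate
  in a 1–3 min window immediately preceding the stimulus;
* joint-ISI burst detection — a burst begins at a spike preceded by at least
  100 ms of silence and followed by a second spike within 10 ms (defaults of
  :class:`~spikephys.core.BurstCriteria`), and extends while subsequent ISIs
  stay within the intra-burst limit;
* CV2 local irregularity, ``CV2 = 2·|ISI2 − ISI1| / (ISI2 + ISI1)`` for each
  adjacent ISI pair: ~0 for clock-like firing, ~1 for Poisson-like firing,
  bounded by 2.

Rates use half-open epoch membership ``[onset, onset + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .core import (BurstCriteria, Epoch, NeuronMetrics, NeuronRecord,
                   SpikeTrain, ValidationError)

__all__ = [
    "AnalysisConfig",
    "BurstEvent",
    "Cv2Series",
    "Psth",
    "compute_isis",
    "firing_rate",
    "net_evoked_rate",
    "psth",
    "joint_isi_map",
    "detect_bursts",
    "burst_rate",
    "cv2_series",
    "summarize_neuron",
]

METRIC_COLUMNS = ["background_hz", "net_innocuous_hz", "net_noxious_hz",
                  "burst_rate_per_min", "mean_cv2"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis settings.

    ``background_window_s`` is the pre-stimulus window used for net evoked
    activity; 120 s by default, admissible range 60–180 s (the "mean value
    of 1–3 min" convention).
    """

    burst_criteria: BurstCriteria = field(default_factory=BurstCriteria)
    background_window_s: float = 120.0
    psth_bin_s: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 60.0 <= self.background_window_s <= 180.0:
            raise ValidationError(
                "background_window_s must lie in [60, 180] s, got "
                f"{self.background_window_s}"
            )


@dataclass(frozen=True)
class BurstEvent:
    """A detected burst: onset spike time, spike count, the silent period
    preceding the onset, and the intra-burst ISIs."""

    onset_s: float
    n_spikes: int
    silent_period_s: float
    intra_isis_s: tuple


@dataclass(frozen=True)
class Cv2Series:
    """CV2 per adjacent ISI pair plus the per-pair mean ISI (the x-axis of
    the conventional CV2-vs-mean-ISI scatter)."""

    isi1: np.ndarray
    isi2: np.ndarray
    values: np.ndarray
    mean_isi: np.ndarray

    @property
    def mean_cv2(self) -> float:
        return float(np.mean(self.values))

    @property
    def n_pairs(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class Psth:
    """Peristimulus time histogram: counts and rates per half-open bin."""

    bin_edges_s: np.ndarray
    counts_per_bin: np.ndarray
    rate_per_bin: np.ndarray
    partial_bin_dropped: bool = False


def compute_isis(train: SpikeTrain) -> np.ndarray:
    """Interspike intervals in seconds; empty array for < 2 spikes."""
    if train.n_spikes < 2:
        return np.empty(0)
    return np.diff(train.timestamps)


def firing_rate(train: SpikeTrain, epoch: Epoch) -> float:
    """Mean firing rate (spikes/s) over ``[onset, onset + duration)``."""
    ts = train.timestamps
    n = int(np.count_nonzero((ts >= epoch.onset) & (ts < epoch.t_stop)))
    return n / epoch.duration


def net_evoked_rate(train: SpikeTrain, stim: Epoch,
                    background_window_s: float = 120.0) -> float:
    """Stimulus-epoch rate minus the immediately preceding background rate.

    The background window is ``[onset - background_window_s, onset)``; it
    must fit inside the recording span.  The result may be negative (net
    inhibition).
    """
    if not 0 < background_window_s:
        raise ValidationError("background window must be positive")
    bg_onset = stim.onset - background_window_s
    if bg_onset < train.t_start:
        raise ValidationError(
            f"stimulus {stim.label!r} at {stim.onset:g}s: insufficient "
            f"pre-stimulus time for a {background_window_s:g}s background window"
        )
    bg = Epoch("background", bg_onset, background_window_s,
               condition_tag=stim.condition_tag)
    return firing_rate(train, stim) - firing_rate(train, bg)


def psth(train: SpikeTrain, window: Epoch, bin_width_s: float = 1.0) -> Psth:
    """Binned spike counts and rates over the window, half-open bins.

    A trailing partial bin (when the bin width does not divide the window)
    is dropped and flagged.
    """
    if bin_width_s <= 0:
        raise ValidationError(f"bin width must be > 0, got {bin_width_s}")
    n_bins = int(np.floor(window.duration / bin_width_s + 1e-9))
    if n_bins < 1:
        raise ValidationError("window shorter than one bin")
    dropped = (window.duration - n_bins * bin_width_s) > 1e-9
    edges = window.onset + bin_width_s * np.arange(n_bins + 1)
    ts = train.timestamps
    sel = ts[(ts >= edges[0]) & (ts < edges[-1])]
    counts, _ = np.histogram(sel, bins=edges)
    return Psth(edges, counts, counts / bin_width_s, dropped)


def _preceding_gaps(train: SpikeTrain) -> np.ndarray:
    """Gap before each spike: ISIs, plus the observed pre-first-spike silence."""
    ts = train.timestamps
    return np.diff(ts, prepend=train.t_start)


def joint_isi_map(train: SpikeTrain, criteria: BurstCriteria = BurstCriteria(),
                  include_initial_gap: bool = True) -> pd.DataFrame:
    """Joint-ISI return map: previous interval vs subsequent ISI per spike.

    Returns a DataFrame with columns ``isi1`` (previous interval), ``isi2``
    (subsequent ISI) and ``is_burst_start`` (True iff ``isi1 >=
    min_silent_s`` and ``isi2 <= max_intra_isi_s`` — the dashed burst
    rectangle of a joint-ISI plot).

    With ``include_initial_gap`` the first entry uses the observed silence
    between ``t_start`` and the first spike as ``isi1``, so flagged rows
    correspond one-to-one with bursts from :func:`detect_bursts`.  Fewer
    than 3 spikes (no true ISI pair) yields an empty map.
    """
    if train.n_spikes < 3:
        return pd.DataFrame(columns=["isi1", "isi2", "is_burst_start"])
    isis = compute_isis(train)
    if include_initial_gap:
        isi1 = np.concatenate(([train.timestamps[0] - train.t_start], isis[:-1]))
        isi2 = isis
    else:
        isi1, isi2 = isis[:-1], isis[1:]
    flag = (isi1 >= criteria.min_silent_s) & (isi2 <= criteria.max_intra_isi_s)
    return pd.DataFrame({"isi1": isi1, "isi2": isi2, "is_burst_start": flag})


def detect_bursts(train: SpikeTrain,
                  criteria: BurstCriteria = BurstCriteria()) -> List[BurstEvent]:
    """Scan the train for bursts.

    A spike starts a burst iff its preceding gap (from the previous spike,
    or from ``t_start`` for the first spike: observed silence counts) is at
    least ``min_silent_s`` and the next ISI is at most ``max_intra_isi_s``.
    The burst then extends over every subsequent spike while ISIs stay
    within ``max_intra_isi_s``; bursts never overlap.
    """
    ts = train.timestamps
    n = ts.size
    if n < 2:
        return []
    gaps = _preceding_gaps(train)
    isis = np.diff(ts)
    bursts: List[BurstEvent] = []
    i = 0
    while i < n - 1:
        if gaps[i] >= criteria.min_silent_s and isis[i] <= criteria.max_intra_isi_s:
            j = i + 1
            while j < n - 1 and isis[j] <= criteria.max_intra_isi_s:
                j += 1
            bursts.append(BurstEvent(
                onset_s=float(ts[i]),
                n_spikes=j - i + 1,
                silent_period_s=float(gaps[i]),
                intra_isis_s=tuple(isis[i:j]),
            ))
            i = j + 1
        else:
            i += 1
    return bursts


def burst_rate(bursts: List[BurstEvent], epoch: Epoch) -> float:
    """Bursts whose onset falls in the epoch, per minute."""
    if epoch.duration <= 0:
        raise ValidationError("epoch duration must be positive")
    n = sum(1 for b in bursts if epoch.onset <= b.onset_s < epoch.t_stop)
    return 60.0 * n / epoch.duration


def cv2_series(train: SpikeTrain) -> Optional[Cv2Series]:
    """CV2 for each adjacent ISI pair; ``None`` when fewer than 3 spikes.

    CV2 = 2·|ISI2 − ISI1| / (ISI2 + ISI1); values lie in [0, 2], are
    symmetric in the two intervals, and invariant to rescaling time.
    """
    isis = compute_isis(train)
    if isis.size < 2:
        return None
    a, b = isis[:-1], isis[1:]
    return Cv2Series(isi1=a, isi2=b,
                     values=2.0 * np.abs(b - a) / (b + a),
                     mean_isi=(a + b) / 2.0)


def summarize_neuron(rec: NeuronRecord,
                     config: AnalysisConfig = AnalysisConfig()
                     ) -> Dict[str, NeuronMetrics]:
    """Full per-neuron summary, one :class:`NeuronMetrics` per condition.

    Background rate, burst rate and mean CV2 come from the condition's
    background epoch; net evoked rates from each stimulus epoch minus its
    preceding background window.  Missing required epochs raise an error
    naming the neuron and condition.
    """
    out: Dict[str, NeuronMetrics] = {}
    for tag in rec.condition_tags:
        bg = rec.epochs_for(tag, "background")
        if not bg:
            raise ValidationError(
                f"neuron {rec.train.unit_id!r}, condition {tag!r}: "
                "no background epoch")
        bg_epoch = bg[0]
        nets = {}
        for label in ("innocuous", "noxious"):
            stims = rec.epochs_for(tag, label)
            if not stims:
                raise ValidationError(
                    f"neuron {rec.train.unit_id!r}, condition {tag!r}: "
                    f"no {label} epoch")
            nets[label] = net_evoked_rate(rec.train, stims[0],
                                          config.background_window_s)
        bg_train = rec.train.slice(bg_epoch.onset, bg_epoch.t_stop)
        bursts = detect_bursts(bg_train, config.burst_criteria)
        cv2 = cv2_series(bg_train)
        out[tag] = NeuronMetrics(
            unit_id=rec.train.unit_id,
            condition_tag=tag,
            background_hz=firing_rate(rec.train, bg_epoch),
            net_innocuous_hz=nets["innocuous"],
            net_noxious_hz=nets["noxious"],
            burst_rate_per_min=burst_rate(bursts, bg_epoch),
            mean_cv2=None if cv2 is None else cv2.mean_cv2,
            n_isi_pairs=0 if cv2 is None else cv2.n_pairs,
        )
    return out
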