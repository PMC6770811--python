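"""Plain-text interchange formats.

Three small CSV formats carry a cohort:

* spike timestamp file — one column, header ``time_s``, one spike time
  (seconds, 6-decimal canonical output) per line;
* epoch file — ``label,onset,duration,intensity_g,area_mm2,condition_tag``;
* cohort manifest — ``unit_id,spike_file,epoch_file,surgery,vector,drug_protocol``
  (paths relative to the manifest).

An optional JSON sidecar ``<spike_file>.meta.json`` with ``t_start``/``t_stop``
pins the recording span; without it the span defaults to the first/last spike,
which slightly inflates rate estimates on sparse trains (documented caveat).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Epoch, NeuronRecord, SpikeTrain, ValidationError

__all__ = [
    "read_spike_train",
    "write_spike_train",
    "read_epochs",
    "write_epochs",
    "read_manifest",
    "load_cohort",
]

SPIKE_HEADER = "time_s"
EPOCH_COLUMNS = ["label", "onset", "duration", "intensity_g", "area_mm2",
                 "condition_tag"]
MANIFEST_COLUMNS = ["unit_id", "spike_file", "epoch_file", "surgery", "vector",
                    "drug_protocol"]


def read_spike_train(path, unit_id: str = "",
                     t_start: Optional[float] = None,
                     t_stop: Optional[float] = None) -> SpikeTrain:
    """Read a one-column timestamp CSV into a validated :class:`SpikeTrain`.

    Accepts a bare list of decimal seconds or the same with a ``time_s``
    header.  Non-monotone or duplicate timestamps raise a
    :class:`ValidationError` naming the offending line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if lines and lines[0].strip() == SPIKE_HEADER:
        first_data_line = 2
        lines = lines[1:]
    else:
        first_data_line = 1
    values = []
    for i, line in enumerate(lines):
        s = line.strip()
        if not s:
            continue
        try:
            values.append(float(s))
        except ValueError:
            raise ValidationError(
                f"{path}: line {first_data_line + i}: not a timestamp: {s!r}"
            ) from None
    if not values:
        raise ValidationError(f"{path}: no spike timestamps found")
    ts = np.asarray(values)
    bad = np.nonzero(np.diff(ts) <= 0)[0]
    if bad.size:
        i = int(bad[0])
        raise ValidationError(
            f"{path}: line {first_data_line + i + 1}: timestamps must be "
            f"strictly increasing ({ts[i]:.6f} -> {ts[i + 1]:.6f})"
        )
    meta = _sidecar(path)
    if t_start is None:
        t_start = meta.get("t_start", float(ts[0]))
    if t_stop is None:
        t_stop = meta.get("t_stop", float(ts[-1]))
    if not unit_id:
        unit_id = meta.get("unit_id", path.stem)
    return SpikeTrain(ts, float(t_start), float(t_stop), unit_id)


def _sidecar(path: Path) -> dict:
    side = path.with_name(path.name + ".meta.json")
    if side.exists():
        return json.loads(side.read_text())
    return {}


def write_spike_train(train: SpikeTrain, path, sidecar: bool = True) -> None:
    """Write canonical 6-decimal timestamps plus a span sidecar."""
    path = Path(path)
    body = "\n".join(f"{t:.6f}" for t in train.timestamps)
    path.write_text(f"{SPIKE_HEADER}\n{body}\n")
    if sidecar:
        meta = {"t_start": train.t_start, "t_stop": train.t_stop,
                "unit_id": train.unit_id}
        path.with_name(path.name + ".meta.json").write_text(
            json.dumps(meta, sort_keys=True) + "\n")


def read_epochs(path) -> List[Epoch]:
    """Read and validate an epoch annotation CSV, sorted by onset.

    Overlapping stimulus epochs within one condition are rejected.
    """
    df = pd.read_csv(path, dtype={"label": str, "condition_tag": str})
    missing = [c for c in ("label", "onset", "duration") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: epoch file missing columns {missing}")
    epochs = []
    for row in df.itertuples(index=False):
        epochs.append(Epoch(
            label=row.label,
            onset=float(row.onset),
            duration=float(row.duration),
            intensity_g=_opt(getattr(row, "intensity_g", None)),
            area_mm2=_opt(getattr(row, "area_mm2", None)),
            condition_tag=_tag(getattr(row, "condition_tag", "")),
        ))
    epochs.sort(key=lambda e: e.onset)
    stims = [e for e in epochs if e.is_stimulus]
    for a, b in zip(stims, stims[1:]):
        if a.overlaps(b):
            raise ValidationError(
                f"{path}: overlapping stimulus epochs "
                f"{a.label}@{a.onset:g}s and {b.label}@{b.onset:g}s"
            )
    return epochs


def _opt(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def _tag(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return str(v)


def write_epochs(epochs: Sequence[Epoch], path) -> None:
    rows = [{
        "label": e.label, "onset": e.onset, "duration": e.duration,
        "intensity_g": e.intensity_g, "area_mm2": e.area_mm2,
        "condition_tag": e.condition_tag,
    } for e in epochs]
    pd.DataFrame(rows, columns=EPOCH_COLUMNS).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {missing}")
    return df


def load_cohort(manifest_path) -> List[NeuronRecord]:
    """Load every neuron listed in a cohort manifest.

    Extra manifest columns (e.g. per-metric inclusion masks ``include_*``)
    are preserved by the pipeline layer, which re-reads the manifest.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    records = []
    for row in df.itertuples(index=False):
        train = read_spike_train(base / row.spike_file, unit_id=str(row.unit_id))
        epochs = read_epochs(base / row.epoch_file)
        records.append(NeuronRecord(
            train=train, epochs=tuple(epochs), surgery=row.surgery,
            vector=row.vector, drug_protocol=str(row.drug_protocol)))
    return records
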