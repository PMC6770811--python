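"""Seeded generator of synthetic spike-train cohorts.

The generative model is a gamma-renewal tonic process (with an absolute
refractory period) superposed with a compound burst process:

* tonic spikes: ISIs are ``refractory_s + Gamma(shape, scale)``, with the
  scale calibrated so the *total* background rate (tonic + burst spikes,
  after silent-gap carving) equals ``bg_rate_hz``.  ``gamma_shape`` steers
  regularity: 1 is Poisson-like (CV2 near 1), large shapes are clock-like
  (CV2 near 0).  The 15 ms refractory period keeps tonic ISIs above the
  10 ms intra-burst criterion, so every detected burst is an injected one.
* bursts: events at Poisson rate ``burst_rate_per_min``, each carrying
  ``2 + Geometric`` spikes (mean ``burst_size``) with i.i.d. intra-burst
  ISIs below ``intra_burst_isi_s``; tonic spikes are carved out of a
  >=105 ms window before each burst onset (the enforced silent period) and
  a 20 ms guard after the last burst spike.

Stimulus epochs multiply all rates by an evoked gain for their 15 s span;
drug-condition segments multiply all rates by a per-condition factor.  It
is a statistical stand-in for amygdala single-unit phenotypes (neuropathic
hyperactivity, increased burstiness, irregular firing), not a biophysical
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Epoch, NeuronRecord, SpikeTrain, ValidationError
from .io import MANIFEST_COLUMNS, write_epochs, write_spike_train

__all__ = [
    "SimulationParams",
    "GroupSpec",
    "CohortDesign",
    "EpochLayout",
    "SHAM_PARAMS",
    "SNL_PARAMS",
    "PROTOCOL_CONDITIONS",
    "simulate_background",
    "simulate_neuron",
    "simulate_records",
    "simulate_cohort",
    "default_cohort_design",
    "design_from_dict",
]

# silent-gap carving margins around each injected burst (seconds)
_PRE_CLEAR = 0.105
_POST_CLEAR = 0.020
_BURST_SPACING = 0.050  # extra spacing beyond the cleared windows


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters for one neuron phenotype.

    ``bg_rate_hz`` is the target total background firing rate (spikes/s);
    ``evoked_gain_*`` multiply all rates during the 15 s stimulus;
    ``drug_effect`` is the default rate multiplier for drug conditions of
    the canonical protocols; ``gamma_shape`` sets ISI regularity (1 =
    Poisson-like).
    """

    bg_rate_hz: float = 2.0
    evoked_gain_innoc: float = 1.5
    evoked_gain_nox: float = 2.5
    burst_rate_per_min: float = 1.0
    burst_size: float = 3.0
    intra_burst_isi_s: float = 0.006
    gamma_shape: float = 3.0
    refractory_s: float = 0.015
    drug_effect: float = 1.0

    def __post_init__(self) -> None:
        if min(self.bg_rate_hz, self.evoked_gain_innoc, self.evoked_gain_nox,
               self.gamma_shape, self.drug_effect) <= 0:
            raise ValidationError("rates, gains and gamma_shape must be > 0")
        if self.burst_rate_per_min < 0:
            raise ValidationError("burst_rate_per_min must be >= 0")
        if not 0 < self.intra_burst_isi_s <= 0.010:
            raise ValidationError("intra_burst_isi_s must lie in (0, 0.010] s")
        if self.burst_rate_per_min > 0 and self.burst_size < 2:
            raise ValidationError("burst_size (mean spikes per burst) must be >= 2")
        if self.refractory_s < 0:
            raise ValidationError("refractory_s must be >= 0")


#: default phenotypes: sham controls vs neuropathic (SNL) hyperactivity —
#: SNL doubles background and burst rates, raises the evoked gains, and
#: drops the gamma shape to 1 (Poisson-like, CV2 near 1)
SHAM_PARAMS = SimulationParams(bg_rate_hz=2.0, burst_rate_per_min=2.0,
                               gamma_shape=3.0)
SNL_PARAMS = SimulationParams(bg_rate_hz=4.0, burst_rate_per_min=4.0,
                              evoked_gain_innoc=2.0, evoked_gain_nox=3.5,
                              gamma_shape=1.0)


def _mean_burst_spikes(params: SimulationParams) -> float:
    return max(params.burst_size, 2.0)


def _tonic_rate(params: SimulationParams, mult: float) -> float:
    """Tonic renewal rate such that the total rate equals bg_rate_hz * mult.

    Burst spikes add ``lam_b * burst_size`` Hz and the carved silent windows
    remove tonic spikes over a fraction ``lam_b * w`` of the time.
    """
    r = params.bg_rate_hz * mult
    lam_b = params.burst_rate_per_min * mult / 60.0
    m = _mean_burst_spikes(params)
    span = (m - 1.0) * 0.7 * params.intra_burst_isi_s
    w = _PRE_CLEAR + span + _POST_CLEAR
    if lam_b * w > 0.5:
        raise ValidationError(
            f"burst rate {params.burst_rate_per_min * mult:g}/min too high: "
            "enforced silent periods would cover most of the recording")
    tonic = (r - lam_b * m) / (1.0 - lam_b * w)
    if tonic <= 0:
        raise ValidationError(
            "burst spikes alone exceed the requested background rate; "
            "lower burst_rate_per_min or burst_size")
    if params.refractory_s > 0 and tonic >= 1.0 / params.refractory_s:
        raise ValidationError(
            f"tonic rate {tonic:g} Hz incompatible with refractory period "
            f"{params.refractory_s:g} s")
    return tonic


def _renewal_spikes(rate: float, shape: float, refractory: float,
                    duration: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-renewal spikes on [0, duration); a warm-up stretch before 0 is
    simulated and discarded so the process starts near equilibrium."""
    mean_isi = 1.0 / rate
    scale = (mean_isi - refractory) / shape
    warmup = 5.0 * mean_isi
    total = warmup + duration
    # draw ISIs in batches until the span is covered
    n_guess = max(16, int(total * rate * 1.35) + 8)
    isis = refractory + rng.gamma(shape, scale, size=n_guess)
    t = np.cumsum(isis)
    while t.size and t[-1] < total:
        more = refractory + rng.gamma(shape, scale, size=n_guess)
        t = np.concatenate([t, t[-1] + np.cumsum(more)])
    t = t[t < total] - warmup
    return t[t >= 0.0]


def _burst_spikes(params: SimulationParams, mult: float, duration: float,
                  rng: np.random.Generator) -> Tuple[np.ndarray, List[Tuple[float, float]]]:
    """Burst spike times and the (clear_start, clear_end) carving windows."""
    lam_b = params.burst_rate_per_min * mult / 60.0
    if lam_b <= 0 or duration <= _PRE_CLEAR + 0.1:
        return np.empty(0), []
    n_bursts = rng.poisson(lam_b * duration)
    if n_bursts == 0:
        return np.empty(0), []
    m = _mean_burst_spikes(params)
    p_geo = 1.0 if m <= 2.0 else 1.0 / (m - 1.0)
    spikes: List[np.ndarray] = []
    windows: List[Tuple[float, float]] = []
    onsets = np.sort(rng.uniform(_PRE_CLEAR, duration, size=n_bursts))
    last_end = -np.inf
    for onset in onsets:
        n_spk = 2 + int(rng.geometric(p_geo)) - 1
        intra = rng.uniform(0.4, 1.0, size=n_spk - 1) * params.intra_burst_isi_s
        times = onset + np.concatenate(([0.0], np.cumsum(intra)))
        if times[-1] + _POST_CLEAR >= duration:
            continue
        if onset - _PRE_CLEAR < last_end + _BURST_SPACING:
            continue  # too close to the previous burst's guard window
        spikes.append(times)
        windows.append((onset - _PRE_CLEAR, times[-1] + _POST_CLEAR))
        last_end = times[-1] + _POST_CLEAR
    if not spikes:
        return np.empty(0), []
    return np.concatenate(spikes), windows


def _simulate_interval(params: SimulationParams, duration: float,
                       rate_mult: float, rng: np.random.Generator,
                       with_bursts: bool = True) -> np.ndarray:
    tonic_rate = _tonic_rate(params, rate_mult) if with_bursts \
        else params.bg_rate_hz * rate_mult
    tonic = _renewal_spikes(tonic_rate, params.gamma_shape,
                            params.refractory_s, duration, rng)
    if not with_bursts:
        return tonic
    burst, windows = _burst_spikes(params, rate_mult, duration, rng)
    if windows:
        keep = np.ones(tonic.size, dtype=bool)
        for a, b in windows:
            keep &= ~((tonic >= a) & (tonic <= b))
        tonic = tonic[keep]
    return np.sort(np.concatenate([tonic, burst]))


def simulate_background(params: SimulationParams, duration_s: float,
                        rng: np.random.Generator,
                        rate_multiplier: float = 1.0,
                        unit_id: str = "") -> SpikeTrain:
    """Simulate a background (unstimulated) stretch of ``duration_s`` seconds."""
    if duration_s <= 0:
        raise ValidationError("duration must be > 0")
    ts = _simulate_interval(params, duration_s, rate_multiplier, rng)
    ts = _dedupe(ts)
    return SpikeTrain(ts, 0.0, duration_s, unit_id)


def _dedupe(ts: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Drop numerically coincident spikes (guards strict monotonicity)."""
    if ts.size < 2:
        return ts
    keep = np.concatenate(([True], np.diff(ts) > eps))
    return ts[keep]


@dataclass(frozen=True)
class EpochLayout:
    """Timing template of one condition segment.

    Defaults: 5-min background, then 15 s innocuous and noxious stimuli,
    each preceded by >= 120 s of unstimulated time (net-evoked baseline)
    and separated by >= 180 s.
    """

    segment_s: float = 720.0
    background_onset: float = 0.0
    background_s: float = 300.0
    innocuous_onset: float = 420.0
    noxious_onset: float = 630.0
    stimulus_s: float = 15.0

    def intervals(self):
        """(start, stop, rate-gain kind) tiling of one segment."""
        i0, i1 = self.innocuous_onset, self.innocuous_onset + self.stimulus_s
        n0, n1 = self.noxious_onset, self.noxious_onset + self.stimulus_s
        return [(0.0, i0, "bg"), (i0, i1, "innocuous"), (i1, n0, "bg"),
                (n0, n1, "noxious"), (n1, self.segment_s, "bg")]


#: canonical drug protocols -> (condition tag, rate-multiplier source) pairs.
#: "effect" applies SimulationParams.drug_effect; "baseline" applies 1.0.
PROTOCOL_CONDITIONS: Dict[str, Tuple[Tuple[str, str], ...]] = {
    "none": (("predrug", "baseline"),),
    "antagonist_only": (("predrug", "baseline"), ("antagonist", "effect")),
    "agonist_then_antagonist": (("predrug", "baseline"), ("agonist", "effect"),
                                ("agonist+antagonist", "baseline")),
    "antagonist_then_agonist": (("predrug", "baseline"), ("antagonist", "effect"),
                                ("antagonist+agonist", "effect")),
}


def _conditions_for(protocol: str, params: SimulationParams,
                    ) -> List[Tuple[str, float]]:
    if protocol not in PROTOCOL_CONDITIONS:
        raise ValidationError(
            f"unknown drug protocol {protocol!r}; "
            f"known: {sorted(PROTOCOL_CONDITIONS)}")
    out = []
    for tag, kind in PROTOCOL_CONDITIONS[protocol]:
        out.append((tag, params.drug_effect if kind == "effect" else 1.0))
    return out


def simulate_neuron(unit_id: str, params: SimulationParams,
                    rng: np.random.Generator,
                    protocol: str = "none",
                    surgery: str = "sham", vector: str = "none",
                    layout: EpochLayout = EpochLayout()) -> NeuronRecord:
    """Simulate one neuron: one segment per drug condition, each with a
    background epoch and both stimulus epochs."""
    conditions = _conditions_for(protocol, params)
    gains = {"bg": 1.0, "innocuous": params.evoked_gain_innoc,
             "noxious": params.evoked_gain_nox}
    all_spikes = []
    epochs: List[Epoch] = []
    for seg_i, (tag, mult) in enumerate(conditions):
        offset = seg_i * layout.segment_s
        for a, b, kind in layout.intervals():
            ts = _simulate_interval(params, b - a, mult * gains[kind], rng)
            all_spikes.append(ts + offset + a)
        epochs.append(Epoch("background", offset + layout.background_onset,
                            layout.background_s, condition_tag=tag))
        epochs.append(Epoch("innocuous", offset + layout.innocuous_onset,
                            layout.stimulus_s, 100.0, 6.0, tag))
        epochs.append(Epoch("noxious", offset + layout.noxious_onset,
                            layout.stimulus_s, 500.0, 6.0, tag))
    ts = _dedupe(np.sort(np.concatenate(all_spikes)))
    t_stop = len(conditions) * layout.segment_s
    train = SpikeTrain(ts, 0.0, t_stop, unit_id)
    return NeuronRecord(train=train, epochs=tuple(epochs), surgery=surgery,
                        vector=vector, drug_protocol=protocol)


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: labels, size, phenotype, between-neuron spread.

    ``rate_dispersion`` and ``burst_dispersion`` are the sigmas of
    mean-preserving lognormal jitters applied per neuron to the background
    firing rate and the burst rate respectively (0 disables them).  Burst
    propensity is given less between-neuron spread than overall
    excitability so that burst-rate group contrasts stay detectable at
    realistic cohort sizes.
    """

    name: str
    n_neurons: int
    params: SimulationParams
    surgery: str = "sham"
    vector: str = "none"
    drug_protocol: str = "none"
    rate_dispersion: float = 0.25
    burst_dispersion: float = 0.15

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValidationError(f"group {self.name!r}: n_neurons must be >= 1")
        if self.rate_dispersion < 0 or self.burst_dispersion < 0:
            raise ValidationError("dispersions must be >= 0")


@dataclass(frozen=True)
class CohortDesign:
    groups: Tuple[GroupSpec, ...]
    seed: int = 0
    layout: EpochLayout = EpochLayout()

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if not self.groups:
            raise ValidationError("cohort design needs at least one group")


def _neuron_rng(seed: int, group_i: int, neuron_i: int) -> np.random.Generator:
    """Independent per-neuron substream: adding neurons or groups elsewhere
    never changes this neuron's spikes."""
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence([seed, group_i, neuron_i])))


def _lognorm_factor(sigma: float, rng: np.random.Generator) -> float:
    """Mean-preserving lognormal multiplier (E[f] = 1)."""
    if sigma <= 0:
        return 1.0
    return float(np.exp(rng.normal(-0.5 * sigma ** 2, sigma)))


def _jitter(params: SimulationParams, sigma_rate: float, sigma_burst: float,
            rng: np.random.Generator) -> SimulationParams:
    return replace(
        params,
        bg_rate_hz=params.bg_rate_hz * _lognorm_factor(sigma_rate, rng),
        burst_rate_per_min=params.burst_rate_per_min
        * _lognorm_factor(sigma_burst, rng))


def simulate_records(design: CohortDesign) -> List[NeuronRecord]:
    """Simulate the whole cohort in memory, reproducibly from the seed."""
    records = []
    for gi, g in enumerate(design.groups):
        for ni in range(g.n_neurons):
            rng = _neuron_rng(design.seed, gi, ni)
            params = _jitter(g.params, g.rate_dispersion, g.burst_dispersion,
                             rng)
            unit_id = f"{g.name}_{ni:03d}"
            records.append(simulate_neuron(
                unit_id, params, rng, protocol=g.drug_protocol,
                surgery=g.surgery, vector=g.vector, layout=design.layout))
    return records


def simulate_cohort(design: CohortDesign, out_dir) -> Path:
    """Simulate and write the cohort files; returns the manifest path.

    Output is byte-reproducible from the design seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in simulate_records(design):
        uid = rec.train.unit_id
        spike_file, epoch_file = f"{uid}.spikes.csv", f"{uid}.epochs.csv"
        write_spike_train(rec.train, out_dir / spike_file)
        write_epochs(rec.epochs, out_dir / epoch_file)
        rows.append({"unit_id": uid, "spike_file": spike_file,
                     "epoch_file": epoch_file, "surgery": rec.surgery,
                     "vector": rec.vector, "drug_protocol": rec.drug_protocol})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def default_cohort_design(seed: int = 0, null: bool = False,
                          n_sham: int = 18, n_snl: int = 10,
                          n_kd: int = 6) -> CohortDesign:
    """Three-group background/evoked cohort: sham controls (n=18),
    neuropathic SNL (n=10), and SNL with receptor knockdown (n=6, sham-like
    phenotype).  With ``null=True`` all groups share the sham phenotype."""
    snl = SHAM_PARAMS if null else SNL_PARAMS
    return CohortDesign(groups=(
        GroupSpec("sham_ctrl", n_sham, SHAM_PARAMS, "sham", "control_shRNA"),
        GroupSpec("snl_ctrl", n_snl, snl, "SNL", "control_shRNA"),
        GroupSpec("snl_kd", n_kd, SHAM_PARAMS, "SNL", "5HT2CR_shRNA"),
    ), seed=seed)


def design_from_dict(cfg: dict) -> CohortDesign:
    """Build a design from a YAML/JSON-style dict (see the CLI docs)."""
    groups = []
    for g in cfg.get("groups", []):
        params = SimulationParams(**g.get("params", {}))
        groups.append(GroupSpec(
            name=g["name"], n_neurons=int(g["n_neurons"]), params=params,
            surgery=g.get("surgery", "sham"), vector=g.get("vector", "none"),
            drug_protocol=g.get("drug_protocol", "none"),
            rate_dispersion=float(g.get("rate_dispersion", 0.25)),
            burst_dispersion=float(g.get("burst_dispersion", 0.15))))
    layout = EpochLayout(**cfg.get("layout", {}))
    return CohortDesign(tuple(groups), seed=int(cfg.get("seed", 0)),
                        layout=layout)
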