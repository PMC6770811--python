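"""Figure-style panels: PSTHs, joint-ISI maps with the burst rectangle,
and group bar summaries (mean ± SE)."""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import BurstCriteria, Epoch, NeuronRecord, SpikeTrain
from .metrics import AnalysisConfig, Psth, joint_isi_map, psth

__all__ = ["plot_psth", "plot_joint_isi", "plot_group_bars",
           "save_cohort_panels"]


def plot_psth(train: SpikeTrain, window: Epoch, bin_width_s: float = 1.0,
              stim_epochs: Sequence[Epoch] = (), ax=None):
    """Spikes-per-second histogram with stimulus spans marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 2.5))
    h = psth(train, window, bin_width_s)
    ax.bar(h.bin_edges_s[:-1], h.rate_per_bin, width=bin_width_s,
           align="edge", color="k", linewidth=0)
    ymax = max(1.0, float(h.rate_per_bin.max()) * 1.15)
    for e in stim_epochs:
        ax.plot([e.onset, e.t_stop], [ymax, ymax], lw=3,
                color="tab:red" if e.label == "noxious" else "tab:blue")
        ax.text(e.onset, ymax * 1.02, e.label, fontsize=7)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("spikes/s")
    return ax


def plot_joint_isi(train: SpikeTrain, criteria: BurstCriteria = BurstCriteria(),
                   ax=None):
    """Joint-ISI return map (previous vs subsequent ISI, log-log) with the
    dashed burst-start rectangle; burst-start pairs highlighted."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.2))
    m = joint_isi_map(train, criteria)
    if len(m):
        bs = m["is_burst_start"]
        ax.loglog(m.loc[~bs, "isi1"], m.loc[~bs, "isi2"], ".", ms=3,
                  color="0.4")
        ax.loglog(m.loc[bs, "isi1"], m.loc[bs, "isi2"], ".", ms=4,
                  color="tab:red")
        hi = max(m["isi1"].max(), m["isi2"].max()) * 2
    else:
        hi = 10.0
    ax.plot([criteria.min_silent_s, criteria.min_silent_s, hi, hi,
             criteria.min_silent_s],
            [1e-4, criteria.max_intra_isi_s, criteria.max_intra_isi_s,
             1e-4, 1e-4],
            "r--", lw=1)
    ax.set_xlabel("previous ISI (s)")
    ax.set_ylabel("subsequent ISI (s)")
    return ax


def plot_group_bars(group_summary: pd.DataFrame, metric: str,
                    group_col: str = "group", ax=None):
    """Bar plot of group means with SE error bars for one metric."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.0))
    sub = group_summary[group_summary["metric"] == metric]
    x = np.arange(len(sub))
    ax.bar(x, sub["mean"], yerr=sub["se"], capsize=3, color="0.7",
           edgecolor="k")
    ax.set_xticks(x)
    ax.set_xticklabels(sub[group_col], rotation=30, ha="right", fontsize=7)
    ax.set_ylabel(metric)
    return ax


def save_cohort_panels(records: Sequence[NeuronRecord], out_dir,
                       config: AnalysisConfig = AnalysisConfig(),
                       max_neurons: int = 3) -> List[Path]:
    """Render PSTH + joint-ISI panels for the first few neurons."""
    out_dir = Path(out_dir)
    paths = []
    for rec in records[:max_neurons]:
        tag = rec.condition_tags[0]
        stims = [e for e in rec.epochs_for(tag) if e.is_stimulus]
        window = Epoch("background", rec.train.t_start,
                       rec.train.duration, condition_tag=tag)
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3),
                                       gridspec_kw={"width_ratios": [2, 1]})
        plot_psth(rec.train, window, config.psth_bin_s, stims, ax=ax1)
        bg = rec.epochs_for(tag, "background")[0]
        plot_joint_isi(rec.train.slice(bg.onset, bg.t_stop),
                       config.burst_criteria, ax=ax2)
        fig.suptitle(rec.train.unit_id, fontsize=9)
        fig.tight_layout()
        p = out_dir / f"{rec.train.unit_id}_panel.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
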