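"""Statsmodels-style comparison models over per-neuron metric tables.

Two model classes cover the cohort designs used here:

* :class:`CohortComparison` — between-group: one-way ANOVA with Bonferroni
  post hocs per metric across surgery/vector groups (neurons are the
  sampling unit, one condition per neuron);
* :class:`WithinNeuronComparison` — within-neuron drug conditions: paired t
  (2 conditions) or repeated-measures ANOVA with Bonferroni paired-t post
  hocs (>= 3 conditions) per metric.

Both are built from a tidy per-neuron metrics table (or directly from a
cohort manifest) and their ``fit()`` returns a results object carrying
group summaries (mean ± SE), the test battery, an exclusion log, and a
``summary()`` text table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import NeuronRecord, ValidationError
from .metrics import METRIC_COLUMNS, AnalysisConfig, summarize_neuron
from .stats import StatResult, oneway_anova_bonferroni, paired_t, \
    rm_anova_bonferroni

__all__ = [
    "metrics_table",
    "CohortComparison",
    "CohortComparisonResults",
    "WithinNeuronComparison",
    "WithinNeuronComparisonResults",
]

METRIC_LABELS = {
    "background_hz": "background activity (Hz)",
    "net_innocuous_hz": "net evoked, innocuous (Hz)",
    "net_noxious_hz": "net evoked, noxious (Hz)",
    "burst_rate_per_min": "burst rate (bursts/min)",
    "mean_cv2": "irregularity (mean CV2)",
}


def metrics_table(records: Sequence[NeuronRecord],
                  config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Tidy per-neuron table: one row per (neuron, condition)."""
    rows = []
    for rec in records:
        for tag, m in summarize_neuron(rec, config).items():
            rows.append({
                "unit_id": m.unit_id, "group": rec.group,
                "surgery": rec.surgery, "vector": rec.vector,
                "drug_protocol": rec.drug_protocol, "condition_tag": tag,
                "background_hz": m.background_hz,
                "net_innocuous_hz": m.net_innocuous_hz,
                "net_noxious_hz": m.net_noxious_hz,
                "burst_rate_per_min": m.burst_rate_per_min,
                "mean_cv2": np.nan if m.mean_cv2 is None else m.mean_cv2,
                "n_isi_pairs": m.n_isi_pairs,
            })
    return pd.DataFrame(rows)


def _group_summary(table: pd.DataFrame, group_col: str,
                   metrics: Sequence[str]) -> pd.DataFrame:
    rows = []
    for g, sub in table.groupby(group_col, sort=False):
        for m in metrics:
            x = sub[m].dropna()
            rows.append({group_col: g, "metric": m, "n": len(x),
                         "mean": x.mean(),
                         "se": x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1
                         else np.nan})
    return pd.DataFrame(rows)


def _fmt_summary(title: str, group_summary: pd.DataFrame, tests: Dict[str, StatResult],
                 group_col: str) -> str:
    lines = [title, "=" * len(title)]
    for m, res in tests.items():
        lines.append(f"\n{METRIC_LABELS.get(m, m)}")
        sub = group_summary[group_summary["metric"] == m]
        for r in sub.itertuples(index=False):
            lines.append(f"  {getattr(r, group_col):<28} n={r.n:<3d} "
                         f"mean±SE = {r.mean:.3f} ± {r.se:.3f}")
        lines.append(f"  {res.test_name}: stat={res.statistic:.3f} "
                     f"df=({res.format_df()}) p={res.p_value:.4g}")
        for c in res.posthoc:
            star = " *" if c.p_corrected < res.alpha else ""
            lines.append(f"    {c.label}: p_corr={c.p_corrected:.4g}{star}")
    return "\n".join(lines)


@dataclass
class CohortComparisonResults:
    """Fitted between-group comparison: per-metric ANOVA + post hocs."""

    per_neuron: pd.DataFrame
    group_summary: pd.DataFrame
    tests: Dict[str, StatResult]
    exclusions: pd.DataFrame
    alpha: float

    def summary(self) -> str:
        return _fmt_summary("Between-group comparison (one-way ANOVA, "
                            "Bonferroni post hocs)",
                            self.group_summary, self.tests, "group")


class CohortComparison:
    """Between-group comparison of per-neuron metrics.

    Parameters
    ----------
    table
        Tidy metrics table (see :func:`metrics_table`) restricted to one
        condition per neuron (rows with other ``condition_tag`` values can
        be filtered via ``condition_tag``).
    group_col
        Column defining the groups (default the composite ``group``).
    metrics
        Metric columns to test; neurons with a missing value for a metric
        are excluded listwise for that metric and logged.
    """

    def __init__(self, table: pd.DataFrame, group_col: str = "group",
                 metrics: Sequence[str] = tuple(METRIC_COLUMNS),
                 condition_tag: Optional[str] = None, alpha: float = 0.05):
        if condition_tag is not None:
            table = table[table["condition_tag"] == condition_tag]
        self.table = table.reset_index(drop=True)
        self.group_col = group_col
        self.metrics = list(metrics)
        self.alpha = alpha
        counts = self.table.groupby(group_col).size()
        if len(counts) < 2:
            raise ValidationError("between-group comparison needs >= 2 groups")
        small = counts[counts < 2]
        if len(small):
            raise ValidationError(
                f"groups with n < 2 neurons: {dict(small)}")

    @classmethod
    def from_manifest(cls, manifest_path, config: AnalysisConfig = AnalysisConfig(),
                      **kwargs) -> "CohortComparison":
        from .io import load_cohort
        records = load_cohort(manifest_path)
        table = metrics_table(records, config)
        table = _apply_masks(table, manifest_path)
        return cls(table, **kwargs)

    @classmethod
    def from_records(cls, records: Sequence[NeuronRecord],
                     config: AnalysisConfig = AnalysisConfig(),
                     **kwargs) -> "CohortComparison":
        return cls(metrics_table(records, config), **kwargs)

    def fit(self) -> CohortComparisonResults:
        tests: Dict[str, StatResult] = {}
        excl_rows = []
        for m in self.metrics:
            groups = []
            for g, sub in self.table.groupby(self.group_col, sort=False):
                x = sub[m]
                for uid in sub.loc[x.isna(), "unit_id"]:
                    excl_rows.append({"unit_id": uid, "metric": m,
                                      "reason": "metric undefined (listwise)"})
                groups.append((str(g), x.dropna().to_numpy()))
            tests[m] = oneway_anova_bonferroni(
                groups, alpha=self.alpha,
                name=f"one-way ANOVA [{m}]")
        return CohortComparisonResults(
            per_neuron=self.table,
            group_summary=_group_summary(self.table, self.group_col, self.metrics),
            tests=tests,
            exclusions=pd.DataFrame(excl_rows,
                                    columns=["unit_id", "metric", "reason"]),
            alpha=self.alpha)


def _apply_masks(table: pd.DataFrame, manifest_path) -> pd.DataFrame:
    """Apply optional per-metric inclusion masks from manifest columns
    ``include_<metric>`` (0/1): masked-out neurons get NaN for that metric
    and are excluded listwise from its group test."""
    from .io import read_manifest
    mf = read_manifest(manifest_path)
    mask_cols = [c for c in mf.columns if c.startswith("include_")]
    if not mask_cols:
        return table
    mf = mf.set_index(mf["unit_id"].astype(str))
    table = table.copy()
    for c in mask_cols:
        metric = c[len("include_"):]
        if metric not in table.columns:
            continue
        excluded = set(mf.index[mf[c].astype(float) == 0.0])
        table.loc[table["unit_id"].isin(excluded), metric] = np.nan
    return table


@dataclass
class WithinNeuronComparisonResults:
    """Fitted within-neuron drug-condition comparison."""

    per_neuron: pd.DataFrame
    condition_order: Tuple[str, ...]
    group_summary: pd.DataFrame
    tests: Dict[str, StatResult]
    exclusions: pd.DataFrame
    alpha: float

    def summary(self) -> str:
        k = len(self.condition_order)
        kind = "paired t-test" if k == 2 else "repeated measures ANOVA, " \
                                             "Bonferroni post hocs"
        return _fmt_summary(f"Within-neuron comparison ({kind})",
                            self.group_summary, self.tests, "condition_tag")


class WithinNeuronComparison:
    """Within-neuron comparison across drug conditions.

    Each neuron must carry every condition in ``condition_order`` (neurons
    missing a condition, or with an undefined metric in any condition, are
    excluded listwise and logged).  With two conditions the test is a
    paired t; with three or more it is the uncorrected-df repeated-measures
    ANOVA with Bonferroni paired-t post hocs.
    """

    def __init__(self, table: pd.DataFrame,
                 condition_order: Optional[Sequence[str]] = None,
                 metrics: Sequence[str] = tuple(METRIC_COLUMNS),
                 alpha: float = 0.05):
        self.table = table.reset_index(drop=True)
        if condition_order is None:
            condition_order = list(dict.fromkeys(self.table["condition_tag"]))
        if len(condition_order) < 2:
            raise ValidationError("within-neuron comparison needs >= 2 conditions")
        self.condition_order = tuple(condition_order)
        self.metrics = list(metrics)
        self.alpha = alpha

    @classmethod
    def from_records(cls, records: Sequence[NeuronRecord],
                     config: AnalysisConfig = AnalysisConfig(),
                     **kwargs) -> "WithinNeuronComparison":
        return cls(metrics_table(records, config), **kwargs)

    def _wide(self, metric: str):
        """n x k matrix of one metric, plus the exclusion log."""
        wide = self.table.pivot_table(index="unit_id", columns="condition_tag",
                                      values=metric, aggfunc="first")
        excl = []
        missing_cond = [c for c in self.condition_order if c not in wide.columns]
        if missing_cond:
            raise ValidationError(
                f"no neuron carries condition(s) {missing_cond}")
        wide = wide[list(self.condition_order)]
        bad = wide.index[wide.isna().any(axis=1)]
        for uid in bad:
            excl.append({"unit_id": uid, "metric": metric,
                         "reason": "missing condition or undefined metric"})
        return wide.drop(index=bad), excl

    def fit(self) -> WithinNeuronComparisonResults:
        tests: Dict[str, StatResult] = {}
        excl_rows: List[dict] = []
        for m in self.metrics:
            wide, excl = self._wide(m)
            excl_rows.extend(excl)
            if len(wide) < 2:
                raise ValidationError(
                    f"metric {m!r}: fewer than 2 complete neurons")
            if len(self.condition_order) == 2:
                a, b = self.condition_order
                tests[m] = paired_t(wide[a].to_numpy(), wide[b].to_numpy(),
                                    alpha=self.alpha,
                                    name=f"paired t [{m}] {a} vs {b}")
            else:
                tests[m] = rm_anova_bonferroni(
                    wide.to_numpy(), condition_labels=self.condition_order,
                    alpha=self.alpha, name=f"RM-ANOVA [{m}]")
        sub = self.table[self.table["condition_tag"].isin(self.condition_order)]
        return WithinNeuronComparisonResults(
            per_neuron=self.table,
            condition_order=self.condition_order,
            group_summary=_group_summary(sub, "condition_tag", self.metrics),
            tests=tests,
            exclusions=pd.DataFrame(excl_rows,
                                    columns=["unit_id", "metric", "reason"]),
            alpha=self.alpha)
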