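"""End-to-end cohort analysis: records -> metrics -> tests -> report files."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from .core import NeuronRecord, ValidationError
from .metrics import AnalysisConfig
from .models import (CohortComparison, WithinNeuronComparison, metrics_table,
                     _apply_masks)
from .simulate import PROTOCOL_CONDITIONS
from .stats import StatResult

__all__ = ["AnalysisReport", "run_group_analysis", "run_drug_analysis",
           "write_report"]


@dataclass
class AnalysisReport:
    """Everything one analysis run produced, ready to serialize."""

    per_neuron_table: pd.DataFrame
    group_summary: pd.DataFrame
    group_tests: Dict[str, StatResult]
    exclusions: pd.DataFrame
    run_metadata: dict

    def tests_frame(self) -> pd.DataFrame:
        rows = []
        for metric, res in self.group_tests.items():
            rows.append({"metric": metric, "test": res.test_name,
                         "comparison": "omnibus", "statistic": res.statistic,
                         "df": res.format_df(), "p_raw": res.p_value,
                         "p_corrected": res.p_value,
                         "significant": res.significant})
            for c in res.posthoc:
                rows.append({"metric": metric, "test": res.test_name,
                             "comparison": c.label, "statistic": c.statistic,
                             "df": "", "p_raw": c.p_raw,
                             "p_corrected": c.p_corrected,
                             "significant": c.p_corrected < res.alpha})
        return pd.DataFrame(rows)


def _metadata(config: AnalysisConfig, kind: str, extra: dict | None = None) -> dict:
    cfg = {"min_silent_s": config.burst_criteria.min_silent_s,
           "max_intra_isi_s": config.burst_criteria.max_intra_isi_s,
           "background_window_s": config.background_window_s,
           "psth_bin_s": config.psth_bin_s, "alpha": config.alpha}
    blob = json.dumps(cfg, sort_keys=True).encode()
    meta = {"analysis": kind, "version": __version__, "config": cfg,
            "config_hash": hashlib.sha256(blob).hexdigest()[:16]}
    if extra:
        meta.update(extra)
    return meta


def run_group_analysis(records: Sequence[NeuronRecord],
                       config: AnalysisConfig = AnalysisConfig(),
                       condition_tag: str = "predrug",
                       manifest_path=None) -> AnalysisReport:
    """Between-group comparison of background/evoked/burst/CV2 metrics.

    One-way ANOVA with Bonferroni post hocs per metric across the cohort's
    surgery/vector groups, on the given condition (default the predrug
    segment).  Optional per-metric inclusion masks are honoured when a
    manifest with ``include_*`` columns is given.
    """
    table = metrics_table(records, config)
    if manifest_path is not None:
        table = _apply_masks(table, manifest_path)
    model = CohortComparison(table, condition_tag=condition_tag,
                             alpha=config.alpha)
    res = model.fit()
    return AnalysisReport(
        per_neuron_table=res.per_neuron,
        group_summary=res.group_summary,
        group_tests=res.tests,
        exclusions=res.exclusions,
        run_metadata=_metadata(config, "group_comparison",
                               {"condition_tag": condition_tag}))


def run_drug_analysis(records: Sequence[NeuronRecord], protocol: str,
                      config: AnalysisConfig = AnalysisConfig()
                      ) -> AnalysisReport:
    """Within-neuron drug-condition comparison for one protocol.

    Two-condition protocols use a paired t-test per metric; three-condition
    protocols use the repeated-measures ANOVA with Bonferroni paired-t post
    hocs.  Neurons missing a required condition are excluded and logged.
    """
    if protocol not in PROTOCOL_CONDITIONS:
        raise ValidationError(
            f"unknown drug protocol {protocol!r}; known: "
            f"{sorted(PROTOCOL_CONDITIONS)}")
    conditions = [tag for tag, _ in PROTOCOL_CONDITIONS[protocol]]
    subset = [r for r in records if r.drug_protocol == protocol]
    if not subset:
        raise ValidationError(f"no neurons with drug protocol {protocol!r}")
    model = WithinNeuronComparison.from_records(
        subset, config, condition_order=conditions, alpha=config.alpha)
    res = model.fit()
    return AnalysisReport(
        per_neuron_table=res.per_neuron,
        group_summary=res.group_summary,
        group_tests=res.tests,
        exclusions=res.exclusions,
        run_metadata=_metadata(config, "drug_comparison",
                               {"protocol": protocol,
                                "conditions": conditions}))


def write_report(report: AnalysisReport, out_dir, plots: bool = False,
                 records: Optional[Sequence[NeuronRecord]] = None) -> List[Path]:
    """Write the numeric contract surface: per-neuron CSV, tests CSV,
    group-summary CSV, exclusion log, and JSON run metadata.  With
    ``plots=True`` and records supplied, PSTH and joint-ISI panels are
    rendered as well."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    def _write(df: pd.DataFrame, name: str):
        p = out_dir / name
        df.to_csv(p, index=False, float_format="%.6g")
        paths.append(p)

    _write(report.per_neuron_table, "per_neuron.csv")
    _write(report.group_summary, "group_summary.csv")
    _write(report.tests_frame(), "tests.csv")
    _write(report.exclusions, "exclusions.csv")
    meta_path = out_dir / "run_metadata.json"
    meta = dict(report.run_metadata)
    meta["n_rows_per_neuron"] = int(len(report.per_neuron_table))
    meta["n_exclusions"] = int(len(report.exclusions))
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    paths.append(meta_path)
    if plots and records:
        from .plotting import save_cohort_panels
        paths.extend(save_cohort_panels(records, out_dir))
    return paths
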