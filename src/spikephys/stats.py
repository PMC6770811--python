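"""Group and within-neuron statistical tests.

The comparison battery used throughout the package:

* two-tailed paired t-test (predrug vs drug, within neuron);
* one-way between-group ANOVA with Bonferroni-corrected pairwise
  pooled-variance t post hocs (sham vs neuropathic vs knockdown);
* one-way within-subject repeated-measures ANOVA with Bonferroni-corrected
  paired-t post hocs, reported with uncorrected degrees of freedom
  (k−1, (k−1)(n−1)) — no sphericity correction.

The sampling unit is the neuron.  Bonferroni correction multiplies each raw
pairwise p by the number of pairwise comparisons, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .core import ValidationError

__all__ = [
    "StatResult",
    "PosthocComparison",
    "paired_t",
    "oneway_anova_bonferroni",
    "rm_anova_bonferroni",
    "bonferroni",
]


def bonferroni(p_raw: float, n_comparisons: int) -> float:
    """Bonferroni-corrected p: min(1, p · m)."""
    return min(1.0, p_raw * n_comparisons)


@dataclass(frozen=True)
class PosthocComparison:
    label: str
    statistic: float
    p_raw: float
    p_corrected: float

    @property
    def significant(self) -> bool:
        return self.p_corrected < 0.05


@dataclass(frozen=True)
class StatResult:
    """Outcome of one omnibus test plus its post hoc comparisons."""

    test_name: str
    statistic: float
    df: Tuple[int, ...]
    p_value: float
    posthoc: Tuple[PosthocComparison, ...] = ()
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def format_df(self) -> str:
        return ",".join(str(d) for d in self.df)

    def __str__(self) -> str:
        s = (f"{self.test_name}: stat={self.statistic:.4g} "
             f"df=({self.format_df()}) p={self.p_value:.4g}")
        for c in self.posthoc:
            s += f"\n  {c.label}: t={c.statistic:.4g} p_corr={c.p_corrected:.4g}"
        return s


def _paired_t_core(pre: np.ndarray, post: np.ndarray):
    d = post - pre
    n = d.size
    sd = float(np.std(d, ddof=1))
    m = float(np.mean(d))
    if sd == 0.0:
        if m == 0.0:
            return 0.0, 1.0, n - 1, True
        return float(np.sign(m)) * np.inf, 0.0, n - 1, True
    t = m / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), float(p), n - 1, False


def paired_t(pre: Sequence[float], post: Sequence[float],
             alpha: float = 0.05, name: str = "paired t") -> StatResult:
    """Two-tailed paired t-test, df = n − 1.

    Degenerate inputs are flagged rather than erroring: all differences
    zero gives t = 0, p = 1; zero-variance differences with nonzero mean
    give |t| = inf, p = 0.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValidationError("paired t requires two equal-length 1-d samples")
    if pre.size < 2:
        raise ValidationError("paired t requires n >= 2 pairs")
    t, p, df, degen = _paired_t_core(pre, post)
    return StatResult(name, t, (df,), p, alpha=alpha, degenerate=degen)


def _pooled_t(x: np.ndarray, y: np.ndarray):
    """Two-sample pooled-variance t statistic and two-tailed p."""
    nx, ny = x.size, y.size
    df = nx + ny - 2
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / df
    if sp2 == 0.0:
        diff = np.mean(x) - np.mean(y)
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff)) * np.inf, 0.0
    t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    return float(t), float(2.0 * sps.t.sf(abs(t), df))


def oneway_anova_bonferroni(groups: Sequence[Tuple[str, Sequence[float]]],
                            alpha: float = 0.05,
                            name: str = "one-way ANOVA") -> StatResult:
    """Between-group one-way ANOVA, F with df (k−1, N−k), plus
    Bonferroni-corrected pairwise pooled-variance t comparisons over all
    k(k−1)/2 group pairs."""
    if len(groups) < 2:
        raise ValidationError("ANOVA requires >= 2 groups")
    labels = [g[0] for g in groups]
    data = [np.asarray(g[1], dtype=float) for g in groups]
    for lab, x in zip(labels, data):
        if x.size < 2:
            raise ValidationError(f"group {lab!r} has n < 2")
    k = len(data)
    N = sum(x.size for x in data)
    grand = np.mean(np.concatenate(data))
    ss_between = sum(x.size * (np.mean(x) - grand) ** 2 for x in data)
    ss_within = sum(np.sum((x - np.mean(x)) ** 2) for x in data)
    df1, df2 = k - 1, N - k
    degenerate = False
    if ss_within == 0.0:
        degenerate = True
        if ss_between == 0.0:
            F, p = 0.0, 1.0
        else:
            F, p = np.inf, 0.0
    else:
        F = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(F, df1, df2))
    n_pairs = k * (k - 1) // 2
    posthoc = []
    for (la, xa), (lb, xb) in combinations(zip(labels, data), 2):
        t, praw = _pooled_t(xa, xb)
        posthoc.append(PosthocComparison(f"{la} vs {lb}", t, praw,
                                         bonferroni(praw, n_pairs)))
    return StatResult(name, float(F), (df1, df2), float(p), tuple(posthoc),
                      alpha, degenerate)


def rm_anova_bonferroni(matrix, condition_labels: Optional[Sequence[str]] = None,
                        alpha: float = 0.05,
                        name: str = "repeated measures ANOVA") -> StatResult:
    """One-way within-subject (repeated measures) ANOVA.

    ``matrix`` is n subjects × k conditions, complete (no missing cells;
    no imputation).  F carries df (k−1, (k−1)(n−1)) with no sphericity
    correction; post hocs are Bonferroni-corrected paired t-tests over all
    condition pairs.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValidationError("RM-ANOVA requires an n x k matrix")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValidationError("RM-ANOVA requires n >= 2 subjects and k >= 2 conditions")
    if np.isnan(X).any():
        raise ValidationError("RM-ANOVA matrix has missing cells; no imputation")
    if condition_labels is None:
        condition_labels = [f"cond{j + 1}" for j in range(k)]
    if len(condition_labels) != k:
        raise ValidationError("condition_labels length must match k")

    grand = X.mean()
    col_means = X.mean(axis=0)
    row_means = X.mean(axis=1)
    ss_cond = n * np.sum((col_means - grand) ** 2)
    ss_subj = k * np.sum((row_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    degenerate = False
    if ss_err <= 1e-12 * max(ss_total, 1.0):
        degenerate = True
        if ss_cond <= 1e-12 * max(ss_total, 1.0):
            F, p = 0.0, 1.0
        else:
            F, p = np.inf, 0.0
    else:
        F = (ss_cond / df1) / (ss_err / df2)
        p = float(sps.f.sf(F, df1, df2))
    n_pairs = k * (k - 1) // 2
    posthoc = []
    for a, b in combinations(range(k), 2):
        t, praw, _, _ = _paired_t_core(X[:, a], X[:, b])
        posthoc.append(PosthocComparison(
            f"{condition_labels[a]} vs {condition_labels[b]}",
            t, praw, bonferroni(praw, n_pairs)))
    return StatResult(name, float(F), (df1, df2), float(p), tuple(posthoc),
                      alpha, degenerate)
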