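"""Nonparametric comparison of the four methods across subjects.

Small subject counts and heteroskedastic accuracies rule out ANOVA, so
methods are compared with the Kruskal–Wallis H test; when it is
significant, pairwise Dunn z-tests (with the pooled tie correction) are
applied post hoc, with Bonferroni–Holm adjustment of the pairwise p values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

MIN_SUBJECTS = 5


@dataclass
class MetricComparison:
    metric: str
    kruskal_h: float
    kruskal_p: float
    dunn_p: pd.DataFrame | None  # symmetric, unit diagonal; None if KW n.s.

    def to_dict(self) -> dict:
        out = {
            "metric": self.metric,
            "kruskal_h": self.kruskal_h,
            "kruskal_p": self.kruskal_p,
        }
        if self.dunn_p is not None:
            out["dunn_p"] = {
                a: {b: float(self.dunn_p.loc[a, b]) for b in self.dunn_p.columns}
                for a in self.dunn_p.index
            }
        return out


@dataclass
class ComparisonReport:
    metrics: dict  # metric name -> MetricComparison
    n_subjects: int
    underpowered: bool

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "underpowered": self.underpowered,
            "metrics": {k: v.to_dict() for k, v in self.metrics.items()},
        }


def dunn_holm(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Dunn z-tests on pooled ranks with Holm-adjusted p values.

    The z statistic for groups i, j is the mean-rank difference over
    ``sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))`` where ``T`` is the pooled tie
    correction ``sum(t^3 - t) / (12(N - 1))``.
    """
    names = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    pos = 0
    for name, v in zip(names, values):
        mean_ranks[name] = ranks[pos : pos + len(v)].mean()
        pos += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    pvals = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / len(values[i]) + 1.0 / len(values[j])))
        z = abs(mean_ranks[names[i]] - mean_ranks[names[j]]) / se
        pvals.append(2.0 * sps.norm.sf(z))
    adjusted = multipletests(pvals, method="holm")[1] if pairs else []
    out = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (i, j), p in zip(pairs, adjusted):
        out.iloc[i, j] = out.iloc[j, i] = min(float(p), 1.0)
    return out


def compare_methods(
    metric_values: dict[str, dict[str, np.ndarray]],
    alpha: float = 0.05,
) -> ComparisonReport:
    """Compare methods across subjects, one Kruskal–Wallis test per metric.

    ``metric_values`` maps metric name -> {method name -> per-subject
    values}.  Dunn post-hoc tests are run only when the omnibus test is
    significant.  Fewer than five subjects triggers an underpowered
    warning; at least two methods are required.
    """
    report_metrics: dict[str, MetricComparison] = {}
    n_subjects = 0
    underpowered = False
    for metric, groups in metric_values.items():
        if len(groups) < 2:
            raise ValueError("need at least 2 methods to compare")
        sizes = [len(v) for v in groups.values()]
        n_subjects = max(n_subjects, max(sizes))
        if min(sizes) < MIN_SUBJECTS:
            underpowered = True
            warnings.warn(
                f"fewer than {MIN_SUBJECTS} subjects for metric {metric!r}; "
                "results are underpowered"
            )
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
        if all(np.allclose(a, arrays[0]) for a in arrays) and all(
            np.ptp(a) == 0 for a in arrays
        ):
            h, p = 0.0, 1.0
        else:
            h, p = sps.kruskal(*arrays)
        dunn = dunn_holm(groups) if p < alpha else None
        report_metrics[metric] = MetricComparison(
            metric=metric, kruskal_h=float(h), kruskal_p=float(p), dunn_p=dunn
        )
    return ComparisonReport(
        metrics=report_metrics, n_subjects=n_subjects, underpowered=underpowered
    )
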