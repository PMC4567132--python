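"""Group comparisons of CTA-panel expression and CpG-island methylation.

Panel expression is summarized per sample as the mean over panel genes of
log2(RSEM+1) (mean of logs); global methylation as the mean beta over a probe
subset. Two groups are compared with Welch's (unequal-variance) t-test, three
or more with one-way ANOVA; for three-level groupings the three pairwise Welch
tests are reported as well. Significance bands follow the usual box-plot
legend: NS, * (P < 0.05), ** (P < 0.01), *** (P < 0.001). P-values are
reported per comparison without multiplicity correction by default; a
Benjamini-Hochberg option is available on the table builder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    CTAPanel,
    ExpressionMatrix,
    MethylationMatrix,
    ValidationError,
)
import logging

logger = logging.getLogger(__name__)


def significance_band(p: float) -> str:
    """Map a p-value to the box-plot legend band (NS / * / ** / ***)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass(frozen=True)
class GroupComparison:
    """Result of comparing one statistic across the levels of one grouping."""

    grouping: str
    measure: str
    summary: pd.DataFrame  # per group: n, mean, median, q25, q75
    test: str  # "welch_t" | "anova_oneway"
    statistic: float
    p_value: float
    band: str
    pairwise: dict[tuple[str, str], tuple[float, float, str]] = field(default_factory=dict)


def mean_panel_expression(
    expression: ExpressionMatrix,
    panel: CTAPanel,
    sample: str | None = None,
) -> float | pd.Series:
    """Mean log2(RSEM+1) over panel genes, per sample.

    Panel genes absent from the matrix are dropped (count logged); with no
    panel gene present this is an error. Returns a scalar for one ``sample``
    or a per-sample series when ``sample`` is None.
    """
    present = [g for g in panel.gene_ids if g in expression.rsem.index]
    absent = len(panel.gene_ids) - len(present)
    if not present:
        raise ValidationError(f"no gene of panel {panel.name!r} present in expression matrix")
    if absent:
        logger.info("panel %s: %d genes absent from expression matrix", panel.name, absent)
    log_expr = np.log2(expression.rsem.loc[present].astype(float) + 1.0)
    means = log_expr.mean(axis=0)
    if sample is not None:
        return float(means.loc[sample])
    return means


def mean_cpg_methylation(
    methylation: MethylationMatrix,
    probe_subset: Sequence[str],
    sample: str | None = None,
) -> float | pd.Series:
    """Mean beta over the non-missing entries of a probe subset, per sample."""
    present = [p for p in probe_subset if p in methylation.beta.index]
    if not present:
        raise ValidationError("no probe of the subset present in the methylation matrix")
    sub = methylation.beta.loc[present]
    means = sub.mean(axis=0, skipna=True)
    if sample is not None:
        val = means.loc[sample]
        if pd.isna(val):
            raise ValidationError(f"all probes missing for sample {sample!r}")
        return float(val)
    return means


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        # degenerate: no within-group variation to test against
        return 0.0, 1.0 if np.mean(a) == np.mean(b) else np.finfo(float).tiny
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    grouping: str = "group",
    measure: str = "value",
) -> GroupComparison:
    """Welch t-test (two groups) or one-way ANOVA (three or more).

    Each group needs at least two values. Identical data across all groups is
    reported as p = 1 (NS) by convention. For three or more groups, all
    pairwise Welch tests are attached.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValidationError("need at least two groups to compare")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValidationError(f"group {g!r} has fewer than two values")

    summary = pd.DataFrame(
        {
            "group": list(groups),
            "n": [len(v) for v in groups.values()],
            "mean": [float(np.mean(v)) for v in groups.values()],
            "median": [float(np.median(v)) for v in groups.values()],
            "q25": [float(np.percentile(v, 25)) for v in groups.values()],
            "q75": [float(np.percentile(v, 75)) for v in groups.values()],
        }
    ).set_index("group")

    arrays = list(groups.values())
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        test = "welch_t" if len(groups) == 2 else "anova_oneway"
        return GroupComparison(grouping, measure, summary, test, 0.0, 1.0, "NS")

    if len(groups) == 2:
        stat, p = _welch(arrays[0], arrays[1])
        test = "welch_t"
        pairwise = {}
    else:
        stat, p = stats.f_oneway(*arrays)
        stat, p = float(stat), float(p)
        test = "anova_oneway"
        pairwise = {}
        for g1, g2 in combinations(groups, 2):
            s, pp = _welch(groups[g1], groups[g2])
            pairwise[(g1, g2)] = (s, pp, significance_band(pp))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return GroupComparison(grouping, measure, summary, test, stat, p, significance_band(p), pairwise)


_GROUPINGS = ("xci_group", "histology", "tcga_subtype")


def expression_by_group_table(
    calls: pd.DataFrame,
    expression: ExpressionMatrix,
    panels: Sequence[CTAPanel],
    clinical: pd.DataFrame | None = None,
    groupings: Sequence[str] = _GROUPINGS,
    bh_correct: bool = False,
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """One comparison per (panel x grouping), long-format.

    ``calls`` supplies ``sample_id``, ``xci_group`` and ``histology``;
    ``clinical`` (indexed by sample) supplies any further grouping columns
    such as ``tcga_subtype``. Samples without expression data are dropped.
    Returns the results table plus the full comparison objects (which carry
    per-group summaries and pairwise tests).
    """
    meta = calls.set_index("sample_id")[["xci_group", "histology"]].copy()
    if clinical is not None:
        for col in clinical.columns:
            if col not in meta.columns:
                meta[col] = clinical[col].reindex(meta.index)
    shared = [s for s in meta.index if s in set(expression.sample_ids)]
    if not shared:
        raise ValidationError("no samples shared between calls and expression matrix")
    meta = meta.loc[shared]

    rows = []
    comparisons = []
    for panel in panels:
        panel_means = mean_panel_expression(expression, panel)
        panel_means = panel_means.reindex(shared).dropna()
        for grouping in groupings:
            if grouping not in meta.columns:
                continue
            labels = meta.loc[panel_means.index, grouping].dropna()
            groups = {
                g: panel_means.loc[idx].to_numpy()
                for g, idx in labels.groupby(labels).groups.items()
            }
            groups = {g: v for g, v in groups.items() if len(v) >= 2}
            if len(groups) < 2:
                raise ValidationError(
                    f"grouping {grouping!r} has fewer than two usable groups"
                )
            comp = compare_groups(groups, grouping=grouping, measure=panel.name)
            comparisons.append(comp)
            rows.append(
                {
                    "panel": panel.name,
                    "grouping": grouping,
                    "test": comp.test,
                    "statistic": comp.statistic,
                    "p_value": comp.p_value,
                    "band": comp.band,
                    "groups": ";".join(f"{g}:n={len(v)}" for g, v in groups.items()),
                }
            )
    table = pd.DataFrame(rows)
    if bh_correct and len(table):
        table["p_adjusted"] = _benjamini_hochberg(table["p_value"].to_numpy())
    return table, comparisons


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
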