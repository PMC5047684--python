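"""Group-comparison statistics: line pooling, t-tests, ANOVA/Tukey, -dCt.

The study design has two cell lines per group (control A/B, CPVT A/B).
Before any between-group comparison, the two sub-lines of a group are
compared by a two-sample t-test; when they do not differ (p >= alpha) their
cells are pooled and the group is analyzed as one sample, otherwise the
comparison is run per line and the report says so.  Two-condition contrasts
use Welch's t-test; three or more conditions use one-way ANOVA with Tukey's
HSD post-hoc pairwise comparisons.  qPCR expression is summarized as
-dCt = -(C_T,gene - C_T,reference), binned low/medium/high for heatmaps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "LINES",
    "CONDITIONS",
    "ComparisonResult",
    "PoolingDecision",
    "ExpressionTable",
    "pool_lines",
    "two_sample_ttest",
    "oneway_anova_tukey",
    "neg_delta_ct",
    "holm_correct",
]

LINES = ("control_A", "control_B", "cpvt_A", "cpvt_B")
CONDITIONS = ("baseline", "iso", "flec", "nad")
GROUP_OF_LINE = {"control_A": "control", "control_B": "control",
                 "cpvt_A": "cpvt", "cpvt_B": "cpvt"}


@dataclass
class ComparisonResult:
    test: str                       # "t_test" | "anova_tukey"
    statistic: float
    p_value: float
    pooled: bool = True
    groups: list = field(default_factory=list)
    pairwise: Optional[list] = None  # [(A, B, adjusted p)] for Tukey

    def to_dict(self) -> dict:
        d = {"test": self.test, "statistic": self.statistic,
             "p_value": self.p_value, "pooled": self.pooled,
             "groups": list(self.groups)}
        if self.pairwise is not None:
            d["pairwise"] = [list(p) for p in self.pairwise]
        return d


@dataclass
class PoolingDecision:
    group: str
    line_a: str
    line_b: str
    pooled: bool
    p_value: Optional[float]
    reason: str

    def to_dict(self) -> dict:
        return {"group": self.group, "line_a": self.line_a,
                "line_b": self.line_b, "pooled": self.pooled,
                "p_value": self.p_value, "reason": self.reason}


def two_sample_ttest(x, y, equal_var: bool = False) -> ComparisonResult:
    """Two-sample t-test (Welch by default), two-sided.

    When both samples are degenerate (zero variance) with equal means the
    difference is exactly zero and p = 1 by convention; degenerate samples
    with unequal means give p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group")
    if np.var(x) == 0 and np.var(y) == 0:
        same = float(np.mean(x)) == float(np.mean(y))
        return ComparisonResult("t_test", 0.0 if same else math.inf,
                                1.0 if same else 0.0)
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return ComparisonResult("t_test", float(t), float(p))


def pool_lines(table: pd.DataFrame, variable: str, alpha: float = 0.05,
               equal_var: bool = False
               ) -> tuple[pd.DataFrame, list[PoolingDecision]]:
    """Apply the line-pooling rule to one variable of a measurement table.

    ``table`` has columns (cell_id, line, condition, variable, value).  For
    each group whose two sub-lines are present, the sub-lines are compared
    by two-sample t-test over that variable (all conditions combined);
    when p >= alpha the sub-lines are pooled and the ``line`` column is
    replaced by the group name.  A sub-line with n < 2 declines pooling.
    Returns the (possibly) pooled table and the decision record.
    """
    sub = table[table["variable"] == variable]
    out = table.copy()
    decisions: list[PoolingDecision] = []
    for group in ("control", "cpvt"):
        lines = [ln for ln in LINES if GROUP_OF_LINE[ln] == group]
        a = sub.loc[sub["line"] == lines[0], "value"].to_numpy(float)
        b = sub.loc[sub["line"] == lines[1], "value"].to_numpy(float)
        if a.size == 0 and b.size == 0:
            continue
        if a.size < 2 or b.size < 2:
            decisions.append(PoolingDecision(
                group, lines[0], lines[1], False, None,
                f"sub-line with n < 2 (n={a.size}, {b.size})"))
            continue
        res = two_sample_ttest(a, b, equal_var=equal_var)
        pooled = res.p_value >= alpha
        reason = (f"no significant sub-line difference (p={res.p_value:.3g})"
                  if pooled else
                  f"sub-lines differ (p={res.p_value:.3g}); kept separate")
        decisions.append(PoolingDecision(group, lines[0], lines[1], pooled,
                                         res.p_value, reason))
        if pooled:
            mask = out["line"].isin(lines) & (out["variable"] == variable)
            out.loc[mask, "line"] = group
    return out, decisions


def oneway_anova_tukey(groups: dict[str, Sequence[float]]
                       ) -> ComparisonResult:
    """One-way ANOVA with Tukey HSD post-hoc pairwise comparisons.

    ``groups`` maps group name to sample.  Requires >= 3 groups with
    n >= 2 each.  The F statistic is the between/within mean-square ratio;
    Tukey-adjusted p-values come from the studentized range distribution.
    Identical groups give F = 0 and all adjusted p = 1.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 3:
        raise ValueError("Tukey HSD needs >= 3 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    f, p = sps.f_oneway(*arrays)
    if not math.isfinite(f):       # all groups constant and identical
        f, p = 0.0, 1.0
    tk = sps.tukey_hsd(*arrays)
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pij = float(tk.pvalue[i, j])
            pairwise.append((names[i], names[j],
                             1.0 if math.isnan(pij) else pij))
    return ComparisonResult("anova_tukey", float(f), float(p),
                            groups=names, pairwise=pairwise)


def holm_correct(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (optional across-variable correction)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


@dataclass
class ExpressionTable:
    """-dCt expression values with heatmap bins."""

    table: pd.DataFrame             # sample, gene, ct, neg_delta_ct, heat_bin
    reference_gene: str
    bin_edges: tuple[float, float]  # low/medium and medium/high cutpoints


def neg_delta_ct(ct_table: pd.DataFrame, reference_gene: str,
                 bin_thresholds: Optional[tuple[float, float]] = None
                 ) -> ExpressionTable:
    """Reference-normalized expression -dCt = -(C_T,gene - C_T,reference).

    Samples missing the reference gene are excluded with a warning.  Heat
    bins (low/medium/high) use ``bin_thresholds`` or, by default, the
    tertiles of the non-reference -dCt values; bin assignment is monotone
    in -dCt.
    """
    req = {"sample", "gene", "ct"}
    if not req.issubset(ct_table.columns):
        raise ValueError(f"C_T table must have columns {sorted(req)}")
    if ct_table.duplicated(["sample", "gene"]).any():
        raise ValueError("duplicate (sample, gene) rows")
    ref = ct_table[ct_table["gene"] == reference_gene] \
        .set_index("sample")["ct"]
    missing = sorted(set(ct_table["sample"]) - set(ref.index))
    if missing:
        logger.warning("samples missing reference gene excluded: %s", missing)
    df = ct_table[ct_table["sample"].isin(ref.index)].copy()
    df["neg_delta_ct"] = -(df["ct"].to_numpy()
                           - ref.loc[df["sample"]].to_numpy())
    if bin_thresholds is None:
        vals = df.loc[df["gene"] != reference_gene, "neg_delta_ct"]
        if vals.size:
            lo, hi = np.percentile(vals, [100 / 3, 200 / 3])
        else:
            lo, hi = 0.0, 0.0
    else:
        lo, hi = bin_thresholds
        if hi < lo:
            raise ValueError("bin thresholds must be ordered")
    df["heat_bin"] = np.where(df["neg_delta_ct"] <= lo, "low",
                              np.where(df["neg_delta_ct"] <= hi, "medium",
                                       "high"))
    return ExpressionTable(table=df.reset_index(drop=True),
                           reference_gene=reference_gene,
                           bin_edges=(float(lo), float(hi)))
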