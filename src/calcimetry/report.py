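"""Cohort report assembly.

Rolls the per-cell stage outputs into one document: leak/load group
comparisons, line-scan classification counts, spark summaries with KDEs,
and rhythm (CV / DAD) summaries, each comparison annotated with its
line-pooling decision.  The rendered JSON is deterministic: regenerating
the report from the same inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as st

logger = logging.getLogger(__name__)

__all__ = ["build_report", "report_json", "classification_counts"]

MEASUREMENT_COLUMNS = ("cell_id", "line", "condition", "variable", "value")


def classification_counts(classifications: pd.DataFrame) -> pd.DataFrame:
    """Per (line, condition) counts of normal / SCW / other scans.

    ``classifications`` has columns (cell_id, line, condition, label)."""
    tab = (classifications
           .groupby(["line", "condition", "label"], sort=True)
           .size().unstack("label", fill_value=0))
    for lab in ("normal", "scw", "other"):
        if lab not in tab.columns:
            tab[lab] = 0
    tab = tab[["normal", "scw", "other"]]
    tab.columns = ["n_normal", "n_scw", "n_other"]
    return tab.reset_index()


def _compare_conditions(sub: pd.DataFrame, alpha: float) -> Optional[dict]:
    """Compare one variable across conditions within one (pooled) line."""
    groups = {c: g["value"].to_numpy(float)
              for c, g in sub.groupby("condition", sort=True)}
    groups = {c: v for c, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        return None
    if len(groups) == 2:
        (na, xa), (nb, xb) = sorted(groups.items())
        res = st.two_sample_ttest(xa, xb)
        res.groups = [na, nb]
    else:
        res = st.oneway_anova_tukey(groups)
    d = res.to_dict()
    d["significant"] = bool(res.p_value < alpha)
    d["group_means"] = {c: float(np.mean(v)) for c, v in sorted(groups.items())}
    d["group_n"] = {c: int(v.size) for c, v in sorted(groups.items())}
    return d


def build_report(measurements: pd.DataFrame,
                 classifications: Optional[pd.DataFrame] = None,
                 spark_summaries: Optional[dict] = None,
                 rhythm: Optional[dict] = None,
                 expression: Optional[st.ExpressionTable] = None,
                 alpha: float = 0.05) -> dict:
    """Assemble the cohort report.

    ``measurements`` is the long-format table (cell_id, line, condition,
    variable, value).  Rows whose line or condition falls outside the closed
    vocabularies are dropped and listed.  For every variable the line-pooling
    rule is applied, then conditions are compared per (pooled) group with a
    t-test (2 conditions) or one-way ANOVA + Tukey HSD (>= 3).
    """
    report: dict = {"alpha": alpha, "comparisons": {}, "pooling": {}}
    if measurements is None or measurements.empty:
        report["dropped_rows"] = []
        if classifications is not None and not classifications.empty:
            report["classification_counts"] = classification_counts(
                classifications).to_dict(orient="records")
        return report

    missing = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns {sorted(missing)}")
    ok = (measurements["line"].isin(st.LINES)
          & measurements["condition"].isin(st.CONDITIONS))
    dropped = measurements.loc[~ok]
    if len(dropped):
        logger.warning("dropping %d rows with unknown line/condition",
                       len(dropped))
    report["dropped_rows"] = sorted(map(str, dropped["cell_id"].tolist()))
    mt = measurements.loc[ok]

    for variable in sorted(mt["variable"].unique()):
        pooled_tab, decisions = st.pool_lines(mt, variable, alpha=alpha)
        report["pooling"][variable] = [d.to_dict() for d in decisions]
        sub = pooled_tab[pooled_tab["variable"] == variable]
        comps = {}
        for line, g in sub.groupby("line", sort=True):
            c = _compare_conditions(g, alpha)
            if c is not None:
                c["pooled"] = line in ("control", "cpvt")
                comps[str(line)] = c
        report["comparisons"][variable] = comps

    if classifications is not None and not classifications.empty:
        report["classification_counts"] = classification_counts(
            classifications).to_dict(orient="records")
    if spark_summaries is not None:
        report["sparks"] = spark_summaries
    if rhythm is not None:
        report["rhythm"] = rhythm
    if expression is not None:
        report["expression"] = {
            "reference_gene": expression.reference_gene,
            "bin_edges": list(expression.bin_edges),
            "values": expression.table[
                ["sample", "gene", "neg_delta_ct", "heat_bin"]
            ].to_dict(orient="records"),
        }
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def report_json(report: dict) -> str:
    """Deterministic JSON rendering (sorted keys, fixed separators)."""
    return json.dumps(report, sort_keys=True, indent=2, default=_jsonable)
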