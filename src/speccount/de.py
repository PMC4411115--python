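"""Differential expression between two stages.

A protein detected in every run of one stage and no run of the other is
called stage-exclusive — differential by presence/absence, taking precedence
over any test.  Every other protein detected in either stage gets a
two-sample Student's t test (pooled variance by default, Welch by flag) on
its per-run expression values; it is differentially expressed when the
two-sided p-value falls below alpha (default 0.05, uncorrected, matching the
raw-threshold convention of spectral-count studies; Benjamini-Hochberg is
available by flag).

Degenerate variance cases are resolved rather than failed: two constant
equal groups give t = 0, p = 1; two constant unequal groups give p = 0 with
a degenerate flag, since the group difference is exact.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, ExpressionMatrix
from .errors import DesignError, ValidationError
from .overlap import DetectionTable

__all__ = [
    "DEParams",
    "DERecord",
    "TTestResult",
    "student_t_test",
    "classify_de",
    "records_to_frame",
    "de_summary",
    "format_percent",
]

NOT_DE = "not_de"
DE = "de"
EXCLUSIVE_A = "exclusive_A"
EXCLUSIVE_B = "exclusive_B"


@dataclass(frozen=True)
class DEParams:
    alpha: float = 0.05
    variant: str = "pooled"  # or "welch"
    exclusivity_mode: str = "rule"  # "rule": presence/absence; "test": t-test only
    bh_correct: bool = False

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.variant not in ("pooled", "welch"):
            raise ValidationError(f"unknown t-test variant {self.variant!r}")
        if self.exclusivity_mode not in ("rule", "test"):
            raise ValidationError(f"unknown exclusivity_mode {self.exclusivity_mode!r}")


class TTestResult(NamedTuple):
    t_stat: float
    df: float
    p_value: float
    degenerate: bool


def student_t_test(group_a: Sequence[float], group_b: Sequence[float], variant: str = "pooled") -> TTestResult:
    """Two-sided two-sample t test; pooled df = nA + nB - 2, Welch by flag."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    df = float(a.size + b.size - 2)
    if var_a == 0.0 and var_b == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0, False)
        return TTestResult(math.copysign(math.inf, a.mean() - b.mean()), df, 0.0, True)
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    if variant == "welch":
        df = float(res.df)
    return TTestResult(float(res.statistic), df, float(res.pvalue), False)


@dataclass(frozen=True)
class DERecord:
    accession: str
    mean_a: float
    mean_b: float
    t_stat: Optional[float]
    df: Optional[float]
    p_value: Optional[float]
    de_class: str
    degenerate: bool = False


def _presence(counts: CountMatrix, stage: str) -> pd.DataFrame:
    return counts.stage_columns(stage) > 0


def classify_de(
    expr: ExpressionMatrix,
    counts: CountMatrix,
    stage_a: str,
    stage_b: str,
    params: Optional[DEParams] = None,
    detection: Optional[DetectionTable] = None,
) -> list:
    """Classify each protein detected at either stage as not_de / de / exclusive.

    Run-level presence (needed for the all-vs-none exclusivity rule) comes
    from the count matrix; a precomputed :class:`DetectionTable` may be
    supplied to define "detected at a stage" (default: present in >= 1 run).
    Proteins detected in neither stage are excluded from the output.
    """
    p = params or DEParams()
    for s in (stage_a, stage_b):
        if s not in expr.design.stages:
            raise DesignError(f"unknown stage {s!r}")
    runs_a = expr.design.runs_for_stage(stage_a)
    runs_b = expr.design.runs_for_stage(stage_b)
    if len(runs_a) < 2 or len(runs_b) < 2:
        raise DesignError("both stages need at least 2 runs")

    pres_a = _presence(counts, stage_a)
    pres_b = _presence(counts, stage_b)
    if detection is not None:
        det_a = detection.stage_set(stage_a)
        det_b = detection.stage_set(stage_b)
    else:
        det_a = set(pres_a.index[pres_a.any(axis=1)])
        det_b = set(pres_b.index[pres_b.any(axis=1)])

    records = []
    for acc in expr.proteins:
        in_a, in_b = acc in det_a, acc in det_b
        if not (in_a or in_b):
            continue
        xa = expr.values.loc[acc, runs_a].to_numpy(dtype=float)
        xb = expr.values.loc[acc, runs_b].to_numpy(dtype=float)
        mean_a, mean_b = float(xa.mean()), float(xb.mean())
        if p.exclusivity_mode == "rule":
            all_a, none_a = bool(pres_a.loc[acc].all()), bool(~pres_a.loc[acc].any())
            all_b, none_b = bool(pres_b.loc[acc].all()), bool(~pres_b.loc[acc].any())
            if all_a and none_b:
                records.append(DERecord(acc, mean_a, mean_b, None, None, None, EXCLUSIVE_A))
                continue
            if all_b and none_a:
                records.append(DERecord(acc, mean_a, mean_b, None, None, None, EXCLUSIVE_B))
                continue
        res = student_t_test(xa, xb, p.variant)
        records.append(
            DERecord(acc, mean_a, mean_b, res.t_stat, res.df, res.p_value, NOT_DE, res.degenerate)
        )

    if p.bh_correct:
        tested = [r for r in records if r.p_value is not None]
        if tested:
            order = np.argsort([r.p_value for r in tested], kind="stable")
            m = len(tested)
            adj = np.empty(m)
            prev = 1.0
            ranked = [tested[i] for i in order]
            for i in range(m - 1, -1, -1):
                prev = min(prev, ranked[i].p_value * m / (i + 1))
                adj[i] = prev
            adj_map = {id(r): adj[i] for i, r in enumerate(ranked)}
            records = [
                r if r.p_value is None else DERecord(
                    r.accession, r.mean_a, r.mean_b, r.t_stat, r.df, adj_map[id(r)], r.de_class, r.degenerate
                )
                for r in records
            ]

    return [
        DERecord(r.accession, r.mean_a, r.mean_b, r.t_stat, r.df, r.p_value, DE, r.degenerate)
        if (r.de_class == NOT_DE and r.p_value is not None and r.p_value < p.alpha)
        else r
        for r in records
    ]


def records_to_frame(records: Sequence[DERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": r.accession,
                "mean_a": r.mean_a,
                "mean_b": r.mean_b,
                "t_stat": r.t_stat,
                "df": r.df,
                "p_value": r.p_value,
                "class": r.de_class,
                "degenerate": r.degenerate,
            }
            for r in records
        ]
    )


def de_summary(records: Sequence[DERecord], union_count: Optional[int] = None) -> dict:
    """Counts of DE + exclusive calls and their share of the two-stage union."""
    n_de = sum(1 for r in records if r.de_class == DE)
    n_ex = sum(1 for r in records if r.de_class in (EXCLUSIVE_A, EXCLUSIVE_B))
    total = union_count if union_count is not None else len(records)
    frac = 100.0 * (n_de + n_ex) / total if total else float("nan")
    return {
        "n_de": n_de,
        "n_exclusive": n_ex,
        "n_changed": n_de + n_ex,
        "union": total,
        "percent": frac,
        "percent_label": format_percent(frac),
    }


def format_percent(percent: float) -> str:
    """Round to one decimal and drop a trailing .0 (1.98 -> '2%', 3.53 -> '3.5%')."""
    r = round(percent, 1)
    if r == int(r):
        return f"{int(r)}%"
    return f"{r}%"
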