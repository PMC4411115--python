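"""Frequency and proportional-frequency profiles of expression values.

Expression values are binned into unit-width bins from "< -2" to "> 8":
an open bottom bin (-inf, -2), interior half-open bins [k, k+1) for
k = -2..7, and a top bin [8, +inf).  The half-open convention puts every
real value in exactly one bin; a value of exactly 8 lands in the top bin.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = ["BIN_LABELS", "BinHistogram", "bin_expression", "profile_matrix", "plot_profiles"]

_EDGES = np.arange(-2, 9)  # -2 .. 8
BIN_LABELS = ["< -2"] + [f"[{k},{k + 1})" for k in range(-2, 8)] + ["> 8"]


@dataclass(frozen=True)
class BinHistogram:
    counts: tuple
    proportions: tuple
    labels: tuple = tuple(BIN_LABELS)
    empty: bool = False  # flagged when built from no values

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_label": self.labels, "count": self.counts, "proportion": self.proportions}
        )


def bin_expression(values: Sequence[float]) -> BinHistogram:
    """Histogram of expression values over the < -2 .. > 8 bin grid."""
    arr = np.asarray(values, dtype=float)
    if arr.size and not np.isfinite(arr).all():
        raise ValueError("expression values must be finite")
    if arr.size == 0:
        z = (0,) * len(BIN_LABELS)
        return BinHistogram(z, (0.0,) * len(BIN_LABELS), empty=True)
    idx = np.digitize(arr, _EDGES)  # 0 => < -2, len(_EDGES) => >= 8
    counts = np.bincount(idx, minlength=len(BIN_LABELS))
    props = counts / arr.size
    return BinHistogram(tuple(int(c) for c in counts), tuple(float(p) for p in props))


def profile_matrix(expr: ExpressionMatrix, by: str = "stage") -> pd.DataFrame:
    """Long-form profile table, one histogram per stage (pooled runs), per run, or overall.

    ``by`` is one of ``stage`` (default; one curve per stage, runs pooled),
    ``run``, or ``all``.
    """
    frames = []
    if by == "stage":
        groups = [(s, expr.stage_columns(s).to_numpy().ravel()) for s in expr.design.stages]
    elif by == "run":
        groups = [(r, expr.values[r].to_numpy()) for r in expr.values.columns]
    elif by == "all":
        groups = [("all", expr.values.to_numpy().ravel())]
    else:
        raise ValueError(f"by must be 'stage', 'run' or 'all', got {by!r}")
    for name, vals in groups:
        df = bin_expression(vals).to_frame()
        df["group"] = name
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def plot_profiles(profile: pd.DataFrame, path, proportional: bool = False) -> None:
    """Line plot of (proportional) frequency per bin, one line per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ycol = "proportion" if proportional else "count"
    fig, ax = plt.subplots(figsize=(7, 4))
    for name, sub in profile.groupby("group", sort=False):
        ax.plot(range(len(sub)), sub[ycol].to_numpy(), marker="o", label=str(name))
    ax.set_xticks(range(len(BIN_LABELS)), BIN_LABELS, rotation=45, ha="right")
    ax.set_xlabel("protein expression value bin")
    ax.set_ylabel("proportional frequency" if proportional else "frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
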