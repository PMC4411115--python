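"""Trimmed-mean normalization of spectral counts to protein expression values.

Each run (column) is scaled so that its 4% trimmed mean — the mean after
discarding the top and bottom 2% of values — equals a fixed target of 100.
Remaining zeros (non-detections) are then set to a small value of 1 and the
whole column is log2-transformed.  The result is the "protein expression
value" used by every downstream analysis; a non-detected protein has
expression log2(1) = 0 exactly.

The trim count per tail is k = floor(n * trim_fraction_per_tail), operating
on sorted positions (standard trimmed-mean semantics), so short runs trim
nothing.  Zeros are part of the assembled column and are included in the
trimmed-mean computation by default; ``detected_only=True`` restricts the
trimmed mean to positive counts instead.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix
from .errors import DegenerateSampleError, ValidationError

__all__ = [
    "NormalizationParams",
    "trimmed_mean",
    "normalize_run",
    "log2_with_zero_rule",
    "normalize_matrix",
]


@dataclass(frozen=True)
class NormalizationParams:
    trim_fraction_per_tail: float = 0.02
    target: float = 100.0
    zero_fill: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.trim_fraction_per_tail < 0.5):
            raise ValidationError("trim_fraction_per_tail must lie in [0, 0.5)")
        if self.target <= 0:
            raise ValidationError("target must be positive")
        if self.zero_fill <= 0:
            raise ValidationError("zero_fill must be positive")


def trimmed_mean(values: Sequence[float], trim_fraction_per_tail: float = 0.02) -> float:
    """Mean after removing floor(n*f) values from each end of the sorted list."""
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise DegenerateSampleError("trimmed_mean of empty input")
    k = math.floor(n * trim_fraction_per_tail)
    if 2 * k >= n:
        raise DegenerateSampleError(f"trimming {k} per tail leaves no values (n={n})")
    return float(arr[k : n - k].mean())


def normalize_run(
    counts: Sequence[float],
    params: Optional[NormalizationParams] = None,
    detected_only: bool = False,
) -> np.ndarray:
    """Scale one run's counts so their trimmed mean equals ``params.target``.

    Zeros remain zero at this step; the zero rule applies only before the
    log transform.
    """
    p = params or NormalizationParams()
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    basis = arr[arr > 0] if detected_only else arr
    if basis.size == 0:
        raise DegenerateSampleError("run has no positive counts")
    tm = trimmed_mean(basis, p.trim_fraction_per_tail)
    if tm == 0:
        raise DegenerateSampleError("trimmed mean is zero; cannot scale run")
    return arr / tm * p.target


def log2_with_zero_rule(values: Sequence[float], params: Optional[NormalizationParams] = None) -> np.ndarray:
    """Replace zeros by ``zero_fill`` (default 1), then take log2 elementwise."""
    p = params or NormalizationParams()
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValidationError("log2_with_zero_rule requires non-negative input")
    filled = np.where(arr == 0, p.zero_fill, arr)
    return np.log2(filled)


def normalize_matrix(
    m: CountMatrix,
    params: Optional[NormalizationParams] = None,
    detected_only: bool = False,
) -> ExpressionMatrix:
    """Column-wise normalization of a count matrix to expression values."""
    p = params or NormalizationParams()
    out = {}
    for run_id in m.counts.columns:
        col = m.counts[run_id].to_numpy()
        if not (col > 0).any():
            raise DegenerateSampleError(f"run {run_id!r} has an all-zero count column")
        out[run_id] = log2_with_zero_rule(normalize_run(col, p, detected_only), p)
    df = pd.DataFrame(out, index=m.counts.index)
    return ExpressionMatrix(df, m.design)
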