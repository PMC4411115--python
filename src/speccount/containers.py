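"""Core in-memory containers for spectral-count experiments.

An experiment is a set of LC-MS/MS runs, each summarised by a protein-level
report (accession, Mascot-style protein score, spectral count, percent
coverage).  Runs are organised by developmental stage and replicate through a
:class:`SampleDesign`; counts and normalized expression values live in
pandas DataFrames wrapped by :class:`CountMatrix` / :class:`ExpressionMatrix`
so that row order (lexicographic by accession) and the run/column
correspondence are guaranteed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, ValidationError

__all__ = [
    "ProteinHit",
    "RunReport",
    "SampleDesign",
    "CountMatrix",
    "ExpressionMatrix",
]


@dataclass(frozen=True)
class ProteinHit:
    """One protein identification in one run.

    ``matches`` is the spectral count (number of interpretable MS/MS spectra
    assigned to the protein), the semi-quantitative abundance proxy the whole
    pipeline is built on.  ``score`` is identification confidence, not
    abundance.
    """

    accession: str
    description: str = ""
    score: float = 0.0
    matches: int = 0
    coverage: float = 0.0
    peptides: Optional[frozenset] = None

    def __post_init__(self):
        if not self.accession:
            raise ValidationError("accession must be non-empty")
        if self.score < 0:
            raise ValidationError(f"{self.accession}: negative score {self.score}")
        if self.matches < 0 or int(self.matches) != self.matches:
            raise ValidationError(
                f"{self.accession}: matches must be a non-negative integer, got {self.matches}"
            )
        if not (0.0 <= self.coverage <= 100.0):
            raise ValidationError(
                f"{self.accession}: coverage {self.coverage} outside [0, 100]"
            )


@dataclass(frozen=True)
class RunReport:
    """Protein-level identifications of a single LC-MS/MS run."""

    run_id: str
    stage: str
    replicate: int
    hits: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "hits", tuple(self.hits))

    def accessions(self) -> list:
        return [h.accession for h in self.hits]

    def replace_hits(self, hits: Iterable[ProteinHit]) -> "RunReport":
        return RunReport(self.run_id, self.stage, self.replicate, tuple(hits))


@dataclass(frozen=True)
class SampleDesign:
    """Ordered mapping of runs to (stage, replicate).

    Stages keep first-appearance order; every (stage, replicate) pair and
    every run_id must be unique.
    """

    runs: tuple = field(default_factory=tuple)  # of (run_id, stage, replicate)

    def __post_init__(self):
        runs = tuple((str(r), str(s), int(k)) for r, s, k in self.runs)
        object.__setattr__(self, "runs", runs)
        ids = [r for r, _, _ in runs]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate run_id in design")
        pairs = [(s, k) for _, s, k in runs]
        if len(set(pairs)) != len(pairs):
            raise DesignError("duplicate (stage, replicate) pair in design")
        if not runs:
            raise DesignError("design has no runs")

    @property
    def run_ids(self) -> list:
        return [r for r, _, _ in self.runs]

    @property
    def stages(self) -> list:
        seen: dict = {}
        for _, s, _ in self.runs:
            seen.setdefault(s, None)
        return list(seen)

    def runs_for_stage(self, stage: str) -> list:
        out = [r for r, s, _ in self.runs if s == stage]
        if not out:
            raise DesignError(f"unknown stage {stage!r}")
        return out

    def stage_of(self, run_id: str) -> str:
        for r, s, _ in self.runs:
            if r == run_id:
                return s
        raise DesignError(f"unknown run_id {run_id!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.runs, columns=["run_id", "stage", "replicate"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleDesign":
        return cls(tuple(df[["run_id", "stage", "replicate"]].itertuples(index=False, name=None)))


def _check_axes(df: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    if list(df.columns) != design.run_ids:
        missing = set(design.run_ids) - set(df.columns)
        if missing:
            raise DesignError(f"matrix lacks columns for runs {sorted(missing)}")
        df = df[design.run_ids]
    if not df.index.is_unique:
        raise ValidationError("duplicate accession rows")
    return df.sort_index()


@dataclass(frozen=True)
class CountMatrix:
    """proteins x runs integer spectral-count matrix; absence encoded as 0."""

    counts: pd.DataFrame
    design: SampleDesign

    def __post_init__(self):
        df = _check_axes(self.counts, self.design)
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValidationError("counts must be integers")
            df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        df.index.name = "accession"
        object.__setattr__(self, "counts", df)

    @property
    def proteins(self) -> list:
        return list(self.counts.index)

    def stage_columns(self, stage: str) -> pd.DataFrame:
        return self.counts[self.design.runs_for_stage(stage)]


@dataclass(frozen=True)
class ExpressionMatrix:
    """proteins x runs matrix of normalized, log2 protein expression values."""

    values: pd.DataFrame
    design: SampleDesign

    def __post_init__(self):
        df = _check_axes(self.values, self.design).astype(float)
        if not np.isfinite(df.to_numpy()).all():
            raise ValidationError("expression values must be finite")
        df.index.name = "accession"
        object.__setattr__(self, "values", df)

    @property
    def proteins(self) -> list:
        return list(self.values.index)

    def stage_columns(self, stage: str) -> pd.DataFrame:
        return self.values[self.design.runs_for_stage(stage)]
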