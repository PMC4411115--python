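"""Per-stage detection calls and n-set (Venn) overlap accounting.

A protein is detected at a stage when it appears (spectral count >= 1 after
identification filtering) in at least ``min_runs`` runs of that stage.  The
Venn summary reports per-stage sizes, pairwise and triple intersections, the
seven exclusive regions of a 3-set diagram, and all unions; the counts are
mutually consistent under inclusion-exclusion by construction.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .containers import CountMatrix, RunReport
from .errors import DesignError, ValidationError

__all__ = ["DetectionTable", "VennSummary", "call_detection", "venn_counts", "venn_from_sets", "region_members"]


@dataclass(frozen=True)
class DetectionTable:
    """proteins x stages boolean detection calls."""

    detected: pd.DataFrame  # bool, index accession, columns stages
    min_runs: int = 1

    def __post_init__(self):
        df = self.detected.astype(bool).sort_index()
        df.index.name = "accession"
        object.__setattr__(self, "detected", df)

    @property
    def stages(self) -> list:
        return list(self.detected.columns)

    def stage_set(self, stage: str) -> Set[str]:
        if stage not in self.detected.columns:
            raise DesignError(f"unknown stage {stage!r}")
        col = self.detected[stage]
        return set(col.index[col])


def call_detection(
    matrix: CountMatrix,
    reports: Optional[Sequence[RunReport]] = None,
    min_runs: int = 1,
) -> DetectionTable:
    """Call per-stage detection from the (filtered) count matrix.

    Presence in a run means a positive count; when the filtered ``reports``
    are supplied, presence means membership in that run's report instead
    (covering reported hits with zero spectral counts).
    """
    design = matrix.design
    n_per_stage = {s: len(design.runs_for_stage(s)) for s in design.stages}
    if min_runs < 1 or min_runs > min(n_per_stage.values()):
        raise ValidationError(f"min_runs must lie in [1, {min(n_per_stage.values())}]")

    if reports is not None:
        present = pd.DataFrame(False, index=matrix.counts.index, columns=design.run_ids)
        for rep in reports:
            if rep.run_id not in design.run_ids:
                raise DesignError(f"report for unknown run_id {rep.run_id!r}")
            accs = [a for a in set(rep.accessions()) if a in present.index]
            present.loc[accs, rep.run_id] = True
    else:
        present = matrix.counts > 0

    det = {}
    for stage in design.stages:
        det[stage] = present[design.runs_for_stage(stage)].sum(axis=1) >= min_runs
    return DetectionTable(pd.DataFrame(det), min_runs=min_runs)


@dataclass(frozen=True)
class VennSummary:
    """Overlap accounting for n detection sets (the contract case is n = 3)."""

    stages: tuple
    per_stage: Dict[str, int]
    pairwise: Dict[tuple, int]
    triple: Optional[int]
    regions: Dict[tuple, int]  # exclusive regions keyed by the stage subset
    unions: Dict[tuple, int]

    @property
    def total(self) -> int:
        return self.unions[tuple(self.stages)]

    def to_dict(self) -> dict:
        def k(sub):
            return "&".join(sub)

        d = {
            "stages": list(self.stages),
            "per_stage": dict(self.per_stage),
            "pairwise": {k(p): v for p, v in self.pairwise.items()},
            "regions_exclusive": {k(r) or "none": v for r, v in self.regions.items()},
            "unions": {"|".join(u): v for u, v in self.unions.items()},
            "total": self.total,
        }
        if self.triple is not None:
            d["triple"] = self.triple
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def venn_from_sets(sets: Mapping[str, Set[str]]) -> VennSummary:
    """Overlap accounting from explicit per-stage membership sets."""
    stages = tuple(sets)
    n = len(stages)
    if n < 2:
        raise ValidationError("need at least two sets")
    per_stage = {s: len(sets[s]) for s in stages}
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in itertools.combinations(stages, 2)
    }
    triple = None
    if n == 3:
        triple = len(sets[stages[0]] & sets[stages[1]] & sets[stages[2]])

    universe = set().union(*sets.values())
    regions: Dict[tuple, int] = {}
    for r in range(1, n + 1):
        for sub in itertools.combinations(stages, r):
            inside = set.intersection(*(sets[s] for s in sub)) if sub else set()
            outside = set().union(*(sets[s] for s in stages if s not in sub), set())
            regions[sub] = len(inside - outside)

    unions = {}
    for r in range(2, n + 1):
        for sub in itertools.combinations(stages, r):
            unions[sub] = len(set().union(*(sets[s] for s in sub)))
    return VennSummary(stages, per_stage, pairwise, triple, regions, unions)


def venn_counts(table: DetectionTable) -> VennSummary:
    """Venn summary of a detection table (one set per stage)."""
    return venn_from_sets({s: table.stage_set(s) for s in table.stages})


def region_members(table: DetectionTable) -> Dict[tuple, list]:
    """Sorted accession lists per exclusive Venn region (for STRING/DAVID upload)."""
    stages = table.stages
    sets = {s: table.stage_set(s) for s in stages}
    out: Dict[tuple, list] = {}
    for r in range(1, len(stages) + 1):
        for sub in itertools.combinations(stages, r):
            inside = set.intersection(*(sets[s] for s in sub))
            outside = set().union(*(sets[s] for s in stages if s not in sub), set())
            out[sub] = sorted(inside - outside)
    return out
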