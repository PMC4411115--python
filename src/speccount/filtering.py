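"""Identification filtering: score threshold and shared-peptide redundancy.

Proteins are designated hits when their Mascot-style protein score exceeds a
threshold (default 35, strict inequality).  When several proteins are
explained by exactly the same set of peptides, only the one with the greatest
percent sequence coverage is kept; ties break to the lexicographically
smallest accession so output is deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .containers import RunReport
from .errors import ValidationError

__all__ = ["FilterParams", "apply_score_threshold", "resolve_shared_peptides", "filter_report"]


@dataclass(frozen=True)
class FilterParams:
    score_threshold: float = 35.0
    strict: bool = True  # strict: keep score > threshold; else score >= threshold

    def __post_init__(self):
        if self.score_threshold < 0:
            raise ValidationError("score_threshold must be >= 0")


def apply_score_threshold(report: RunReport, params: Optional[FilterParams] = None) -> RunReport:
    """Keep hits whose score passes the threshold; order preserved."""
    p = params or FilterParams()
    if p.strict:
        kept = [h for h in report.hits if h.score > p.score_threshold]
    else:
        kept = [h for h in report.hits if h.score >= p.score_threshold]
    return report.replace_hits(kept)


def resolve_shared_peptides(report: RunReport) -> RunReport:
    """Collapse groups of hits with identical peptide sets to the best-covered one.

    Hits without peptide information pass through unchanged (the operation is
    the identity when no peptide sets are present).  Within a group the
    survivor maximises coverage, ties broken by smallest accession.
    """
    groups: dict = {}
    for h in report.hits:
        if h.peptides:
            groups.setdefault(h.peptides, []).append(h)
    losers = set()
    for members in groups.values():
        if len(members) < 2:
            continue
        winner = min(members, key=lambda h: (-h.coverage, h.accession))
        losers.update(id(h) for h in members if h is not winner)
    return report.replace_hits(h for h in report.hits if id(h) not in losers)


def filter_report(report: RunReport, params: Optional[FilterParams] = None) -> RunReport:
    """Full identification filter: score threshold then redundancy resolution."""
    return resolve_shared_peptides(apply_score_threshold(report, params))
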