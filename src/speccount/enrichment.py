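"""Local Fisher-exact / EASE-score term enrichment.

Over-representation of an uploaded gene list in each annotation term is
scored with the one-tailed hypergeometric tail P(X >= k), where k is the
number of list genes annotated to the term, n the list size, K the term's
background hits and N the background ("whole genome") size.  The EASE score
is the same tail with the list-hit count decremented by one (a conservative
jackknife: a single-gene overlap can never look enriched).  Terms passing
an EASE threshold (default 0.1) are ranked ascending and truncated to the
top N (default 10), matching the common DAVID-style report.

Annotation sets use the GMT exchange format: one term per line,
``term_id <TAB> term_name <TAB> gene1 <TAB> gene2 ...``.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple, Union

import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError

__all__ = [
    "AnnotationSets",
    "EnrichmentRecord",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "fisher_enrichment",
    "rank_terms",
    "records_to_frame",
]


@dataclass(frozen=True)
class AnnotationSets:
    """term_id -> (term_name, member genes)."""

    terms: Dict[str, Tuple[str, frozenset]]

    def __post_init__(self):
        for tid, (name, genes) in self.terms.items():
            if not genes:
                raise ValidationError(f"term {tid!r} has an empty gene set")

    def __len__(self):
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.items())


def read_gmt(path: Union[str, Path]) -> AnnotationSets:
    terms = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"GMT line needs id, name and >=1 gene: {line[:60]!r}")
        terms[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
    return AnnotationSets(terms)


def write_gmt(annotations: AnnotationSets, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for tid, (name, genes) in annotations.terms.items():
            fh.write("\t".join([tid, name, *sorted(genes)]) + "\n")


def read_gene_list(path: Union[str, Path]) -> Set[str]:
    return {ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()}


def write_gene_list(genes: Iterable[str], path: Union[str, Path]) -> None:
    Path(path).write_text("\n".join(sorted(set(genes))) + "\n")


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    term_name: str
    k: int  # list hits
    n: int  # list size
    K: int  # background hits
    N: int  # background size
    fisher_p: float
    ease_p: float
    rank: Optional[int] = None


def _upper_tail(k: int, N: int, K: int, n: int) -> float:
    # P(X >= k) for X ~ Hypergeom(N, K, n)
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_enrichment(
    gene_list: Set[str],
    background: Set[str],
    annotations: AnnotationSets,
) -> list:
    """One EnrichmentRecord per term; terms the list misses get p = 1."""
    offenders = sorted(set(gene_list) - set(background))
    if offenders:
        raise ValidationError(f"gene list not contained in background: {offenders[:10]}")
    N = len(background)
    n = len(gene_list)
    records = []
    for tid, (name, genes) in annotations.terms.items():
        term_bg = genes & background
        K = len(term_bg)
        k = len(term_bg & gene_list)
        fisher_p = _upper_tail(k, N, K, n)
        ease_p = _upper_tail(max(k - 1, 0), N, K, n)
        records.append(EnrichmentRecord(tid, name, k, n, K, N, fisher_p, ease_p))
    return records


def rank_terms(
    records: Sequence[EnrichmentRecord],
    threshold: float = 0.1,
    top_n: int = 10,
) -> list:
    """Keep ease_p < threshold, sort ascending (tie: term_id), rank 1..top_n."""
    passed = [r for r in records if r.ease_p < threshold]
    passed.sort(key=lambda r: (r.ease_p, r.term_id))
    return [replace(r, rank=i + 1) for i, r in enumerate(passed[:top_n])]


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "fisher_p": r.fisher_p,
                "ease_p": r.ease_p,
                "rank": r.rank,
            }
            for r in records
        ]
    )
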