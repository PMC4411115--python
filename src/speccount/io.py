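"""Reading and writing protein reports, designs and matrices.

Canonical on-disk formats are tab-delimited text:

* protein report: header ``accession description score matches coverage
  [peptides]`` (peptides semicolon-joined); comma dialect accepted.
* design file: ``run_id stage replicate``.
* matrices: first column ``accession``, remaining columns run ids; reals are
  written with 17 significant digits so write-then-read is lossless.

An xlsx shim (:func:`read_run_report_xlsx`) maps spreadsheet columns by name
for supplementary-table style inputs.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix, ProteinHit, RunReport, SampleDesign
from .errors import DesignError, ReportFormatError, ValidationError

__all__ = [
    "read_run_report",
    "read_run_report_xlsx",
    "read_design",
    "write_design",
    "assemble_count_matrix",
    "write_table",
    "write_count_matrix",
    "read_count_matrix",
    "write_expression_matrix",
    "read_expression_matrix",
    "write_run_report",
]

_SEPS = {"tab": "\t", "comma": ","}
MANDATORY = ("accession", "score", "matches")


def _sep(dialect: str) -> str:
    try:
        return _SEPS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_SEPS)}")


def _hits_from_frame(df: pd.DataFrame, where: str) -> tuple:
    for col in MANDATORY:
        if col not in df.columns:
            raise ReportFormatError(f"{where}: missing mandatory column {col!r}")
    hits = []
    for row in df.itertuples(index=False):
        matches = getattr(row, "matches")
        if matches < 0:
            raise ValidationError(f"{where}: negative matches for {row.accession}")
        peps = getattr(row, "peptides", None)
        if isinstance(peps, str) and peps:
            peptides = frozenset(p for p in peps.split(";") if p)
        else:
            peptides = None
        cov = getattr(row, "coverage", 0.0)
        if cov is None or (isinstance(cov, float) and math.isnan(cov)):
            cov = 0.0
        desc = getattr(row, "description", "")
        if not isinstance(desc, str):
            desc = "" if desc is None or (isinstance(desc, float) and math.isnan(desc)) else str(desc)
        hits.append(
            ProteinHit(
                accession=str(row.accession),
                description=desc,
                score=float(getattr(row, "score")),
                matches=int(matches),
                coverage=float(cov),
                peptides=peptides,
            )
        )
    return tuple(hits)


def read_run_report(
    path: Union[str, Path],
    run_id: Optional[str] = None,
    stage: str = "",
    replicate: int = 1,
    dialect: str = "tab",
) -> RunReport:
    """Parse one run's protein report; rows are kept in file order.

    The reader never deduplicates: redundancy between proteins explained by
    the same peptides is resolved later by the identification filter.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect))
    hits = _hits_from_frame(df, str(path))
    return RunReport(run_id or path.stem, stage, replicate, hits)


def read_run_report_xlsx(
    path: Union[str, Path],
    column_map: Mapping[str, str],
    run_id: Optional[str] = None,
    stage: str = "",
    replicate: int = 1,
    sheet: Union[int, str] = 0,
) -> RunReport:
    """Import a spreadsheet report, mapping columns by name.

    ``column_map`` maps canonical field names (``accession``, ``score``,
    ``matches``, optionally ``description``, ``coverage``, ``peptides``) to
    the spreadsheet's own column headers.
    """
    path = Path(path)
    raw = pd.read_excel(path, sheet_name=sheet)
    rename = {}
    for canon, actual in column_map.items():
        if actual not in raw.columns:
            raise ReportFormatError(f"{path}: spreadsheet lacks column {actual!r}")
        rename[actual] = canon
    df = raw.rename(columns=rename)
    hits = _hits_from_frame(df, str(path))
    return RunReport(run_id or path.stem, stage, replicate, hits)


def write_run_report(report: RunReport, path: Union[str, Path]) -> None:
    rows = []
    for h in report.hits:
        rows.append(
            {
                "accession": h.accession,
                "description": h.description,
                "score": h.score,
                "matches": h.matches,
                "coverage": h.coverage,
                "peptides": ";".join(sorted(h.peptides)) if h.peptides else "",
            }
        )
    pd.DataFrame(rows, columns=["accession", "description", "score", "matches", "coverage", "peptides"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_design(path: Union[str, Path], dialect: str = "tab") -> SampleDesign:
    df = pd.read_csv(path, sep=_sep(dialect))
    for col in ("run_id", "stage", "replicate"):
        if col not in df.columns:
            raise ReportFormatError(f"{path}: missing design column {col!r}")
    return SampleDesign.from_frame(df.astype({"run_id": str, "stage": str, "replicate": int}))


def write_design(design: SampleDesign, path: Union[str, Path]) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def assemble_count_matrix(reports: Sequence[RunReport], design: SampleDesign) -> CountMatrix:
    """Union per-run reports into a proteins x runs count matrix.

    A protein absent from a run gets count 0; duplicate accessions within one
    report (which the identification filter should already have resolved) have
    their spectral counts summed.  Rows are sorted lexicographically.
    """
    by_run = {}
    for rep in reports:
        if rep.run_id not in design.run_ids:
            raise DesignError(f"report for unknown run_id {rep.run_id!r}")
        if rep.run_id in by_run:
            raise DesignError(f"duplicate report for run_id {rep.run_id!r}")
        by_run[rep.run_id] = rep
    missing = [r for r in design.run_ids if r not in by_run]
    if missing:
        raise DesignError(f"no report for design runs {missing}")

    accessions = sorted({h.accession for rep in reports for h in rep.hits})
    mat = pd.DataFrame(0, index=pd.Index(accessions, name="accession"), columns=design.run_ids, dtype=np.int64)
    for run_id, rep in by_run.items():
        for h in rep.hits:
            mat.loc[h.accession, run_id] += h.matches
    return CountMatrix(mat, design)


def write_table(table, path: Union[str, Path]) -> None:
    """Tab-delimited writer for matrices and record tables.

    Reals are written with enough digits to round-trip bit-faithfully at
    double precision.
    """
    if isinstance(table, CountMatrix):
        df = table.counts.reset_index()
    elif isinstance(table, ExpressionMatrix):
        df = table.values.reset_index()
    elif isinstance(table, pd.DataFrame):
        df = table
    else:
        raise TypeError(f"cannot serialize {type(table).__name__}")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


write_count_matrix = write_table
write_expression_matrix = write_table


def _read_matrix_frame(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "accession":
        raise ReportFormatError(f"{path}: first column must be 'accession'")
    return df.set_index("accession")


def read_count_matrix(path: Union[str, Path], design: SampleDesign) -> CountMatrix:
    return CountMatrix(_read_matrix_frame(path), design)


def read_expression_matrix(path: Union[str, Path], design: SampleDesign) -> ExpressionMatrix:
    return ExpressionMatrix(_read_matrix_frame(path), design)
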