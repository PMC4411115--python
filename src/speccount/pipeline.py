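"""End-to-end pipeline: filter -> normalize -> profile -> venn -> DE -> cluster -> enrich.

Driven by a flat YAML config; every output table is written under one
directory together with a ``manifest.json`` recording input hashes, the
effective parameters and the package version, so a rerun with identical
inputs and config reproduces byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Dict, List, Optional, Union

import yaml

from . import __version__
from .containers import SampleDesign
from .de import DEParams, classify_de, de_summary, records_to_frame
from .enrichment import (
    fisher_enrichment,
    rank_terms,
    read_gene_list,
    read_gmt,
    records_to_frame as enrich_frame,
    write_gene_list,
)
from .errors import ConfigError, DesignError
from .filtering import FilterParams, filter_report
from .io import assemble_count_matrix, read_design, read_run_report, write_table
from .normalization import NormalizationParams, normalize_matrix
from .overlap import call_detection, region_members, venn_counts
from .profiles import profile_matrix
from .clustering import distance_matrix, hierarchical_cluster

__all__ = ["load_config", "run_pipeline"]

log = logging.getLogger("speccount")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a mapping")
    cfg.setdefault("_config_dir", str(Path(path).parent))
    return cfg


def _resolve(cfg: dict, value: str) -> Path:
    p = Path(value)
    if not p.is_absolute() and "_config_dir" in cfg:
        p = Path(cfg["_config_dir"]) / p
    return p


def _report_paths(cfg: dict, design: SampleDesign) -> Dict[str, Path]:
    if "reports" in cfg:
        return {rid: _resolve(cfg, p) for rid, p in cfg["reports"].items()}
    if "report_dir" in cfg:
        pattern = cfg.get("report_pattern", "report_{run_id}.tsv")
        base = _resolve(cfg, cfg["report_dir"])
        return {rid: base / pattern.format(run_id=rid) for rid in design.run_ids}
    raise ConfigError("config needs 'reports' (run_id -> path) or 'report_dir'")


def run_pipeline(config: Union[dict, str, Path], out_dir: Union[str, Path]) -> dict:
    """Execute the full analysis; returns (and writes) the output manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(name)s: %(message)s")

    design = read_design(_resolve(cfg, cfg["design"]))
    report_paths = _report_paths(cfg, design)

    de_cfg = dict(cfg.get("de", {}))
    stage_pairs = de_cfg.pop("stage_pairs", None)
    if stage_pairs is None:
        stages = design.stages
        stage_pairs = [(stages[0], s) for s in stages[1:]]
    stage_pairs = [tuple(p) for p in stage_pairs]
    for a, b in stage_pairs:  # fail fast, before any computation
        for s in (a, b):
            if s not in design.stages:
                raise DesignError(f"stage pair names unknown stage {s!r}")

    fparams = FilterParams(**cfg.get("filter", {}))
    nparams_cfg = dict(cfg.get("normalization", {}))
    detected_only = nparams_cfg.pop("detected_only", False)
    nparams = NormalizationParams(**nparams_cfg)
    dparams = DEParams(**de_cfg)
    det_cfg = cfg.get("detection", {})
    clus_cfg = cfg.get("clustering", {})
    enr_cfg = cfg.get("enrichment", {})

    inputs = {str(p): _sha256(p) for p in sorted(report_paths.values())}
    inputs[str(_resolve(cfg, cfg["design"]))] = _sha256(_resolve(cfg, cfg["design"]))

    reports = []
    for rid in design.run_ids:
        rep = read_run_report(
            report_paths[rid],
            run_id=rid,
            stage=design.stage_of(rid),
            dialect=cfg.get("dialect", "tab"),
        )
        filtered = filter_report(rep, fparams)
        log.info("filter %s: %d hits in, %d retained", rid, len(rep.hits), len(filtered.hits))
        reports.append(filtered)

    outputs: Dict[str, Path] = {}

    matrix = assemble_count_matrix(reports, design)
    outputs["counts"] = out / "counts.tsv"
    write_table(matrix, outputs["counts"])
    log.info("assemble: %d proteins x %d runs", len(matrix.proteins), len(design.run_ids))

    expr = normalize_matrix(matrix, nparams, detected_only=detected_only)
    outputs["expr"] = out / "expr.tsv"
    write_table(expr, outputs["expr"])

    prof = profile_matrix(expr, by=cfg.get("profile_by", "stage"))
    outputs["profile"] = out / "profile.tsv"
    write_table(prof, outputs["profile"])

    detection = call_detection(matrix, reports=reports, min_runs=det_cfg.get("min_runs", 1))
    venn = venn_counts(detection)
    outputs["venn"] = out / "venn.json"
    venn.to_json(outputs["venn"])
    log.info("venn: total %d proteins across %d stages", venn.total, len(venn.stages))
    for region, members in region_members(detection).items():
        name = "region_" + "_".join(region).replace(".", "")
        outputs[name] = out / f"{name}.txt"
        write_gene_list(members, outputs[name])

    annotations = read_gmt(_resolve(cfg, enr_cfg["gmt"])) if enr_cfg.get("gmt") else None
    background = (
        read_gene_list(_resolve(cfg, enr_cfg["background"]))
        if enr_cfg.get("background")
        else set(matrix.proteins)
    )

    de_summaries = {}
    for a, b in stage_pairs:
        records = classify_de(expr, matrix, a, b, dparams, detection=detection)
        tag = f"{a}_vs_{b}".replace(".", "")
        outputs[f"de_{tag}"] = out / f"de_{tag}.tsv"
        write_table(records_to_frame(records), outputs[f"de_{tag}"])
        union = len(detection.stage_set(a) | detection.stage_set(b))
        summary = de_summary(records, union_count=union)
        de_summaries[tag] = summary
        log.info(
            "de %s vs %s: %d de + %d exclusive of %d (%s)",
            a, b, summary["n_de"], summary["n_exclusive"], union, summary["percent_label"],
        )
        changed = [r.accession for r in records if r.de_class != "not_de"]
        outputs[f"de_list_{tag}"] = out / f"de_list_{tag}.txt"
        write_gene_list(changed, outputs[f"de_list_{tag}"])

        if annotations is not None:
            gene_list = set(changed) & background
            enr = rank_terms(
                fisher_enrichment(gene_list, background, annotations),
                threshold=enr_cfg.get("ease_threshold", 0.1),
                top_n=enr_cfg.get("top_n", 10),
            )
            outputs[f"enrich_{tag}"] = out / f"enrich_{tag}.tsv"
            write_table(enrich_frame(enr), outputs[f"enrich_{tag}"])
            log.info("enrich %s: %d terms pass", tag, len(enr))

    outputs["de_summary"] = out / "de_summary.json"
    with open(outputs["de_summary"], "w") as fh:
        json.dump(de_summaries, fh, indent=2, sort_keys=True)
        fh.write("\n")

    dist = distance_matrix(expr, axis=clus_cfg.get("axis", "runs"), metric=clus_cfg.get("metric", "euclidean"))
    dend = hierarchical_cluster(dist, linkage=clus_cfg.get("linkage", "complete"))
    outputs["tree"] = out / "tree.nwk"
    outputs["tree"].write_text(dend.to_newick() + "\n")
    merges = records_to_merge_frame(dend)
    outputs["merges"] = out / "merges.tsv"
    write_table(merges, outputs["merges"])

    manifest = {
        "version": __version__,
        "inputs": inputs,
        "params": {
            "filter": fparams.__dict__,
            "normalization": {**nparams.__dict__, "detected_only": detected_only},
            "detection": {"min_runs": detection.min_runs},
            "de": {**dparams.__dict__, "stage_pairs": [list(p) for p in stage_pairs]},
            "clustering": {
                "axis": clus_cfg.get("axis", "runs"),
                "metric": clus_cfg.get("metric", "euclidean"),
                "linkage": clus_cfg.get("linkage", "complete"),
            },
            "enrichment": {
                "ease_threshold": enr_cfg.get("ease_threshold", 0.1),
                "top_n": enr_cfg.get("top_n", 10),
            },
        },
        "de_summaries": de_summaries,
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in sorted(outputs.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def records_to_merge_frame(dend):
    import pandas as pd

    return pd.DataFrame(
        [{"node_i": i, "node_j": j, "height": h, "size": s} for i, j, h, s in dend.merges]
    )
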