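"""Synthetic spectral-count experiments with known ground truth.

The generator emulates a developmental time-course of 3 stages x 3 replicate
runs.  Per-protein baseline abundance is lognormal across proteins (log2
mean 3, sd 1.5, i.e. a median of ~8 spectra) and per-run counts are drawn
from a negative binomial with var = mu + dispersion * mu^2 (Poisson in the
dispersion -> 0 limit), the standard overdispersion model for counting data
with biological replicates.

Proteins belong to truth classes:

* ``conserved`` — abundant (baseline +2 log2) and flat across stages, so they
  are detected everywhere;
* ``de_up`` / ``de_down`` — the last (postnatal-like) stage's mean is shifted
  by +/- ``true_lfc`` log2 units relative to the earlier stages;
* ``exclusive`` (fraction per stage) — zero mean outside one stage; their
  baseline is floored at the abundance median so that absence in other
  stages reflects biology, not sampling depth;
* the remainder is the null class: flat, moderate abundance.

Because all systematic differences load on the last stage, the earlier
(embryonic-like) stages are more alike than either is to the last one, which
is what the clustering step is expected to recover.

Detection is modelled at the protein level only: a run's report contains a
protein when its count reaches ``detection_floor``; true hits get scores
strictly above the 35 identification threshold and decoy rows get scores
below it.  A single root seed derives per-run substreams, so adding runs
never perturbs earlier runs' draws.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import ProteinHit, RunReport, SampleDesign
from .enrichment import AnnotationSets
from .errors import ConfigError

__all__ = ["SimConfig", "generate_experiment", "generate_annotations", "write_experiment"]

DEFAULT_STAGES = ("E13.5", "E15.5", "P1")


@dataclass(frozen=True)
class SimConfig:
    n_stages: int = 3
    runs_per_stage: int = 3
    n_proteins: int = 2000
    class_fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "conserved": 0.15,
            "de_up": 0.05,
            "de_down": 0.05,
            "exclusive_per_stage": 0.05,
        }
    )
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.5
    true_lfc: float = 3.0
    dispersion: float = 0.2
    detection_floor: int = 1
    score_params: Dict[str, float] = field(
        default_factory=lambda: {
            "hit_mean": 80.0,
            "hit_sd": 15.0,
            "decoy_rate": 0.1,
            "decoy_low": 5.0,
            "decoy_high": 35.0,
        }
    )
    stage_labels: Optional[Tuple[str, ...]] = None
    seed: int = 0

    def __post_init__(self):
        if self.runs_per_stage < 2:
            raise ConfigError("runs_per_stage must be >= 2")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        fr = self.class_fractions
        total = (
            fr.get("conserved", 0.0)
            + fr.get("de_up", 0.0)
            + fr.get("de_down", 0.0)
            + fr.get("exclusive_per_stage", 0.0) * self.n_stages
        )
        if any(v < 0 or v > 1 for v in fr.values()) or total > 1.0 + 1e-12:
            raise ConfigError("class fractions must lie in [0,1] and sum to <= 1")
        labels = self.stage_labels
        if labels is None:
            labels = DEFAULT_STAGES if self.n_stages == 3 else tuple(f"S{i + 1}" for i in range(self.n_stages))
        if len(labels) != self.n_stages:
            raise ConfigError("stage_labels length must equal n_stages")
        object.__setattr__(self, "stage_labels", tuple(labels))

    @property
    def stages(self) -> Tuple[str, ...]:
        return self.stage_labels


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, *key])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and var mu + dispersion*mu^2 (Poisson at 0)."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if dispersion == 0:
        out[pos] = rng.poisson(mu[pos])
        return out
    r = 1.0 / dispersion
    p = r / (r + mu[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def _truth_table(config: SimConfig) -> pd.DataFrame:
    n = config.n_proteins
    fr = config.class_fractions
    n_cons = round(fr.get("conserved", 0.0) * n)
    n_up = round(fr.get("de_up", 0.0) * n)
    n_down = round(fr.get("de_down", 0.0) * n)
    n_excl = round(fr.get("exclusive_per_stage", 0.0) * n)

    classes: List[str] = []
    classes += ["conserved"] * n_cons
    classes += ["de_up"] * n_up
    classes += ["de_down"] * n_down
    for s in range(config.n_stages):
        classes += [f"exclusive_{config.stages[s]}"] * n_excl
    if len(classes) > n:
        raise ConfigError("class fractions allocate more proteins than n_proteins")
    classes += ["null"] * (n - len(classes))

    width = len(str(n))
    accessions = [f"P{i + 1:0{width}d}" for i in range(n)]
    rng = _rng(config.seed, 0)
    base_log2 = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)

    rows = []
    for acc, cls, b in zip(accessions, classes, base_log2):
        mus = {}
        for si, stage in enumerate(config.stages):
            log2mu = b
            if cls == "conserved":
                log2mu = b + 2.0
            elif cls == "de_up" and si == config.n_stages - 1:
                log2mu = b + config.true_lfc
            elif cls == "de_down" and si == config.n_stages - 1:
                log2mu = b - config.true_lfc
            if cls.startswith("exclusive_"):
                log2mu = max(b, config.baseline_log2_mean)
            mu = float(2.0**log2mu)
            if cls.startswith("exclusive_") and stage != cls[len("exclusive_") :]:
                mu = 0.0
            mus[stage] = mu
        first, last = config.stages[0], config.stages[-1]
        if mus[first] > 0 and mus[last] > 0:
            lfc = float(np.log2(mus[last] / mus[first]))
        else:
            lfc = float("nan")
        rows.append({"accession": acc, "class": cls, **{f"mu_{s}": mus[s] for s in config.stages}, "true_lfc": lfc})
    return pd.DataFrame(rows).set_index("accession")


def generate_experiment(config: SimConfig) -> Tuple[List[RunReport], SampleDesign, pd.DataFrame]:
    """Draw a full experiment: per-run reports, the design, and the truth table."""
    truth = _truth_table(config)
    design = SampleDesign(
        tuple(
            (f"{stage}_r{rep}", stage, rep)
            for stage in config.stages
            for rep in range(1, config.runs_per_stage + 1)
        )
    )
    sp = config.score_params
    reports = []
    for si, stage in enumerate(config.stages):
        mu = truth[f"mu_{stage}"].to_numpy()
        for rep in range(1, config.runs_per_stage + 1):
            rng = _rng(config.seed, 1, si, rep)
            counts = _nb_draw(rng, mu, config.dispersion)
            detected = counts >= config.detection_floor
            scores = np.maximum(
                rng.normal(sp["hit_mean"], sp["hit_sd"], size=counts.size), 35.0 + 1e-3
            )
            coverages = rng.uniform(5.0, 60.0, size=counts.size)
            hits = [
                ProteinHit(
                    accession=acc,
                    description=f"synthetic {cls} protein",
                    score=float(sc),
                    matches=int(c),
                    coverage=float(round(cov, 2)),
                )
                for acc, cls, c, sc, cov, ok in zip(
                    truth.index, truth["class"], counts, scores, coverages, detected
                )
                if ok
            ]
            n_decoys = int(round(sp.get("decoy_rate", 0.0) * config.n_proteins))
            for d in range(n_decoys):
                hits.append(
                    ProteinHit(
                        accession=f"DECOY_{stage}_r{rep}_{d + 1:04d}",
                        description="synthetic sub-threshold identification",
                        score=float(rng.uniform(sp["decoy_low"], sp["decoy_high"])),
                        matches=int(rng.integers(1, 4)),
                        coverage=float(round(rng.uniform(1.0, 10.0), 2)),
                    )
                )
            reports.append(RunReport(f"{stage}_r{rep}", stage, rep, tuple(hits)))
    return reports, design, truth


def generate_annotations(
    truth: pd.DataFrame,
    n_terms: int = 20,
    enriched_class: str = "de_up",
    enrichment_factor: float = 10.0,
    seed: int = 0,
    term_size: int = 50,
) -> AnnotationSets:
    """Random gene sets over the truth universe, one enriched for a class.

    The designated first term samples members of ``enriched_class`` with
    ``enrichment_factor`` times the background inclusion weight; all other
    terms are uniform draws, so they carry no signal.
    """
    if enrichment_factor < 1:
        raise ConfigError("enrichment_factor must be >= 1")
    classes = truth["class"].astype(str)
    in_class = (classes == enriched_class) | classes.str.startswith(enriched_class)
    if not in_class.any():
        raise ConfigError(f"class {enriched_class!r} absent from truth table")
    genes = np.array(truth.index)
    rng = _rng(seed, 7)
    terms = {}
    m = min(term_size, len(genes))
    w = np.where(in_class.to_numpy(), enrichment_factor, 1.0)
    w = w / w.sum()
    members = rng.choice(genes, size=m, replace=False, p=w)
    terms["T0001"] = (f"enriched_for_{enriched_class}", frozenset(members))
    for t in range(1, n_terms):
        members = rng.choice(genes, size=m, replace=False)
        terms[f"T{t + 1:04d}"] = (f"random_term_{t + 1}", frozenset(members))
    return AnnotationSets(terms)


def write_experiment(
    reports: Sequence[RunReport],
    design: SampleDesign,
    truth: pd.DataFrame,
    out_dir,
    annotations: Optional[AnnotationSets] = None,
) -> Dict[str, Path]:
    """Write per-run report TSVs, the design, the truth table and optional GMT."""
    from .enrichment import write_gmt
    from .io import write_design, write_run_report

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for rep in reports:
        p = out_dir / f"report_{rep.run_id}.tsv"
        write_run_report(rep, p)
        paths[f"report_{rep.run_id}"] = p
    write_design(design, out_dir / "design.tsv")
    paths["design"] = out_dir / "design.tsv"
    truth.reset_index().to_csv(out_dir / "truth.tsv", sep="\t", index=False, float_format="%.17g")
    paths["truth"] = out_dir / "truth.tsv"
    if annotations is not None:
        write_gmt(annotations, out_dir / "annotations.gmt")
        paths["annotations"] = out_dir / "annotations.gmt"
    return paths
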