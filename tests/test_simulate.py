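import numpy as np
import pandas as pd
import pytest

import speccount as sc
from speccount.errors import ConfigError
from speccount.filtering import filter_report
from speccount.simulate import SimConfig, generate_annotations, generate_experiment


class TestDeterminism:
    def test_same_seed_identical_reports(self):
        cfg = SimConfig(seed=42, n_proteins=200)
        r1, d1, t1 = generate_experiment(cfg)
        r2, d2, t2 = generate_experiment(cfg)
        assert d1 == d2
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seeds_differ(self):
        a, _, _ = generate_experiment(SimConfig(seed=1, n_proteins=200))
        b, _, _ = generate_experiment(SimConfig(seed=2, n_proteins=200))
        assert a != b

    def test_adding_runs_preserves_earlier_draws(self):
        base = generate_experiment(SimConfig(seed=5, n_proteins=100))[0]
        wider = generate_experiment(SimConfig(seed=5, n_proteins=100, runs_per_stage=4))[0]
        by_run_base = {r.run_id: r for r in base}
        by_run_wider = {r.run_id: r for r in wider}
        for rid, rep in by_run_base.items():
            assert by_run_wider[rid] == rep


class TestConfigValidation:
    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(class_fractions={"conserved": 0.9, "de_up": 0.5})
        with pytest.raises(ConfigError):
            SimConfig(class_fractions={"conserved": -0.1})

    def test_single_replicate_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(runs_per_stage=1)

    def test_stage_labels_default_to_developmental_names(self):
        assert SimConfig().stages == ("E13.5", "E15.5", "P1")
        assert SimConfig(n_stages=4).stages == ("S1", "S2", "S3", "S4")


class TestCountModel:
    def test_no_effect_classes_and_no_floor_fill_every_run(self):
        cfg = SimConfig(
            seed=3,
            n_proteins=150,
            dispersion=0.0,
            detection_floor=0,
            class_fractions={"conserved": 0.5},
            score_params={"hit_mean": 80, "hit_sd": 10, "decoy_rate": 0.0,
                          "decoy_low": 5, "decoy_high": 35},
        )
        reports, design, truth = generate_experiment(cfg)
        for rep in reports:
            assert len(rep.hits) == cfg.n_proteins
        filtered = [filter_report(r) for r in reports]
        m = sc.assemble_count_matrix(filtered, design)
        det = sc.call_detection(m, reports=filtered)
        venn = sc.venn_counts(det)
        assert venn.regions[tuple(design.stages)] == cfg.n_proteins

    def test_true_hit_scores_always_pass_threshold(self):
        reports, _, _ = generate_experiment(SimConfig(seed=9, n_proteins=300))
        for rep in reports:
            true_hits = [h for h in rep.hits if not h.accession.startswith("DECOY")]
            assert all(h.score > 35.0 for h in true_hits)
            decoys = [h for h in rep.hits if h.accession.startswith("DECOY")]
            assert decoys and all(h.score < 35.0 for h in decoys)

    def test_negative_binomial_moments(self):
        cfg = SimConfig(
            seed=13,
            n_proteins=6000,
            baseline_log2_sd=0.0,  # every protein at mu = 2^3 = 8
            dispersion=0.3,
            class_fractions={},
            detection_floor=0,
            score_params={"hit_mean": 80, "hit_sd": 10, "decoy_rate": 0.0,
                          "decoy_low": 5, "decoy_high": 35},
        )
        reports, design, _ = generate_experiment(cfg)
        counts = np.array([h.matches for h in reports[0].hits], dtype=float)
        mu = 8.0
        var = mu + cfg.dispersion * mu**2  # 27.2
        assert counts.mean() == pytest.approx(mu, rel=0.05)
        assert counts.var() == pytest.approx(var, rel=0.10)

    def test_exclusive_means_zero_outside_their_stage(self):
        _, _, truth = generate_experiment(SimConfig(seed=4, n_proteins=300))
        for stage in ("E13.5", "E15.5", "P1"):
            sub = truth[truth["class"] == f"exclusive_{stage}"]
            assert len(sub) > 0
            for other in ("E13.5", "E15.5", "P1"):
                col = sub[f"mu_{other}"]
                assert (col > 0).all() if other == stage else (col == 0).all()


class TestTruthRecovery:
    def test_stage_exclusives_recovered_by_classifier(self):
        cfg = SimConfig(seed=7, n_proteins=500,
                        class_fractions={"exclusive_per_stage": 0.2})
        reports, design, truth = generate_experiment(cfg)
        filtered = [filter_report(r) for r in reports]
        m = sc.assemble_count_matrix(filtered, design)
        expr = sc.normalize_matrix(m)
        s1, s2 = design.stages[0], design.stages[1]
        records = {r.accession: r for r in sc.classify_de(expr, m, s1, s2)}
        excl = truth.index[truth["class"] == f"exclusive_{s1}"]
        assert len(excl) == 100
        hit = sum(1 for a in excl if a in records and records[a].de_class == "exclusive_A")
        assert hit >= 95

    def test_null_de_rate_stays_calibrated(self, default_experiment):
        """<=9% of flat null-class proteins are called de between the two
        stages whose true means are identical."""
        truth = default_experiment["truth"]
        m = default_experiment["matrix"]
        expr = default_experiment["expr"]
        design = default_experiment["design"]
        s1, s2 = design.stages[:2]
        null_accs = set(truth.index[truth["class"] == "null"])
        records = sc.classify_de(expr, m, s1, s2)
        null_recs = [r for r in records if r.accession in null_accs]
        de_rate = sum(1 for r in null_recs if r.de_class == "de") / len(null_recs)
        assert de_rate <= 0.09

    def test_large_fold_changes_recovered_at_low_dispersion(self):
        """Proteins with |log2 FC| = 3 at dispersion 0.1 and n=3 are mostly
        classed de or exclusive."""
        cfg = SimConfig(seed=2, dispersion=0.1)
        reports, design, truth = generate_experiment(cfg)
        filtered = [filter_report(r) for r in reports]
        m = sc.assemble_count_matrix(filtered, design)
        expr = sc.normalize_matrix(m)
        s1, s3 = design.stages[0], design.stages[-1]
        records = {r.accession: r for r in sc.classify_de(expr, m, s1, s3)}
        de_accs = truth.index[truth["class"].isin(["de_up", "de_down"])]
        recovered = sum(
            1 for a in de_accs if a in records and records[a].de_class != "not_de"
        )
        assert recovered / len(de_accs) >= 0.8


class TestAnnotations:
    def test_strongly_enriched_term_ranks_first(self):
        _, _, truth = generate_experiment(SimConfig(seed=21, n_proteins=800))
        ann = generate_annotations(truth, n_terms=15, enriched_class="de_up",
                                   enrichment_factor=20.0, seed=21)
        gene_list = set(truth.index[truth["class"] == "de_up"])
        background = set(truth.index)
        ranked = sc.rank_terms(sc.fisher_enrichment(gene_list, background, ann))
        assert ranked and ranked[0].term_id == "T0001"

    def test_unit_factor_carries_no_signal(self):
        _, _, truth = generate_experiment(SimConfig(seed=22, n_proteins=600))
        gene_list = set(truth.index[truth["class"] == "de_up"])
        background = set(truth.index)
        ps = []
        for seed in range(12):
            ann = generate_annotations(truth, n_terms=2, enrichment_factor=1.0, seed=seed)
            (r,) = [x for x in sc.fisher_enrichment(gene_list, background, ann)
                    if x.term_id == "T0001"]
            ps.append(r.fisher_p)
        # roughly uniform: not systematically tiny
        assert np.median(ps) > 0.05

    def test_absent_class_rejected(self):
        _, _, truth = generate_experiment(SimConfig(seed=23, n_proteins=100))
        with pytest.raises(ConfigError):
            generate_annotations(truth, enriched_class="no_such_class")

    def test_bad_factor_rejected(self):
        _, _, truth = generate_experiment(SimConfig(seed=23, n_proteins=100))
        with pytest.raises(ConfigError):
            generate_annotations(truth, enrichment_factor=0.5)
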