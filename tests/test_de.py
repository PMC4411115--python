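import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import speccount as sc
from speccount.containers import CountMatrix, SampleDesign
from speccount.de import (
    DE,
    EXCLUSIVE_A,
    EXCLUSIVE_B,
    NOT_DE,
    DEParams,
    classify_de,
    de_summary,
    format_percent,
    student_t_test,
)
from speccount.errors import DesignError, ValidationError
from speccount.normalization import normalize_matrix


class TestStudentT:
    def test_identical_groups(self):
        res = student_t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.t_stat == 0.0 and res.p_value == 1.0 and not res.degenerate

    def test_hand_pooled_triple(self):
        # pooled variance 1, se = sqrt(2/3), t = -10*sqrt(3/2) = -sqrt(150)
        res = student_t_test([0.0, 1.0, 2.0], [10.0, 11.0, 12.0])
        assert res.t_stat == pytest.approx(-math.sqrt(150.0), rel=1e-12)
        assert res.df == 4
        assert res.p_value == pytest.approx(2.0 * stats.t.sf(math.sqrt(150.0), 4), rel=1e-9)
        assert res.p_value == pytest.approx(2.552e-4, rel=1e-3)

    def test_degenerate_constant_unequal_groups(self):
        res = student_t_test([5.0, 5.0, 5.0], [7.0, 7.0, 7.0])
        assert res.p_value == 0.0 and res.degenerate

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            student_t_test([1.0], [2.0, 3.0])

    def test_welch_uses_satterthwaite_df(self):
        a, b = [0.0, 1.0, 2.0, 4.0], [10.0, 11.0, 15.0]
        res = student_t_test(a, b, variant="welch")
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t_stat == pytest.approx(ref.statistic)
        assert res.df == pytest.approx(ref.df)
        assert res.df != len(a) + len(b) - 2


def two_stage_matrix(rows):
    """rows: accession -> 6 counts, runs a1 a2 a3 b1 b2 b3."""
    design = SampleDesign(
        (("a1", "A", 1), ("a2", "A", 2), ("a3", "A", 3),
         ("b1", "B", 1), ("b2", "B", 2), ("b3", "B", 3))
    )
    df = pd.DataFrame.from_dict(rows, orient="index", columns=design.run_ids)
    df.index.name = "accession"
    return CountMatrix(df, design)


class TestClassifyDE:
    def test_all_versus_none_is_exclusive(self):
        m = two_stage_matrix({"PX": [8, 9, 10, 0, 0, 0], "REF": [20, 20, 20, 20, 20, 20]})
        expr = normalize_matrix(m)
        records = {r.accession: r for r in classify_de(expr, m, "A", "B")}
        assert records["PX"].de_class == EXCLUSIVE_A

    def test_swapping_stages_mirrors_classes_and_keeps_p(self):
        m = two_stage_matrix(
            {
                "PX": [8, 9, 10, 0, 0, 0],
                "PY": [0, 0, 0, 5, 6, 7],
                "PZ": [3, 9, 27, 30, 41, 55],
                "REF": [20, 21, 20, 20, 19, 20],
            }
        )
        expr = normalize_matrix(m)
        fwd = {r.accession: r for r in classify_de(expr, m, "A", "B")}
        rev = {r.accession: r for r in classify_de(expr, m, "B", "A")}
        assert fwd["PX"].de_class == EXCLUSIVE_A and rev["PX"].de_class == EXCLUSIVE_B
        assert fwd["PY"].de_class == EXCLUSIVE_B and rev["PY"].de_class == EXCLUSIVE_A
        assert rev["PZ"].t_stat == pytest.approx(-fwd["PZ"].t_stat)
        assert rev["PZ"].p_value == pytest.approx(fwd["PZ"].p_value)
        assert rev["PZ"].de_class == fwd["PZ"].de_class

    def test_alpha_threshold_is_strict(self):
        m = two_stage_matrix({"PZ": [3, 9, 27, 30, 41, 55], "REF": [20, 20, 21, 20, 20, 19]})
        expr = normalize_matrix(m)
        (rec,) = [r for r in classify_de(expr, m, "A", "B") if r.accession == "PZ"]
        p = rec.p_value
        just_above = classify_de(expr, m, "A", "B", DEParams(alpha=min(p * 1.01, 0.999)))
        just_below = classify_de(expr, m, "A", "B", DEParams(alpha=p * 0.99))
        assert {r.accession: r.de_class for r in just_above}["PZ"] == DE
        assert {r.accession: r.de_class for r in just_below}["PZ"] == NOT_DE

    def test_undetected_in_both_stages_excluded(self):
        m = two_stage_matrix({"GONE": [0, 0, 0, 0, 0, 0], "REF": [20, 20, 20, 20, 20, 20]})
        expr = normalize_matrix(m)
        assert "GONE" not in {r.accession for r in classify_de(expr, m, "A", "B")}

    def test_partial_detection_is_tested_not_exclusive(self):
        m = two_stage_matrix({"PP": [8, 0, 10, 0, 0, 0], "REF": [20, 20, 20, 20, 20, 20]})
        expr = normalize_matrix(m)
        records = {r.accession: r for r in classify_de(expr, m, "A", "B")}
        assert records["PP"].de_class in (DE, NOT_DE)
        assert records["PP"].p_value is not None

    def test_exclusivity_mode_test_uses_t_machinery_only(self):
        m = two_stage_matrix({"PX": [8, 9, 10, 0, 0, 0], "REF": [20, 20, 20, 21, 20, 20]})
        expr = normalize_matrix(m)
        records = {
            r.accession: r
            for r in classify_de(expr, m, "A", "B", DEParams(exclusivity_mode="test"))
        }
        assert records["PX"].de_class in (DE, NOT_DE)

    def test_unknown_stage_rejected(self):
        m = two_stage_matrix({"P": [1, 2, 3, 4, 5, 6]})
        expr = normalize_matrix(m)
        with pytest.raises(DesignError):
            classify_de(expr, m, "A", "Z")

    def test_bh_correction_weakly_raises_p(self):
        rows = {f"P{i}": list(np.arange(1, 7) * (i + 1)) for i in range(10)}
        m = two_stage_matrix(rows)
        expr = normalize_matrix(m)
        raw = {r.accession: r.p_value for r in classify_de(expr, m, "A", "B")}
        adj = {
            r.accession: r.p_value
            for r in classify_de(expr, m, "A", "B", DEParams(bh_correct=True))
        }
        assert all(adj[a] >= raw[a] - 1e-15 for a in raw)


class TestSummary:
    @pytest.mark.parametrize(
        "n_changed,union,label", [(39, 1966, "2%"), (71, 2011, "3.5%")]
    )
    def test_percent_formatting_matches_convention(self, n_changed, union, label):
        assert format_percent(100.0 * n_changed / union) == label

    def test_summary_counts_its_own_records(self, default_experiment):
        m = default_experiment["matrix"]
        expr = default_experiment["expr"]
        det = default_experiment["detection"]
        stages = default_experiment["design"].stages
        records = classify_de(expr, m, stages[0], stages[1], detection=det)
        union = len(det.stage_set(stages[0]) | det.stage_set(stages[1]))
        s = de_summary(records, union_count=union)
        assert s["n_changed"] == s["n_de"] + s["n_exclusive"]
        assert s["percent"] == pytest.approx(100.0 * s["n_changed"] / union)
        assert len(records) == union
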