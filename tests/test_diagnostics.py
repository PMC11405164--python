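"""ROC/AUROC/Youden, confusion metrics, stratification and reallocation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilkit.diagnostics import (
    DiagnosticModel,
    auroc,
    classification_metrics,
    evaluate_table,
    reorganize_low_scores,
    roc_curve,
    stratify_by_grade,
    youden_cutoff,
)


def pair_count_auroc(cases, controls) -> float:
    """Independent oracle: P(case > control) + 0.5 P(tie), by enumeration."""
    wins = ties = 0
    for c in cases:
        for n in controls:
            if c > n:
                wins += 1
            elif c == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def table(cases, controls, grades=None) -> pd.DataFrame:
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(len(cases) + len(controls))],
        "score": list(cases) + list(controls),
        "label": ["case"] * len(cases) + ["control"] * len(controls),
    })
    if grades is not None:
        df["grade"] = grades
    return df


class TestROC:
    def test_perfect_separation(self):
        roc = roc_curve([2.0, 3.0, 1.0, 1.5], ["case", "case", "control", "control"])
        assert auroc(roc) == pytest.approx(1.0)
        # curve passes through (fpr=0, sens=1)
        hit = roc[(roc["fpr"] == 0) & (roc["sensitivity"] == 1)]
        assert not hit.empty

    def test_exchangeable_scores(self):
        roc = roc_curve([1.0, 2.0, 1.0, 2.0], ["case", "case", "control", "control"])
        assert auroc(roc) == pytest.approx(0.5)

    def test_worked_example_seven_ninths(self):
        roc = roc_curve(
            [1.2, 1.5, 2.0, 1.0, 1.3, 1.4],
            ["case"] * 3 + ["control"] * 3,
        )
        assert auroc(roc) == pytest.approx(7 / 9, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], ["case", "case"])

    def test_trapezoid_equals_pair_counting(self, rng):
        for _ in range(50):
            n_c, n_n = rng.integers(1, 30, size=2)
            cases = np.round(rng.uniform(1, 3, n_c), 2)  # rounding forces ties
            ctrls = np.round(rng.uniform(1, 3, n_n), 2)
            labels = ["case"] * n_c + ["control"] * n_n
            got = auroc(roc_curve(np.concatenate([cases, ctrls]), labels))
            assert got == pytest.approx(pair_count_auroc(cases, ctrls), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.uniform(1, 3, 60)
        labels = np.where(rng.random(60) < 0.5, "case", "control")
        if len(set(labels)) < 2:
            labels[:2] = ["case", "control"]
        got = auroc(roc_curve(scores, labels))
        assert got == pytest.approx(roc_auc_score(labels == "case", scores), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.uniform(1, 3, 40)
        labels = np.array(["case"] * 20 + ["control"] * 20)
        a1 = auroc(roc_curve(scores, labels))
        a2 = auroc(roc_curve(np.exp(scores), labels))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_duplicating_every_record_preserves_polyline(self):
        scores = [1.2, 1.5, 2.0, 1.0, 1.3, 1.4]
        labels = ["case"] * 3 + ["control"] * 3
        r1 = roc_curve(scores, labels)
        r2 = roc_curve(scores * 2, labels * 2)
        pd.testing.assert_frame_equal(r1, r2)
        # and a duplicated single record never introduces a new threshold
        r3 = roc_curve(scores + [1.5], labels + ["case"])
        assert set(r3["threshold"]) == set(r1["threshold"])


class TestYouden:
    def test_worked_example(self):
        roc = roc_curve(
            [1.2, 1.5, 2.0, 1.0, 1.3, 1.4],
            ["case"] * 3 + ["control"] * 3,
        )
        cut, sens, spec = youden_cutoff(roc)
        assert cut == pytest.approx(1.5)
        assert sens == pytest.approx(2 / 3)
        assert spec == pytest.approx(1.0)

    def test_perfect_separation_reports_min_case_score(self):
        roc = roc_curve([2.0, 3.0, 1.0, 1.5], ["case", "case", "control", "control"])
        cut, sens, spec = youden_cutoff(roc)
        assert cut == pytest.approx(2.0)
        assert sens == spec == 1.0

    def test_all_equal_scores_give_zero_j(self):
        roc = roc_curve([1.0] * 4, ["case", "case", "control", "control"])
        cut, sens, spec = youden_cutoff(roc)
        assert sens + spec - 1 == pytest.approx(0.0)


class TestClassificationMetrics:
    def test_perfect_table(self):
        m = classification_metrics(50, 0, 50, 0)
        assert (m.sensitivity, m.specificity, m.accuracy, m.precision) == (1, 1, 1, 1)
        assert m.mcc == pytest.approx(1.0)

    def test_independent_table_gives_zero_mcc(self):
        assert classification_metrics(25, 25, 25, 25).mcc == pytest.approx(0.0)

    def test_hand_computed_mcc(self):
        m = classification_metrics(3, 1, 4, 2)
        assert m.mcc == pytest.approx(10 / np.sqrt(600))
        assert m.sensitivity == pytest.approx(3 / 5)
        assert m.specificity == pytest.approx(4 / 5)
        assert m.accuracy == pytest.approx(7 / 10)
        assert m.precision == pytest.approx(3 / 4)

    def test_zero_denominators_flagged(self):
        m = classification_metrics(0, 0, 5, 5)  # nothing predicted positive
        assert m.precision == 0.0
        assert m.sensitivity == 0.0
        assert "precision" in m.zero_denominator
        assert "mcc" in m.zero_denominator

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(-1, 0, 0, 1)

    def test_matches_sklearn_mcc(self, rng):
        from sklearn.metrics import matthews_corrcoef

        y = rng.integers(0, 2, 80)
        p = rng.integers(0, 2, 80)
        tp = int(np.sum((y == 1) & (p == 1)))
        fp = int(np.sum((y == 0) & (p == 1)))
        tn = int(np.sum((y == 0) & (p == 0)))
        fn = int(np.sum((y == 1) & (p == 0)))
        assert classification_metrics(tp, fp, tn, fn).mcc == pytest.approx(
            matthews_corrcoef(y, p), abs=1e-12
        )

    def test_label_prediction_swap_symmetry(self):
        # MCC is invariant under swapping y <-> prediction (transpose of table)
        m1 = classification_metrics(3, 1, 4, 2)
        m2 = classification_metrics(3, 2, 4, 1)
        assert m1.mcc == pytest.approx(m2.mcc)


class TestStratify:
    def make_graded(self, n_mild=5, n_mod=4, n_ctrl=12):
        cases = [1.2 + 0.1 * i for i in range(n_mild + n_mod)]
        grades = [1, 2] * (n_mild // 2) + [1] * (n_mild % 2) + [3, 4, 5, 3][:n_mod]
        ctrls = [1.0 + 0.01 * i for i in range(n_ctrl)]
        return table(cases, ctrls, grades=grades + [0] * n_ctrl)

    def test_strata_sizes_matched(self):
        out = stratify_by_grade(self.make_graded(), seed=3)
        assert len(out["mild"]) == 10  # 5 cases + 5 matched controls
        assert len(out["moderate"]) == 8
        for sub in out.values():
            assert (sub["label"] == "case").sum() == (sub["label"] == "control").sum()

    def test_same_seed_reproducible(self):
        a = stratify_by_grade(self.make_graded(), seed=11)
        b = stratify_by_grade(self.make_graded(), seed=11)
        pd.testing.assert_frame_equal(a["mild"], b["mild"])

    def test_insufficient_controls_refused(self):
        df = self.make_graded(n_mild=6, n_mod=0, n_ctrl=3)
        with pytest.raises(ValueError, match="replacement"):
            stratify_by_grade(df, seed=0)

    def test_empty_stratum_is_none(self):
        df = self.make_graded(n_mild=4, n_mod=0)
        out = stratify_by_grade(df, seed=0)
        assert out["moderate"] is None


class TestReorganize:
    def test_half_of_low_scores_moved(self):
        cases = [1.0, 1.05, 1.1, 1.15] + [2.0] * 12  # quartile cutoff ~1.19
        df = table(cases, [1.0] * 16)
        out, info = reorganize_low_scores(df, seed=5)
        assert info["n_low"] == 4
        assert info["n_moved"] == 2
        assert len(out) == len(df)
        assert (out["label"] == "control").sum() == 16 + 2

    def test_single_low_case_moves_nothing(self):
        # q25 of {1.0, 2.0} is 1.25 (type-7): only one case at/below it
        df = table([1.0, 2.0], [1.0] * 4)
        out, info = reorganize_low_scores(df, seed=5)
        assert info["n_low"] == 1 and info["n_moved"] == 0
        pd.testing.assert_series_equal(out["label"], df["label"])

    def test_moved_records_become_grade_zero(self):
        cases = [1.0, 1.02, 1.04, 1.06] + [2.0] * 12
        df = table(cases, [1.0] * 16, grades=[1] * 16 + [0] * 16)
        out, info = reorganize_low_scores(df, seed=1)
        moved = out[(out["label"] == "control") & (out["subject_id"].isin(df["subject_id"][:16]))]
        assert (moved["grade"] == 0).all()

    def test_total_count_invariant_across_seeds(self):
        df = table([1.0, 1.1, 1.2, 1.3, 2.0, 2.5], [1.0] * 6)
        for seed in range(10):
            out, info = reorganize_low_scores(df, seed=seed)
            assert len(out) == 12
            assert 0 <= info["n_moved"] == info["n_low"] // 2

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ValueError):
            reorganize_low_scores(table([2.0], [1.0]), quantile=1.5)


class TestDiagnosticModel:
    def test_fit_reports_consistent_metrics(self):
        df = table([1.2, 1.5, 2.0], [1.0, 1.3, 1.4])
        res = DiagnosticModel(df).fit()
        assert res.report.auroc == pytest.approx(7 / 9)
        assert res.report.youden_cutoff == pytest.approx(1.5)
        tp, fp, tn, fn = res.confusion
        assert (tp, fp, tn, fn) == (2, 0, 3, 1)
        assert res.report.sensitivity_pct == pytest.approx(100 * 2 / 3)
        assert "AUROC" in res.summary()

    def test_evaluate_table_rows(self):
        rng = np.random.default_rng(0)
        cases = rng.uniform(1.2, 3.0, 20)
        ctrls = rng.uniform(1.0, 1.25, 20)
        grades = list(rng.integers(1, 3, 10)) + list(rng.integers(3, 6, 10))
        df = table(cases, ctrls, grades=grades + [0] * 20)
        rows = evaluate_table(df, seed=2)
        assert set(rows) == {"overall", "mild", "moderate", "reorganized"}
        assert rows["overall"].auroc > 0.9

    def test_evaluate_table_without_grades(self):
        df = table([1.5, 2.0], [1.0, 1.1])
        rows = evaluate_table(df, seed=0)
        assert set(rows) == {"overall", "reorganized"}

    def test_permuted_labels_near_chance(self, rng):
        scores = rng.uniform(1, 2, 400)
        labels = rng.permutation(["case"] * 200 + ["control"] * 200)
        res = DiagnosticModel(pd.DataFrame({"score": scores, "label": labels})).fit()
        assert abs(res.report.auroc - 0.5) < 0.1
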