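"""Weighted kappa and single-rater ICC against hand calculations and references."""

import numpy as np
import pandas as pd
import pytest

from capclean.agreement import (
    IccResult,
    RatingTable,
    icc_single,
    linear_weighted_kappa,
    linear_weights,
    per_fold_kappa_report,
    quadratic_weights,
    weighted_kappa,
)


def _table(scores, raters=("r1", "r2")):
    scores = np.asarray(scores)
    n = scores.shape[0]
    return RatingTable(
        scores=scores,
        frame_ids=tuple(f"f{i}" for i in range(n)),
        video_ids=tuple(f"v{i % 4}" for i in range(n)),
        raters=raters,
    )


class TestWeights:
    def test_linear_weights_structure(self):
        w = linear_weights(4)
        assert np.allclose(np.diag(w), 1.0)
        assert np.allclose(w, w.T)
        assert w[0, 3] == 0.0 and w[0, 1] == pytest.approx(2 / 3)


class TestWeightedKappa:
    def test_perfect_agreement(self, rng):
        a = rng.integers(1, 5, 40)
        assert linear_weighted_kappa(a, a).kappa == pytest.approx(1.0)

    def test_hand_computed_minus_one(self):
        # p_o = 2/3, p_e = 5/6 -> kappa = (2/3 - 5/6)/(1/6) = -1
        res = linear_weighted_kappa(np.array([1, 2]), np.array([2, 1]), k=4)
        assert res.kappa == pytest.approx(-1.0)

    def test_symmetry(self, rng):
        a = rng.integers(1, 5, 60)
        b = rng.integers(1, 5, 60)
        assert linear_weighted_kappa(a, b).kappa == pytest.approx(
            linear_weighted_kappa(b, a).kappa
        )

    def test_invariant_under_category_order_reversal(self, rng):
        a = rng.integers(1, 5, 60)
        b = rng.integers(1, 5, 60)
        assert linear_weighted_kappa(5 - a, 5 - b).kappa == pytest.approx(
            linear_weighted_kappa(a, b).kappa
        )

    def test_identity_weights_recover_unweighted_cohen(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(1, 5, 80)
        b = np.clip(a + rng.integers(-1, 2, 80), 1, 4)
        res = weighted_kappa(a, b, k=4, weights=np.eye(4))
        assert res.kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_matches_sklearn_linear_weights(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            n = int(rng.integers(10, 120))
            a = rng.integers(1, 5, n)
            b = np.clip(a + rng.integers(-2, 3, n), 1, 4)
            mine = linear_weighted_kappa(a, b).kappa
            ref = cohen_kappa_score(a, b, labels=[1, 2, 3, 4], weights="linear")
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_standard_error_matches_statsmodels(self, rng):
        from statsmodels.stats.inter_rater import cohens_kappa

        for _ in range(10):
            n = int(rng.integers(30, 120))
            a = rng.integers(1, 5, n)
            b = np.clip(a + rng.integers(-1, 2, n), 1, 4)
            table = np.zeros((4, 4))
            np.add.at(table, (a - 1, b - 1), 1)
            ref = cohens_kappa(table, wt="linear")
            mine = linear_weighted_kappa(a, b)
            assert mine.kappa == pytest.approx(ref.kappa, abs=1e-10)
            assert mine.se == pytest.approx(np.sqrt(ref.var_kappa), abs=1e-10)

    def test_ci_brackets_point_estimate(self, rng):
        a = rng.integers(1, 5, 50)
        b = np.clip(a + rng.integers(-1, 2, 50), 1, 4)
        res = linear_weighted_kappa(a, b)
        assert res.ci95[0] <= res.kappa <= res.ci95[1]

    def test_degenerate_marginals_flagged(self):
        res = linear_weighted_kappa(np.array([2, 2, 2]), np.array([2, 2, 2]), k=4)
        assert not res.defined

    def test_input_validation(self):
        with pytest.raises(ValueError):
            linear_weighted_kappa(np.array([1, 2]), np.array([1]))
        with pytest.raises(ValueError):
            linear_weighted_kappa(np.array([0, 1]), np.array([1, 2]))

    def test_quadratic_weights_systematically_higher(self, rng):
        a = rng.integers(1, 5, 200)
        b = np.clip(a + rng.integers(-2, 3, 200), 1, 4)
        lin = linear_weighted_kappa(a, b).kappa
        quad = weighted_kappa(a, b, weights=quadratic_weights(4)).kappa
        assert quad >= lin


class TestIccSingle:
    def test_identical_columns_give_one(self, rng):
        col = rng.integers(1, 5, 20)
        t = _table(np.column_stack([col, col]))
        assert icc_single(t, "C1").icc == pytest.approx(1.0)
        assert icc_single(t, "A1").icc == pytest.approx(1.0)

    def test_hand_computed_offset_table(self):
        # rows (1,2),(2,3),(3,4): MSR=2, MSC=1.5, MSE=0
        x = np.array([[1, 2], [2, 3], [3, 4]])
        c1 = icc_single(x, "C1")
        a1 = icc_single(x, "A1")
        assert c1.icc == pytest.approx(1.0)
        assert a1.icc == pytest.approx(2 / 3)
        assert (c1.msr, c1.msc, c1.mse) == pytest.approx((2.0, 1.5, 0.0))

    @pytest.mark.parametrize("form,ping_type", [("C1", "ICC(C,1)"), ("A1", "ICC(A,1)")])
    def test_matches_pingouin_on_random_tables(self, rng, form, ping_type):
        import pingouin as pg

        worst_icc = worst_ci = 0.0
        for _ in range(50):
            n = int(rng.integers(5, 40))
            m = int(rng.integers(2, 5))
            x = rng.integers(1, 5, (n, m)).astype(float)
            if np.ptp(x) == 0:
                continue
            df = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(n), m),
                    "rater": np.tile(np.arange(m), n),
                    "score": x.ravel(),
                }
            )
            ref = pg.intraclass_corr(df, "subject", "rater", "score")
            row = ref[ref["Type"] == ping_type].iloc[0]
            mine = icc_single(x, form)
            worst_icc = max(worst_icc, abs(mine.icc - row["ICC"]))
            ci = row["CI95"]
            worst_ci = max(
                worst_ci, abs(mine.ci95[0] - ci[0]), abs(mine.ci95[1] - ci[1])
            )
        assert worst_icc < 1e-6
        # pingouin rounds its CI bounds to 2 decimals
        assert worst_ci < 5e-3

    def test_constant_table_flagged_undefined(self):
        res = icc_single(np.full((5, 3), 2.0), "A1")
        assert not res.defined

    def test_ci_brackets_point_estimate(self, rng):
        x = rng.integers(1, 5, (30, 3)).astype(float)
        for form in ("C1", "A1"):
            res = icc_single(x, form)
            assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            icc_single(np.array([[1, 2]]), "C1")


class TestRatingTable:
    def test_rejects_out_of_range_scores(self):
        with pytest.raises(ValueError):
            _table(np.array([[1, 5], [2, 2]]))

    def test_long_and_wide_loaders_agree(self, tmp_path):
        wide = pd.DataFrame(
            {
                "frame_id": ["f0", "f1", "f2"],
                "video_id": ["v0", "v0", "v1"],
                "sp1": [1, 2, 3],
                "sp2": [2, 2, 4],
            }
        )
        wide_path = tmp_path / "wide.csv"
        wide.to_csv(wide_path, index=False)
        t_wide = RatingTable.from_wide_csv(wide_path)
        long = wide.melt(
            id_vars=["frame_id", "video_id"], var_name="rater", value_name="score"
        )
        t_long = RatingTable.from_long(long)
        np.testing.assert_array_equal(np.sort(t_wide.scores, 0), np.sort(t_long.scores, 0))

    def test_incomplete_long_table_rejected(self):
        df = pd.DataFrame(
            {
                "frame_id": ["f0", "f0", "f1"],
                "video_id": ["v0", "v0", "v0"],
                "rater": ["a", "b", "a"],
                "score": [1, 2, 3],
            }
        )
        with pytest.raises(ValueError, match="incomplete"):
            RatingTable.from_long(df)


class TestPerFoldReport:
    def test_single_fold_pooled_equals_fold_value(self, rng):
        t = _table(np.column_stack([rng.integers(1, 5, 12), rng.integers(1, 5, 12)]))
        folds = {v: 0 for v in t.video_ids}
        rep = per_fold_kappa_report(t, folds)
        by_fold = rep.set_index("fold")["kappa"]
        assert by_fold["0"] == pytest.approx(by_fold["all"])

    def test_fold_relabeling_leaves_pooled_unchanged(self, rng):
        scores = np.column_stack([rng.integers(1, 5, 24), rng.integers(1, 5, 24)])
        t = _table(scores)
        videos = sorted(set(t.video_ids))
        f1 = {v: i % 2 for i, v in enumerate(videos)}
        f2 = {v: 1 - (i % 2) for i, v in enumerate(videos)}
        k1 = per_fold_kappa_report(t, f1).set_index("fold")["kappa"]["all"]
        k2 = per_fold_kappa_report(t, f2).set_index("fold")["kappa"]["all"]
        assert k1 == pytest.approx(k2)

    def test_missing_video_assignment_rejected(self, rng):
        t = _table(np.column_stack([rng.integers(1, 5, 8), rng.integers(1, 5, 8)]))
        with pytest.raises(ValueError, match="without fold"):
            per_fold_kappa_report(t, {"v0": 0})

    def test_three_raters_give_three_pairs(self, rng):
        t = _table(
            np.column_stack([rng.integers(1, 5, 12) for _ in range(3)]),
            raters=("method", "sp1", "sp2"),
        )
        folds = {v: 0 for v in t.video_ids}
        rep = per_fold_kappa_report(t, folds)
        assert rep["pair"].nunique() == 3

    def test_plot_writes_file(self, tmp_path, rng):
        from capclean.agreement import plot_fold_kappa

        t = _table(np.column_stack([rng.integers(1, 5, 16), rng.integers(1, 5, 16)]))
        folds = {v: i % 2 for i, v in enumerate(sorted(set(t.video_ids)))}
        rep = per_fold_kappa_report(t, folds)
        out = tmp_path / "kappa.png"
        plot_fold_kappa(rep, out)
        assert out.stat().st_size > 0
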