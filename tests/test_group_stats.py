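import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hs
from statsmodels.stats.multitest import multipletests

from narralex.corpus_io import RaterCodingTable
from narralex.group_stats import (
    DegenerateDataError, ancova_group_effect, bh_adjust, cohens_d,
    comparison_frame, krippendorff_alpha, levene_test, partial_correlation,
    run_comparison_battery, two_sample_t,
)


class TestLevene:
    def test_copied_sample_has_zero_statistic(self):
        x = [1.0, 2.0, 5.0, 7.0]
        W, p = levene_test(x, list(x))
        assert W == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_point_samples_equal_ranges(self):
        W, _ = levene_test([0.0, 1.0], [5.0, 6.0])
        assert W == pytest.approx(0.0, abs=1e-12)

    def test_identical_constants_degenerate(self):
        with pytest.raises(DegenerateDataError):
            levene_test([3.0, 3.0, 3.0], [3.0, 3.0])

    def test_detects_hundredfold_spread(self):
        # power check at desk scale: spread 1 vs 100, n = 50
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 50)
            y = rng.normal(0, 100, 50)
            _, p = levene_test(x, y)
            hits += p < 0.05
        assert hits >= 190  # >= 95% of 200 seeds


class TestTwoSampleT:
    def test_textbook_pooled_formula(self):
        # x={1,2,3}, y={4,5,6}: s_p^2 = 1, se = sqrt(2/3), t = -3/se, df = 4
        res = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.test_kind == "student"
        assert res.t == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0))
        assert res.df == 4.0
        assert np.sign(res.t) == np.sign(res.mean1 - res.mean2)

    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = two_sample_t(x, list(x))
        assert res.t == 0.0
        assert res.p_raw == pytest.approx(1.0)

    def test_welch_student_agree_with_equal_variance_and_n(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 30)
        student = two_sample_t(x, y, gate=0.0)   # gate 0: never Welch
        welch = two_sample_t(x, y, gate=1.01)    # gate > 1: always Welch
        assert student.test_kind == "student" and welch.test_kind == "welch"
        assert student.t == pytest.approx(welch.t, abs=1e-10)
        assert student.df == 60 - 2
        assert welch.df <= student.df + 1e-9

    def test_swapping_groups_negates_t(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0, 1, 20), rng.normal(1, 3, 25)
        ab = two_sample_t(x, y)
        ba = two_sample_t(y, x)
        assert ab.t == pytest.approx(-ba.t)
        assert ab.p_raw == pytest.approx(ba.p_raw)
        assert ab.df == pytest.approx(ba.df)

    def test_welch_branch_on_unequal_spread(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 60)
        y = rng.normal(0, 12, 60)
        res = two_sample_t(x, y)
        assert res.test_kind == "welch"
        assert res.df != int(res.df) or res.df < 118  # Satterthwaite shrinks df

    def test_double_degenerate_is_an_error(self):
        with pytest.raises(DegenerateDataError):
            two_sample_t([2.0, 2.0], [2.0, 2.0])


class TestCohensD:
    def test_zero_for_identical(self):
        x = [1.0, 2.0, 3.0]
        assert cohens_d(x, list(x)) == 0.0

    def test_one_pooled_sd_apart(self):
        x = np.array([0.0, 2.0, 4.0])
        y = x + x.std(ddof=1)
        assert cohens_d(y, x) == pytest.approx(1.0)

    def test_sign_matches_t(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(1, 1, 15), rng.normal(0, 1, 15)
        assert np.sign(cohens_d(x, y)) == np.sign(two_sample_t(x, y).t)

    def test_zero_pooled_sd_is_an_error(self):
        with pytest.raises(DegenerateDataError):
            cohens_d([1.0, 1.0], [2.0, 2.0])

    def test_planted_effect_recovered_at_scale(self):
        # direct Gaussian check of the estimator, d = 0.5, n = 200/group
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            estimates.append(cohens_d(rng.normal(0.5, 1, 200),
                                      rng.normal(0.0, 1, 200)))
        assert abs(float(np.median(estimates)) - 0.5) < 0.15


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_ties_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hs.lists(hs.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    def test_matches_reference_and_bounds(self, pvals):
        ours = bh_adjust(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        assert ours == pytest.approx(ref, abs=1e-12)
        assert np.all(ours >= np.asarray(pvals) - 1e-15)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(ours[order]) >= -1e-12)


class TestAncova:
    def test_perfect_confound_absorbed(self):
        rng = np.random.default_rng(2)
        cov = rng.normal(0, 1, 40)
        groups = ["A"] * 20 + ["B"] * 20
        res = ancova_group_effect(cov, groups, cov)
        assert res.group_effect_estimate == pytest.approx(0.0, abs=1e-10)
        assert res.covariate_estimate == pytest.approx(1.0)

    def test_planted_offset_detected(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = np.concatenate([rng.normal(2, 1, 50), rng.normal(0, 1, 50)])
            cov = rng.normal(0, 1, 100)
            res = ancova_group_effect(y, ["A"] * 50 + ["B"] * 50, cov)
            hits += res.group_effect_p < 0.05
        assert hits == 50  # d = 2 at n = 50/group: essentially certain

    def test_null_type_i_near_nominal(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = rng.normal(0, 1, 100)
            cov = rng.normal(0, 1, 100)
            res = ancova_group_effect(y, ["A"] * 50 + ["B"] * 50, cov)
            hits += res.group_effect_p < 0.05
        assert hits / n_seeds < 0.10

    def test_constant_covariate_is_an_error(self):
        with pytest.raises(DegenerateDataError):
            ancova_group_effect([1.0, 2.0, 3.0, 4.0], ["A", "A", "B", "B"],
                                [5.0, 5.0, 5.0, 5.0])


class TestPartialCorrelation:
    def test_proportional_variables(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 30)
        control = rng.normal(0, 1, 30)
        res = partial_correlation(x, 2 * x, control)
        assert res.r_partial == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_y_equal_to_control_degenerate(self):
        rng = np.random.default_rng(1)
        c = rng.normal(0, 1, 20)
        with pytest.raises(DegenerateDataError):
            partial_correlation(rng.normal(0, 1, 20), c, c)

    def test_known_trivariate_partial_correlation(self):
        # x, y share a control plus correlated residuals: r_partial = 0.3
        rng = np.random.default_rng(42)
        n = 5000
        z = rng.normal(0, 1, n)
        rho = 0.3
        e1 = rng.normal(0, 1, n)
        e2 = rho * e1 + math.sqrt(1 - rho ** 2) * rng.normal(0, 1, n)
        res = partial_correlation(z + e1, 0.5 * z + e2, z)
        assert res.r_partial == pytest.approx(0.3, abs=0.05)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            "x": rng.normal(0, 1, 60), "y": rng.normal(0, 1, 60),
            "c": rng.normal(0, 1, 60),
        })
        df["y"] += 0.4 * df["x"] + 0.3 * df["c"]
        ref = pingouin.partial_corr(df, x="x", y="y", covar="c")
        res = partial_correlation(df["x"], df["y"], df["c"])
        assert res.r_partial == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)


def _alpha_bruteforce(codes: np.ndarray) -> float:
    """Independent oracle: alpha from explicitly enumerated value pairs."""
    pairs = []
    for row in codes:
        vals = row[~np.isnan(row)]
        m = vals.size
        if m < 2:
            continue
        for i in range(m):
            for j in range(m):
                if i != j:
                    pairs.append((vals[i], vals[j], m))
    n_total = sum(1.0 / (m - 1) for _, _, m in pairs)
    d_o = sum((1.0 / (m - 1)) for a, b, m in pairs if a != b) / n_total
    # expected disagreement from the marginal value counts
    from collections import Counter

    marg = Counter()
    for a, _, m in pairs:
        marg[a] += 1.0 / (m - 1)
    d_e = sum(marg[a] * marg[b] for a in marg for b in marg if a != b) / (
        n_total * (n_total - 1))
    return 1.0 - d_o / d_e


class TestKrippendorffAlpha:
    def _table(self, codes):
        codes = np.asarray(codes, dtype=float)
        return RaterCodingTable(
            item_ids=[f"i{k}" for k in range(codes.shape[0])],
            rater_ids=[f"r{k}" for k in range(codes.shape[1])],
            codes=codes,
        )

    def test_perfect_agreement(self):
        codes = np.tile(np.arange(10) % 2, (3, 1)).T
        res = krippendorff_alpha(self._table(codes), bootstrap_reps=0)
        assert res.alpha == 1.0

    def test_hand_built_coincidence_matrix(self):
        # 2 raters, 4 binary items, agreement on 3:
        # coincidence o00=4, o11=2, o01=o10=1; Do=2, De=30/7, alpha=8/15
        codes = [[0, 0], [1, 1], [0, 0], [0, 1]]
        res = krippendorff_alpha(self._table(codes), bootstrap_reps=0)
        assert res.alpha == pytest.approx(8 / 15)
        assert res.alpha == pytest.approx(_alpha_bruteforce(np.asarray(
            codes, dtype=float)))

    def test_matches_bruteforce_with_missing_codes(self):
        rng = np.random.default_rng(17)
        codes = rng.integers(0, 3, (30, 4)).astype(float)
        codes[rng.random((30, 4)) < 0.2] = np.nan
        keep = (~np.isnan(codes)).sum(axis=1) >= 2
        codes = codes[keep]
        res = krippendorff_alpha(self._table(codes), bootstrap_reps=0)
        assert res.alpha == pytest.approx(_alpha_bruteforce(codes))

    def test_random_coders_near_zero(self):
        rng = np.random.default_rng(23)
        codes = rng.integers(0, 2, (1000, 2)).astype(float)
        res = krippendorff_alpha(self._table(codes), bootstrap_reps=0)
        assert abs(res.alpha) < 0.1

    def test_relabeling_and_rater_permutation_invariance(self):
        rng = np.random.default_rng(29)
        codes = rng.integers(0, 2, (40, 3)).astype(float)
        base = krippendorff_alpha(self._table(codes), bootstrap_reps=0).alpha
        relabeled = krippendorff_alpha(self._table(1.0 - codes),
                                       bootstrap_reps=0).alpha
        permuted = krippendorff_alpha(self._table(codes[:, [2, 0, 1]]),
                                      bootstrap_reps=0).alpha
        assert base == pytest.approx(relabeled)
        assert base == pytest.approx(permuted)

    def test_bootstrap_ci_brackets_alpha_and_is_seeded(self):
        rng = np.random.default_rng(31)
        truth = rng.random(60) < 0.4
        codes = np.column_stack([
            np.where(rng.random(60) < 0.85, truth, ~truth) for _ in range(3)
        ]).astype(float)
        r1 = krippendorff_alpha(self._table(codes), bootstrap_reps=400, seed=7)
        r2 = krippendorff_alpha(self._table(codes), bootstrap_reps=400, seed=7)
        assert r1.ci_low <= r1.alpha <= r1.ci_high
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)


class TestComparisonBattery:
    def _features(self, rng, n=30, offset=0.0):
        import pandas as pd

        cols = {}
        for var in ("authentic", "clout", "analytic", "pos_tone", "neg_tone",
                    "social", "total_pronouns", "pron_I", "pron_we",
                    "pron_you", "pron_she_he", "pron_they"):
            a = rng.normal(0, 1, n)
            b = rng.normal(offset if var == "neg_tone" else 0.0, 1, n)
            cols[var] = np.concatenate([a, b])
        df = pd.DataFrame(cols)
        labels = ["G1"] * n + ["G2"] * n
        return df, labels

    def test_single_variable_family_unadjusted(self):
        rng = np.random.default_rng(3)
        df, labels = self._features(rng)
        res = run_comparison_battery(df, ("G1", "G2", labels),
                                     families={"solo": ["neg_tone"]})
        assert len(res) == 1
        assert res[0].p_adj == pytest.approx(res[0].p_raw)

    def test_identical_groups_all_null(self):
        import pandas as pd

        rng = np.random.default_rng(4)
        half = pd.DataFrame({
            v: rng.normal(0, 1, 20)
            for v in ("neg_tone", "pos_tone", "social")
        })
        df = pd.concat([half, half], ignore_index=True)
        labels = ["G1"] * 20 + ["G2"] * 20
        res = run_comparison_battery(
            df, ("G1", "G2", labels),
            families={"fam": ["neg_tone", "pos_tone", "social"]})
        assert all(r.t == 0.0 and r.p_adj == pytest.approx(1.0) for r in res)

    def test_family_wise_adjustment_is_within_family(self):
        rng = np.random.default_rng(5)
        df, labels = self._features(rng, n=60, offset=1.5)
        res = run_comparison_battery(df, ("G1", "G2", labels))
        by_family = {}
        for r in res:
            by_family.setdefault(r.family, []).append(r)
        for fam, rows in by_family.items():
            recomputed = bh_adjust([r.p_raw for r in rows])
            assert [r.p_adj for r in rows] == pytest.approx(recomputed)

    def test_too_small_group_is_an_error(self):
        rng = np.random.default_rng(6)
        df, labels = self._features(rng, n=2)
        labels = ["G1"] * 3 + ["G2"] * 1
        with pytest.raises(DegenerateDataError):
            run_comparison_battery(df, ("G1", "G2", labels))

    def test_frame_column_order(self):
        rng = np.random.default_rng(8)
        df, labels = self._features(rng)
        frame = comparison_frame(run_comparison_battery(df, ("G1", "G2", labels)))
        assert list(frame.columns[:4]) == ["family", "variable", "group1",
                                           "group2"]
        assert (frame["p_adj"] >= frame["p_raw"] - 1e-12).all()
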