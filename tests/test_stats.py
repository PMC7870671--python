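import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from vitreoquant import (
    AnalysisConfig,
    InsufficientDataError,
    UndefinedAUCError,
    ValidationError,
    bland_altman_regression,
    deviation_from_reference,
    icc_absolute_agreement,
    paired_wilcoxon_holm,
    run_reliability_analysis,
    simulate_score_matrix,
    split_roc,
)
from vitreoquant.errors import DegenerateTestWarning


def anova_icc_oracle(x):
    """Loop-based two-way ANOVA mean squares -> ICC(2,1), independent path."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((r - grand) ** 2 for r in row) / (n - 1)
    msc = n * sum((c - grand) ** 2 for c in col) / (k - 1)
    sse = sum(
        (x[i, j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def holm_oracle(p_values):
    """Hand step-down rule with enforced monotonicity."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p_values[i])
        adjusted[i] = min(1.0, running)
    return adjusted


def concordance_oracle(scores, labels):
    pos, neg = scores[labels], scores[~labels]
    wins = np.sum(pos[:, None] > neg[None, :]) + 0.5 * np.sum(pos[:, None] == neg[None, :])
    return wins / (len(pos) * len(neg))


class TestICC:
    def test_identical_columns_give_perfect_agreement(self):
        x = np.tile(np.arange(6, dtype=float)[:, None], (1, 3))
        res = icc_absolute_agreement(x)
        assert res.icc == 1.0
        assert res.ci_low == res.ci_high == 1.0

    def test_hand_matrix_matches_mean_squares_oracle(self):
        x = np.array(
            [[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2], [10, 5, 6], [6, 2, 4]],
            dtype=float,
        )
        res = icc_absolute_agreement(x)
        assert abs(res.icc - anova_icc_oracle(x)) < 1e-10
        assert res.ci_low <= res.icc <= res.ci_high

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        n, k = 10, 4
        x = rng.normal(0, 1, (n, k)) + rng.normal(0, 2, (n, 1))
        res = icc_absolute_agreement(x)
        long = pd.DataFrame(
            {
                "t": np.repeat(np.arange(n), k),
                "r": np.tile(np.arange(k), n),
                "v": x.ravel(),
            }
        )
        tab = pg.intraclass_corr(long, targets="t", raters="r", ratings="v")
        row = tab[tab["Type"] == "ICC(A,1)"].iloc[0]
        assert abs(res.icc - row["ICC"]) < 1e-10
        assert abs(res.ci_low - row["CI95"][0]) < 5e-3  # pingouin rounds to 2 dp
        assert abs(res.ci_high - row["CI95"][1]) < 5e-3

    def test_variance_ratio_recovery(self, rng):
        x = simulate_score_matrix(200, 9, between_sd=3.0, within_sd=1.0, rng=rng)
        res = icc_absolute_agreement(x)
        assert abs(res.icc - 0.9) < 0.05

    def test_rows_with_missing_dropped(self, rng):
        x = rng.normal(0, 1, (6, 3))
        x[2, 1] = np.nan
        res = icc_absolute_agreement(x)
        assert res.n_subjects == 5 and res.n_dropped == 1

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            icc_absolute_agreement(np.ones((1, 3)))

    def test_consistency_variant(self, rng):
        x = rng.normal(0, 1, (8, 3)) + np.array([0.0, 1.0, 2.0])  # rater offsets
        agree = icc_absolute_agreement(x, model="absolute_agreement")
        consist = icc_absolute_agreement(x, model="consistency")
        assert consist.icc > agree.icc  # offsets penalise absolute agreement only


class TestDeviation:
    def test_identity_is_exact_zero(self):
        s = np.array([0.1, 0.2, 0.3])
        res = deviation_from_reference(s, s)
        assert res.median_abs_diff == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_loa_formula_on_fixed_vector(self):
        # differences {-1, 0, 1}: mean 0, sample SD 1 -> LoA = ±1.96
        res = deviation_from_reference(np.array([0.0, 1.0, 2.0]), np.array([1.0, 1.0, 1.0]))
        assert res.loa_low == pytest.approx(-1.96)
        assert res.loa_high == pytest.approx(1.96)
        assert res.median_abs_diff == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            deviation_from_reference(np.ones(3), np.ones(4))


class TestBlandAltmanRegression:
    def test_recovers_proportional_bias(self, rng):
        ref = rng.uniform(0.0, 0.1, 200)
        scheme = ref + 0.5 * ref + rng.normal(0, 0.002, 200)
        res = bland_altman_regression(scheme, ref, exclusion_threshold=10.0)
        assert abs(res.slope - 0.5 / 1.25) < 0.1  # slope of diff on mean

    def test_exclusion_counts(self, rng):
        ref = np.concatenate([rng.uniform(0, 0.08, 20), np.full(4, 0.5)])
        scheme = ref.copy()
        scheme[:20] += rng.normal(0, 0.001, 20)
        res = bland_altman_regression(scheme, ref, exclusion_threshold=0.1)
        assert res.n_excluded == 4 and res.n_used == 20

    def test_full_exclusion_raises(self):
        big = np.array([0.2, 0.3, 0.4, 0.5])
        with pytest.raises(InsufficientDataError):
            bland_altman_regression(big, big, exclusion_threshold=0.1)

    def test_null_p_values_are_uniform(self, rng):
        """Differences independent of means: slope p-values are U(0,1)."""
        ps = []
        for _ in range(500):
            means = rng.uniform(0, 0.1, 30)
            diffs = rng.normal(0, 0.01, 30)
            scheme, ref = means + diffs / 2, means - diffs / 2
            ps.append(bland_altman_regression(scheme, ref, exclusion_threshold=1.0).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestWilcoxonHolm:
    def test_adjustment_matches_hand_rule_on_fixed_vectors(self):
        for p_raw in ([0.01, 0.02, 0.04], [0.04, 0.01, 0.02], [0.3, 0.2, 0.9, 0.01]):
            from statsmodels.stats.multitest import multipletests

            _, adj, _, _ = multipletests(p_raw, method="holm")
            assert np.allclose(adj, holm_oracle(p_raw))
        assert holm_oracle([0.01, 0.02, 0.04]) == [0.03, 0.04, 0.04]

    def test_pipeline_adjusted_matches_hand_rule(self, rng):
        table = pd.DataFrame(
            {
                "a": rng.normal(0.5, 1, 25),
                "b": rng.normal(0.0, 1, 25),
                "c": rng.normal(0.1, 1, 25),
            }
        )
        results = paired_wilcoxon_holm(table, [("a", "b"), ("a", "c"), ("b", "c")])
        raw = [r.p_raw for r in results]
        assert np.allclose([r.p_adjusted for r in results], holm_oracle(raw))
        assert all(r.p_adjusted >= r.p_raw for r in results)

    def test_identical_samples_degenerate(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [0.0, 1.0, 5.0]})
        with pytest.warns(DegenerateTestWarning):
            results = paired_wilcoxon_holm(table, [("a", "b"), ("a", "c")])
        assert results[0].p_raw == 1.0 and results[0].degenerate

    def test_single_comparison_unadjusted(self, rng):
        table = pd.DataFrame({"a": rng.normal(1, 1, 15), "b": rng.normal(0, 1, 15)})
        (res,) = paired_wilcoxon_holm(table, [("a", "b")])
        assert res.p_adjusted == res.p_raw


class TestSplitROC:
    def test_perfect_predictor(self, rng):
        r = rng.normal(0, 1, 40)
        res = split_roc(r, r, split="median")
        assert res.auc == 1.0

    def test_perfect_anti_predictor(self, rng):
        r = rng.normal(0, 1, 40)
        assert split_roc(-r, r, split="median").auc == 0.0

    def test_empty_class_raises(self):
        r = np.array([5.0, 5.0, 5.0, 6.0])
        with pytest.raises(UndefinedAUCError):
            split_roc(r, r, split="lower_quartile")

    def test_ci_bounds_ordered_and_clipped(self, rng):
        r = rng.normal(0, 1, 30)
        s = r + rng.normal(0, 1, 30)
        res = split_roc(s, r)
        assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(data=st.data())
    def test_auc_equals_concordance_oracle_with_ties(self, data):
        n = data.draw(st.integers(8, 30))
        ref = np.asarray(data.draw(st.lists(st.integers(0, 6), min_size=n, max_size=n)), float)
        score = np.asarray(data.draw(st.lists(st.integers(0, 6), min_size=n, max_size=n)), float)
        if np.unique(ref).size < 2:
            return
        labels = ref >= np.median(ref)
        if labels.all() or not labels.any():
            return
        res = split_roc(score, ref, split="median")
        assert abs(res.auc - concordance_oracle(score, labels)) < 1e-12


class TestFullReport:
    def _wide(self, rng, n_eyes=20, noise=0.002):
        base = rng.uniform(0.01, 0.09, (n_eyes, 1))
        return pd.DataFrame(base + rng.normal(0, noise, (n_eyes, 9)))

    def test_degenerate_cohort_flagged(self):
        # dyadic values keep every scheme mean exactly equal to the reference
        wide = pd.DataFrame(np.tile(np.arange(1, 13)[:, None] / 16.0, (1, 9)))
        with pytest.warns(DegenerateTestWarning):
            rep = run_reliability_analysis(wide)
        assert any("degenerate" in f for f in rep.flags)
        assert all(a.median_abs_diff == 0.0 for a in rep.agreement.values())
        assert rep.icc.icc == 1.0

    def test_reference_conservation(self, rng):
        rep = run_reliability_analysis(self._wide(rng))
        nine = rep.agreement["9s"]
        assert nine.median_abs_diff == 0.0 and nine.loa_low == 0.0 and nine.loa_high == 0.0

    def test_two_eye_cohort_partial(self, rng):
        wide = self._wide(rng, n_eyes=2)
        rep = run_reliability_analysis(wide)
        assert -1.0 <= rep.icc.icc <= 1.0
        assert all(v is None for v in rep.regression.values())
        assert any("regression" in f for f in rep.flags)

    def test_report_serialises(self, rng):
        import json

        rep = run_reliability_analysis(self._wide(rng))
        payload = json.dumps(rep.to_dict())
        assert "icc" in payload
        t1, t2 = rep.table1(), rep.table2("median")
        assert set(t1["scheme"]) == {"1c", "3c", "5c", "7c", "3w"}
        assert t2.shape[0] == 5

    def test_custom_config_subset(self, rng):
        cfg = AnalysisConfig(schemes=("1c", "3w"), comparisons=(("1c", "3w"),), splits=("median",))
        rep = run_reliability_analysis(self._wide(rng), cfg)
        assert set(rep.roc["median"][i].scheme for i in range(2)) == {"1c", "3w"}
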