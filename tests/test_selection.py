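import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aptwhabitat.selection import (
    EmptySelectionError,
    SelectionCascade,
    SelectionConfig,
    compare_selected_features,
    correlation_prune,
    icc_filter,
    lasso_linear_cd,
    lasso_score,
    mrmr_select,
    ttest_filter,
)


def balanced_labels(n):
    return np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]


class TestICCFilter:
    def test_identical_readers_keep_all(self, rng):
        t1 = pd.DataFrame(rng.normal(size=(20, 6)), columns=list("abcdef"))
        assert icc_filter(t1, t1.copy(), 0.85) == list("abcdef")

    def test_noisy_reader_drops(self, rng):
        t1 = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        t2 = t1 + 100.0 * rng.normal(size=(30, 3))
        assert icc_filter(t1, t2, 0.85) == []

    def test_six_patient_manual_anova(self):
        x1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        x2 = np.array([1.1, 2.2, 2.9, 4.2, 4.8, 6.1])
        from aptwhabitat.evaluation import icc_two_rater

        expected_icc = icc_two_rater(x1, x2).icc  # itself validated by hand elsewhere
        t1 = pd.DataFrame({"f": x1})
        t2 = pd.DataFrame({"f": x2})
        kept = icc_filter(t1, t2, icc_min=expected_icc - 1e-9)
        assert kept == ["f"]
        assert icc_filter(t1, t2, icc_min=expected_icc + 1e-9) == []

    def test_zero_variance_dropped_with_warning(self, rng):
        t1 = pd.DataFrame({"x": np.ones(10), "y": rng.normal(size=10)})
        t2 = t1.copy()
        with pytest.warns(UserWarning, match="zero-variance"):
            kept = icc_filter(t1, t2, 0.85)
        assert kept == ["y"]

    def test_column_mismatch_error(self, rng):
        t1 = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        t2 = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "c"])
        with pytest.raises(ValueError):
            icc_filter(t1, t2)


class TestTTestFilter:
    def test_null_survival_fraction_near_p_max(self, rng):
        n, m = 300, 4000
        labels = balanced_labels(n)
        table = pd.DataFrame(rng.normal(size=(n, m)))
        table.columns = [f"f{i}" for i in range(m)]
        kept = ttest_filter(table, labels, p_max=0.05)
        assert len(kept) / m == pytest.approx(0.05, abs=0.015)

    def test_perfect_separator_kept(self, rng):
        labels = balanced_labels(40)
        table = pd.DataFrame(
            {"sig": labels + 1e-3 * rng.normal(size=40), "noise": rng.normal(size=40)}
        )
        kept = ttest_filter(table, labels, 0.05)
        assert "sig" in kept

    def test_manual_welch_4v4(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0, 8.0])
        t_manual = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 4)
        ref = stats.ttest_ind(b, a, equal_var=False)
        assert ref.statistic == pytest.approx(-t_manual)
        table = pd.DataFrame({"f": np.r_[a, b]})
        labels = np.r_[np.zeros(4, int), np.ones(4, int)]
        kept = ttest_filter(table, labels, p_max=ref.pvalue + 1e-9)
        assert kept == ["f"]
        assert ttest_filter(table, labels, p_max=ref.pvalue - 1e-9) == []

    def test_small_class_error(self):
        with pytest.raises(ValueError):
            ttest_filter(pd.DataFrame({"f": [1.0, 2.0, 3.0]}), [0, 0, 1])


class TestCorrelationPrune:
    def test_duplicate_column_one_survives(self, rng):
        x = rng.normal(size=60)
        labels = balanced_labels(60)
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=60)})
        kept = correlation_prune(table, labels, 0.9)
        assert sorted(kept)[-1] == "c" and len(kept) == 2

    def test_uncorrelated_noop(self, rng):
        table = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        labels = balanced_labels(200)
        assert correlation_prune(table, labels, 0.9) == list("abcde")

    def test_brute_force_rule_replay(self, rng):
        """Survivors match an independent replay of the greedy rule."""
        for trial in range(5):
            r = np.random.default_rng(100 + trial)
            n = 80
            base = r.normal(size=(n, 3))
            cols = {}
            for i in range(5):
                mix = r.random(3)
                cols[f"f{i}"] = base @ mix + 0.3 * r.normal(size=n)
            table = pd.DataFrame(cols)
            labels = balanced_labels(n)
            got = correlation_prune(table, labels, corr_max=0.6)

            # independent replay
            p = {
                c: stats.ttest_ind(
                    table[c][labels == 1], table[c][labels == 0], equal_var=False
                ).pvalue
                for c in table
            }
            alive = list(table.columns)
            while True:
                best_pair, best_r = None, 0.6
                for a, b in itertools.combinations(alive, 2):
                    rr = abs(np.corrcoef(table[a], table[b])[0, 1])
                    if rr > best_r:
                        best_r, best_pair = rr, (a, b)
                if best_pair is None:
                    break
                a, b = best_pair
                if p[a] > p[b]:
                    alive.remove(a)
                elif p[b] > p[a]:
                    alive.remove(b)
                else:
                    alive.remove(max(a, b))
            assert got == alive


class TestMRMR:
    def test_generating_signal_ranks_first(self, rng):
        n = 100
        labels = balanced_labels(n)
        table = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"n{i}" for i in range(6)])
        table["sig"] = labels + 0.2 * rng.normal(size=n)
        out = mrmr_select(table, labels, 3)
        assert out[0] == "sig"

    def test_duplicate_penalized(self):
        """The exact duplicate carries redundancy ~1 at the second greedy
        step, so a weaker independent feature overtakes it (hand-checked:
        F_weak - r_weak,strong > F_strong - 1 for this construction)."""
        r = np.random.default_rng(2)
        n = 16
        labels = balanced_labels(n)
        strong = labels + 1.1 * r.standard_normal(n)
        clone = strong + 1e-9 * r.standard_normal(n)
        weak = labels + 1.6 * r.standard_normal(n)
        table = pd.DataFrame({"strong": strong, "clone": clone, "weak": weak})
        f = stats.f_oneway(
            table[labels == 1], table[labels == 0], axis=0
        ).statistic
        assert f[0] > f[2]  # clone is more relevant in isolation...
        assert f[0] - 1.0 < f[2] - abs(np.corrcoef(weak, strong)[0, 1])
        out = mrmr_select(table, labels, 2)
        assert out == ["strong", "weak"]  # ...but loses after the penalty

    def test_exhaustive_greedy_replay(self, rng):
        n = 60
        labels = balanced_labels(n)
        table = pd.DataFrame(
            rng.normal(size=(n, 5)) + labels[:, None] * rng.random(5)[None, :],
            columns=list("abcde"),
        )
        got = mrmr_select(table, labels, 5)
        X = table.to_numpy()
        f = stats.f_oneway(X[labels == 1], X[labels == 0], axis=0).statistic
        corr = np.abs(np.corrcoef(X, rowvar=False))
        cols = list(table.columns)
        selected, remaining = [], list(range(5))
        for _ in range(5):
            best, best_score = None, -np.inf
            for j in remaining:
                red = np.mean([corr[j, s] for s in selected]) if selected else 0.0
                sc = f[j] - red
                if sc > best_score:
                    best, best_score = j, sc
            selected.append(best)
            remaining.remove(best)
        assert got == [cols[j] for j in selected]

    def test_k_nonpositive(self, rng):
        with pytest.raises(ValueError):
            mrmr_select(pd.DataFrame({"a": [1.0, 2.0]}), [0, 1], 0)


class TestLasso:
    def test_soft_threshold_closed_form_orthonormal(self, rng):
        """Coordinate descent equals the analytic soft-threshold solution."""
        n, p = 64, 8
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))  # orthonormal columns
        beta = np.array([3.0, -2.0, 1.5, 0.5, 0.0, 0.0, 0.0, 0.0])
        y = Q @ beta + 0.1 * rng.normal(size=n)
        for lam in (0.05, 0.5, 1.5):
            got = lasso_linear_cd(Q, y, lam)
            ols = Q.T @ y
            expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_lambda_infinity_all_zero(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        np.testing.assert_array_equal(lasso_linear_cd(X, y, 1e9), np.zeros(4))

    def test_logistic_empty_selection_fails_loudly(self, rng):
        n = 40
        labels = balanced_labels(n)
        table = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        with pytest.raises(EmptySelectionError):
            # grid pinned at huge lambda: every coefficient shrinks to zero
            lasso_score(
                table, labels, folds=2, n_lambdas=2, lambda_min_ratio=1.0, seed=0
            )

    def test_score_identity(self, rng):
        n = 60
        labels = balanced_labels(n)
        table = pd.DataFrame(rng.normal(size=(n, 6)), columns=list("abcdef"))
        table["sig"] = labels * 2.0 + 0.3 * rng.normal(size=n)
        rep = lasso_score(table, labels, folds=5, n_lambdas=30, seed=1)
        score = rep.score(table)
        z = (table[rep.final_features] - rep.zscore_mean[rep.final_features]) / (
            rep.zscore_std[rep.final_features]
        )
        manual = rep.intercept + z.to_numpy() @ rep.coefficients
        np.testing.assert_allclose(score.to_numpy(), manual, atol=1e-12)
        assert (rep.coefficients != 0).all()


class TestCompareSelected:
    def test_planted_effect_significant(self, rng):
        n = 80
        labels = balanced_labels(n)
        table = pd.DataFrame({"sig": labels + 0.3 * rng.normal(size=n)})
        out = compare_selected_features(table, labels, ["sig"])
        assert out.loc["sig", "p"] < 0.05
        assert out.loc["sig", "mean_pos"] > out.loc["sig", "mean_neg"]

    def test_determinism(self, rng):
        n = 40
        labels = balanced_labels(n)
        table = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        a = compare_selected_features(table, labels, ["a", "b"])
        b = compare_selected_features(table, labels, ["a", "b"])
        pd.testing.assert_frame_equal(a, b)

    def test_empty_selection_error(self, rng):
        with pytest.raises(ValueError):
            compare_selected_features(pd.DataFrame({"a": [1.0, 2.0]}), [0, 1], [])


class TestCascade:
    def _make_data(self, seed, n=60, m=40):
        r = np.random.default_rng(seed)
        labels = balanced_labels(n)
        X = r.normal(size=(n, m))
        X[:, 0] += labels * 1.5
        X[:, 1] += labels * 1.2
        table = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(m)])
        noise = r.standard_normal((n, m)) * (0.02 * table.std().to_numpy())[None, :]
        reader2 = table + noise
        return table, reader2, labels

    def test_monotone_stage_counts(self):
        table, reader2, labels = self._make_data(0)
        c = SelectionCascade(SelectionConfig(seed=3, mrmr_k=10, n_lambdas=25)).fit(
            table, labels, reader2_table=reader2
        )
        counts = [len(v) for _, v in c.report.surviving_per_stage]
        assert counts == sorted(counts, reverse=True)
        assert c.report.surviving_per_stage[0][0] == "input"

    def test_deterministic_given_seed(self):
        table, reader2, labels = self._make_data(1)
        cfg = SelectionConfig(seed=5, mrmr_k=10, n_lambdas=25)
        a = SelectionCascade(cfg).fit(table, labels, reader2_table=reader2)
        b = SelectionCascade(cfg).fit(table, labels, reader2_table=reader2)
        assert a.report.final_features == b.report.final_features
        np.testing.assert_array_equal(a.report.coefficients, b.report.coefficients)
        pd.testing.assert_series_equal(a.score(table), b.score(table))

    def test_informative_features_selected(self):
        table, reader2, labels = self._make_data(2)
        c = SelectionCascade(SelectionConfig(seed=1, mrmr_k=10, n_lambdas=25)).fit(
            table, labels, reader2_table=reader2
        )
        assert {"f00", "f01"} & set(c.report.final_features)
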