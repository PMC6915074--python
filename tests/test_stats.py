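"""Accuracy transforms, permutation inference, rm-ANOVA, contrasts,
and answer-table aggregation, each checked against an independent oracle."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import somatobci as sb
from somatobci.stats import (
    ANSWER_TABLE_COLUMNS,
    PermConfig,
    aggregate_answer_table,
    edge_corrected_proportion,
    logit,
    permutation_test,
    permute_labels_within_runs,
    polynomial_contrast_weights,
    polynomial_contrasts,
    reference_answer_table,
    rm_anova,
)


class TestTransforms:
    @pytest.mark.parametrize(
        "correct,total,expected",
        [(5, 5, 0.9), (0, 5, -0.1), (9, 18, 8.5 / 18)],
    )
    def test_edge_correction(self, correct, total, expected):
        assert edge_corrected_proportion(correct, total) == pytest.approx(
            expected
        )

    def test_edge_correction_rejects_zero_total(self):
        with pytest.raises(ValueError):
            edge_corrected_proportion(0, 0)

    @pytest.mark.parametrize("p,expected", [(0.5, 0.0), (0.9, np.log(9.0))])
    def test_logit_values(self, p, expected):
        assert logit(p) == pytest.approx(expected, abs=1e-12)

    def test_logit_antisymmetry(self):
        for p in (0.1, 0.3, 0.77):
            assert logit(p) == pytest.approx(-logit(1 - p))

    @pytest.mark.parametrize("p", [-0.1, 0.0, 1.0, 1.3])
    def test_logit_domain_error(self, p):
        with pytest.raises(ValueError):
            logit(p)


class _FixedErrorScheme:
    """CV stand-in returning a scripted sequence of error values."""

    def __init__(self, observed, null_value):
        self.calls = 0
        self.observed = observed
        self.null_value = null_value

    def __call__(self, feats):
        class R:
            pass

        r = R()
        r.error = self.observed if self.calls == 0 else self.null_value
        self.calls += 1
        return r


def _dummy_features(n=8):
    return sb.TrialFeatures(
        X=np.zeros((n, 2)),
        y=np.repeat([1, -1], n // 2),
        run_ids=np.array(["r1"] * (n // 2) + ["r2"] * (n // 2)),
        trial_onsets=np.arange(n, dtype=float),
    )


class TestPermutationTest:
    def test_p_floor_when_observed_beats_every_null(self):
        scheme = _FixedErrorScheme(observed=0.0, null_value=0.5)
        res = permutation_test(
            _dummy_features(), scheme, PermConfig(n_perm=2000)
        )
        assert res.p == pytest.approx(1 / 2001)

    def test_p_is_one_when_null_ties_observed(self):
        scheme = _FixedErrorScheme(observed=0.5, null_value=0.5)
        res = permutation_test(
            _dummy_features(), scheme, PermConfig(n_perm=100)
        )
        assert res.p == 1.0

    def test_stratified_shuffle_preserves_run_class_counts(self):
        rng = np.random.default_rng(0)
        y = np.repeat([1, -1], 6)
        run_ids = np.tile(np.repeat(["a", "b", "c"], 2), 2)
        for _ in range(20):
            perm = permute_labels_within_runs(y, run_ids, rng)
            for run in "abc":
                idx = run_ids == run
                assert perm[idx].sum() == y[idx].sum()

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """2 runs x 4 trials: all 36 balanced within-run relabellings."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 6))
        X[:, 0] += np.repeat([1.0, -1.0], 4).repeat(1)  # weak signal
        y = np.array([1, 1, -1, -1, 1, 1, -1, -1])
        run_ids = np.array(["a"] * 4 + ["b"] * 4)
        feats = sb.TrialFeatures(
            X=X, y=y, run_ids=run_ids, trial_onsets=np.arange(8.0)
        )
        observed = sb.cv_leave_one_run_out(feats).error

        null = []
        for pos_a in combinations(range(4), 2):
            for pos_b in combinations(range(4), 2):
                labels = -np.ones(8, dtype=int)
                labels[list(pos_a)] = 1
                labels[[4 + p for p in pos_b]] = 1
                null.append(
                    sb.cv_leave_one_run_out(feats.with_labels(labels)).error
                )
        p_exact = float(np.mean(np.asarray(null) <= observed + 1e-12))

        res = permutation_test(feats, cfg=PermConfig(n_perm=2000, seed=9))
        assert res.observed_error == pytest.approx(observed)
        assert res.p == pytest.approx(p_exact, abs=0.02)


def _classical_oneway_oracle(data):
    """Textbook one-way within-subject F and GG epsilon."""
    n, k = data.shape
    grand = data.mean()
    col = data.mean(axis=0)
    row = data.mean(axis=1)
    ss_level = n * np.sum((col - grand) ** 2)
    ss_err = np.sum(
        (data - row[:, None] - col[None, :] + grand) ** 2
    )
    F = (ss_level / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    S = np.cov(data, rowvar=False)
    sbar = S.mean()
    sdiag = np.diag(S).mean()
    srow = S.mean(axis=1)
    eps = (k * (sdiag - sbar)) ** 2 / (
        (k - 1)
        * ((S**2).sum() - 2 * k * (srow**2).sum() + k**2 * sbar**2)
    )
    return F, eps


class TestRmAnova:
    TOY = np.array(
        [
            [3.0, 5.0, 9.0],
            [2.0, 4.0, 6.0],
            [5.0, 6.0, 11.0],
            [4.0, 4.0, 7.0],
        ]
    )

    def test_matches_direct_formula_oracle(self):
        F, eps = _classical_oneway_oracle(self.TOY)
        res = rm_anova(self.TOY, [("level", 3)])["level"]
        assert res.F == pytest.approx(F, abs=1e-8)
        assert res.gg_epsilon == pytest.approx(eps, abs=1e-8)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        long = pd.DataFrame(
            {
                "y": self.TOY.ravel(),
                "subj": np.repeat(np.arange(4), 3),
                "lev": np.tile(np.arange(3), 4),
            }
        )
        table = pg.rm_anova(
            data=long, dv="y", within="lev", subject="subj", correction=True
        )
        res = rm_anova(self.TOY, [("level", 3)])["level"]
        assert res.F == pytest.approx(float(table["F"].iloc[0]), abs=1e-8)
        assert res.gg_epsilon == pytest.approx(
            float(table["eps"].iloc[0]), abs=1e-8
        )
        assert res.p_gg == pytest.approx(
            float(table["p_GG_corr"].iloc[0]), abs=1e-8
        )

    def test_two_level_epsilon_is_exactly_one(self):
        rng = np.random.default_rng(1)
        res = rm_anova(rng.normal(size=(6, 2)), [("a", 2)])["a"]
        assert res.gg_epsilon == 1.0

    def test_two_level_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(2)
        d = rng.normal(size=(9, 2)) + [0.0, 0.4]
        t = sps.ttest_rel(d[:, 0], d[:, 1]).statistic
        res = rm_anova(d, [("a", 2)])["a"]
        assert res.F == pytest.approx(t**2, rel=1e-10)

    def test_two_way_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(3)
        data = rng.normal(size=(6, 6)) + rng.normal(size=(1, 6))
        rows = []
        for s in range(6):
            c = 0
            for a in range(2):
                for b in range(3):
                    rows.append({"subj": s, "A": a, "B": b, "y": data[s, c]})
                    c += 1
        oracle = AnovaRM(pd.DataFrame(rows), "y", "subj", within=["A", "B"]).fit()
        mine = rm_anova(data, [("A", 2), ("B", 3)])
        for eff, key in (("A", "A"), ("B", "B"), ("A:B", "A x B")):
            assert mine[key].F == pytest.approx(
                float(oracle.anova_table.loc[eff, "F Value"]), rel=1e-8
            )

    def test_compound_symmetric_data_has_epsilon_near_one(self):
        rng = np.random.default_rng(4)
        subject_effect = rng.normal(size=(200, 1))
        data = subject_effect + rng.normal(size=(200, 4))
        res = rm_anova(data, [("level", 4)])["level"]
        assert res.gg_epsilon == pytest.approx(1.0, abs=0.05)

    def test_missing_cells_rejected(self):
        data = self.TOY.copy()
        data[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova(data, [("level", 3)])


class TestPolynomialContrasts:
    def test_weights_orthonormal_for_five_levels(self):
        W = polynomial_contrast_weights(5)
        assert W.shape == (4, 5)
        np.testing.assert_allclose(W @ W.T, np.eye(4), atol=1e-12)
        np.testing.assert_allclose(W.sum(axis=1), 0.0, atol=1e-12)

    def test_exactly_linear_data_has_zero_quadratic_f(self):
        rng = np.random.default_rng(0)
        slopes = rng.uniform(0.5, 2.0, size=6)
        data = np.outer(slopes, np.arange(5.0))
        table = polynomial_contrasts(data).set_index("name")
        assert table.loc["quadratic", "F"] == 0.0
        assert table.loc["linear", "F"] > 0

    def test_constant_data_all_zero(self):
        table = polynomial_contrasts(np.full((5, 4), 3.0))
        assert (table["F"] == 0.0).all()


class TestAnswerAggregation:
    def test_single_subject_single_run(self):
        df = pd.DataFrame({"subject": ["S1"], "p": [0.8]})
        out = aggregate_answer_table(df, ["p"])
        assert out.loc["p", "overall"] == pytest.approx(0.8)

    def test_two_stage_averaging(self):
        df = pd.DataFrame(
            {"subject": ["S1", "S2", "S2"], "p": [1.0, 0.8, 1.0]}
        )
        out = aggregate_answer_table(df, ["p"])
        assert out.loc["p", "overall"] == pytest.approx(0.95)

    def test_reference_table_full_training_column(self):
        table = reference_answer_table()
        out = aggregate_answer_table(table, ANSWER_TABLE_COLUMNS)
        assert out.loc["t1_6", "overall"] == pytest.approx(0.86, abs=0.005)
        without = aggregate_answer_table(
            table[table.subject != "S03"], ANSWER_TABLE_COLUMNS
        )
        assert without.loc["t1_6", "overall"] == pytest.approx(0.92, abs=0.005)
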