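"""Statistics layer against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renalmri.cohort_stats import (
    bland_altman,
    classifier_samples,
    correlate,
    pca_classifier,
    roc_auc,
    two_way_anova_bonferroni,
    univariate_auc,
    validate_cohort_table,
)
from renalmri.synthetic import CohortSpec, make_cohort


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def auc_by_pair_counting(labels, scores):
    """Mann-Whitney AUC by exhaustive positive-negative pair enumeration."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def anova_by_sums_of_squares(df):
    """Balanced two-way ANOVA F statistics from first-principles SS."""
    a_levels = sorted(df["side"].unique())
    b_levels = sorted(df["timepoint"].unique())
    n = df.groupby(["side", "timepoint"])["value"].count().iloc[0]
    grand = df["value"].mean()
    ya = df.groupby("side")["value"].mean()
    yb = df.groupby("timepoint")["value"].mean()
    yab = df.groupby(["side", "timepoint"])["value"].mean()
    a, b = len(a_levels), len(b_levels)
    ss_a = n * b * sum((ya[i] - grand) ** 2 for i in a_levels)
    ss_b = n * a * sum((yb[j] - grand) ** 2 for j in b_levels)
    ss_ab = n * sum((yab[(i, j)] - ya[i] - yb[j] + grand) ** 2
                    for i in a_levels for j in b_levels)
    ss_e = sum((row.value - yab[(row.side, row.timepoint)]) ** 2
               for row in df.itertuples())
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = a * b * (n - 1)
    return {"A": (ss_a / df_a) / (ss_e / df_e),
            "B": (ss_b / df_b) / (ss_e / df_e),
            "AB": (ss_ab / df_ab) / (ss_e / df_e)}


def make_table(values_fn, n_animals=6, parameters=("P",)):
    rows = []
    for i in range(n_animals):
        for tp in ("baseline", "day1", "day15"):
            for side in ("left", "right"):
                for p in parameters:
                    rows.append({"animal_id": f"m{i}", "timepoint": tp,
                                 "side": side, "parameter": p,
                                 "value": values_fn(i, tp, side, p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

class TestROC:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [1.0, 2.0, 3.0, 4.0]).auc == 1.0

    def test_complete_ties(self):
        assert roc_auc([0, 1], [5.0, 5.0]).auc == 0.5

    def test_hand_enumerated(self):
        assert roc_auc([0, 0, 1, 1], [1.0, 3.0, 2.0, 4.0]).auc == pytest.approx(0.75)

    def test_orientation_not_flipped(self):
        assert roc_auc([0, 0, 1, 1], [4.0, 3.0, 2.0, 1.0]).auc == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [1.0, 2.0, 3.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        labels=st.lists(st.integers(0, 1), min_size=2, max_size=12),
        raw_scores=st.lists(st.integers(0, 5), min_size=12, max_size=12),
    )
    def test_matches_pair_counting_oracle(self, labels, raw_scores):
        if len(set(labels)) < 2:
            return
        scores = [float(s) for s in raw_scores[: len(labels)]]
        got = roc_auc(labels, scores).auc
        assert got == pytest.approx(auc_by_pair_counting(labels, scores), abs=1e-12)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

class TestTwoWayAnova:
    def test_all_identical_values(self):
        table = make_table(lambda *a: 3.14)
        res = two_way_anova_bonferroni(table, "P")
        assert np.all(res.table["F"].to_numpy() == 0.0)
        assert np.all(res.table["PR(>F)"].to_numpy() == 1.0)
        assert np.all(res.pairwise["p_adjusted"].to_numpy() == 1.0)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(7)
        table = make_table(lambda i, tp, side, p: float(rng.normal(
            10 + (1.0 if side == "right" else 0.0)
            + {"baseline": 0, "day1": 2, "day15": -1}[tp], 1.0)))
        res = two_way_anova_bonferroni(table, "P")
        oracle = anova_by_sums_of_squares(table)
        assert res.table.loc["C(side)", "F"] == pytest.approx(oracle["A"], abs=1e-8)
        assert res.table.loc["C(timepoint)", "F"] == pytest.approx(oracle["B"], abs=1e-8)
        assert res.table.loc["C(side):C(timepoint)", "F"] == pytest.approx(
            oracle["AB"], abs=1e-8)

    def test_side_effect_only_at_day1(self):
        rng = np.random.default_rng(3)
        def value(i, tp, side, p):
            shift = 5.0 if (tp == "day1" and side == "right") else 0.0
            return float(rng.normal(10.0 + shift, 0.5))
        res = two_way_anova_bonferroni(make_table(value), "P")
        pw = res.pairwise.set_index("timepoint")["p_adjusted"]
        assert pw["day1"] < 0.05
        assert pw["baseline"] > 0.05

    def test_bonferroni_never_exceeds_one(self):
        table = make_table(lambda i, tp, side, p: float(i))
        res = two_way_anova_bonferroni(table, "P")
        assert np.all(res.pairwise["p_adjusted"] <= 1.0)

    def test_missing_parameter_rejected(self):
        with pytest.raises(ValueError):
            two_way_anova_bonferroni(make_table(lambda *a: 1.0), "missing")


# ---------------------------------------------------------------------------
# PCA classifier
# ---------------------------------------------------------------------------

class TestPCAClassifier:
    def _xy(self, n=20, seed=0, sep=0.0, p=4):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(0, 1, (n, p)) + sep * y[:, None]
        return pd.DataFrame(X, columns=[f"v{i}" for i in range(p)]), y

    def test_perfectly_correlated_columns_rank_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 20)
        X = pd.DataFrame({"a": base, "b": 3 * base + 1})
        y = (base > 0).astype(int)
        res = pca_classifier(X, y)
        assert res["pca"].variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_loadings_orthonormal(self):
        X, y = self._xy(seed=2)
        L = pca_classifier(X, y)["pca"].loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_variance_fractions_sum_to_one(self):
        X, y = self._xy(seed=3)
        vf = pca_classifier(X, y)["pca"].variance_fraction
        assert vf.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(pca_classifier(X, y)["pca"].cumulative_variance) >= -1e-12)

    def test_scores_covariance_diagonal(self):
        X, y = self._xy(seed=4, n=40)
        scores = pca_classifier(X, y)["pca"].scores
        cov = np.cov(scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-10

    def test_separable_direction_yields_auc_one(self):
        X, y = self._xy(n=30, seed=5, sep=8.0)
        res = pca_classifier(X, y, cumulative_variance_target=0.999)
        assert max(c.auc for c in res["roc"].values()) == 1.0

    def test_constant_column_dropped(self):
        X, y = self._xy(seed=6)
        X["const"] = 1.0
        res = pca_classifier(X, y)
        assert res["pca"].dropped_constant == ("const",)
        assert "const" not in res["pca"].loadings.index

    def test_too_few_parameters_rejected(self):
        X, y = self._xy(seed=7, p=1)
        with pytest.raises(ValueError):
            pca_classifier(X, y)


# ---------------------------------------------------------------------------
# Correlation & Bland-Altman
# ---------------------------------------------------------------------------

class TestCorrelate:
    def test_exact_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlate(x, 2 * x + 1)["r2"] == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert correlate(x, y)["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed(self):
        res = correlate([1, 2, 3, 4], [1, 3, 2, 4])
        assert res["r"] == pytest.approx(0.8)
        assert res["r2"] == pytest.approx(0.64)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_constant_offset(self):
        a = np.array([10.0, 20.0, 30.0])
        res = bland_altman(a, a - 10.0)
        assert res.bias == pytest.approx(10.0)
        assert res.loa_low == pytest.approx(10.0)
        assert res.loa_high == pytest.approx(10.0)

    def test_hand_computed(self):
        res = bland_altman(np.array([0.0, 10.0, 20.0]), np.zeros(3))
        assert res.bias == pytest.approx(10.0)
        assert res.loa_low == pytest.approx(10.0 - 1.96 * 10.0)
        assert res.loa_high == pytest.approx(10.0 + 1.96 * 10.0)

    def test_identical_methods(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a, a)
        assert res.bias == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.ones(3), np.ones(4))

    def test_bias_and_sd_recovery_over_seeds(self):
        bias_true, sd_true = 40.0, 20.0
        sds = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            a = rng.uniform(50, 200, 10)
            b = a - bias_true + rng.normal(0, sd_true, 10)
            res = bland_altman(a, b)
            sds.append(res.sd)
        # the constant bias is recovered exactly at zero noise
        exact = bland_altman(np.arange(10.0) + bias_true, np.arange(10.0))
        assert exact.bias == pytest.approx(bias_true, abs=1e-12)
        assert np.mean(sds) == pytest.approx(sd_true, rel=0.15)


# ---------------------------------------------------------------------------
# Cohort wiring
# ---------------------------------------------------------------------------

class TestCohortWiring:
    def test_class_definition(self):
        coh = make_cohort(CohortSpec(seed=0))["cohort"]
        X, y = classifier_samples(coh, ["FT", "Volume"])
        # 9 animals x 2 sides at baseline healthy + 9 x 2 injured timepoints
        assert len(y) == 36
        assert y.sum() == 18
        idx = X.index.to_frame(index=False)
        assert set(idx.loc[y == 1, "side"]) == {"right"}
        assert set(idx.loc[y == 0, "timepoint"]) == {"baseline"}

    def test_schema_validation(self):
        coh = make_cohort(CohortSpec(seed=0))["cohort"]
        validate_cohort_table(coh)
        bad = coh.copy()
        bad.loc[0, "timepoint"] = "day99"
        with pytest.raises(ValueError):
            validate_cohort_table(bad)

    def test_univariate_orientation(self):
        coh = make_cohort(CohortSpec(n_animals=60, seed=1))["cohort"]
        X, y = classifier_samples(coh, ["Volume", "f"])
        aucs = univariate_auc(X, y)
        assert aucs["Volume"].auc > 0.8   # volume falls sharply with injury
        assert abs(aucs["f"].auc - 0.5) < 0.2  # f barely discriminates
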