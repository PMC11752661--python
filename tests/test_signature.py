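import numpy as np
import pandas as pd
import pytest

from mirsig.dataio import DataError
from mirsig.signature import (
    CONSTANT_KINDS,
    SearchConfig,
    crossvalidated_metrics,
    derive_constants,
    enumerate_candidates,
    filter_by_criteria,
    fisher_lda,
    make_folds,
    n_discriminants,
    search_signatures,
    variable_count_sweep,
)


def _separable(rng, n_per=40, d=2, shift=6.0):
    X0 = rng.normal(size=(n_per, d))
    X1 = rng.normal(size=(n_per, d)) + shift
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n_per), np.ones(n_per)].astype(int)
    return X, y


class TestFisherLda:
    def test_matches_matrix_inverse_oracle(self, rng):
        X, y = _separable(rng, shift=1.0)
        w = fisher_lda(X, y)
        X1, X0 = X[y == 1], X[y == 0]
        S = ((len(X1) - 1) * np.cov(X1.T) + (len(X0) - 1) * np.cov(X0.T)) / (len(X) - 2)
        expected = np.linalg.inv(S) @ (X1.mean(0) - X0.mean(0))
        assert np.allclose(w, expected, atol=1e-10)

    def test_case_mean_projects_above_control_mean(self, rng):
        X, y = _separable(rng, shift=2.0)
        w = fisher_lda(X, y)
        s = X @ w
        assert s[y == 1].mean() > s[y == 0].mean()

    def test_equal_class_means_error(self, rng):
        X0 = rng.normal(size=(20, 2))
        X = np.vstack([X0, X0])
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        with pytest.raises(DataError, match="equal class means"):
            fisher_lda(X, y)

    def test_one_dimensional_reduction(self, rng):
        x0 = rng.normal(0, 1.5, size=30)
        x1 = rng.normal(2, 1.5, size=30)
        X = np.r_[x0, x1][:, None]
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        w = fisher_lda(X, y)
        s2 = (29 * x0.var(ddof=1) + 29 * x1.var(ddof=1)) / 58
        assert w[0] == pytest.approx((x1.mean() - x0.mean()) / s2, abs=1e-10)
        assert w[0] > 0

    def test_affine_rescaling_of_one_marker_leaves_refit_scores_equivalent(self, rng):
        X, y = _separable(rng, d=3, shift=1.0)
        w1 = fisher_lda(X, y)
        X2 = X.copy()
        X2[:, 1] = 5.0 * X2[:, 1] + 7.0
        w2 = fisher_lda(X2, y)
        s1, s2 = X @ w1, X2 @ w2
        # same discriminant direction up to affine transformation of scores
        assert np.allclose(s1 - s1.mean(), s2 - s2.mean(), atol=1e-8)


class TestDeriveConstants:
    def test_perfect_separation_classifies_perfectly_at_all_constants(self):
        scores = np.r_[np.zeros(10), np.ones(10) + 5]
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        consts = derive_constants(scores, y)
        for c in consts.values():
            assert ((scores > c) == (y == 1)).all()

    def test_sens80_constant_is_nearest_rank_case_quantile(self):
        cases = np.arange(1.0, 11.0)
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        scores = np.r_[cases - 100, cases]
        consts = derive_constants(scores, y)
        # nearest rank: 2nd smallest case score; sensitivity 8/10 on ties rule
        assert consts["sens80"] == 2.0
        sens = (cases > consts["sens80"]).mean()
        assert sens >= 0.8
        # brute-force: no larger candidate constant keeps sensitivity >= 0.8
        for c in cases[cases > consts["sens80"]]:
            assert (cases > c).mean() < 0.8

    def test_spec80_constant_is_nearest_rank_control_quantile(self):
        controls = np.arange(1.0, 11.0)
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        scores = np.r_[controls, controls + 100]
        consts = derive_constants(scores, y)
        assert consts["spec80"] == 8.0
        assert (controls <= consts["spec80"]).mean() >= 0.8
        for c in controls[controls < consts["spec80"]]:
            assert (controls <= c).mean() < 0.8

    def test_translation_equivariance(self, rng):
        scores = rng.normal(size=30)
        y = (rng.uniform(size=30) > 0.5).astype(int)
        y[:6] = 1
        y[6:12] = 0
        c0 = derive_constants(scores, y)
        c1 = derive_constants(scores + 11.5, y)
        for k in CONSTANT_KINDS:
            assert c1[k] == pytest.approx(c0[k] + 11.5, abs=1e-9)

    def test_fewer_than_five_per_class_errors(self):
        with pytest.raises(DataError):
            derive_constants(np.arange(8.0), np.r_[np.zeros(4), np.ones(4)].astype(int))


class TestEnumeration:
    def test_five_of_sixteen_gives_4368_subsets_13104_discriminants(self):
        markers = [f"m{i}" for i in range(16)]
        subsets = enumerate_candidates(markers, 5)
        assert len(subsets) == 4368
        assert n_discriminants(16, 5) == 13104

    def test_small_counts(self):
        assert len(enumerate_candidates(list("abcde"), 5)) == 1
        assert n_discriminants(5, 5) == 3
        assert len(enumerate_candidates(list("abcdef"), 5)) == 6
        assert n_discriminants(6, 5) == 18

    def test_subset_larger_than_marker_list_errors(self):
        with pytest.raises(DataError):
            enumerate_candidates(list("abc"), 5)


def _cohort(rng, n0=60, n1=60, p=6, shift=0.0):
    ids = [f"s{i:03d}" for i in range(n0 + n1)]
    X = pd.DataFrame(rng.normal(size=(n0 + n1, p)), index=ids, columns=[f"m{i}" for i in range(p)])
    y = pd.Series(np.r_[np.zeros(n0), np.ones(n1)].astype(int), index=ids)
    X.loc[y == 1] += shift
    ca = pd.Series(np.exp2(rng.normal(4 + 1.0 * y, 1.0)), index=ids)
    return X, y, ca


class TestCrossValidation:
    def test_fifty_heldout_evaluations(self, rng):
        X, y, ca = _cohort(rng)
        folds = make_folds(y, SearchConfig(seed=1))
        assert len(folds) == 50
        for tr, te in folds:
            assert len(np.unique(y.to_numpy()[te])) == 2
        out = crossvalidated_metrics(("m0", "m1", "m2", "m3", "m4"), X, y, ca, SearchConfig(seed=1))
        assert out["n_folds_evaluated"] == 50

    def test_separable_classes_give_perfect_metrics(self, rng):
        X, y, ca = _cohort(rng, shift=8.0)
        out = crossvalidated_metrics(("m0", "m1", "m2", "m3", "m4"), X, y, ca, SearchConfig(seed=1))
        assert out["auc_mean"] == 1.0
        # midpoint constant separates perfectly; the 80%-guarantee constants
        # trade the guaranteed rate down toward 0.8 but keep the other rate 1
        assert out["mean_sens"]["max_separation"] == 1.0
        assert out["mean_spec"]["max_separation"] == 1.0
        assert out["mean_spec"]["sens80"] == 1.0 and out["mean_sens"]["sens80"] >= 0.75
        assert out["mean_sens"]["spec80"] == 1.0 and out["mean_spec"]["spec80"] >= 0.75

    def test_shuffled_labels_give_null_auc(self, rng):
        X, y, ca = _cohort(rng, n0=142, n1=142, shift=1.5)
        yp = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        out = crossvalidated_metrics(("m0", "m1", "m2", "m3", "m4"), X, yp, ca, SearchConfig(seed=2))
        assert abs(out["auc_mean"] - 0.5) < 0.05

    def test_batched_search_agrees_with_single_subset_path(self, rng):
        X, y, ca = _cohort(rng, p=6, shift=1.0)
        cfg = SearchConfig(seed=4)
        table = search_signatures(X, y, ca, cfg)
        assert len(table) == 3 * 6
        for subset in [("m0", "m1", "m2", "m3", "m4"), ("m1", "m2", "m3", "m4", "m5")]:
            single = crossvalidated_metrics(subset, X, y, ca, cfg)
            rows = table[table["mirnas"] == subset].set_index("constant_kind")
            for kind in CONSTANT_KINDS:
                assert rows.loc[kind, "mean_sens"] == pytest.approx(single["mean_sens"][kind], abs=1e-12)
                assert rows.loc[kind, "mean_spec"] == pytest.approx(single["mean_spec"][kind], abs=1e-12)
                assert rows.loc[kind, "auc_mean"] == pytest.approx(single["auc_mean"], abs=1e-12)
                assert rows.loc[kind, "auc_ci_low"] == pytest.approx(single["auc_ci_low"], abs=1e-12)


class TestSelection:
    def _table(self, **overrides):
        row = {
            "mirnas": ("a", "b", "c", "d", "e"),
            "constant_kind": "max_separation",
            "mean_sens": 0.82,
            "mean_spec": 0.81,
            "auc_mean": 0.89,
            "auc_ci_low": 0.83,
            "auc_ci_high": 0.95,
            "ca199_auc_mean": 0.83,
        }
        row.update(overrides)
        return pd.DataFrame([row])

    def test_passing_candidate_kept(self):
        out = filter_by_criteria(self._table(), SearchConfig())
        assert len(out) == 1

    def test_ci_low_below_bound_dropped(self):
        out = filter_by_criteria(self._table(auc_ci_low=0.79), SearchConfig())
        assert len(out) == 0

    def test_empty_input_gives_empty_output(self):
        cols = self._table().columns
        out = filter_by_criteria(pd.DataFrame(columns=cols), SearchConfig())
        assert len(out) == 0

    def test_tightening_thresholds_is_monotone(self, rng):
        X, y, ca = _cohort(rng, p=6, shift=1.2)
        table = search_signatures(X, y, ca, SearchConfig(seed=5))
        prev = None
        for s in (0.5, 0.7, 0.8, 0.9):
            kept = filter_by_criteria(table, SearchConfig(sens_threshold=s, spec_threshold=s, auc_ci_low_threshold=s))
            keys = set(map(tuple, kept[["mirnas", "constant_kind"]].itertuples(index=False)))
            if prev is not None:
                assert keys <= prev
            prev = keys


class TestVariableCountSweep:
    def test_three_informative_markers_plateau_by_size_three(self, rng):
        # markers m0..m2 carry the effect; m3..m5 are noise
        X, y, ca = _cohort(rng, n0=80, n1=80, p=6)
        X.loc[y == 1, ["m0", "m1", "m2"]] += 2.0
        cfg = SearchConfig(seed=6)
        out = variable_count_sweep(X, y, ca, sizes=(3, 5), config=cfg).set_index("subset_size")
        assert abs(out.loc[3, "best_auc_mean"] - out.loc[5, "best_auc_mean"]) < 0.02

    def test_size_beyond_marker_count_errors(self, rng):
        X, y, ca = _cohort(rng, p=4)
        with pytest.raises(DataError):
            variable_count_sweep(X, y, ca, sizes=(5,), config=SearchConfig(seed=0))
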