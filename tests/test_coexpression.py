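import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirsig import coexpression
from mirsig.coexpression import (
    ModuleSet,
    NetworkConfig,
    adjacency_tom,
    detect_modules,
    module_eigengenes,
    module_trait_relationships,
    partition_agreement,
    select_disease_mirnas,
)
from mirsig.dataio import DataError


def _blocks(rng, sizes, n_samples=100, within=0.9):
    """Expression with planted correlation blocks (zero between blocks)."""
    lam = np.sqrt(within / (1 - within))
    rows, labels = [], []
    for b, size in enumerate(sizes):
        f = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(lam * f + rng.normal(size=n_samples))
            labels.append(b + 1)
    ids = [f"m{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids), pd.Series(labels, index=ids)


def brute_force_tom_dissimilarity(values, power):
    """Triple-loop evaluation of the topological-overlap formula."""
    X = values.to_numpy(float)
    p = X.shape[0]
    a = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i != j:
                a[i, j] = abs(np.corrcoef(X[i], X[j])[0, 1]) ** power
    k = a.sum(axis=1)
    tom = np.eye(p)
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(p) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return 1.0 - tom


class TestAdjacencyTom:
    def test_identical_profiles_have_zero_dissimilarity(self, rng):
        row = rng.normal(size=20)
        values = pd.DataFrame([row, row], index=["a", "b"])
        d = adjacency_tom(values, NetworkConfig())
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_uncorrelated_pair_in_two_node_network(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # exactly orthogonal to x
        d = adjacency_tom(pd.DataFrame([x, y], index=["a", "b"]), NetworkConfig())
        assert d.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_on_random_five_nodes(self, rng):
        values = pd.DataFrame(rng.normal(size=(5, 30)), index=list("abcde"))
        d = adjacency_tom(values, NetworkConfig(soft_power=5))
        expected = brute_force_tom_dissimilarity(values, 5)
        assert np.allclose(d.to_numpy(), expected, atol=1e-12)

    def test_tom_bounds_and_symmetry(self, rng):
        values = pd.DataFrame(rng.normal(size=(12, 40)))
        d = adjacency_tom(values, NetworkConfig()).to_numpy()
        assert np.allclose(d, d.T)
        assert (d >= -1e-12).all() and (d <= 1.0 + 1e-12).all()
        assert np.allclose(np.diag(d), 0.0)

    def test_constant_row_errors_with_name(self, rng):
        values = pd.DataFrame(rng.normal(size=(3, 10)), index=["a", "flat", "c"])
        values.loc["flat"] = 1.0
        with pytest.raises(DataError, match="flat"):
            adjacency_tom(values, NetworkConfig())


class TestDetectModules:
    def test_recovers_two_planted_blocks(self, rng):
        values, truth = _blocks(rng, [15, 15])
        d = adjacency_tom(values, NetworkConfig())
        labels = detect_modules(d, NetworkConfig(min_module_size=10))
        assert labels.max() == 2
        assert partition_agreement(labels, truth) >= 0.9

    def test_below_min_size_all_unassigned_with_warning(self, rng):
        values, _ = _blocks(rng, [8])
        d = adjacency_tom(values, NetworkConfig())
        with pytest.warns(UserWarning):
            labels = detect_modules(d, NetworkConfig(min_module_size=10))
        assert (labels == 0).all()

    def test_deterministic_on_identical_input(self, rng):
        values, _ = _blocks(rng, [12, 12, 12])
        d = adjacency_tom(values, NetworkConfig())
        a = detect_modules(d, NetworkConfig())
        b = detect_modules(d, NetworkConfig())
        pd.testing.assert_series_equal(a, b)

    def test_label_invariance_under_row_permutation(self, rng):
        values, _ = _blocks(rng, [15, 15])
        perm = rng.permutation(len(values))
        d1 = adjacency_tom(values, NetworkConfig())
        d2 = adjacency_tom(values.iloc[perm], NetworkConfig())
        l1 = detect_modules(d1, NetworkConfig())
        l2 = detect_modules(d2, NetworkConfig())
        assert partition_agreement(l1, l2) == 1.0 and partition_agreement(l2, l1) == 1.0


class TestEigengenes:
    def test_identical_members_reproduce_the_profile(self, rng):
        row = rng.normal(size=30)
        z = (row - row.mean()) / row.std()
        values = pd.DataFrame([row, row, row], index=["a", "b", "c"])
        eig = module_eigengenes(values, pd.Series(1, index=values.index))
        assert np.allclose(eig.loc[1], z, atol=1e-10)

    def test_sign_flip_of_members_keeps_positive_orientation(self, rng):
        values, _ = _blocks(rng, [10])
        assignment = pd.Series(1, index=values.index)
        e1 = module_eigengenes(values, assignment)
        e2 = module_eigengenes(-values, assignment)
        m1 = np.mean([np.corrcoef(e1.loc[1], values.loc[m])[0, 1] for m in values.index])
        m2 = np.mean([np.corrcoef(e2.loc[1], -values.loc[m])[0, 1] for m in values.index])
        assert m1 > 0 and m2 > 0

    def test_matches_svd_oracle(self, rng):
        values = pd.DataFrame(rng.normal(size=(3, 25)), index=["a", "b", "c"])
        eig = module_eigengenes(values, pd.Series(1, index=values.index)).loc[1].to_numpy()
        X = values.to_numpy()
        Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        pc1 = Vt[0] / Vt[0].std()
        align = np.sign(pc1 @ eig)
        assert np.allclose(eig, align * pc1, atol=1e-10)

    def test_explains_at_least_single_member_variance(self, rng):
        values, _ = _blocks(rng, [12])
        eig = module_eigengenes(values, pd.Series(1, index=values.index)).loc[1]
        X = values.to_numpy()
        Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        var_eig = np.mean([(np.corrcoef(eig, r)[0, 1]) ** 2 for r in Xs])
        var_best_member = max(
            np.mean([(np.corrcoef(Xs[i], r)[0, 1]) ** 2 for r in Xs]) for i in range(len(Xs))
        )
        assert var_eig >= var_best_member - 1e-12


class TestModuleTraits:
    def test_perfect_correlation(self):
        e = pd.DataFrame([np.arange(10.0)], index=[1])
        traits = pd.DataFrame({"t": np.arange(10.0)}, index=e.columns)
        r, p = module_trait_relationships(e, traits)
        assert r.loc[1, "t"] == pytest.approx(1.0)
        assert p.loc[1, "t"] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_r_and_p_on_five_points(self, rng):
        e = pd.DataFrame([rng.normal(size=5)], index=[1])
        traits = pd.DataFrame({"t": rng.normal(size=5)}, index=e.columns)
        r, p = module_trait_relationships(e, traits)
        rr, pp = stats.pearsonr(e.loc[1], traits["t"])
        assert r.loc[1, "t"] == pytest.approx(rr, abs=1e-10)
        assert p.loc[1, "t"] == pytest.approx(pp, abs=1e-10)

    def test_null_p_values_approximately_uniform(self, rng):
        n, reps = 100, 1000
        X = rng.normal(size=(reps, n))
        Y = rng.normal(size=(reps, n))
        xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        ys = (Y - Y.mean(1, keepdims=True)) / Y.std(1, keepdims=True)
        r = (xs * ys).mean(axis=1)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_constant_trait_reported_as_zero_with_p_one(self, rng):
        e = pd.DataFrame([rng.normal(size=8)], index=[1])
        traits = pd.DataFrame({"flat": np.ones(8)}, index=e.columns)
        r, p = module_trait_relationships(e, traits)
        assert r.loc[1, "flat"] == 0.0 and p.loc[1, "flat"] == 1.0


class TestDiseaseSelection:
    def _module_set(self, r_rows, p_rows):
        cols = ["disease_score", "log_cea", "log_ca199", "ct_score", "cn_score", "cm_score", "serum_storage_min"]
        labels = list(range(1, len(r_rows) + 1))
        assignment = pd.Series(
            sum([[lab] * 2 for lab in labels], []),
            index=[f"m{lab}_{i}" for lab in labels for i in range(2)],
        )
        return ModuleSet(
            assignment=assignment,
            module_trait_r=pd.DataFrame(r_rows, index=labels, columns=cols),
            module_trait_p=pd.DataFrame(p_rows, index=labels, columns=cols),
        )

    def test_disease_significant_module_selected(self):
        ms = self._module_set(
            [[0.29, 0.22, 0.23, 0.1, 0.1, 0.1, 0.02]],
            [[1e-4, 1e-3, 1e-3, 0.2, 0.2, 0.2, 0.8]],
        )
        selected = select_disease_mirnas(ms)
        assert set(selected) == {"m1_0", "m1_1"}
        assert bool(ms.disease_flags[1]) and not bool(ms.rejected_flags[1])

    def test_storage_dominated_module_rejected(self):
        ms = self._module_set(
            [[0.05, 0.02, 0.03, 0.02, 0.01, 0.02, 0.40]],
            [[0.03, 0.5, 0.5, 0.7, 0.9, 0.8, 1e-8]],
        )
        selected = select_disease_mirnas(ms)
        assert selected == []
        assert bool(ms.rejected_flags[1])

    def test_no_significant_module_returns_empty_with_warning(self):
        ms = self._module_set(
            [[0.05, 0.02, 0.03, 0.02, 0.01, 0.02, 0.02]],
            [[0.4, 0.5, 0.5, 0.7, 0.9, 0.8, 0.9]],
        )
        with pytest.warns(UserWarning):
            assert select_disease_mirnas(ms) == []
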