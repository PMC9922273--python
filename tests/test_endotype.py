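"""Network modules, consensus clustering, clinical tests and the tree."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from somaqtl import NetworkConfig, ProteinMatrix, protein_score
from somaqtl.endotype import (compare_endotypes_clinical, consensus_cluster,
                              detect_modules, pick_soft_threshold,
                              residualize, tom_similarity,
                              train_endotype_tree)


def _planted_residuals(rng, n=300, sizes=(30, 30), noise=40, within=0.7):
    """Block-correlated analytes: latent factor per block, plus noise."""
    cols = []
    truth = []
    lam = np.sqrt(within / (1 - within))
    for b, size in enumerate(sizes):
        f = rng.standard_normal(n)
        block = lam * f[:, None] + rng.standard_normal((n, size))
        cols.append(block)
        truth += [b + 1] * size
    cols.append(rng.standard_normal((n, noise)))
    truth += [0] * noise
    X = np.concatenate(cols, axis=1) / np.sqrt(1 + lam**2)
    ids = pd.Index([f"a{j}" for j in range(X.shape[1])], name="analyte_id")
    return pd.DataFrame(X, columns=ids), np.array(truth)


class TestResidualize:
    def _cov(self, rng, n):
        return pd.DataFrame({
            "age": rng.normal(60, 8, n), "sex": rng.integers(0, 2, n),
            "center": rng.integers(0, 3, n),
        }, index=pd.Index([f"S{i}" for i in range(n)], name="sample_id"))

    def test_orthogonal_covariates_center_only(self, rng):
        cov = self._cov(rng, 200)
        data = pd.DataFrame(rng.normal(5, 1, (200, 10)), index=cov.index)
        out = residualize(data, cov)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)

    def test_perfect_covariate_fit_zero_residuals(self, rng):
        cov = self._cov(rng, 100)
        data = pd.DataFrame({"a0": 3.0 * cov["age"]}, index=cov.index)
        out = residualize(data, cov)
        np.testing.assert_allclose(out["a0"], 0.0, atol=1e-8)

    def test_residuals_uncorrelated_with_covariates(self, rng):
        cov = self._cov(rng, 300)
        data = pd.DataFrame(rng.normal(size=(300, 5)), index=cov.index)
        data = data.add(0.1 * cov["age"], axis=0)
        out = residualize(data, cov)
        for c in ("age", "sex"):
            r = np.corrcoef(out.to_numpy().T, cov[c].to_numpy())[-1, :-1]
            assert np.abs(r).max() < 1e-10

    def test_missing_covariates_dropped(self, rng):
        cov = self._cov(rng, 50)
        cov.loc[cov.index[0], "age"] = np.nan
        data = pd.DataFrame(rng.normal(size=(50, 3)), index=cov.index)
        with pytest.warns(UserWarning, match="missing covariates"):
            out = residualize(data, cov)
        assert len(out) == 49


class TestSoftThreshold:
    def test_connectivity_decreases_with_power(self, rng):
        data, _ = _planted_residuals(rng)
        tab = pick_soft_threshold(data, powers=(1, 3, 5, 7))
        assert (np.diff(tab["mean_k"]) < 0).all()

    def test_modular_data_reaches_good_fit(self, rng):
        """Heterogeneous modules (varied sizes and loadings, the realistic
        co-expression structure) reach a strong scale-free fit."""
        cols = []
        for size in (40, 25, 15, 10, 10):
            f = rng.standard_normal(500)
            lam = rng.uniform(0.5, 2.0, size)
            cols.append(lam * f[:, None] + rng.standard_normal((500, size)))
        cols.append(rng.standard_normal((500, 30)))
        data = pd.DataFrame(np.concatenate(cols, axis=1))
        tab = pick_soft_threshold(data, powers=(4, 6, 8, 10, 12))
        good = tab.loc[tab["fit_ok"]]
        assert good["r2"].max() > 0.8
        assert (good["slope"] < 0).any()

    def test_pure_noise_low_fit_at_power_one(self, rng):
        data, _ = _planted_residuals(rng, n=2000, sizes=(), noise=100)
        tab = pick_soft_threshold(data, powers=(1,))
        row = tab.iloc[0]
        assert (not row["fit_ok"]) or row["r2"] < 0.5

    def test_too_few_analytes_rejected(self, rng):
        with pytest.raises(ValueError):
            pick_soft_threshold(pd.DataFrame(rng.normal(size=(50, 10))))


class TestTom:
    def test_identical_profiles_tom_one(self, rng):
        base = rng.standard_normal(100)
        data = pd.DataFrame({"a": base, "b": base, "c": base})
        tom = tom_similarity(data, NetworkConfig(power=6))
        np.testing.assert_allclose(tom, 1.0, atol=1e-10)

    def test_independent_noise_tom_near_zero(self, rng):
        data = pd.DataFrame(rng.standard_normal((2000, 30)))
        tom = tom_similarity(data, NetworkConfig(power=6))
        off = tom[~np.eye(30, dtype=bool)]
        assert off.max() < 0.05

    def test_matches_elementwise_formula(self, rng):
        data = pd.DataFrame(rng.standard_normal((50, 5)))
        power = 7.0
        tom = tom_similarity(data, NetworkConfig(power=power))
        R = np.corrcoef(data.to_numpy(), rowvar=False)
        A = np.abs(R) ** power
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=0)
        for i in range(5):
            for j in range(5):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                num = sum(A[i, u] * A[u, j] for u in range(5)
                          if u not in (i, j)) + A[i, j]
                den = min(k[i], k[j]) + 1 - A[i, j]
                assert tom[i, j] == pytest.approx(num / den, rel=1e-10)

    def test_symmetry_unit_diagonal_bounded(self, rng):
        for _ in range(20):
            data = pd.DataFrame(rng.standard_normal((40, 15)))
            tom = tom_similarity(data, NetworkConfig(power=11))
            np.testing.assert_allclose(tom, tom.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(tom), 1.0)
            assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_constant_analyte_named(self, rng):
        data = pd.DataFrame(rng.standard_normal((30, 4)))
        data.iloc[:, 2] = 5.0
        with pytest.raises(ValueError, match="constant"):
            tom_similarity(data, NetworkConfig())


class TestModules:
    def test_planted_partition_recovered(self, rng):
        data, truth = _planted_residuals(rng, n=400, sizes=(40, 40), noise=40)
        cfg = NetworkConfig(power=6, min_module_size=30)
        tom = tom_similarity(data, cfg)
        labels = detect_modules(tom, cfg, data.columns)
        assert labels.max() == 2
        planted = truth > 0
        agree = adjusted_rand_score(truth[planted], labels[planted])
        assert agree > 0.95

    def test_min_size_above_n_gives_zero_modules(self, rng):
        data, _ = _planted_residuals(rng, n=200, sizes=(20, 20), noise=0)
        cfg = NetworkConfig(power=6, min_module_size=100)
        with pytest.warns(UserWarning, match="no module"):
            labels = detect_modules(tom_similarity(data, cfg), cfg)
        assert (labels == 0).all()

    def test_permutation_equivariance(self, rng):
        data, _ = _planted_residuals(rng, n=300, sizes=(30, 30), noise=20)
        cfg = NetworkConfig(power=6, min_module_size=20)
        labels = detect_modules(tom_similarity(data, cfg), cfg, data.columns)
        perm = rng.permutation(data.shape[1])
        shuffled = data.iloc[:, perm]
        labels_p = detect_modules(tom_similarity(shuffled, cfg), cfg,
                                  shuffled.columns)
        assert adjusted_rand_score(labels[shuffled.columns], labels_p) == 1.0


class TestConsensus:
    def test_degenerate_single_replicate_binary(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 4)))
        res = consensus_cluster(X, k_max=3, n_reps=1, subsample=1.0, seed=0)
        M = res.consensus[2]
        assert set(np.unique(M)) <= {0.0, 1.0}
        assert np.allclose(M, M.T) and np.allclose(np.diag(M), 1.0)

    def test_two_blobs_recovered(self, rng):
        X = np.concatenate([rng.normal(0, 1, (40, 5)),
                            rng.normal(5, 1, (40, 5))])
        res = consensus_cluster(pd.DataFrame(X), k_max=4, n_reps=50, seed=1)
        truth = np.repeat([0, 1], 40)
        M = res.consensus[2]
        same = truth[:, None] == truth[None, :]
        off = ~np.eye(80, dtype=bool)
        assert M[same & off].mean() > 0.95
        assert M[~same].mean() < 0.05
        assert adjusted_rand_score(truth, res.labels[2]) > 0.9
        assert res.chosen_k == 2

    def test_consensus_entries_are_proportions(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 3)))
        res = consensus_cluster(X, k_max=3, n_reps=30, seed=2)
        for M in res.consensus.values():
            assert M.min() >= 0.0 and M.max() <= 1.0

    def test_k_max_validation(self, rng):
        with pytest.raises(ValueError):
            consensus_cluster(pd.DataFrame(rng.normal(size=(30, 3))), k_max=1)

    def test_tracking_table_shape(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 3)))
        res = consensus_cluster(X, k_max=4, n_reps=10, seed=3)
        track = res.tracking()
        assert list(track.columns) == ["k=2", "k=3", "k=4"]
        assert len(track) == 30


class TestClinicalComparison:
    def _clinical(self, rng, n=200, ptau_shift=0.0, sex_conf=0.0):
        lab = pd.Series(rng.integers(1, 3, n),
                        index=pd.Index([f"S{i}" for i in range(n)]))
        sex = rng.integers(0, 2, n)
        clin = pd.DataFrame({
            "age": rng.normal(62, 8, n), "sex": sex,
            "ptau": rng.normal(14, 2, n) + ptau_shift * (lab == 2),
            "abeta": rng.normal(900, 150, n) + sex_conf * sex,
            "total_tau": rng.normal(170, 40, n),
            "asyn": rng.normal(1500, 300, n),
            "updrs1": rng.normal(5, 2, n), "moca": rng.normal(27, 2, n),
        }, index=lab.index)
        return lab, clin

    def test_null_no_findings(self, rng):
        lab, clin = self._clinical(rng)
        out = compare_endotypes_clinical(lab, clin)
        from somaqtl.preprocess import bh_fdr
        assert (bh_fdr(out["p"]) > 0.05).all()

    def test_ptau_shift_flagged_with_direction(self, rng):
        lab, clin = self._clinical(rng, ptau_shift=-5.0)
        out = compare_endotypes_clinical(lab, clin).set_index("variable")
        assert out.loc["ptau", "p"] < 1e-6
        assert out.loc["ptau", "direction"] == "lower for endotype 2"

    def test_sex_adjustment_prevents_confounding(self, rng):
        """A variable driven purely by sex (and sex imbalanced between
        endotypes) is not attributed to the endotype once adjusted."""
        n = 400
        lab = pd.Series(np.repeat([1, 2], n // 2),
                        index=pd.Index([f"S{i}" for i in range(n)]))
        sex = (rng.random(n) < np.where(lab == 2, 0.8, 0.2)).astype(int)
        clin = pd.DataFrame({
            "age": rng.normal(62, 8, n), "sex": sex,
            "ptau": rng.normal(14, 2, n) + 3.0 * sex,
        }, index=lab.index)
        out = compare_endotypes_clinical(
            lab, clin, quantitative=("ptau",)).set_index("variable")
        from scipy import stats as sps
        naive_p = sps.ttest_ind(clin.loc[lab == 1, "ptau"],
                                clin.loc[lab == 2, "ptau"]).pvalue
        assert naive_p < 0.01
        assert out.loc["ptau", "p"] > 0.05

    def test_too_small_groups_rejected(self, rng):
        lab, clin = self._clinical(rng, 8)
        lab.iloc[:] = 1
        lab.iloc[0] = 2
        with pytest.raises(ValueError):
            compare_endotypes_clinical(lab, clin)


class TestProteinScore:
    def test_zero_weights(self, toy_protein_matrix):
        w = {a: 0.0 for a in toy_protein_matrix.analyte_ids[:3]}
        assert (protein_score(w, toy_protein_matrix) == 0).all()

    def test_single_weight_identity(self, toy_protein_matrix):
        aid = toy_protein_matrix.analyte_ids[2]
        s = protein_score({aid: 1.0}, toy_protein_matrix)
        pd.testing.assert_series_equal(s, toy_protein_matrix.values[aid],
                                       check_names=False)

    def test_manual_dot_product(self, toy_protein_matrix):
        ids = list(toy_protein_matrix.analyte_ids[:3])
        w = {ids[0]: 0.5, ids[1]: -1.0, ids[2]: 2.0}
        s = protein_score(w, toy_protein_matrix)
        v = toy_protein_matrix.values
        expected = 0.5 * v[ids[0]] - 1.0 * v[ids[1]] + 2.0 * v[ids[2]]
        np.testing.assert_allclose(s, expected)

    def test_missing_analyte_listed(self, toy_protein_matrix):
        with pytest.raises(ValueError, match="ghost"):
            protein_score({"ghost": 1.0}, toy_protein_matrix)

    def test_empty_weights_rejected(self, toy_protein_matrix):
        with pytest.raises(ValueError):
            protein_score({}, toy_protein_matrix)


class TestTree:
    def _clinical(self, rng, n, ptau):
        return pd.DataFrame({
            "age": rng.normal(62, 8, n), "sex": rng.integers(0, 2, n),
            "ptau": ptau,
            "abeta": rng.normal(900, 150, n),
            "total_tau": rng.normal(170, 40, n),
            "asyn": rng.normal(1500, 300, n),
            "updrs1": rng.normal(5, 2, n), "moca": rng.normal(27, 2, n),
        }, index=pd.Index([f"S{i}" for i in range(n)]))

    def test_separable_single_split_at_cutoff(self, rng):
        """Perfectly separable p-tau around 11: one split, threshold inside
        the separating gap, perfect test accuracy."""
        n = 200
        labels = pd.Series(rng.integers(1, 3, n),
                           index=pd.Index([f"S{i}" for i in range(n)]))
        ptau = np.where(labels == 2, rng.uniform(6, 10.2, n),
                        rng.uniform(11.8, 16, n))
        tree = train_endotype_tree(self._clinical(rng, n, ptau), labels, seed=0)
        assert tree.n_splits == 1
        var, thr = tree.root_split()
        assert var == "ptau"
        assert 10.2 < thr < 11.8
        assert tree.test_accuracy == 1.0
        assert tree.test_auc == 1.0

    def test_null_prunes_to_root(self, rng):
        n = 400
        labels = pd.Series(np.where(rng.random(n) < 0.6, 1, 2),
                           index=pd.Index([f"S{i}" for i in range(n)]))
        ptau = rng.normal(12, 3, n)       # independent of the labels
        tree = train_endotype_tree(self._clinical(rng, n, ptau), labels, seed=0)
        assert tree.root_split() is None
        majority = labels.value_counts(normalize=True).max()
        assert abs(tree.test_accuracy - majority) < 0.15

    def test_pruning_monotone_in_cv_error(self, rng):
        n = 300
        labels = pd.Series(rng.integers(1, 3, n),
                           index=pd.Index([f"S{i}" for i in range(n)]))
        ptau = np.where(labels == 2, rng.normal(9, 2, n), rng.normal(13, 2, n))
        tree = train_endotype_tree(self._clinical(rng, n, ptau), labels, seed=1)
        cv = tree.cv_errors
        full = cv["cv_error"].iloc[0] + cv["cv_se"].iloc[0]
        assert tree.chosen_cv_error <= full + 1e-12

    def test_single_class_stump(self, rng):
        n = 60
        labels = pd.Series(1, index=pd.Index([f"S{i}" for i in range(n)]))
        with pytest.warns(UserWarning, match="single-class"):
            tree = train_endotype_tree(self._clinical(rng, n, rng.normal(12, 2, n)),
                                       labels, seed=0)
        assert tree.root_split() is None
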