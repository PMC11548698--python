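"""Median profiles, Kendall tau-b, PCA and clustering against oracles."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from leafmorph.stats import (
    build_species_profiles,
    cluster_species,
    kendall_matrix,
    median_profiles,
    run_pca,
)


def brute_tau_b(x, y):
    """Tau-b by explicit enumeration of all pairs."""
    nc = nd = tx = ty = 0
    for i, j in combinations(range(len(x)), 2):
        a = np.sign(x[i] - x[j])
        b = np.sign(y[i] - y[j])
        if a == 0 and b == 0:
            continue
        if a == 0:
            tx += 1
        elif b == 0:
            ty += 1
        elif a == b:
            nc += 1
        else:
            nd += 1
    denom = math.sqrt((nc + nd + tx) * (nc + nd + ty))
    return (nc - nd) / denom if denom else np.nan


class TestMedianProfiles:
    def test_median_conventions(self):
        t = pd.DataFrame({"species": ["a"] * 3 + ["b"] * 2, "A": [1, 2, 100, 1, 3]})
        out = median_profiles(t, features=["A"])
        assert out.loc["a", "A"] == 2.0  # odd n: middle value
        assert out.loc["b", "A"] == 2.0  # even n: mean of middle two

    def test_missing_feature_named(self):
        t = pd.DataFrame({"species": ["a"], "A": [np.nan]})
        with pytest.raises(ValueError, match="A"):
            median_profiles(t, features=["A"])


class TestKendall:
    def test_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        df = pd.DataFrame({"x": x, "same": x.copy(), "neg": -x})
        m = kendall_matrix(df, level="cell")
        assert m.loc["x", "same"] == pytest.approx(1.0)
        assert m.loc["x", "neg"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T, equal_nan=True)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.integers(0, 4, size=(6, 4)).astype(float), columns=list("abcd")
        )
        m = kendall_matrix(df, level="cell")
        for u, v in combinations("abcd", 2):
            expected = brute_tau_b(df[u].to_numpy(), df[v].to_numpy())
            if np.isnan(expected):
                assert np.isnan(m.loc[u, v])
            else:
                assert m.loc[u, v] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_is_nan(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "const": [5.0] * 4})
        m = kendall_matrix(df, level="cell")
        assert np.isnan(m.loc["x", "const"])
        assert m.loc["const", "const"] == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = kendall_matrix(pd.DataFrame({"x": x, "y": y}), level="cell")
        warped = kendall_matrix(
            pd.DataFrame({"x": np.exp(3 * x), "y": y**3}), level="cell"
        )
        assert base.loc["x", "y"] == pytest.approx(warped.loc["x", "y"], abs=1e-12)

    def test_image_level_aggregation(self):
        df = pd.DataFrame(
            {
                "image_id": ["i1"] * 5 + ["i2"] * 5 + ["i3"] * 5,
                "A": np.arange(15, dtype=float),
                "P": np.arange(15, dtype=float) * 2,
            }
        )
        m = kendall_matrix(df, features=["A", "P"], level="image")
        assert m.loc["A", "P"] == pytest.approx(1.0)

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="3 rows"):
            kendall_matrix(pd.DataFrame({"a": [1.0, 2], "b": [2.0, 1]}), level="cell")


class TestPCA:
    def test_rank_one_input(self):
        prof = pd.DataFrame({"f1": [1.0, 2, 3, 4], "f2": [2.0, 4, 6, 8]},
                            index=list("wxyz"))
        res = run_pca(prof)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        prof = pd.DataFrame(rng.normal(size=(9, 6)))
        res = run_pca(prof)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(res.variance_fractions) <= 1e-12)

    def test_isotropic_two_features(self):
        rng = np.random.default_rng(3)
        prof = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["u", "v"])
        res = run_pca(prof)
        assert res.variance_fractions[0] == pytest.approx(0.5, abs=0.02)

    def test_reconstruction_and_orthonormality(self):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(rng.normal(size=(8, 5)))
        res = run_pca(prof)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(5), atol=1e-10)
        Z = (prof - prof.mean()) / prof.std(ddof=1)
        assert np.abs(res.scores.to_numpy() @ L.T - Z.to_numpy()).max() < 1e-8

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(6)
        prof = pd.DataFrame(rng.normal(size=(12, 4)))
        res = run_pca(prof, standardize=False)
        sk = PCA().fit(prof.to_numpy() - prof.to_numpy().mean(axis=0))
        assert np.allclose(res.variance_fractions, sk.explained_variance_ratio_,
                           atol=1e-10)

    def test_zero_variance_feature_named(self):
        prof = pd.DataFrame({"ok": [1.0, 2, 3], "flat": [7.0, 7, 7]})
        with pytest.raises(ValueError, match="flat"):
            run_pca(prof)


class TestClustering:
    def test_two_species_single_merge(self):
        prof = pd.DataFrame({"f": [0.0, 1.0], "g": [1.0, 0.0]}, index=["a", "b"])
        res = cluster_species(prof)
        assert res.linkage.shape == (1, 4)

    def test_duplicate_rows_merge_first_at_zero(self):
        prof = pd.DataFrame(
            {"f": [0.0, 0.0, 5.0], "g": [1.0, 1.0, 9.0]}, index=["a", "b", "c"]
        )
        res = cluster_species(prof)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(7)
        prof = pd.DataFrame(rng.normal(size=(6, 3)), index=list("abcdef"))
        shuffled = prof.sample(frac=1.0, random_state=1)
        a = cluster_species(prof).flat_labels(3)
        b = cluster_species(shuffled).flat_labels(3)
        groups_a = {frozenset(k for k, v in a.items() if v == i) for i in set(a.values())}
        groups_b = {frozenset(k for k, v in b.items() if v == i) for i in set(b.values())}
        assert groups_a == groups_b

    def test_unknown_metric_lists_supported(self):
        prof = pd.DataFrame({"f": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="euclidean"):
            cluster_species(prof, metric="warsaw")

    def test_newick_round_trips_names(self):
        prof = pd.DataFrame(np.eye(4), index=["sp1", "sp2", "sp3", "sp4"])
        nwk = cluster_species(prof).to_newick()
        assert nwk.endswith(";")
        for name in prof.index:
            assert name in nwk

    def test_two_regimes_recovered(self):
        """Species medians drawn from two parameter regimes cluster perfectly."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(8)
        big = rng.normal([2000, 0.75, 40], [60, 0.02, 2], size=(4, 3))
        small = rng.normal([800, 0.92, 15], [40, 0.02, 2], size=(4, 3))
        prof = pd.DataFrame(
            np.vstack([big, small]),
            columns=["A", "CC", "st_D"],
            index=[f"sp{i}" for i in range(8)],
        )
        labels = cluster_species(prof).flat_labels(2)
        pred = [labels[f"sp{i}"] for i in range(8)]
        assert adjusted_rand_score([0] * 4 + [1] * 4, pred) == 1.0
        scores = run_pca(prof).scores["PC1"]
        lo, hi = scores.iloc[:4], scores.iloc[4:]
        assert max(lo) < min(hi) or max(hi) < min(lo)


class TestSpeciesProfiles:
    def _cells(self):
        rng = np.random.default_rng(9)
        rows = []
        for sp, base in (("a", 100.0), ("b", 200.0)):
            for side in ("ab", "ad"):
                for cls in ("pavement", "stoma"):
                    for _ in range(5):
                        rows.append(
                            {
                                "species": sp,
                                "side": side,
                                "cell_class": cls,
                                "A": base + rng.normal(),
                                "CC": 0.9,
                                "st_density_per_mm2": 30.0 if sp == "a" else 60.0,
                            }
                        )
        return pd.DataFrame(rows)

    def test_qualified_feature_names(self):
        prof = build_species_profiles(self._cells())
        assert {"A_ab", "A_ad", "st_A_ab", "st_A_ad", "st_D_ab", "st_D_ad"} <= set(
            prof.columns
        )
        assert list(prof.index) == ["a", "b"]
        assert prof.loc["a", "A_ab"] == pytest.approx(100.0, abs=2.0)

    def test_trichome_join_and_density_imputation(self):
        trich = pd.DataFrame(
            {"tr_L": [300.0], "tr_D": [5.0], "gtr_L": [np.nan], "gtr_D": [0.0]},
            index=pd.Index(["a"], name="species"),
        )
        prof = build_species_profiles(self._cells(), trich)
        assert prof.loc["a", "tr_D"] == 5.0
        assert prof.loc["b", "tr_D"] == 0.0  # absent density imputed as 0
        assert np.isnan(prof.loc["b", "tr_L"])  # absent length stays missing
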