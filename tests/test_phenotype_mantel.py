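import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from ssrpop.distance_tree import DistanceMatrix, distance_matrix
from ssrpop.phenotype_mantel import (
    descriptive_stats,
    euclidean_matrix,
    load_trait_table,
    mantel,
    pca,
    per_trait_mantel,
    standardize,
)


def _random_dm(rng, n, labels=None):
    d = squareform(rng.random(n * (n - 1) // 2))
    return DistanceMatrix(labels or [f"a{i}" for i in range(n)], d)


class TestDescriptives:
    def test_hand_values(self):
        t = pd.DataFrame({"x": [2.0, 4.0]}, index=["a", "b"])
        s = descriptive_stats(t)
        assert s.loc["x", "mean"] == pytest.approx(3.0)
        assert s.loc["x", "sd"] == pytest.approx(np.sqrt(2), rel=1e-6)
        assert s.loc["x", "cv_percent"] == pytest.approx(47.1405, rel=1e-4)

    def test_constant_trait(self):
        t = pd.DataFrame({"x": [5.0, 5.0, 5.0]}, index=list("abc"))
        s = descriptive_stats(t)
        assert s.loc["x", "sd"] == 0.0
        assert s.loc["x", "cv_percent"] == 0.0

    def test_scale_invariance_of_cv(self, rng):
        t = pd.DataFrame({"x": rng.uniform(1, 10, 8)}, index=[f"a{i}" for i in range(8)])
        s1 = descriptive_stats(t)
        s2 = descriptive_stats(t * 7.3)
        assert s1.loc["x", "cv_percent"] == pytest.approx(s2.loc["x", "cv_percent"])

    def test_zero_mean_flagged(self):
        t = pd.DataFrame({"x": [-1.0, 1.0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="CV undefined"):
            s = descriptive_stats(t)
        assert np.isnan(s.loc["x", "cv_percent"])


class TestEuclidean:
    def test_identical_accessions_zero(self):
        t = pd.DataFrame({"x": [1.0, 1.0, 2.0], "y": [0.0, 0.0, 5.0]}, index=list("abc"))
        d = euclidean_matrix(t)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_two_accessions_single_trait(self):
        t = pd.DataFrame({"x": [2.0, 4.0]}, index=["a", "b"])
        d = euclidean_matrix(t)
        z = (np.array([2.0, 4.0]) - 3.0) / np.sqrt(2)
        assert d.values[0, 1] == pytest.approx(abs(z[0] - z[1]))

    def test_hand_computed_unstandardized(self):
        t = pd.DataFrame(
            {"x": [0.0, 3.0, 0.0], "y": [0.0, 4.0, 1.0]}, index=list("abc")
        )
        d = euclidean_matrix(t, standardize_traits=False)
        assert d.values[0, 1] == pytest.approx(5.0)
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_zero_variance_trait_dropped_with_warning(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [7.0, 7.0, 7.0]}, index=list("abc"))
        with pytest.warns(UserWarning, match="zero-variance"):
            d = euclidean_matrix(t)
        assert d.n == 3

    def test_triangle_inequality(self, rng):
        t = pd.DataFrame(
            rng.normal(size=(10, 4)), index=[f"a{i}" for i in range(10)]
        )
        d = euclidean_matrix(t).values
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestPca:
    def test_perfectly_correlated_traits(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t = pd.DataFrame({"a": x, "b": 2 * x}, index=[f"s{i}" for i in range(4)])
        _, _, ev = pca(t)
        assert ev[0] == pytest.approx(100.0)

    def test_single_trait(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 5.0]}, index=list("xyz"))
        _, _, ev = pca(t)
        assert ev[0] == pytest.approx(100.0)

    def test_explained_variance_properties(self, rng):
        t = pd.DataFrame(
            rng.normal(size=(12, 6)), index=[f"s{i}" for i in range(12)]
        )
        _, loadings, ev = pca(t)
        assert ev.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(ev) <= 1e-9)
        # sign convention: largest-magnitude loading entry positive
        for col in loadings.columns:
            v = loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] >= 0

    def test_scores_reproduce_standardized_distances(self, rng):
        t = pd.DataFrame(
            rng.normal(size=(9, 4)), index=[f"s{i}" for i in range(9)]
        )
        scores, _, _ = pca(t)
        d_scores = squareform(pdist(scores.to_numpy()))
        d_direct = euclidean_matrix(t).values
        np.testing.assert_allclose(d_scores, d_direct, atol=1e-8)


class TestMantel:
    def test_identity_gives_r_one(self, rng):
        d = _random_dm(rng, 8)
        res = mantel(d, d, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        d = _random_dm(rng, 8)
        scaled = DistanceMatrix(
            d.labels, 3.0 * d.values + 0.1 * (1 - np.eye(d.n))
        )
        res = mantel(d, scaled, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_common_relabeling_invariance(self, rng):
        d1, d2 = _random_dm(rng, 9), _random_dm(rng, 9)
        r0 = mantel(d1, d2, n_permutations=19, seed=0).r
        perm = rng.permutation(9)
        p1 = DistanceMatrix(
            [d1.labels[i] for i in perm], d1.values[np.ix_(perm, perm)]
        )
        p2 = DistanceMatrix(
            [d2.labels[i] for i in perm], d2.values[np.ix_(perm, perm)]
        )
        assert mantel(p1, p2, n_permutations=19, seed=0).r == pytest.approx(r0)

    def test_matches_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel

        d1, d2 = _random_dm(rng, 10), _random_dm(rng, 10)
        mine = mantel(d1, d2, n_permutations=9, seed=1)
        r_sk, _, _ = sk_mantel(
            SkDM(d1.values, ids=d1.labels),
            SkDM(d2.values, ids=d2.labels),
            method="pearson",
            permutations=9,
            alternative="greater",
        )
        assert mine.r == pytest.approx(float(r_sk), abs=1e-12)

    def test_p_value_floor_and_seed(self, rng):
        d = _random_dm(rng, 8)
        res = mantel(d, d, n_permutations=199, seed=5)
        assert res.p_value >= 1 / 200
        again = mantel(d, d, n_permutations=199, seed=5)
        assert res.p_value == again.p_value

    def test_label_mismatch_rejected(self, rng):
        d1 = _random_dm(rng, 5)
        d2 = _random_dm(rng, 5, labels=[f"b{i}" for i in range(5)])
        with pytest.raises(ValueError, match="labels"):
            mantel(d1, d2)

    def test_zero_variance_rejected(self):
        ones = 1.0 - np.eye(5)
        d1 = DistanceMatrix([f"a{i}" for i in range(5)], ones)
        d2 = DistanceMatrix([f"a{i}" for i in range(5)], ones * 0.5)
        with pytest.raises(ValueError, match="variance"):
            mantel(d1, d2)


class TestPerTraitMantel:
    def test_constant_trait_flagged(self, structured_panel):
        bm, _ = structured_panel
        g = distance_matrix(bm)
        traits = pd.DataFrame(
            {"c": np.ones(len(bm.accessions)), "v": np.arange(len(bm.accessions))},
            index=bm.accessions, dtype=float,
        )
        with pytest.warns(UserWarning, match="constant"):
            tab = per_trait_mantel(g, traits, n_permutations=19, seed=0)
        assert np.isnan(tab.loc["c", "r"])
        assert not np.isnan(tab.loc["v", "r"])

    def test_genetically_driven_trait_ranks_first(self):
        # one fully genetic trait vs ten noise traits: the driven trait has
        # the largest Mantel r in nearly every run on a divergent panel
        from ssrpop.synthetic_data import (
            SimPhenotypeSpec,
            SimPopulationSpec,
            simulate_band_matrix,
            simulate_phenotypes,
        )

        rng = np.random.default_rng(8)
        wins, n_runs = 0, 25
        for _ in range(n_runs):
            bm, _ = simulate_band_matrix(
                SimPopulationSpec(n_groups=3, accessions_per_group=20,
                                  theta=0.7, seed=int(rng.integers(2**31)))
            )
            g = distance_matrix(bm)
            driven, _ = simulate_phenotypes(
                bm, SimPhenotypeSpec(n_traits=1, genetic_weight=1.0,
                                     loci_per_trait=200,
                                     seed=int(rng.integers(2**31)))
            )
            noise = pd.DataFrame(
                rng.normal(size=(len(bm.accessions), 10)),
                index=bm.accessions,
                columns=[f"N{i}" for i in range(10)],
            )
            traits = pd.concat([driven, noise], axis=1)
            tab = per_trait_mantel(g, traits, n_permutations=19,
                                   seed=int(rng.integers(2**31)))
            wins += tab["r"].idxmax() == driven.columns[0]
        assert wins / n_runs >= 0.92

    def test_trait_tracking_genetic_geometry_gives_high_r(self, structured_panel):
        # a trait equal to each accession's genetic distance to a reference
        # captures one axis of the distance geometry (strong positive r);
        # the dominant principal coordinate captures most of it (r near 1)
        bm, _ = structured_panel
        g = distance_matrix(bm)
        d2 = g.values**2
        j = np.eye(g.n) - 1.0 / g.n
        b = -0.5 * j @ d2 @ j
        w, v = np.linalg.eigh(b)
        traits = pd.DataFrame(
            {"to_ref": g.values[0, :], "pcoa1": v[:, -1] * np.sqrt(max(w[-1], 0))},
            index=g.labels,
        )
        tab = per_trait_mantel(g, traits, n_permutations=99, seed=2)
        assert tab.loc["to_ref", "r"] > 0.4
        assert tab.loc["pcoa1", "r"] > 0.75
        assert (tab["p_value"] <= 0.05).all()


def test_load_trait_table_validates(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text("accession\tPH\tSD\na\t10\t1\nb\t12\t\n")
    with pytest.raises(ValueError, match="missing"):
        load_trait_table(p)
    p.write_text("accession\tPH\tSD\na\t10\t1\nb\t12\t2\n")
    t = load_trait_table(p)
    assert t.shape == (2, 2)
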