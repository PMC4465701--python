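"""Matrix T, matrix correlations, trait-subset search and d-separation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from phylostruct import Metacommunity, Phylogeny, TraitTable
from phylostruct.community import TRAIT_NAMES
from phylostruct.fuzzy import build_matrix_P
from phylostruct.traits import (MatrixCorrelation, Verdict, build_matrix_T,
                                derive_robustness, dsep_verdict,
                                env_dissimilarity, matrix_correlation,
                                optimal_trait_subset,
                                partial_matrix_correlation,
                                permutation_test_TE, rho_PT, rho_TE_given_P,
                                standardize_traits, trait_dissimilarity)


def make_traits(values: dict, species) -> TraitTable:
    base = {t: [1.0] * len(species) for t in TRAIT_NAMES}
    base.update(values)
    return TraitTable(pd.DataFrame(base, index=species))


class TestRobustness:
    def test_exact_allometry_gives_zero_residuals(self):
        svl = np.array([100.0, 200.0, 400.0, 800.0])
        tt = make_traits({"SVL": svl, "CAM": 0.1 * svl}, list("ABCD"))
        out = derive_robustness(tt)
        np.testing.assert_allclose(out.data["robustness"], 0.0, atol=1e-12)

    def test_fat_species_positive_residual(self):
        svl = np.array([100.0, 200.0, 400.0, 800.0])
        cam = 0.1 * svl
        cam[2] *= 1.5  # fatter than the allometric line
        tt = make_traits({"SVL": svl, "CAM": cam}, list("ABCD"))
        out = derive_robustness(tt)
        assert out.data["robustness"]["C"] > 0

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(1)
        svl = rng.uniform(100, 1000, size=4)
        cam = rng.uniform(10, 100, size=4)
        tt = make_traits({"SVL": svl, "CAM": cam}, list("ABCD"))
        out = derive_robustness(tt)
        x, y = np.log(svl), np.log(cam)
        slope = np.cov(x, y, ddof=0)[0, 1] / np.var(x)
        resid = y - (y.mean() + slope * (x - x.mean()))
        np.testing.assert_allclose(out.data["robustness"], resid, atol=1e-10)

    def test_too_few_species_rejected(self):
        tt = make_traits({}, ["A", "B"])
        with pytest.raises(ValueError):
            derive_robustness(tt)


class TestStandardize:
    def test_ranging(self):
        df = pd.DataFrame({"x": [10.0, 20.0, 30.0]})
        out = standardize_traits(df)
        assert out["x"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_dropped_with_warning(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "c": [5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = standardize_traits(df)
        assert list(out.columns) == ["x"]

    def test_idempotent(self):
        df = pd.DataFrame({"x": [0.0, 0.25, 1.0]})
        out = standardize_traits(standardize_traits(df))
        assert out["x"].tolist() == [0.0, 0.25, 1.0]


class TestMatrixT:
    def test_two_species_mean(self, toy_metacommunity):
        B = pd.DataFrame({"x": [0.0, 1.0, 0.4, 0.8]}, index=list("ABCD"))
        T = build_matrix_T(B, toy_metacommunity)
        assert T.loc["f1", "x"] == pytest.approx(0.5)  # A and B present

    def test_singleton_site_row_equals_species(self):
        presence = pd.DataFrame([[1, 0], [1, 1]], index=["s1", "s2"],
                                columns=["A", "B"])
        mc = Metacommunity(presence, {"s1": "forest", "s2": "non_forest"},
                           {"s1": 1.0, "s2": 2.0})
        B = pd.DataFrame({"x": [0.3, 0.9]}, index=["A", "B"])
        T = build_matrix_T(B, mc)
        assert T.loc["s1", "x"] == pytest.approx(0.3)

    def test_matches_matrix_product_oracle(self, toy_metacommunity):
        rng = np.random.default_rng(4)
        B = pd.DataFrame(rng.random((4, 3)), index=list("ABCD"),
                         columns=["x", "y", "z"])
        T = build_matrix_T(B, toy_metacommunity)
        W = toy_metacommunity.presence.to_numpy().astype(float)
        Wrel = W / W.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(T.to_numpy(), Wrel @ B.to_numpy())

    def test_uncovered_species_rejected(self, toy_metacommunity):
        B = pd.DataFrame({"x": [0.1, 0.2]}, index=["A", "B"])
        with pytest.raises(ValueError, match="without trait values"):
            build_matrix_T(B, toy_metacommunity)


class TestDissimilarities:
    def test_env_mismatch(self, toy_metacommunity):
        E = env_dissimilarity(toy_metacommunity)
        assert E["f1", "f2"] == 0
        assert E["f1", "n1"] == 1

    def test_single_habitat_undefined(self, toy_metacommunity):
        mc = toy_metacommunity.restrict_sites(["f1", "f2"])
        with pytest.raises(ValueError, match="single habitat"):
            env_dissimilarity(mc)

    def test_identical_trait_rows(self):
        T = pd.DataFrame([[0.1, 0.2], [0.1, 0.2], [0.5, 0.9]],
                         index=["a", "b", "c"])
        D = trait_dissimilarity(T)
        assert D["a", "b"] == 0


class TestMatrixCorrelation:
    def test_proportional_matrices(self, toy_metacommunity):
        E = env_dissimilarity(toy_metacommunity)
        double = DistanceMatrix(E.data * 2, ids=list(E.ids))
        assert matrix_correlation(E, double) == pytest.approx(1.0)

    def test_reversed_matrices(self):
        rng = np.random.default_rng(0)
        X = rng.random((4, 2))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(X))
        A = DistanceMatrix(d, ids=list("abcd"))
        rev = d.max() - d
        np.fill_diagonal(rev, 0)
        B = DistanceMatrix(rev, ids=list("abcd"))
        assert matrix_correlation(A, B) == pytest.approx(-1.0)

    def test_hand_computed_four_sites(self):
        dx = np.array([1.0, 2.0, 3.0, 2.5, 1.5, 0.5])
        dy = np.array([0.9, 2.2, 2.7, 2.0, 1.1, 0.8])
        def mat(v):
            m = np.zeros((4, 4))
            m[np.tril_indices(4, -1)] = v
            return DistanceMatrix(m + m.T, ids=list("abcd"))
        expected = np.corrcoef(dx, dy)[0, 1]
        assert matrix_correlation(mat(dx), mat(dy)) == pytest.approx(expected)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(12)
        v = rng.random(6)
        w = rng.random(6)
        def mat(vals):
            m = np.zeros((4, 4))
            m[np.tril_indices(4, -1)] = vals
            return DistanceMatrix(m + m.T, ids=list("abcd"))
        r0 = matrix_correlation(mat(v), mat(w))
        r1 = matrix_correlation(mat(3 * v + 0.2), mat(w))
        assert r0 == pytest.approx(r1)


class TestPermutationTests:
    def test_perfectly_sorted_traits(self, toy_metacommunity):
        # forest species (A, B) high, non-forest (C, D) low, disjoint
        # membership: community means are habitat-constant and rho is 1.
        # The p floor is set by label symmetry: shuffles that keep equal
        # values within either cherry reproduce rho = 1 (8 of 24 here).
        presence = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
            index=["f1", "f2", "n1", "n2"], columns=list("ABCD"))
        mc = Metacommunity(presence, toy_metacommunity.habitat,
                           toy_metacommunity.latitude)
        B = pd.DataFrame({"x": [1.0, 1.0, 0.0, 0.0]}, index=list("ABCD"))
        res = permutation_test_TE(B, mc, n_perm=999,
                                  rng=np.random.default_rng(0))
        assert res.rho == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 3, abs=0.06)

    def test_p_never_zero(self):
        # +1 correction: even when the observed rho beats every draw the
        # p-value sits at its floor 1/(n_perm + 1), never 0
        from phylostruct.traits import _perm_p
        null = np.full(99, -0.5)
        assert _perm_p(null, 0.9) == pytest.approx(1 / 100)
        assert _perm_p(np.full(99, 0.95), 0.9) == 1.0

    def test_seed_reproducibility(self, toy_metacommunity):
        B = pd.DataFrame({"x": [0.0, 0.6, 0.4, 1.0]}, index=list("ABCD"))
        a = permutation_test_TE(B, toy_metacommunity, n_perm=99,
                                rng=np.random.default_rng(5))
        b = permutation_test_TE(B, toy_metacommunity, n_perm=99,
                                rng=np.random.default_rng(5))
        assert a.p == b.p and a.rho == b.rho

    def test_null_p_roughly_uniform(self):
        """Traits independent of habitat give well-spread p-values."""
        rng = np.random.default_rng(77)
        presence = pd.DataFrame(
            (rng.random((6, 8)) < 0.6).astype(int),
            index=[f"s{i}" for i in range(6)],
            columns=[f"sp{i}" for i in range(8)])
        presence.iloc[:, 0] = 1  # no empty sites
        mc = Metacommunity(
            presence,
            {f"s{i}": ("forest" if i % 2 else "non_forest") for i in range(6)},
            {f"s{i}": float(i) for i in range(6)})
        ps = []
        for rep in range(60):
            B = pd.DataFrame({"x": rng.random(8), "y": rng.random(8)},
                             index=presence.columns)
            res = permutation_test_TE(B, mc, n_perm=49, rng=rng)
            ps.append(res.p)
        ps = np.asarray(ps)
        assert 0.25 < ps.mean() < 0.75
        assert (ps < 0.06).mean() < 0.2


class TestPartialCorrelation:
    @staticmethod
    def _mat(vals, ids="abcd"):
        n = len(ids)
        m = np.zeros((n, n))
        m[np.tril_indices(n, -1)] = vals
        return DistanceMatrix(m + m.T, ids=list(ids))

    def test_closed_form_on_fixture(self):
        rng = np.random.default_rng(3)
        dt, de, dp = (rng.random(6) for _ in range(3))
        DT, DE, DP = self._mat(dt), self._mat(de), self._mat(dp)
        r_te = np.corrcoef(dt, de)[0, 1]
        r_tp = np.corrcoef(dt, dp)[0, 1]
        r_ep = np.corrcoef(de, dp)[0, 1]
        expected = (r_te - r_tp * r_ep) / np.sqrt(
            (1 - r_tp ** 2) * (1 - r_ep ** 2))
        assert partial_matrix_correlation(DT, DE, DP) == pytest.approx(expected)

    def test_constant_conditioning_reduces_to_plain(self):
        rng = np.random.default_rng(6)
        dt, de = rng.random(6), rng.random(6)
        DP = self._mat(np.ones(6))
        got = partial_matrix_correlation(self._mat(dt), self._mat(de), DP)
        assert got == pytest.approx(np.corrcoef(dt, de)[0, 1])

    def test_t_determined_by_p_gives_null_partial(self):
        rng = np.random.default_rng(9)
        dp = rng.random(15)
        dt = 0.7 * dp  # trait structure is a copy of phylogenetic structure
        de = rng.random(15)
        got = partial_matrix_correlation(
            self._mat(dt, "abcdef"), self._mat(de, "abcdef"),
            self._mat(dp, "abcdef"))
        assert abs(got) < 1e-8


class TestOptimalSubset:
    def test_single_informative_trait_found(self):
        # disjoint forest/non-forest membership makes the habitat-sorted
        # trait a perfect (rho = 1) axis that noise traits cannot beat
        presence = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
            index=["f1", "f2", "n1", "n2"], columns=list("ABCD"))
        mc = Metacommunity(
            presence,
            {"f1": "forest", "f2": "forest",
             "n1": "non_forest", "n2": "non_forest"},
            {"f1": 5.0, "f2": 10.0, "n1": 20.0, "n2": 25.0})
        rng = np.random.default_rng(10)
        B = pd.DataFrame({
            "good": [1.0, 1.0, 0.0, 0.0],
            "noise1": rng.random(4),
            "noise2": rng.random(4),
        }, index=list("ABCD"))
        subset, rho = optimal_trait_subset(B, mc)
        # exhaustive oracle over all 7 subsets
        D_E = env_dissimilarity(mc)

        def oracle_rho(s):
            try:
                return matrix_correlation(
                    trait_dissimilarity(build_matrix_T(B, mc, s)), D_E)
            except ValueError:
                return -np.inf

        best = max(
            ((s, oracle_rho(s))
             for r in (1, 2, 3)
             for s in itertools.combinations(B.columns, r)),
            key=lambda t: t[1])
        assert rho == pytest.approx(best[1])
        assert subset == ("good",)

    def test_tie_rule_prefers_first_singleton(self, toy_metacommunity):
        B = pd.DataFrame({"t1": [0.1, 0.9, 0.5, 0.7]}, index=list("ABCD"))
        B3 = pd.concat([B, B.rename(columns={"t1": "t2"}),
                        B.rename(columns={"t1": "t3"})], axis=1)
        subset, _ = optimal_trait_subset(B3, toy_metacommunity)
        assert subset == ("t1",)

    def test_greedy_matches_exhaustive_single_signal(self, toy_metacommunity):
        B = pd.DataFrame({
            "good": [1.0, 0.9, 0.1, 0.0],
            "flat": [0.5, 0.5, 0.50001, 0.5],
        }, index=list("ABCD"))
        ex, _ = optimal_trait_subset(B, toy_metacommunity, mode="exhaustive")
        gr, _ = optimal_trait_subset(B, toy_metacommunity, mode="greedy")
        assert ex == gr


class TestDsepVerdict:
    @pytest.mark.parametrize("p_te,p_tep,expected", [
        (0.049, 0.128, Verdict.NICHE_CONSERVATISM),
        (0.4, 0.01, Verdict.NO_CONVERGENCE),
        (0.01, 0.01, Verdict.INDEPENDENT_CONVERGENCE),
    ])
    def test_mapping(self, p_te, p_tep, expected):
        te = MatrixCorrelation(rho=0.5, p=p_te, n_perm=999, scheme="species")
        tep = MatrixCorrelation(rho=0.3, p=p_tep, n_perm=999,
                                scheme="species", conditioned_on="P")
        assert dsep_verdict(te, tep, alpha=0.05) is expected


class TestRhoPT:
    def test_conserved_traits_beat_shuffled_traits(self):
        """Brownian (phylogenetically conserved) traits yield a stronger
        phylogeny-trait correlation than the same traits with species
        identities destroyed.

        Note the species-shuffle null of rho(PT) is itself positively
        structured — sites sharing species have similar community means
        whatever the trait values — so the conserved signal is assessed
        against the shuffled baseline, not against zero.
        """
        from phylostruct.simulate import simulate_dataset
        rhos_c, ps_c, rhos_s, ps_s = [], [], [], []
        for rep in range(10):
            ds = simulate_dataset(n_species=40, n_sites=8, seed=300 + rep,
                                  sigma2=0.5, phi=0.0, gamma=0.5)
            mc = ds.metacommunity
            present = sorted(set(mc.species))
            B = ds.traits.data.loc[present]
            mp = build_matrix_P(ds.phylogeny.subtree(present), mc)
            res = rho_PT(mp, standardize_traits(B), mc, n_perm=99,
                         rng=np.random.default_rng(rep))
            rhos_c.append(res.rho)
            ps_c.append(res.p)
            shuffle = np.random.default_rng(1000 + rep)
            Bs = pd.DataFrame(B.to_numpy()[shuffle.permutation(len(B))],
                              index=B.index, columns=B.columns)
            res_s = rho_PT(mp, standardize_traits(Bs), mc, n_perm=99,
                           rng=np.random.default_rng(rep))
            rhos_s.append(res_s.rho)
            ps_s.append(res_s.p)
        assert np.mean(rhos_c) > np.mean(rhos_s) + 0.1
        assert np.mean(ps_c) < np.mean(ps_s) - 0.15
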