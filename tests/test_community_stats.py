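"""Hellinger, Bray-Curtis, PERMANOVA (against a brute-force oracle), PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from hypothesis.extra.numpy import arrays

from phyllodyn import community_stats as cs
from phyllodyn import phylo_structure as ph
from phyllodyn import synthetic_data as sd

from conftest import brute_force_permanova


class TestHellinger:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([4, 0], [1.0, 0.0]),
            ([1, 1, 1, 1], [0.5, 0.5, 0.5, 0.5]),
            ([9, 16], [0.6, 0.8]),
        ],
    )
    def test_hand_values(self, row, expected):
        m = pd.DataFrame([row])
        out = cs.hellinger(m)
        assert out.iloc[0].tolist() == pytest.approx(expected)

    def test_rows_have_unit_norm(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(0, 50, size=(12, 7)) + 1)
        out = cs.hellinger(m)
        assert np.allclose((out**2).sum(axis=1), 1.0)

    def test_zero_row_names_sample(self):
        m = pd.DataFrame([[1, 2], [0, 0]], index=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            cs.hellinger(m)


class TestBrayCurtis:
    def test_identical_rows_are_zero(self):
        m = pd.DataFrame([[3, 1, 2], [3, 1, 2]])
        assert cs.bray_curtis(m).iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_are_one(self):
        m = pd.DataFrame([[1, 0], [0, 1]])
        assert cs.bray_curtis(m).iloc[0, 1] == pytest.approx(1.0)

    def test_hand_formula(self):
        m = pd.DataFrame([[6, 2, 0], [2, 2, 0]])
        assert cs.bray_curtis(m).iloc[0, 1] == pytest.approx(4 / 12)

    def test_two_zero_rows_rejected(self):
        m = pd.DataFrame([[0, 0], [0, 0], [1, 1]])
        with pytest.raises(ValueError, match="all-zero"):
            cs.bray_curtis(m)

    @settings(derandomize=True, max_examples=30)
    @given(arrays(float, (6, 5), elements=hst.floats(0, 100)))
    def test_bounded_in_unit_interval(self, values):
        m = pd.DataFrame(values + 1e-6)
        d = cs.bray_curtis(m).to_numpy()
        assert ((d >= -1e-12) & (d <= 1 + 1e-12)).all()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)


class TestPermanova:
    def test_no_signal_two_identical_groups(self):
        m = pd.DataFrame([[5, 1, 0]] * 3 + [[5, 1, 0]] * 3)
        m.index = [f"s{i}" for i in range(6)]
        meta = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3}, index=m.index)
        d = cs.bray_curtis(m + np.random.default_rng(0).uniform(0, 0.01, m.shape))
        res = cs.permanova(d, meta, ["g"], permutations="exhaustive")
        assert res.table.loc["g", "R2"] < 0.35
        assert res.table.loc["g", "p"] > 0.5

    def test_disjoint_groups_match_brute_force_and_min_p(self):
        """Two groups with disjoint taxa: sequential SS partition equals the
        explicit centering-matrix oracle to 1e-12 and the exhaustive p equals
        the minimum attainable value."""
        m = pd.DataFrame(
            [[5, 3, 0, 0], [6, 2, 0, 0], [5, 4, 0, 0],
             [0, 0, 4, 4], [0, 0, 5, 3], [0, 0, 3, 5]],
            index=[f"s{i}" for i in range(6)],
        )
        meta = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3}, index=m.index)
        d = cs.bray_curtis(m)
        res = cs.permanova(d, meta, ["g"], permutations="exhaustive")
        oracle = brute_force_permanova(d.to_numpy(), meta, ["g"])
        assert res.table.loc["g", "R2"] == pytest.approx(oracle.loc["g", "R2"], abs=1e-12)
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(oracle.loc["g", "F"], abs=1e-10)
        # minimum attainable p: both same-F partitions of 6 rows into 3+3
        import itertools

        f_obs = res.table.loc["g", "pseudo_F"]
        count = 0
        dm = d.to_numpy()
        for perm in itertools.permutations(range(6)):
            dp = dm[np.ix_(perm, perm)]
            o = brute_force_permanova(dp, meta, ["g"])
            if o.loc["g", "F"] >= f_obs - 1e-9 * (1 + abs(f_obs)):
                count += 1
        assert res.table.loc["g", "p"] == pytest.approx(count / 720)

    def test_multi_term_sequential_partition_matches_oracle(self):
        rng = np.random.default_rng(3)
        n = 8
        m = pd.DataFrame(rng.integers(1, 40, size=(n, 6)),
                         index=[f"s{i}" for i in range(n)])
        meta = pd.DataFrame(
            {"F": ["x", "y"] * 4, "H": ["h1", "h1", "h2", "h2"] * 2},
            index=m.index,
        )
        d = cs.bray_curtis(cs.hellinger(m))
        res = cs.permanova(d, meta, ["F", "H", "F:H"], n_perm=99, seed=0)
        oracle = brute_force_permanova(d.to_numpy(), meta, ["F", "H", "F:H"])
        for term in ("F", "H", "F:H"):
            assert res.table.loc[term, "SS"] == pytest.approx(oracle.loc[term, "SS"], abs=1e-10)
            assert res.table.loc[term, "pseudo_F"] == pytest.approx(
                oracle.loc[term, "F"], abs=1e-10
            )
        assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-9)

    def test_aliased_term_flagged_nan(self):
        m = pd.DataFrame(np.random.default_rng(0).integers(1, 20, (6, 4)),
                         index=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame({"a": ["x", "x", "x", "y", "y", "y"],
                             "b": ["x", "x", "x", "y", "y", "y"]}, index=m.index)
        d = cs.bray_curtis(m)
        res = cs.permanova(d, meta, ["a", "b"], n_perm=49, seed=1)
        assert np.isnan(res.table.loc["b", "R2"])


class TestDepthScan:
    def test_grid_point_one_equals_tip_level_permanova(self, small_sim):
        cfg, tree, clades, iso = small_sim
        ut = ph.ultrametricize(tree, sd.implied_similarity(tree))
        scan = cs.depth_scan(ut, iso, terms=["F", "T_I"], ps_grid=[1.0],
                            n_perm=99, seed=0)
        part = ph.slice_taxa(ut, 1.0)
        counts, gmeta = cs.aggregate_isolates(iso, part)
        d = cs.bray_curtis(cs.hellinger(counts))
        rng = np.random.default_rng(0)
        direct = cs.permanova(d, gmeta, ["F", "T_I"], n_perm=99,
                              seed=int(rng.integers(2**31)))
        got = scan.set_index("term")
        assert got.loc["F", "R2"] == pytest.approx(direct.table.loc["F", "R2"])
        assert got.loc["F", "p"] == pytest.approx(direct.table.loc["F", "p"])

    def test_taxon_count_monotone_in_threshold(self, small_sim):
        cfg, tree, clades, iso = small_sim
        ut = ph.ultrametricize(tree, sd.implied_similarity(tree))
        scan = cs.depth_scan(ut, iso, terms=["F"], n_perm=9, seed=0)
        taxa = scan.drop_duplicates("ps").sort_values("ps")["n_taxa"].to_numpy()
        assert (np.diff(taxa) >= 0).all()

    def test_grid_below_root_rejected(self, small_sim):
        cfg, tree, clades, iso = small_sim
        ut = ph.ultrametricize(tree, sd.implied_similarity(tree))
        with pytest.raises(ValueError, match="root"):
            cs.depth_scan(ut, iso, ps_grid=[0.5], n_perm=9, seed=0)


class TestPca:
    def test_two_samples_single_component(self):
        m = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["a", "b"])
        res = cs.pca(m)
        assert res.explained.iloc[0] == pytest.approx(1.0)

    def test_duplicated_samples_zero_trailing_variance(self):
        m = pd.DataFrame([[1, 2, 3], [3, 1, 2]] * 3, index=[f"s{i}" for i in range(6)])
        res = cs.pca(m)
        assert res.explained.iloc[1:].sum() == pytest.approx(0.0, abs=1e-12)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.uniform(0.1, 1, size=(10, 5)))
        res = cs.pca(m)
        rel = m.div(m.sum(axis=1), axis=0).to_numpy()
        centered = rel - rel.mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, centered, atol=1e-10)

    def test_variance_fractions_sorted_and_sum_to_one(self):
        rng = np.random.default_rng(2)
        res = cs.pca(pd.DataFrame(rng.uniform(0.1, 1, size=(8, 6))))
        e = res.explained.to_numpy()
        assert (np.diff(e) <= 1e-12).all()
        assert e.sum() == pytest.approx(1.0)
        assert (e >= 0).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cs.pca(pd.DataFrame([[1, 2]]))


class TestAsvFactorTests:
    def _meta(self, n, rng):
        return pd.DataFrame(
            {"F": ["MSH"] * (n // 2) + ["SBL"] * (n - n // 2),
             "D": rng.choice([170, 200, 230, 290], size=n)},
            index=[f"s{i}" for i in range(n)],
        )

    def test_perfect_separation_flagged_with_direction(self):
        rng = np.random.default_rng(0)
        n = 24
        meta = self._meta(n, rng)
        m = pd.DataFrame(rng.integers(5, 20, size=(n, 4)).astype(float),
                         index=meta.index, columns=list("wxyz"))
        m.loc[meta["F"] == "SBL", "w"] = 0.0
        res = cs.asv_factor_tests(m, meta)
        w_f = res[(res["taxon"] == "w") & (res["factor"] == "F")].iloc[0]
        assert w_f["significant"] and w_f["direction"] == "MSH"

    def test_constant_taxon_not_flagged(self):
        rng = np.random.default_rng(1)
        meta = self._meta(20, rng)
        m = pd.DataFrame({"const": np.ones(20), "other": rng.uniform(1, 2, 20)},
                         index=meta.index)
        # constant relative abundance: both taxa vary jointly, so use a
        # 2-taxon table where "const"'s relative abundance is fixed at 1/2
        m["other"] = 1.0
        res = cs.asv_factor_tests(m, meta)
        assert not res[res["taxon"] == "const"]["significant"].any()

    def test_planted_forest_bias_recovered(self):
        """20 of 100 taxa with a 4x forest enrichment: most are detected,
        false positives stay near the nominal rate."""
        rng = np.random.default_rng(7)
        n, ntaxa = 60, 100
        meta = self._meta(n, rng)
        base = rng.uniform(0.5, 1.5, size=ntaxa)
        mean = np.tile(base, (n, 1))
        mean[(meta["F"] == "MSH").to_numpy()[:, None] & (np.arange(ntaxa) < 20)[None, :]] *= 4
        counts = np.vstack([rng.multinomial(20000, row / row.sum()) for row in mean])
        m = pd.DataFrame(counts, index=meta.index,
                         columns=[f"t{i}" for i in range(ntaxa)])
        res = cs.asv_factor_tests(m, meta)
        forest = res[res["factor"] == "F"].set_index("taxon")
        hits = forest.loc[[f"t{i}" for i in range(20)], "significant"].sum()
        assert hits >= 18
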