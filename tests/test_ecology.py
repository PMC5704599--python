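import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom

from rumivir import ecology as eco
from rumivir.errors import InputError


def euclid(points, ids=None):
    ids = ids or [f"s{i}" for i in range(len(points))]
    return pd.DataFrame(squareform(pdist(np.asarray(points, float))), index=ids, columns=ids)


class TestChao1:
    def test_hand_case(self):
        assert eco.chao1([5, 1, 1, 2]) == pytest.approx(4.5)

    def test_no_singletons(self):
        assert eco.chao1([5, 4, 2, 2]) == 4

    def test_naive_formula(self):
        counts = [1, 1, 1, 2, 2, 9]
        s, f1, f2 = 6, 3, 2
        assert eco.chao1(counts, bias_corrected=False) == pytest.approx(s + f1**2 / (2 * f2))

    def test_at_least_observed(self, rng):
        for _ in range(20):
            c = rng.integers(0, 5, 30)
            assert eco.chao1(c) >= (c > 0).sum()


class TestShannon:
    def test_two_equal(self):
        assert eco.shannon([1, 1]) == pytest.approx(1.0)

    def test_single_category(self):
        assert eco.shannon([42]) == 0.0

    def test_uniform_maximum(self):
        assert eco.shannon([3] * 16) == pytest.approx(4.0)

    def test_natural_log_base(self):
        assert eco.shannon([1, 1], base=np.e) == pytest.approx(np.log(2))


class TestRarefaction:
    def test_identity_at_full_depth(self, rng):
        counts = pd.DataFrame({"s": rng.integers(0, 9, 6)}, index=list("abcdef"))
        out = eco.rarefy(counts, int(counts["s"].sum()), seed=0)
        pd.testing.assert_frame_equal(out, counts)

    def test_depth_one(self, rng):
        counts = pd.DataFrame({"s": [4, 5, 6]}, index=list("abc"))
        out = eco.rarefy(counts, 1, seed=1)
        assert out["s"].sum() == 1
        assert (out["s"] >= 0).all()

    def test_shallow_sample_skipped(self):
        counts = pd.DataFrame({"deep": [50, 50], "shallow": [1, 1]}, index=["a", "b"])
        with pytest.warns(UserWarning):
            out = eco.rarefy(counts, 10, seed=0)
        assert list(out.columns) == ["deep"]

    def test_expected_richness_matches_hypergeometric(self):
        counts = pd.DataFrame({"s": [40, 25, 10, 5, 2, 1]}, index=list("abcdef"))
        depth, reps = 20, 500
        rng = np.random.default_rng(7)
        rich = []
        for _ in range(reps):
            sub = eco.rarefy(counts, depth, seed=int(rng.integers(2**31)))
            rich.append(int((sub["s"] > 0).sum()))
        observed = np.mean(rich)
        N = counts["s"].sum()
        expected = sum(
            1.0 - hypergeom.pmf(0, N, ni, depth) for ni in counts["s"]
        )
        assert observed == pytest.approx(expected, abs=4 * np.std(rich) / np.sqrt(reps))

    def test_curve_shape(self, rng):
        counts = pd.DataFrame(
            {"s1": rng.integers(0, 40, 20), "s2": rng.integers(0, 40, 20)}
        )
        curve = eco.rarefaction_curve(counts, depths=[10, 50], reps=5, seed=0)
        assert set(curve.columns) == {"sample", "depth", "chao1", "shannon"}
        assert len(curve) == 4


class TestBrayCurtis:
    def test_identical(self):
        t = pd.DataFrame({"a": [1, 2], "b": [1, 2]}, index=["f1", "f2"])
        assert eco.bray_curtis(t).loc["a", "b"] == 0.0

    def test_disjoint(self):
        t = pd.DataFrame({"a": [5, 0], "b": [0, 3]}, index=["f1", "f2"])
        assert eco.bray_curtis(t).loc["a", "b"] == 1.0

    def test_hand_case(self):
        t = pd.DataFrame({"x": [2, 2], "y": [1, 3]}, index=["f1", "f2"])
        assert eco.bray_curtis(t).loc["x", "y"] == pytest.approx(0.25)

    def test_bounds_and_symmetry(self, rng):
        t = pd.DataFrame(rng.integers(0, 20, (10, 6)))
        D = eco.bray_curtis(t)
        assert ((D >= 0) & (D <= 1)).all().all()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)


class TestWeightedUnifrac:
    def test_identical_samples(self):
        tree = "(l1:1,l2:1);"
        t = pd.DataFrame({"a": [3, 1], "b": [3, 1]}, index=["l1", "l2"])
        assert eco.weighted_unifrac(t, tree).loc["a", "b"] == 0.0

    def test_two_leaf_hand_case(self):
        tree = "(l1:1,l2:1);"
        t = pd.DataFrame({"a": [7, 0], "b": [0, 4]}, index=["l1", "l2"])
        assert eco.weighted_unifrac(t, tree).loc["a", "b"] == pytest.approx(2.0)

    def test_star_tree_weighted_l1(self, rng):
        tips = [f"t{i}" for i in range(6)]
        b = 1.7
        tree = "(" + ",".join(f"{t}:{b}" for t in tips) + ");"
        table = pd.DataFrame(
            rng.integers(1, 30, (6, 2)), index=tips, columns=["a", "b"]
        )
        got = eco.weighted_unifrac(table, tree).loc["a", "b"]
        p = table / table.sum()
        assert got == pytest.approx(b * np.abs(p["a"] - p["b"]).sum())

    def test_missing_tip_rejected(self):
        t = pd.DataFrame({"a": [1]}, index=["ghost"])
        with pytest.raises(InputError):
            eco.weighted_unifrac(t, "(l1:1,l2:1);")

    def test_normalized_bounded(self, otu_sim):
        table, newick, _ = otu_sim
        D = eco.weighted_unifrac(table, newick, normalized=True)
        assert (D.to_numpy() <= 1 + 1e-9).all()

    def test_skbio_cross_check(self, otu_sim):
        """Raw form agrees with scikit-bio's implementation."""
        import io as _io

        from skbio import TreeNode
        from skbio.diversity.beta import weighted_unifrac as sk_wu

        table, newick, _ = otu_sim
        sub = table.iloc[:, :4]
        tree = TreeNode.read(_io.StringIO(newick))
        mine = eco.weighted_unifrac(sub, newick)
        for a, b in itertools.combinations(sub.columns, 2):
            ref = sk_wu(
                sub[a].to_numpy(), sub[b].to_numpy(), taxa=list(sub.index), tree=tree,
                validate=True,
            )
            assert mine.loc[a, b] == pytest.approx(ref, rel=1e-9)


class TestPermanova:
    def test_perfect_separation(self):
        # two tight groups: within distance 0, between distance 1
        D = pd.DataFrame(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float,
        )
        design = pd.DataFrame({"g": ["x", "x", "y", "y"]}, index=list("abcd"))
        res = eco.permanova(D, design, terms=("g",), n_perm=99, seed=0)
        assert res.table.loc["g", "R2"] == pytest.approx(1.0)
        assert np.isinf(res.table.loc["g", "F"])
        assert res.table.loc["Residual", "SS"] == pytest.approx(0.0, abs=1e-10)

    def test_r2_sums_to_one(self, design, otu_sim):
        table, _, _ = otu_sim
        D = eco.bray_curtis(table / table.sum())
        res = eco.permanova(D, design.samples.set_index("sample_id"), n_perm=9, seed=0)
        assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-10)
        assert (res.table["P"].dropna() > 0).all()

    def test_exact_matches_brute_force_enumeration(self, rng):
        """Independent oracle: within/between-group SS identity, all n! relabelings."""
        n = 6
        labels = ["a", "a", "a", "b", "b", "b"]
        D = euclid(rng.normal(size=(n, 3)))
        design = pd.DataFrame({"g": labels}, index=D.index)
        res = eco.permanova(D, design, terms=("g",), exact=True)

        def oracle_f(dm, labs):
            sq = dm**2
            ss_tot = sq[np.triu_indices(n, 1)].sum() / n
            ss_w = 0.0
            for g in set(labs):
                idx = [i for i, l in enumerate(labs) if l == g]
                ss_w += sq[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
            k = len(set(labs))
            return ((ss_tot - ss_w) / (k - 1)) / (ss_w / (n - k))

        dm = D.to_numpy()
        f_obs = oracle_f(dm, labels)
        hits = sum(
            oracle_f(dm, [labels[i] for i in perm]) >= f_obs - 1e-12
            for perm in itertools.permutations(range(n))
        )
        assert res.table.loc["g", "F"] == pytest.approx(f_obs)
        import math

        assert res.table.loc["g", "P"] == pytest.approx(hits / math.factorial(n))

    def test_confounded_terms_rejected(self):
        D = euclid(np.random.default_rng(0).normal(size=(4, 2)))
        design = pd.DataFrame(
            {"g": ["x", "x", "y", "y"], "h": ["x", "x", "y", "y"]}, index=D.index
        )
        with pytest.raises(InputError, match="h"):
            eco.permanova(D, design, terms=("g", "h"), n_perm=9)

    def test_seed_reproducibility(self, rng):
        D = euclid(rng.normal(size=(10, 3)))
        design = pd.DataFrame({"g": list("aabbccddee")}, index=D.index)
        r1 = eco.permanova(D, design, terms=("g",), n_perm=99, seed=5)
        r2 = eco.permanova(D, design, terms=("g",), n_perm=99, seed=5)
        assert r1.table.loc["g", "P"] == r2.table.loc["g", "P"]


class TestDispersion:
    def test_mirror_groups_equal_dispersion(self):
        pts = np.array([[1, 0], [-1, 0], [0, 2], [0, -2]])
        pts = np.vstack([pts, -pts])
        D = euclid(pts)
        grouping = pd.Series(["a"] * 4 + ["b"] * 4, index=D.index)
        res = eco.dispersion_test(D, grouping)
        assert res.group_dispersions["a"] == pytest.approx(res.group_dispersions["b"])
        assert res.f_statistic == pytest.approx(0.0, abs=1e-9)

    def test_identical_points_zero_dispersion(self):
        pts = [[0, 0], [0, 0], [0, 0], [5, 5], [6, 5], [5, 6]]
        D = euclid(pts)
        grouping = pd.Series(["a"] * 3 + ["b"] * 3, index=D.index)
        res = eco.dispersion_test(D, grouping)
        assert res.group_dispersions["a"] == pytest.approx(0.0, abs=1e-8)

    def test_euclidean_geometry_oracle(self, rng):
        """Distances to the spatial median match direct computation."""
        pts = rng.normal(size=(12, 4))
        D = euclid(pts)
        grouping = pd.Series(["a"] * 6 + ["b"] * 6, index=D.index)
        res = eco.dispersion_test(D, grouping)
        for g, idx in (("a", slice(0, 6)), ("b", slice(6, 12))):
            sub = pts[idx]
            med = eco._spatial_median(sub, tol=1e-12)
            expected = np.linalg.norm(sub - med, axis=1)
            got = res.distances.iloc[idx].to_numpy()
            np.testing.assert_allclose(np.sort(got), np.sort(expected), atol=1e-6)


class TestIntraGroupContrast:
    def test_all_equal_distances(self):
        n = 6
        D = pd.DataFrame(1.0 - np.eye(n), index=[f"s{i}" for i in range(n)],
                         columns=[f"s{i}" for i in range(n)])
        a = pd.Series(["x", "x", "x", "y", "y", "y"], index=D.index)
        b = pd.Series(["u", "u", "v", "v", "w", "w"], index=D.index)
        t, p = eco.intra_group_contrast(D, a, b)
        assert t == 0.0 and p == 1.0

    def test_forced_direction(self):
        ids = [f"s{i}" for i in range(20)]
        steer = pd.Series([f"st{i % 5}" for i in range(20)], index=ids)
        diet = pd.Series([f"d{i // 5}" for i in range(20)], index=ids)
        D = pd.DataFrame(0.0, index=ids, columns=ids)
        for i, j in itertools.combinations(range(20), 2):
            if steer[ids[i]] == steer[ids[j]]:
                D.iloc[i, j] = D.iloc[j, i] = 1.0
            elif diet[ids[i]] == diet[ids[j]]:
                D.iloc[i, j] = D.iloc[j, i] = 1e-6
            else:
                D.iloc[i, j] = D.iloc[j, i] = 0.5
        t, p = eco.intra_group_contrast(D, steer, diet)
        assert t > 0 and p < 0.01

    def test_hand_formula_oracle(self, rng):
        D = euclid(rng.normal(size=(8, 3)))
        a = pd.Series(list("xxxxyyyy"), index=D.index)
        b = pd.Series(list("uuvvwwzz"), index=D.index)
        t, p = eco.intra_group_contrast(D, a, b)
        da = eco._within_group_distances(D, a)
        db = eco._within_group_distances(D, b)
        # textbook Welch statistic
        va, vb = da.var(ddof=1), db.var(ddof=1)
        t_hand = (da.mean() - db.mean()) / np.sqrt(va / len(da) + vb / len(db))
        assert t == pytest.approx(t_hand)


class TestAlphaAnova:
    def test_constant_response(self, design):
        metric = pd.Series(3.14, index=design.sample_ids)
        table, pairwise = eco.alpha_anova(metric, design.samples.set_index("sample_id"))
        assert (table["F"] == 0).all()
        assert (pairwise["t"] == 0).all()

    def test_planted_diet_shift(self, design):
        rng = np.random.default_rng(0)
        des = design.samples.set_index("sample_id")
        shift = des["diet"].map({"Corn": 0.0, "27CDS": 0.0, "40MDGS": 3.0, "55CS": 3.0})
        metric = pd.Series(rng.normal(0, 0.2, len(des)), index=des.index) + shift
        table, pairwise = eco.alpha_anova(metric, des)
        assert table.loc["diet", "PR(>F)"] < 0.05
        sig = pairwise[(pairwise.group1 == "27CDS") & (pairwise.group2 == "40MDGS")]
        assert sig["P"].iloc[0] < 0.05

    def test_orthogonal_design_order_invariance(self):
        """Balanced orthogonal factors: Type-I SS independent of order."""
        rng = np.random.default_rng(1)
        rows = []
        for a in "pq":
            for b in "uv":
                for rep in range(3):
                    rows.append({"sample_id": f"{a}{b}{rep}", "f1": a, "f2": b})
        des = pd.DataFrame(rows).set_index("sample_id")
        y = pd.Series(rng.normal(size=len(des)), index=des.index)
        t1, _ = eco.alpha_anova(y, des, terms=("f1", "f2"), pairwise_factor="f1")
        t2, _ = eco.alpha_anova(y, des, terms=("f2", "f1"), pairwise_factor="f1")
        assert t1.loc["f1", "sum_sq"] == pytest.approx(t2.loc["f1", "sum_sq"])
        assert t1.loc["f2", "sum_sq"] == pytest.approx(t2.loc["f2", "sum_sq"])
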