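"""Tests of PERMANOVA, SIMPER, BY adjustment, prey merging, and clustering.

Oracles: classical one-way ANOVA F (scipy) for 1-D Euclidean PERMANOVA,
scikit-bio's permanova for the multivariate pseudo-F, brute-force enumeration
for exact permutation p-values, and the step-up formula for BY adjustment.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from trophoniche.multivar_stats import (
    MultivarError,
    benjamini_yekutieli,
    dunn_index,
    hierarchical_cluster,
    lda_validate,
    merge_sources,
    pairwise_permanova,
    pearson_screen,
    permanova,
    permanova_two_way,
    select_k_dunn,
    simper,
)


def by_bruteforce(p):
    """Independent oracle: direct step-up BY formula."""
    p = np.asarray(p, float)
    m = len(p)
    c = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(p)
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * c * p[i] / rank)
        adj[i] = min(1.0, running)
    return adj


class TestPermanova:
    def test_worked_example_pseudo_f_and_exact_p(self):
        res = permanova(np.array([0.0, 1.0, 3.0, 4.0]), ["a", "a", "b", "b"])
        assert res.pseudo_f == pytest.approx(18.0, abs=1e-10)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert (res.ss_among, res.ss_within, res.ss_total) == pytest.approx((9.0, 1.0, 10.0))

    def test_exact_p_matches_naive_enumeration(self, rng):
        # brute force: recompute F for every distinct 3+3 split by hand
        x = rng.normal(size=6)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(x, labels)

        def anova_f(lab):
            groups = [x[np.asarray(lab) == g] for g in ("a", "b")]
            return stats.f_oneway(*groups).statistic

        f_obs = anova_f(labels)
        fs = [anova_f(perm) for perm in set(itertools.permutations(labels))]
        expected = sum(f >= f_obs - 1e-12 for f in fs) / len(fs)
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_pseudo_f_equals_classical_anova_f_on_1d(self, rng):
        for _ in range(10):
            x = rng.normal(size=24)
            labels = rng.permutation(np.repeat(["a", "b", "c"], 8))
            res = permanova(x, labels, n_permutations=9)
            groups = [x[labels == g] for g in ("a", "b", "c")]
            assert res.pseudo_f == pytest.approx(stats.f_oneway(*groups).statistic, abs=1e-8)

    def test_pseudo_f_matches_skbio_on_2d(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        x = rng.normal(size=(30, 2))
        labels = np.repeat(["a", "b", "c"], 10)
        dm = DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(30)])
        expected = sk_permanova(dm, list(labels), permutations=9)["test statistic"]
        res = permanova(x, labels, n_permutations=99, seed=0)
        assert res.pseudo_f == pytest.approx(expected, rel=1e-10)

    def test_ss_decomposition_conserves(self, rng):
        x = rng.normal(size=(40, 3))
        labels = rng.integers(0, 3, size=40)
        while np.bincount(labels, minlength=3).min() < 2:
            labels = rng.integers(0, 3, size=40)
        res = permanova(x, labels, n_permutations=99, seed=1)
        assert res.ss_among + res.ss_within == pytest.approx(res.ss_total, abs=1e-8)

    def test_monte_carlo_agrees_with_exact_within_binomial_error(self, rng):
        x = rng.normal(size=8)
        x[:4] += 1.5
        labels = np.repeat(["a", "b"], 4)
        exact = permanova(x, labels)  # 70 distinct relabelings <= 9999 -> exact
        assert exact.method == "exact"
        # with fewer requested permutations than relabelings, Monte-Carlo kicks in
        mc = permanova(x, labels, n_permutations=60, seed=2)
        assert mc.method == "monte-carlo"
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 60)
        assert abs(mc.p_value - exact.p_value) < 4 * se + 2 / 61

    def test_singleton_group_rejected(self):
        with pytest.raises(MultivarError, match="singleton"):
            permanova(np.arange(5.0), ["a", "a", "a", "a", "b"])

    def test_constant_data_rejected(self):
        with pytest.raises(MultivarError, match="constant"):
            permanova(np.ones(6), ["a", "a", "a", "b", "b", "b"])

    def test_p_bounds(self, rng):
        x = rng.normal(size=40)
        labels = np.repeat(["a", "b"], 20)
        res = permanova(x, labels, n_permutations=199, seed=0)
        assert 1 / 200 <= res.p_value <= 1.0


class TestTwoWayPermanova:
    def test_planted_effect_detected_in_correct_factor(self, rng):
        n = 40
        a = np.repeat(["x", "y"], n // 2)
        b = np.tile(["u", "v"], n // 2)
        data = rng.normal(size=(n, 2))
        data[a == "y"] += 2.0  # effect in factor A only
        res = permanova_two_way(data, a, b, n_permutations=199, seed=0)
        assert res["A"].p_value < 0.05
        assert res["B"].p_value > 0.05
        assert res["A"].pseudo_f > res["B"].pseudo_f


class TestBenjaminiYekutieli:
    def test_three_test_example(self):
        adj = benjamini_yekutieli([0.01, 0.02, 0.03])
        assert adj == pytest.approx([0.055, 0.055, 0.055], abs=1e-12)

    def test_all_ones_stay_one(self):
        assert benjamini_yekutieli([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_single_test_unchanged(self):
        assert benjamini_yekutieli([0.2]) == pytest.approx([0.2])

    def test_matches_bruteforce_formula(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(2, 12))
            assert benjamini_yekutieli(p) == pytest.approx(by_bruteforce(p), abs=1e-12)

    def test_order_invariance(self, rng):
        p = rng.uniform(size=10)
        perm = rng.permutation(10)
        assert benjamini_yekutieli(p)[perm] == pytest.approx(benjamini_yekutieli(p[perm]))

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=15)
        adj = benjamini_yekutieli(np.sort(p))
        assert np.all(np.diff(adj) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(MultivarError):
            benjamini_yekutieli([0.5, 1.5])


class TestPairwise:
    def test_two_groups_adjusted_equals_raw(self, rng):
        x = rng.normal(size=(20, 2))
        labels = np.repeat(["a", "b"], 10)
        out = pairwise_permanova(x, labels, n_permutations=99, seed=0)
        assert len(out) == 1
        assert out.loc[0, "p_adjusted"] == pytest.approx(out.loc[0, "p_value"])

    def test_identical_species_rarely_split(self):
        # two sources simulated from the same distribution should not be
        # distinguished, driving a downstream merge
        from trophoniche.synthetic_data import SourceSpec, generate_prey_samples

        same = [
            SourceSpec("a", -18.5, 0.5, 9.3, 0.5, 15),
            SourceSpec("b", -18.5, 0.5, 9.3, 0.5, 15),
        ]
        nonsig = 0
        for seed in range(100):
            prey = generate_prey_samples(same, seed=seed)
            out = pairwise_permanova(
                prey[["d13C", "d15N"]].to_numpy(),
                prey["species"].to_numpy(),
                n_permutations=199,
                seed=seed,
            )
            nonsig += out.loc[0, "p_adjusted"] > 0.05
        assert nonsig >= 90

    def test_separated_reference_sources_all_distinguished(self):
        from trophoniche.synthetic_data import functional_group_specs, generate_prey_samples

        prey = generate_prey_samples(functional_group_specs(), seed=11)
        out = pairwise_permanova(
            prey[["d13C", "d15N"]].to_numpy(),
            prey["species"].to_numpy(),
            n_permutations=999,
            seed=11,
        )
        assert (out["p_adjusted"] < 0.05).all()


class TestSimper:
    def test_single_variable_contributes_everything(self, rng):
        x = rng.normal(size=(10, 1))
        labels = np.repeat(["a", "b"], 5)
        res = simper(x, labels, ("a", "b"))
        assert res.table["pct"].iloc[0] == pytest.approx(1.0)

    def test_null_variable_contributes_nothing(self):
        x = np.column_stack([np.repeat([0.0, 1.0], 5), np.full(10, 3.0)])
        labels = np.repeat(["a", "b"], 5)
        res = simper(pd.DataFrame(x, columns=["A", "B"]), labels, ("a", "b"))
        tab = res.table.set_index("variable")
        assert tab.loc["A", "pct"] == pytest.approx(1.0)
        assert tab.loc["B", "contribution"] == pytest.approx(0.0)
        assert res.cutoff_set == ("A",)

    def test_contributions_conserve_total_dissimilarity(self, rng):
        x = rng.normal(size=(12, 5))
        labels = np.repeat(["a", "b"], 6)
        res = simper(x, labels, ("a", "b"))
        d2 = ((x[labels == "a"][:, None, :] - x[labels == "b"][None, :, :]) ** 2).sum(-1)
        assert res.table["contribution"].sum() == pytest.approx(res.total_dissimilarity, abs=1e-8)
        assert res.total_dissimilarity == pytest.approx(d2.mean(), abs=1e-8)
        assert (res.table["contribution"] >= 0).all()

    def test_bray_curtis_mode_conserves(self, rng):
        x = rng.uniform(1, 10, size=(8, 4))
        labels = np.repeat(["a", "b"], 4)
        res = simper(x, labels, ("a", "b"), mode="bray_curtis")
        xa, xb = x[labels == "a"], x[labels == "b"]
        bc = np.abs(xa[:, None] - xb[None]).sum(-1) / (xa[:, None] + xb[None]).sum(-1)
        assert res.total_dissimilarity == pytest.approx(bc.mean(), abs=1e-8)

    def test_planted_informative_variables_dominate(self, rng):
        # 14 informative variables of 39: their cumulative share exceeds 70%
        n, p, informative = 30, 39, 14
        x = rng.normal(size=(2 * n, p)) * 0.3
        x[n:, :informative] += 2.0
        labels = np.repeat(["a", "b"], n)
        names = [f"fa{i}" for i in range(p)]
        res = simper(pd.DataFrame(x, columns=names), labels, ("a", "b"))
        share = res.table.set_index("variable").loc[[f"fa{i}" for i in range(informative)], "pct"]
        assert share.sum() > 0.70
        assert set(res.cutoff_set) <= {f"fa{i}" for i in range(informative)}

    def test_unknown_group_rejected(self, rng):
        with pytest.raises(MultivarError, match="unknown group"):
            simper(rng.normal(size=(6, 2)), ["a"] * 3 + ["b"] * 3, ("a", "c"))


class TestMergeSources:
    @staticmethod
    def pairwise_frame(pvals: dict) -> pd.DataFrame:
        rows = [
            {"group_a": a, "group_b": b, "p_value": p, "p_adjusted": p}
            for (a, b), p in pvals.items()
        ]
        return pd.DataFrame(rows)

    def test_indistinguishable_compatible_pair_merges(self):
        units = ["arctic_krill", "copepods"]
        pairwise = self.pairwise_frame({("arctic_krill", "copepods"): 0.68})
        eco = {"arctic_krill": "grazing zooplankton", "copepods": "grazing zooplankton"}
        groups = merge_sources(units, pairwise, eco)
        assert len(groups) == 1
        assert groups[0].members == ("arctic_krill", "copepods")

    def test_region_split_retained_when_significant(self):
        units = ["capelin_est", "herring_est", "capelin_gulf", "herring_gulf"]
        pairwise = self.pairwise_frame(
            {
                ("capelin_est", "herring_est"): 0.92,
                ("capelin_gulf", "herring_gulf"): 0.80,
                ("capelin_est", "capelin_gulf"): 0.002,
                ("capelin_est", "herring_gulf"): 0.002,
                ("herring_est", "capelin_gulf"): 0.002,
                ("herring_est", "herring_gulf"): 0.002,
            }
        )
        eco = {u: "lipid-rich pelagic fish" for u in units}
        groups = merge_sources(units, pairwise, eco)
        names = {g.members for g in groups}
        assert ("capelin_est", "herring_est") in names
        assert ("capelin_gulf", "herring_gulf") in names
        assert len(groups) == 2

    def test_all_significant_keeps_identity(self):
        units = ["a", "b", "c"]
        pairwise = self.pairwise_frame({(x, y): 0.001 for x, y in itertools.combinations(units, 2)})
        eco = {u: "same" for u in units}
        groups = merge_sources(units, pairwise, eco)
        assert [g.members for g in groups] == [("a",), ("b",), ("c",)]

    def test_ecology_blocks_statistical_merge(self):
        units = ["krill", "fish"]
        pairwise = self.pairwise_frame({("krill", "fish"): 0.9})
        eco = {"krill": "zooplankton", "fish": "pelagic fish"}
        assert len(merge_sources(units, pairwise, eco)) == 2

    def test_incomplete_pairwise_table_rejected(self):
        with pytest.raises(MultivarError, match="cover"):
            merge_sources(["a", "b", "c"], self.pairwise_frame({("a", "b"): 0.5}), {})


class TestClustering:
    def test_two_obvious_clusters(self):
        x = np.array([0.0, 1.0, 10.0, 11.0])
        tree = hierarchical_cluster(x, standardize=False)
        labels = tree.cut(2)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_duplicated_rows_join_at_height_zero(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 6.0]])
        tree = hierarchical_cluster(x, standardize=False)
        assert tree.z[0, 2] == pytest.approx(0.0)

    def test_partition_invariant_to_row_order(self, rng):
        x = np.concatenate([rng.normal(0, 0.5, 10), rng.normal(8, 0.5, 10)])
        perm = rng.permutation(20)
        base = hierarchical_cluster(x, standardize=False).cut(2)
        shuffled = hierarchical_cluster(x[perm], standardize=False).cut(2)
        assert np.array_equal(base[perm] == base[perm][0], shuffled == shuffled[0])

    def test_too_few_observations_rejected(self):
        with pytest.raises(MultivarError):
            hierarchical_cluster(np.array([[0.0], [1.0]]))

    def test_dunn_toy_value(self):
        x = np.array([0.0, 1.0, 10.0, 11.0])
        tree = hierarchical_cluster(x, standardize=False)
        sol = select_k_dunn(tree, range(2, 4))
        assert sol.k == 2
        assert sol.dunn == pytest.approx(9.0)

    def test_three_planted_blobs_select_k3(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        x = np.vstack([rng.normal(c, 0.3, size=(12, 2)) for c in centers])
        sol = select_k_dunn(hierarchical_cluster(x, standardize=False), range(2, 6))
        assert sol.k == 3
        assert not sol.low_dunn

    def test_uniform_data_flags_low_dunn(self, rng):
        x = rng.uniform(size=(30, 2))
        with pytest.warns(UserWarning, match="Dunn"):
            sol = select_k_dunn(hierarchical_cluster(x), range(2, 4))
        assert sol.low_dunn

    def test_dunn_singleton_partition_infinite(self):
        assert dunn_index(np.array([0.0, 5.0, 10.0]), [1, 2, 3]) == np.inf


class TestLdaValidate:
    def test_separated_classes_perfect_accuracy(self, rng):
        x = np.vstack([rng.normal(0, 0.3, (15, 2)), rng.normal(8, 0.3, (15, 2))])
        labels = np.repeat([0, 1], 15)
        assert lda_validate(x, labels) == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        x = rng.normal(size=(60, 2))
        accs = [lda_validate(x, rng.permutation(np.repeat([0, 1], 30))) for _ in range(20)]
        # chance level 1/2; leave-one-out is slightly pessimistic under the
        # null, so allow a band rather than a tight binomial bound
        assert 0.35 < np.mean(accs) < 0.6

    def test_class_size_validation(self):
        with pytest.raises(MultivarError):
            lda_validate(np.arange(4.0), [0, 0, 0, 1])


class TestPearsonScreen:
    def test_reports_only_strong_correlations(self, rng):
        axis = rng.normal(size=50)
        df = pd.DataFrame({"strong": axis + rng.normal(0, 0.2, 50), "weak": rng.normal(size=50)})
        out = pearson_screen(df, axis, threshold=0.6)
        assert list(out["variable"]) == ["strong"]
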