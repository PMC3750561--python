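"""Aberration calls, frequency profiles, Ward clustering, branch extraction."""

import numpy as np
import pandas as pd
import pytest

from pathscape import (
    AberrationProfiles,
    PathwaySubgrouper,
    aberration_frequencies,
    call_aberrations,
    cross_group_features,
    extract_subgroups,
    hierarchical_cluster,
)


def profiles_from_p(pe: np.ndarray, pdep: np.ndarray) -> AberrationProfiles:
    pathways = [f"PW{i}" for i in range(pe.shape[0])]
    samples = [f"S{j}" for j in range(pe.shape[1])]
    combined = np.where(pe <= pdep, np.log2(pe), -np.log2(pdep))
    return AberrationProfiles(
        combined=pd.DataFrame(combined, index=pathways, columns=samples),
        p_enrichment=pd.DataFrame(pe, index=pathways, columns=samples),
        p_depletion=pd.DataFrame(pdep, index=pathways, columns=samples),
        B=1000, seed=0,
    )


class TestCalls:
    @pytest.mark.parametrize("pe, pdep, expected", [
        (0.01, 0.8, "E"),
        (0.2, 0.3, "N"),
        (0.04, 0.03, "D"),
        (0.03, 0.03, "E"),   # tie at significance -> enrichment
        (0.9, 0.04, "D"),
    ])
    def test_call_rules(self, pe, pdep, expected):
        prof = profiles_from_p(np.array([[pe]]), np.array([[pdep]]))
        assert call_aberrations(prof, alpha=0.05).iloc[0, 0] == expected

    def test_calls_are_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        pe = rng.uniform(0.001, 1, size=(30, 20))
        pdep = rng.uniform(0.001, 1, size=(30, 20))
        calls = call_aberrations(profiles_from_p(pe, pdep))
        assert set(np.unique(calls.to_numpy())) <= {"E", "D", "N"}

    def test_invalid_alpha(self):
        prof = profiles_from_p(np.array([[0.5]]), np.array([[0.5]]))
        with pytest.raises(ValueError):
            call_aberrations(prof, alpha=0.0)


class TestFrequencies:
    def test_counts_per_group(self):
        calls = pd.DataFrame([["E", "E", "N", "D"]], index=["PW"], columns=list("abcd"))
        out = aberration_frequencies(calls, {s: "g" for s in "abcd"})
        row = out.iloc[0]
        assert row["enr_freq"] == 0.5 and row["dep_freq"] == 0.25 and row["group_size"] == 4

    def test_all_neutral_and_singleton(self):
        calls = pd.DataFrame([["N", "E"]], index=["PW"], columns=["a", "b"])
        out = aberration_frequencies(calls, {"a": "g1", "b": "g2"})
        g1 = out[out["group"] == "g1"].iloc[0]
        g2 = out[out["group"] == "g2"].iloc[0]
        assert (g1["enr_freq"], g1["dep_freq"]) == (0.0, 0.0)
        assert (g2["enr_freq"], g2["dep_freq"]) == (1.0, 0.0)

    def test_unmapped_sample_is_error(self):
        calls = pd.DataFrame([["N"]], index=["PW"], columns=["a"])
        with pytest.raises(ValueError, match="without a group"):
            aberration_frequencies(calls, {})

    def test_enr_plus_dep_at_most_one(self):
        rng = np.random.default_rng(1)
        grid = rng.choice(["E", "D", "N"], size=(12, 30))
        calls = pd.DataFrame(grid, index=[f"P{i}" for i in range(12)],
                             columns=[f"S{j}" for j in range(30)])
        out = aberration_frequencies(calls, {f"S{j}": f"g{j % 3}" for j in range(30)})
        assert ((out["enr_freq"] + out["dep_freq"]) <= 1.0 + 1e-12).all()


class TestHierarchicalCluster:
    def test_first_merge_is_closest_pair_1d(self):
        tree = hierarchical_cluster(np.array([[0.0], [1.0], [5.0]]), labels=list("abc"))
        a, b = int(tree.linkage[0, 0]), int(tree.linkage[0, 1])
        assert {a, b} == {0, 1}

    def test_identical_items_merge_at_zero_height(self):
        tree = hierarchical_cluster(np.array([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]]))
        assert tree.linkage[0, 2] == pytest.approx(0.0)

    def test_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 3))
        labels = [f"i{k}" for k in range(8)]
        t1 = hierarchical_cluster(X, labels=labels)
        perm = rng.permutation(8)
        t2 = hierarchical_cluster(X[perm], labels=[labels[i] for i in perm])
        for k in (2, 3, 4):
            p1 = pd.Series(t1.cut(k), index=labels)
            p2 = pd.Series(t2.cut(k), index=[labels[i] for i in perm]).reindex(labels)
            # same partition up to label permutation
            from sklearn.metrics import adjusted_rand_score
            assert adjusted_rand_score(p1, p2) == pytest.approx(1.0)

    def test_fewer_than_two_items_is_error(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.array([[1.0]]))

    def test_newick_contains_all_leaves(self):
        tree = hierarchical_cluster(np.array([[0.0], [1.0], [5.0]]), labels=list("abc"))
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for leaf in "abc":
            assert leaf in nwk


def _blobs(sizes, centers, seed=0, n_features=5):
    rng = np.random.default_rng(seed)
    X, labels = [], []
    for k, (size, c) in enumerate(zip(sizes, centers)):
        X.append(rng.normal(c, 0.1, size=(size, n_features)))
        labels += [k] * size
    return np.vstack(X), np.array(labels)


class TestExtractSubgroups:
    def test_two_separated_blobs_recovered(self):
        X, truth = _blobs([30, 30], [0.0, 10.0])
        tree = hierarchical_cluster(X)
        a = extract_subgroups(tree, min_size=20, max_size=30, features=X)
        assert a.n_subgroups == 2
        got = a.labels.to_numpy()
        assert len(set(zip(got, truth))) == 2  # one-to-one with planted blobs

    def test_k_override_returns_exact_k(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        tree = hierarchical_cluster(X)
        a = extract_subgroups(tree, k_override=12)
        assert a.n_subgroups == 12
        # matches the standard k-cut of the same tree
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(a.labels.to_numpy(), tree.cut(12)) == pytest.approx(1.0)

    def test_small_cohort_stays_single_group(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 3))
        tree = hierarchical_cluster(X)
        a = extract_subgroups(tree, min_size=20, max_size=30)
        assert a.n_subgroups == 1
        assert a.sizes.iloc[0] == 25

    def test_partition_sizes_sum_to_n(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(83, 6))
        tree = hierarchical_cluster(X)
        a = extract_subgroups(tree, min_size=10, max_size=25, features=X)
        assert int(a.sizes.sum()) == 83
        assert (a.sizes >= 10).all()

    def test_infeasible_constraints_error(self):
        rng = np.random.default_rng(6)
        tree = hierarchical_cluster(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            extract_subgroups(tree, min_size=10, max_size=20)


class TestCrossGroup:
    def _freq_table(self, group, enr, dep):
        return pd.DataFrame({
            "group": group, "pathway": [f"P{i}" for i in range(len(enr))],
            "enr_freq": enr, "dep_freq": dep, "group_size": 10,
        })

    def test_feature_matrix_shape(self):
        t1 = self._freq_table("g1", [0.1, 0.2, 0.3], [0.0, 0.1, 0.2])
        t2 = self._freq_table("g2", [0.5, 0.5, 0.5], [0.1, 0.1, 0.1])
        feats = cross_group_features([t1, t2])
        assert feats.shape == (2, 6)
        assert list(feats.index) == ["g1", "g2"]

    def test_pathway_mismatch_is_error(self):
        t1 = self._freq_table("g1", [0.1, 0.2], [0.0, 0.1])
        t2 = self._freq_table("g2", [0.5], [0.1])
        with pytest.raises(ValueError, match="different pathway list"):
            cross_group_features([t1, t2])

    def test_identical_groups_merge_at_zero(self):
        t1 = self._freq_table("g1", [0.4, 0.2], [0.1, 0.0])
        t2 = self._freq_table("g2", [0.4, 0.2], [0.1, 0.0])
        t3 = self._freq_table("g3", [0.9, 0.9], [0.0, 0.0])
        feats = cross_group_features([t1, t2, t3])
        tree = hierarchical_cluster(feats)
        first = {int(tree.linkage[0, 0]), int(tree.linkage[0, 1])}
        assert first == {0, 1}
        assert tree.linkage[0, 2] == pytest.approx(0.0)


class TestSubgrouperEstimator:
    def test_fit_predict_recovers_blobs(self):
        X, truth = _blobs([25, 25, 25], [0.0, 10.0, 20.0], seed=7)
        model = PathwaySubgrouper(min_size=20, max_size=30)
        labels = model.fit_predict(X)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels, truth) == pytest.approx(1.0)
        assert model.get_params()["min_size"] == 20
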