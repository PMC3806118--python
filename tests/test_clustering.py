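import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from lactmir.clustering import (
    DistanceMatrix,
    agglomerate,
    apply_overrides,
    compute_distances,
    cut_tree,
)
from lactmir.simulate import simulate_patterns

from oracles import average_linkage_from_scratch


def profile_from(rows):
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["early", "peak", "late"]
    ).rename_axis("miRNA")


def partition(labels):
    out = {}
    for item, lab in labels.items():
        out.setdefault(lab, set()).add(item)
    return sorted(map(frozenset, out.values()), key=lambda s: sorted(s))


class TestDistances:
    def test_squared_euclidean(self):
        profile = profile_from({"a": (0, 0, 0), "b": (1, 2, 2)})
        d = compute_distances(profile)
        assert d.values[0, 1] == pytest.approx(9.0)
        assert compute_distances(profile, metric="euclidean").values[0, 1] == pytest.approx(3.0)

    def test_identical_vectors_distance_zero(self):
        profile = profile_from({"a": (5, 5, 5), "b": (5, 5, 5)})
        assert compute_distances(profile).values[0, 1] == 0.0

    def test_rescaled_mode_compares_shapes(self):
        profile = profile_from({"a": (1, 2, 4), "b": (100, 200, 400)})
        assert compute_distances(profile, rescale=True).values[0, 1] == pytest.approx(0.0)

    def test_metric_axioms_on_random_vectors(self, rng):
        profile = profile_from({f"m{i}": rng.uniform(0, 1000, 3) for i in range(100)})
        d = compute_distances(profile).values
        assert (d >= 0).all()
        np.testing.assert_allclose(d, d.T)
        direct = ((profile.loc["m3"] - profile.loc["m7"]) ** 2).sum()
        assert d[3, 7] == pytest.approx(direct)

    def test_missing_stage_rejected(self):
        profile = profile_from({"a": (1, 2, 3)})
        profile.at["a", "peak"] = np.nan
        with pytest.raises(ValueError):
            compute_distances(profile)


class TestAgglomerate:
    def test_two_tight_pairs_merge_first(self):
        profile = profile_from(
            {"a": (0, 0, 0), "b": (1, 0, 0), "x": (100, 100, 100), "y": (101, 100, 100)}
        )
        history = agglomerate(compute_distances(profile))
        first_two = {frozenset(h[0] | h[1]) for h in history[:2]}
        assert first_two == {frozenset({"a", "b"}), frozenset({"x", "y"})}

    def test_single_pair(self):
        profile = profile_from({"a": (0, 0, 0), "b": (1, 2, 2)})
        history = agglomerate(compute_distances(profile))
        assert history == [(frozenset({"a"}), frozenset({"b"}), 9.0)]

    def test_matches_from_scratch_oracle_small_n(self, rng):
        # between-group linkage vs exhaustive recomputation of cross-pair
        # means, including tie-broken instances (integer distances)
        for trial in range(300):
            n = int(rng.integers(2, 7))
            ids = [f"m{i}" for i in range(n)]
            X = rng.integers(0, 4, size=(n, 3)).astype(float)
            diff = X[:, None, :] - X[None, :, :]
            dmat = (diff**2).sum(axis=2)
            history = agglomerate(DistanceMatrix(ids=ids, values=dmat))
            expected = average_linkage_from_scratch(ids, dmat)
            assert len(history) == n - 1
            for (a, b, h), (ea, eb, eh) in zip(history, expected):
                assert {a, b} == {ea, eb}
                assert h == pytest.approx(eh, abs=1e-9)

    def test_agrees_with_scipy_on_tie_free_instance(self, rng):
        n = 15
        X = rng.uniform(0, 100, size=(n, 3))
        profile = profile_from({f"m{i:02d}": X[i] for i in range(n)})
        d = compute_distances(profile, metric="euclidean")
        ours = cut_tree(agglomerate(d), 4)
        scipy_labels = fcluster(
            linkage(squareform(d.values, checks=False), method="average"), 4, "maxclust"
        )
        theirs = {f"m{i:02d}": int(scipy_labels[i]) for i in range(n)}
        assert partition(ours.labels) == partition(theirs)

    def test_heights_non_decreasing(self, rng):
        X = rng.uniform(0, 10, size=(12, 3))
        profile = profile_from({f"m{i:02d}": X[i] for i in range(12)})
        history = agglomerate(compute_distances(profile))
        heights = [h for _, _, h in history]
        assert all(a <= b + 1e-9 for a, b in zip(heights, heights[1:]))

    def test_input_order_irrelevant_without_ties(self, rng):
        X = rng.uniform(0, 10, size=(8, 3))
        ids = [f"m{i}" for i in range(8)]
        profile = profile_from(dict(zip(ids, X)))
        base = partition(cut_tree(agglomerate(compute_distances(profile)), 3).labels)
        perm = rng.permutation(8)
        shuffled = profile.iloc[perm]
        assert partition(cut_tree(agglomerate(compute_distances(shuffled)), 3).labels) == base


class TestCutTree:
    def test_extreme_cuts(self, rng):
        X = rng.uniform(0, 10, size=(6, 3))
        profile = profile_from({f"m{i}": X[i] for i in range(6)})
        history = agglomerate(compute_distances(profile))
        assert len(set(cut_tree(history, 6).labels.values())) == 6
        assert len(set(cut_tree(history, 1).labels.values())) == 1
        with pytest.raises(ValueError):
            cut_tree(history, 7)

    def test_partitions_nest_across_k(self, rng):
        X = rng.uniform(0, 10, size=(10, 3))
        profile = profile_from({f"m{i}": X[i] for i in range(10)})
        history = agglomerate(compute_distances(profile))
        for k in range(2, 10):
            coarse = partition(cut_tree(history, k).labels)
            fine = partition(cut_tree(history, k + 1).labels)
            for cluster in fine:
                assert any(cluster <= c for c in coarse)

    def test_labels_follow_early_expression(self):
        profile = profile_from(
            {"hi1": (900, 10, 10), "hi2": (910, 10, 10), "lo1": (5, 500, 500), "lo2": (6, 500, 500)}
        )
        assignment = cut_tree(agglomerate(compute_distances(profile)), 2, profile=profile)
        assert assignment.labels["hi1"] == "A" and assignment.labels["lo1"] == "B"

    def test_planted_patterns_recovered(self):
        profile, truth = simulate_patterns(k=5, n_per_cluster=5, noise_sd=5.0, seed=4)
        assignment = cut_tree(agglomerate(compute_distances(profile)), 5)
        assert partition(assignment.labels) == partition(truth.cluster_labels)


class TestOverrides:
    def _assignment(self):
        profile = profile_from({"a": (0, 0, 0), "b": (1, 0, 0), "x": (9, 9, 9), "y": (9, 9, 8)})
        return cut_tree(agglomerate(compute_distances(profile)), 2)

    def test_manual_reassignment_recorded(self):
        assignment = self._assignment()
        lab_a = assignment.labels["a"]
        lab_x = assignment.labels["x"]
        moved = apply_overrides(assignment, [("x", lab_a)])
        assert moved.labels["x"] == lab_a
        assert moved.overrides_applied == [("x", lab_x, lab_a)]
        assert {m: l for m, l in moved.labels.items() if m != "x"} == {
            m: l for m, l in assignment.labels.items() if m != "x"
        }

    def test_empty_overrides_identity_and_involution(self):
        assignment = self._assignment()
        assert apply_overrides(assignment, []).labels == assignment.labels
        lab_x, lab_a = assignment.labels["x"], assignment.labels["a"]
        back = apply_overrides(
            apply_overrides(assignment, [("x", lab_a)]), [("x", lab_x)]
        )
        assert back.labels == assignment.labels

    def test_unknown_ids_rejected(self):
        assignment = self._assignment()
        with pytest.raises(ValueError, match="unknown miRNA"):
            apply_overrides(assignment, [("nope", "A")])
        with pytest.raises(ValueError, match="unknown cluster label"):
            apply_overrides(assignment, [("x", "Z")])
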