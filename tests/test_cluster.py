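import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from semark import gene_clustering, render_heatmap, tissue_clustering
from semark.cluster import (
    _agglomerate,
    complete_linkage_bruteforce,
    correlation_distance_matrix,
)
from semark.qpcr import RelExpressionEntry, RelExpressionTable


def _table(profiles: dict[str, dict[str, float]]) -> RelExpressionTable:
    """profiles: gene -> tissue -> log2fc."""
    entries = {
        (g, t): RelExpressionEntry(v, 0.0, 3)
        for g, row in profiles.items()
        for t, v in row.items()
    }
    return RelExpressionTable(entries=entries)


def _square(values: np.ndarray) -> np.ndarray:
    diff = values[:, None, :] - values[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


class TestDistances:
    def test_correlation_distance_bounds_and_symmetry(self):
        rng = np.random.default_rng(0)
        profiles = pd.DataFrame(rng.normal(size=(8, 6)))
        d = correlation_distance_matrix(profiles)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert d.min() >= 0.0 and d.max() <= 2.0

    def test_affine_copies_have_distance_zero(self):
        y = np.array([1.0, 3.0, 2.0, 5.0])
        profiles = pd.DataFrame([y, 2 * y + 3], index=["g1", "g2"])
        assert correlation_distance_matrix(profiles)[0, 1] == pytest.approx(0.0)

    def test_negated_profile_has_distance_two(self):
        y = np.array([1.0, 3.0, 2.0, 5.0])
        profiles = pd.DataFrame([y, -y], index=["g1", "g2"])
        assert correlation_distance_matrix(profiles)[0, 1] == pytest.approx(2.0)

    def test_zero_variance_profile_rejected_naming_gene(self):
        profiles = pd.DataFrame([[1, 1, 1], [1, 2, 3]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            correlation_distance_matrix(profiles)


class TestTissueClustering:
    def test_identical_profiles_merge_first_at_height_zero(self):
        table = _table({"g": {"t1": 1.0, "t2": 1.0, "t3": 9.0}})
        tree = tissue_clustering(table)
        first = tree.merges[0]
        assert first.height == 0.0
        assert {tree.leaves[first.left], tree.leaves[first.right]} == {"t1", "t2"}

    def test_three_one_dim_profiles_merge_nearest_pair_first(self):
        table = _table({"g": {"a": 0.0, "b": 1.0, "c": 10.0}})
        tree = tissue_clustering(table)
        first = tree.merges[0]
        assert {tree.leaves[first.left], tree.leaves[first.right]} == {"a", "b"}
        assert first.height == pytest.approx(1.0)
        # Ward height of the final merge, hand-computed via Lance-Williams:
        # d({c},{a,b})^2 = (2*100 + 2*81 - 1)/3
        assert tree.merges[1].height == pytest.approx(np.sqrt(361 / 3))

    def test_matches_scipy_ward_on_tie_free_data(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(9, 5))
        genes = [f"g{i}" for i in range(5)]
        tissues = [f"t{i}" for i in range(9)]
        table = _table({g: {t: X[j, i] for j, t in enumerate(tissues)} for i, g in enumerate(genes)})
        tree = tissue_clustering(table)
        ours = tree.to_scipy_linkage()
        ref = linkage(X, method="ward")
        assert np.allclose(np.sort(ours[:, 2]), np.sort(ref[:, 2]))

    def test_fewer_than_two_tissues_rejected(self):
        with pytest.raises(ValueError, match="2 tissues"):
            tissue_clustering(_table({"g": {"t1": 1.0}}))

    def test_four_planted_tissue_groups_recovered_at_k4(self):
        rng = np.random.default_rng(11)
        centers = {"A": 0.0, "B": 10.0, "C": -10.0, "D": 25.0}
        genes = [f"g{i}" for i in range(12)]
        tissues, truth = [], {}
        profiles: dict[str, dict[str, float]] = {g: {} for g in genes}
        for grp, center in centers.items():
            for i in range(2):
                t = f"{grp}{i}"
                tissues.append(t)
                truth[t] = grp
                for g in genes:
                    profiles[g][t] = center + rng.normal(0, 0.1)
        tree = tissue_clustering(_table(profiles))
        parts = tree.cut(4)
        recovered = {frozenset(p) for p in parts}
        expected = {
            frozenset(t for t in tissues if truth[t] == grp) for grp in centers
        }
        assert recovered == expected


class TestGeneClustering:
    def test_correlated_genes_merge_first(self):
        y = {"t1": 0.0, "t2": 1.0, "t3": 2.0, "t4": 5.0}
        table = _table(
            {
                "g1": y,
                "g2": {t: 2 * v + 3 for t, v in y.items()},
                "g3": {t: -v for t, v in y.items()},
            }
        )
        tree = gene_clustering(table)
        first = tree.merges[0]
        assert {tree.leaves[first.left], tree.leaves[first.right]} == {"g1", "g2"}
        assert first.height == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_complete_linkage_equals_bruteforce_up_to_six_leaves(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        X = rng.normal(size=(n, 5))
        labels = [f"g{i}" for i in range(n)]
        d = _square(X)
        fast = _agglomerate(d, labels, "complete", "euclidean")
        brute = complete_linkage_bruteforce(d, labels)
        assert fast.merges == brute.merges

    def test_permuting_input_order_yields_identical_tree_structure(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(6, 4))
        labels = [f"g{i}" for i in range(6)]
        d = _square(X)
        tree1 = _agglomerate(d, labels, "complete", "euclidean")
        perm = rng.permutation(6)
        tree2 = _agglomerate(d[np.ix_(perm, perm)], [labels[i] for i in perm], "complete", "euclidean")

        def merge_sets(tree):
            n = len(tree.leaves)
            members = tree._members()
            return sorted(
                (frozenset(tree.leaves[i] for i in members[n + k]), round(m.height, 9))
                for k, m in enumerate(tree.merges)
            )

        assert merge_sets(tree1) == merge_sets(tree2)

    def test_exact_tie_resolves_to_lexicographically_smallest_labels(self):
        # four equidistant points: every pair at distance 1
        d = np.ones((4, 4)) - np.eye(4)
        tree = _agglomerate(d, ["d", "c", "b", "a"], "complete", "euclidean")
        first = tree.merges[0]
        assert {tree.leaves[first.left], tree.leaves[first.right]} == {"a", "b"}


class TestLinkageTree:
    def test_newick_round_trips_leaf_set(self):
        table = _table({"g": {"a": 0.0, "b": 1.0, "c": 10.0}})
        nwk = tissue_clustering(table).to_newick()
        assert nwk.endswith(";")
        for leaf in ("a", "b", "c"):
            assert leaf in nwk

    def test_cut_extremes(self):
        table = _table({"g": {"a": 0.0, "b": 1.0, "c": 10.0}})
        tree = tissue_clustering(table)
        assert tree.cut(1) == [frozenset({"a", "b", "c"})]
        assert sorted(tree.cut(3), key=sorted) == [frozenset({"a"}), frozenset({"b"}), frozenset({"c"})]


class TestRenderHeatmap:
    def _small_table(self):
        return _table(
            {
                "g1": {"rl": 0.0, "ec": 2.0, "gse": 1.0},
                "g2": {"rl": 0.0, "ec": -2.0, "gse": 0.5},
            }
        )

    def test_writes_image_matrix_and_newicks(self, tmp_path):
        table = self._small_table()
        paths = render_heatmap(
            table, tissue_clustering(table), gene_clustering(table), tmp_path / "hm.png"
        )
        for p in paths.values():
            assert p.exists()
        plotted = pd.read_csv(paths["matrix"], sep="\t", index_col=0)
        original = table.profile_matrix()
        assert np.allclose(
            plotted.loc[original.index, original.columns].to_numpy(),
            original.to_numpy(),
        )

    def test_label_mismatch_rejected(self, tmp_path):
        table = self._small_table()
        other = _table({"gX": {"rl": 0.0, "ec": 1.0, "gse": 2.0}, "gY": {"rl": 1.0, "ec": 0.0, "gse": 2.0}})
        with pytest.raises(ValueError, match="mismatch"):
            render_heatmap(
                table, tissue_clustering(table), gene_clustering(other), tmp_path / "x.png"
            )
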