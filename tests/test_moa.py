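"""Pearson-distance clustering, MoA assignment, Newick export, heatmap."""

import io

import numpy as np
import pandas as pd
import pytest

from cytoprofile.config import ReferenceConfig
from cytoprofile.moa import (
    ClusterTree,
    assign_moa,
    export_newick,
    hierarchical_cluster,
    pearson_distance_matrix,
    render_heatmap,
)
from cytoprofile.synthdata import generate_reference_library


def brute_force_upgma(D):
    """Naive UPGMA oracle: repeatedly merge the closest pair, averaging
    dissimilarities weighted by cluster size. Returns merge heights and the
    partition trace (frozensets of leaf indices per merge)."""
    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    heights, partitions = [], []
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        merged = clusters[a] | clusters[b]
        na, nb = len(clusters[a]), len(clusters[b])
        del clusters[a], clusters[b]
        new_dist = {}
        for (i, j), d in dist.items():
            if a in (i, j) or b in (i, j):
                continue
            new_dist[(i, j)] = d
        for c in clusters:
            key_a = (min(a, c), max(a, c))
            key_b = (min(b, c), max(b, c))
            d = (na * dist[key_a] + nb * dist[key_b]) / (na + nb)
            new_dist[(min(c, next_id), max(c, next_id))] = d
        clusters[next_id] = merged
        partitions.append(set(clusters.values()))
        dist = new_dist
        next_id += 1
    return heights, partitions


class TestPearsonDistance:
    def test_identical_profiles_distance_zero(self):
        m = pd.DataFrame([[1.0, 2, 3], [1.0, 2, 3]], index=["a", "b"])
        d = pearson_distance_matrix(m)
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_negated_profile_distance_two(self):
        m = pd.DataFrame([[1.0, 2, 3], [-1.0, -2, -3]], index=["a", "b"])
        assert pearson_distance_matrix(m).loc["a", "b"] == pytest.approx(2.0)

    def test_textbook_formula(self):
        """d = 1 - cov/(sd*sd), computed by hand for x=(1,2,3), y=(1,2,4)."""
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 4.0])
        cov = ((x - x.mean()) * (y - y.mean())).sum() / 2
        r_oracle = cov / (x.std(ddof=1) * y.std(ddof=1))
        m = pd.DataFrame([x, y], index=["x", "y"])
        assert pearson_distance_matrix(m).loc["x", "y"] == pytest.approx(
            1 - r_oracle, abs=1e-12
        )

    def test_axioms(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(8, 10)))
        d = pearson_distance_matrix(m).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 2).all()

    def test_zero_variance_profile_named(self):
        m = pd.DataFrame([[1.0, 1, 1], [1.0, 2, 3]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            pearson_distance_matrix(m)

    def test_missing_values_pairwise_complete(self):
        m = pd.DataFrame(
            [[1.0, 2, 3, 4], [1.0, 2, 3, np.nan], [4.0, 3, 2, 1]],
            index=["a", "b", "c"],
        )
        d = pearson_distance_matrix(m)
        assert d.loc["a", "b"] == pytest.approx(0.0)
        assert d.loc["a", "c"] == pytest.approx(2.0)

    def test_too_few_shared_features(self):
        m = pd.DataFrame(
            [[1.0, 2, np.nan, np.nan], [np.nan, np.nan, 3.0, 4]], index=["a", "b"]
        )
        with pytest.raises(ValueError, match="share"):
            pearson_distance_matrix(m)


class TestHierarchicalClustering:
    def test_two_samples_single_merge(self):
        d = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["A", "B"], columns=["A", "B"])
        tree = hierarchical_cluster(d)
        assert tree.merge_heights().tolist() == [pytest.approx(0.4)]

    def test_three_sample_hand_trace(self):
        """d(A,B)=0.1, d(A,C)=d(B,C)=0.9: merge (A,B)@0.1 then C@0.9."""
        d = pd.DataFrame(
            [[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        tree = hierarchical_cluster(d)
        np.testing.assert_allclose(tree.merge_heights(), [0.1, 0.9])
        assert tree.cut(k=2).tolist()[0] == tree.cut(k=2).tolist()[1] != tree.cut(k=2).tolist()[2]

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_brute_force_oracle(self, n):
        """Merge heights and partition traces equal the naive UPGMA on
        random dissimilarity matrices."""
        rng = np.random.default_rng(n)
        D = rng.uniform(0.05, 2.0, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        names = [f"s{i}" for i in range(n)]
        tree = hierarchical_cluster(pd.DataFrame(D, index=names, columns=names))
        heights, partitions = brute_force_upgma(D)
        np.testing.assert_allclose(np.sort(tree.merge_heights()), np.sort(heights), atol=1e-10)
        for k, part in zip(range(n - 1, 0, -1), partitions):
            cut = tree.cut(k=k)
            found = {
                frozenset(np.flatnonzero(cut.to_numpy() == c)) for c in np.unique(cut)
            }
            assert found == part

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 9))
        d = pearson_distance_matrix(pd.DataFrame(X))
        tree = hierarchical_cluster(d)
        h = tree.merge_heights()
        assert (np.diff(h) >= -1e-12).all()

    def test_invalid_matrices_rejected(self):
        bad = pd.DataFrame([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_cluster(bad)
        neg = pd.DataFrame([[0, -0.5], [-0.5, 0]])
        with pytest.raises(ValueError, match="non-negative"):
            hierarchical_cluster(neg)

    def test_planted_classes_recovered_at_cut(self):
        """Well-separated planted classes reappear exactly at cut k."""
        rng = np.random.default_rng(4)
        k, per, f = 4, 6, 15
        centers = rng.uniform(-1, 1, size=(k, f)) * 3
        X = np.vstack([centers[i] + rng.normal(0, 0.05, (per, f)) for i in range(k)])
        d = pearson_distance_matrix(pd.DataFrame(X))
        cut = hierarchical_cluster(d).cut(k=k).to_numpy()
        true = np.repeat(np.arange(k), per)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(true, cut) == 1.0


class TestAssignMoa:
    def _toy_matrix(self):
        rng = np.random.default_rng(9)
        sigs = np.array([[1.0, -1, 1, -1, 1, 0, 1, -1], [-1.0, 1, 0, 1, -1, 1, -1, 1]])
        rows, names, labels = [], [], {}
        for c, lab in enumerate(["topo", "tubulin"]):
            for i in range(4):
                rows.append(sigs[c] + rng.normal(0, 0.05, 8))
                names.append(f"{lab}_ref{i}")
                labels[f"{lab}_ref{i}"] = lab
        rows.append(sigs[0])  # fraction identical to class-0 signature
        names.append("frac1")
        m = pd.DataFrame(rows, index=names)
        return m, labels

    def test_identical_fraction_gets_class_label(self):
        m, labels = self._toy_matrix()
        tree = hierarchical_cluster(pearson_distance_matrix(m))
        calls = assign_moa(tree, labels, m, cut_height=0.3)
        call = calls.set_index("sample_id").loc["frac1"]
        assert call["predicted_moa"] == "topo"
        assert call["support"] == 1.0
        assert call["nearest_r"] > 0.99

    def test_reference_free_cluster_unassigned(self):
        m, labels = self._toy_matrix()
        lonely = pd.DataFrame(
            [np.array([0.1, 0.1, -1, 1, 1, -1, 0.2, 0.3])], index=["frac2"]
        )
        m2 = pd.concat([m, lonely])
        tree = hierarchical_cluster(pearson_distance_matrix(m2))
        calls = assign_moa(tree, labels, m2, cut_height=0.3).set_index("sample_id")
        assert calls.loc["frac2", "predicted_moa"] == "unassigned"
        assert calls.loc["frac2", "support"] == 0.0

    def test_single_cluster_warns(self):
        m, labels = self._toy_matrix()
        tree = hierarchical_cluster(pearson_distance_matrix(m))
        with pytest.warns(UserWarning, match="single cluster"):
            calls = assign_moa(tree, labels, m, cut_height=2.5)
        assert len(calls) == 1  # calls still emitted

    def test_planted_screen_recovery(self):
        """10 classes, 20 refs each, 50 fractions at noise sd 0.15:
        fractions overwhelmingly recover their generating class."""
        acc, ari = _planted_recovery(noise_sd=0.15, seed=0)
        assert acc >= 0.9
        assert ari >= 0.9

    def test_accuracy_degrades_with_noise(self):
        """Call accuracy is non-increasing in profile noise."""
        accs = [_planted_recovery(noise_sd=sd, seed=1)[0] for sd in (0.05, 0.15, 0.3, 0.6)]
        for a, b in zip(accs, accs[1:]):
            assert b <= a + 0.05  # allow sampling jitter, forbid real inversions
        assert accs[0] > accs[-1]

    def test_feature_shuffle_destroys_support(self):
        """Shuffling fraction feature order drops mean support to ~chance."""
        refs, labels, frac, true = _planted_screen(noise_sd=0.15, seed=2)
        rng = np.random.default_rng(3)
        shuffled = frac.copy()
        shuffled[:] = frac.to_numpy()[:, rng.permutation(frac.shape[1])]
        joint = pd.concat([shuffled, refs])
        tree = hierarchical_cluster(pearson_distance_matrix(joint))
        calls = assign_moa(tree, labels, joint, cut_height=0.3)
        k = labels["moa_label"].nunique()
        assert calls["support"].mean() <= 1.0 / k + 0.1


def _planted_screen(noise_sd, seed):
    cfg = ReferenceConfig(n_compounds=200, n_moa_classes=10, noise_sd=noise_sd)
    refs, labels, class_sigs = generate_reference_library(cfg, seed=seed)
    rng = np.random.default_rng(1000 + seed)
    n_frac = 50
    assign = rng.integers(0, 10, n_frac)
    frac = np.clip(
        class_sigs[assign] + rng.normal(0, noise_sd, (n_frac, class_sigs.shape[1])),
        -1, 1,
    )
    class_labels = labels["moa_label"].unique()
    frac_df = pd.DataFrame(
        frac, index=[f"frac_{i}" for i in range(n_frac)], columns=refs.columns
    )
    true = [class_labels[a] for a in assign]
    return refs, labels, frac_df, true


def _planted_recovery(noise_sd, seed):
    refs, labels, frac_df, true = _planted_screen(noise_sd, seed)
    joint = pd.concat([frac_df, refs])
    tree = hierarchical_cluster(pearson_distance_matrix(joint))
    calls = assign_moa(tree, labels, joint, cut_height=0.3).set_index("sample_id")
    pred = [calls.loc[f, "predicted_moa"] for f in frac_df.index]
    acc = np.mean([p == t for p, t in zip(pred, true)])

    from sklearn.metrics import adjusted_rand_score

    cut = tree.cut(k=10)
    truth_all = true + list(labels["moa_label"])
    ari = adjusted_rand_score(truth_all, cut.to_numpy())
    return acc, ari


class TestNewick:
    def test_two_leaves(self):
        d = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["A", "B"], columns=["A", "B"])
        tree = hierarchical_cluster(d)
        assert export_newick(tree) == "(A:0.2,B:0.2);"

    def test_quoting_spaces(self):
        d = pd.DataFrame(
            [[0, 0.4], [0.4, 0]], index=["my sample", "B"], columns=["my sample", "B"]
        )
        nwk = export_newick(hierarchical_cluster(d))
        assert "'my sample'" in nwk

    def test_roundtrip_heights(self):
        """Re-parsing with an independent reader reproduces merge heights."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(7, 12))
        names = [f"leaf{i}" for i in range(7)]
        d = pearson_distance_matrix(pd.DataFrame(X, index=names))
        tree = hierarchical_cluster(d)
        nwk = export_newick(tree)

        from Bio import Phylo

        parsed = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted(names)
        # leaf depth = root elevation = last merge height / 2 (ultrametric)
        root_h = tree.merge_heights()[-1] / 2
        for leaf in parsed.get_terminals():
            assert parsed.distance(leaf) == pytest.approx(root_h, abs=1e-9)


class TestHeatmap:
    def test_row_order_and_tsv(self, tmp_path):
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, size=(6, 5))
        names = [f"s{i}" for i in range(6)]
        m = pd.DataFrame(X, index=names)
        tree = hierarchical_cluster(pearson_distance_matrix(m))
        fig, ordered = render_heatmap(m, tree, out_tsv=tmp_path / "ordered.tsv")
        expected = [names[i] for i in tree.leaf_order()]
        assert list(ordered.index) == expected
        back = pd.read_csv(tmp_path / "ordered.tsv", sep="\t", index_col=0)
        assert list(back.index) == expected
        import matplotlib.pyplot as plt

        im = fig.axes[0].images[0]
        assert im.get_clim() == (-1.0, 1.0)
        plt.close(fig)

    def test_zero_matrix_uniform(self, tmp_path):
        m = pd.DataFrame(np.zeros((3, 4)), index=["a", "b", "c"])
        tree = hierarchical_cluster(
            pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=m.index, columns=m.index)
        )
        fig, ordered = render_heatmap(m, tree, out_tsv=tmp_path / "z.tsv")
        assert (ordered.to_numpy() == 0).all()
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_mismatched_leaves_rejected(self):
        m = pd.DataFrame(np.zeros((2, 3)), index=["a", "b"])
        tree = ClusterTree(np.array([[0, 1, 0.5, 2.0]]), ["x", "y"])
        with pytest.raises(ValueError, match="disagree"):
            render_heatmap(m, tree)
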