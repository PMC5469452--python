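"""Mode-of-action assignment by profile clustering.

Fraction profiles are clustered together with reference-compound profiles
(compounds with annotated mechanism classes) using average-linkage
hierarchical clustering on Pearson distance d = 1 - r. The tree is cut at a
correlation-derived height (default 0.3, i.e. within-cluster r >= 0.7) and
every fraction inherits the majority mechanism label of the reference
compounds in its cluster.

Note d = 1 - r is a dissimilarity, not a metric (it can violate the triangle
inequality); average linkage does not require metricity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

UNASSIGNED = "unassigned"


def pearson_distance_matrix(profile_matrix: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise dissimilarity d(i,j) = 1 - Pearson r(i,j) over shared features.

    Missing entries are handled pairwise-complete; a pair sharing fewer than
    ``min_shared`` features, or a profile with zero variance, is an error
    (named, not silent NaN). d lies in [0, 2], is symmetric, zero-diagonal.
    """
    X = profile_matrix.to_numpy(dtype=float)
    names = list(profile_matrix.index)
    n, f = X.shape
    if n < 2:
        raise ValueError("need at least 2 profiles")
    has_nan = np.isnan(X).any()

    if not has_nan:
        sd = X.std(axis=1)
        for i in np.flatnonzero(sd == 0):
            raise ValueError(f"profile {names[i]!r} has zero variance; correlation undefined")
        if f < min_shared:
            raise ValueError(f"profiles share only {f} features (< {min_shared})")
        r = np.corrcoef(X)
    else:
        r = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                mask = ~(np.isnan(X[i]) | np.isnan(X[j]))
                if mask.sum() < min_shared:
                    raise ValueError(
                        f"profiles {names[i]!r} and {names[j]!r} share only "
                        f"{int(mask.sum())} features (< {min_shared})"
                    )
                xi, xj = X[i, mask], X[j, mask]
                if xi.std() == 0:
                    raise ValueError(f"profile {names[i]!r} has zero variance; correlation undefined")
                if xj.std() == 0:
                    raise ValueError(f"profile {names[j]!r} has zero variance; correlation undefined")
                r[i, j] = r[j, i] = np.corrcoef(xi, xj)[0, 1]

    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=names, columns=names)


@dataclass
class ClusterTree:
    """Agglomerative tree: scipy linkage matrix plus leaf labels."""

    linkage_matrix: np.ndarray  # scipy (n-1) x 4
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def leaf_order(self) -> list[int]:
        """Leaf order for display: recursive tightest-subtree-first.

        At every internal node the child subtree that merged at the lower
        height is placed first (ties broken by smallest leaf index), giving a
        stable heatmap ordering independent of input permutation details.
        """
        n = self.n_leaves
        Z = self.linkage_matrix
        height = {i: 0.0 for i in range(n)}
        minleaf = {i: i for i in range(n)}
        children = {}
        for k, (a, b, h, _) in enumerate(Z):
            node = n + k
            a, b = int(a), int(b)
            children[node] = (a, b)
            height[node] = float(h)
            minleaf[node] = min(minleaf[a], minleaf[b])

        order: list[int] = []
        stack = [n + len(Z) - 1] if len(Z) else [0]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(node)
                continue
            a, b = children[node]
            first, second = sorted(
                (a, b), key=lambda c: (height[c], minleaf[c])
            )
            stack.append(second)
            stack.append(first)
        return order

    def cut(self, k: int | None = None, height: float | None = None) -> pd.Series:
        """Flat clusters by count (k) or by merge height; labelled by leaf."""
        if (k is None) == (height is None):
            raise ValueError("give exactly one of k or height")
        if k is not None:
            assignment = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        else:
            assignment = hierarchy.fcluster(self.linkage_matrix, t=height, criterion="distance")
        return pd.Series(assignment, index=self.labels, name="cluster")


def hierarchical_cluster(dissimilarity: pd.DataFrame, linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering of a dissimilarity matrix (UPGMA default)."""
    D = dissimilarity.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if (D < 0).any():
        raise ValueError("dissimilarity entries must be non-negative")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(linkage_matrix=Z, labels=list(dissimilarity.index))


def assign_moa(
    tree: ClusterTree,
    reference_labels: pd.DataFrame | dict,
    profile_matrix: pd.DataFrame,
    cut_height: float | None = 0.3,
    k: int | None = None,
) -> pd.DataFrame:
    """Cut the joint tree and label every fraction by its cluster's references.

    ``reference_labels`` maps compound_id -> moa_label (dict, or a DataFrame
    with those two columns). Every sample in the matrix that is not a
    reference is treated as a fraction. Fractions in reference-free clusters
    are labelled "unassigned". The globally nearest reference (by Pearson r)
    is always reported.
    """
    if isinstance(reference_labels, pd.DataFrame):
        ref_map = dict(zip(reference_labels["compound_id"], reference_labels["moa_label"]))
    else:
        ref_map = dict(reference_labels)
    for cid, lab in ref_map.items():
        if not lab:
            raise ValueError(f"reference {cid!r} has an empty moa_label")

    clusters = tree.cut(k=k, height=None if k is not None else cut_height)
    if clusters.nunique() == 1:
        warnings.warn("tree cut yields a single cluster containing everything")

    names = list(profile_matrix.index)
    ref_names = [s for s in names if s in ref_map]
    frac_names = [s for s in names if s not in ref_map]
    if not ref_names:
        raise ValueError("no reference profiles present in the matrix")

    corr = 1.0 - pearson_distance_matrix(profile_matrix).loc[frac_names, ref_names]

    rows = []
    for frac in frac_names:
        cid = clusters[frac]
        members = clusters.index[clusters == cid]
        cluster_refs = [m for m in members if m in ref_map]
        r_row = corr.loc[frac]
        nearest_id = r_row.idxmax()
        nearest_r = float(r_row.max())
        if not cluster_refs:
            predicted, support = UNASSIGNED, 0.0
        else:
            tally = pd.Series([ref_map[m] for m in cluster_refs]).value_counts()
            top = tally[tally == tally.max()].index
            if len(top) == 1:
                predicted = top[0]
            else:  # tie -> label of the nearest tied reference
                tied = [m for m in cluster_refs if ref_map[m] in set(top)]
                predicted = ref_map[r_row[tied].idxmax()]
            support = float(tally[predicted] / len(cluster_refs))
        rows.append(
            {
                "sample_id": frac,
                "predicted_moa": predicted,
                "support": support,
                "nearest_reference": nearest_id,
                "nearest_r": nearest_r,
                "cluster": int(cid),
                "n_cluster_references": len(cluster_refs),
            }
        )
    return pd.DataFrame(rows)


def export_newick(tree: ClusterTree) -> str:
    """Ultrametric Newick text: node elevation = merge height / 2, branch
    lengths = elevation differences. Labels with spaces or Newick
    metacharacters are single-quoted."""
    n = tree.n_leaves
    Z = tree.linkage_matrix

    def quote(name: str) -> str:
        if any(c in name for c in " ()[]:;,'\t"):
            return "'" + name.replace("'", "''") + "'"
        return name

    elev = {i: 0.0 for i in range(n)}
    children = {}
    for kk, (a, b, h, _) in enumerate(Z):
        node = n + kk
        children[node] = (int(a), int(b))
        elev[node] = float(h) / 2.0

    def render(node: int, parent_elev: float) -> str:
        length = parent_elev - elev[node]
        if node < n:
            return f"{quote(tree.labels[node])}:{length:.10g}"
        a, b = children[node]
        return f"({render(a, elev[node])},{render(b, elev[node])}):{length:.10g}"

    if n == 1:
        return f"{quote(tree.labels[0])}:0;"
    root = n + len(Z) - 1
    a, b = children[root]
    return f"({render(a, elev[root])},{render(b, elev[root])});"


def render_heatmap(
    profile_matrix: pd.DataFrame,
    tree: ClusterTree,
    out_png=None,
    out_tsv=None,
):
    """Tree-ordered profile heat map (positive yellow, negative blue).

    Rows follow the tree's leaf order; the diverging colormap is centred at 0
    and spans [-1, 1]. The ordered matrix is also written as TSV so the
    rendering contract is testable without comparing pixels. Returns
    ``(figure, ordered_matrix)``.
    """
    if list(profile_matrix.index) != tree.labels:
        raise ValueError("matrix rows and tree leaves disagree")
    order = tree.leaf_order()
    ordered = profile_matrix.iloc[order]
    if out_tsv is not None:
        ordered.to_csv(out_tsv, sep="\t")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "blue_black_yellow", ["#1f4fd8", "#000000", "#ffe21f"]
    )
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * ordered.shape[1]), max(3, 0.12 * ordered.shape[0]))
    )
    im = ax.imshow(ordered.to_numpy(float), cmap=cmap, vmin=-1.0, vmax=1.0, aspect="auto")
    ax.set_xticks(range(ordered.shape[1]))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(ordered.shape[0]))
    ax.set_yticklabels(ordered.index, fontsize=4)
    fig.colorbar(im, ax=ax, label="feature score")
    fig.tight_layout()
    if out_png is not None:
        fig.savefig(out_png, dpi=150)
        plt.close(fig)
    return fig, ordered
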