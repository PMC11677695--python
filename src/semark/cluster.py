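"""Hierarchical clustering of tissues and genes over log2 fold-change profiles.

Tissues are clustered on Euclidean distances with Ward agglomeration;
genes on correlation distance (1 - Pearson r) with complete linkage
(furthest neighbour). The agglomeration engine is written here rather than
delegated so that merge ties resolve deterministically — by the
lexicographically smallest leaf labels of the candidate pair — making
trees invariant to input ordering; scipy's linkage serves as a cross-check
in the test suite on tie-free data.

Ward distances follow the Lance-Williams update on squared Euclidean
distances, with merge heights reported on the distance (root) scale, the
same convention scipy uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .qpcr import RelExpressionTable


@dataclass(frozen=True)
class Merge:
    left: int
    right: int
    height: float
    size: int


@dataclass(frozen=True)
class LinkageTree:
    """An agglomeration history over labelled leaves.

    Leaves are numbered 0..n-1 in ``leaves`` order; merge *i* creates
    cluster id n+i from two existing cluster ids, as in scipy's linkage
    encoding.
    """

    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]
    method: str
    metric: str

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError(
                f"{len(self.leaves)} leaves need {len(self.leaves) - 1} merges, "
                f"got {len(self.merges)}"
            )

    def _members(self) -> dict[int, list[int]]:
        n = len(self.leaves)
        members = {i: [i] for i in range(n)}
        for k, m in enumerate(self.merges):
            members[n + k] = members[m.left] + members[m.right]
        return members

    def leaf_order(self) -> list[str]:
        """Dendrogram leaf order (left subtree before right, recursively)."""
        if not self.merges:
            return list(self.leaves)
        members = self._members()
        root = len(self.leaves) + len(self.merges) - 1
        return [self.leaves[i] for i in members[root]]

    def cut(self, k: int) -> list[frozenset[str]]:
        """Partition the leaves into k clusters by undoing the last merges."""
        n = len(self.leaves)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        members = self._members()
        active = set(range(n))
        for i, m in enumerate(self.merges[: n - k]):
            active -= {m.left, m.right}
            active.add(n + i)
        return [frozenset(self.leaves[i] for i in members[c]) for c in sorted(active)]

    def to_scipy_linkage(self) -> np.ndarray:
        return np.array(
            [[m.left, m.right, m.height, m.size] for m in self.merges], dtype=float
        )

    def to_newick(self) -> str:
        """Newick string with branch lengths height(parent) - height(child)."""
        n = len(self.leaves)
        heights = {i: 0.0 for i in range(n)}
        for k, m in enumerate(self.merges):
            heights[n + k] = m.height

        def render(node: int, parent_height: float) -> str:
            length = max(parent_height - heights[node], 0.0)
            if node < n:
                return f"{self.leaves[node]}:{length:.6g}"
            m = self.merges[node - n]
            inner = f"({render(m.left, heights[node])},{render(m.right, heights[node])})"
            return f"{inner}:{length:.6g}"

        root = n + len(self.merges) - 1
        if not self.merges:
            return f"({self.leaves[0]}:0);"
        m = self.merges[-1]
        return (
            f"({render(m.left, heights[root])},{render(m.right, heights[root])});"
        )


# ---------------------------------------------------------------------------
# Agglomeration engine (Lance-Williams with deterministic tie-break)
# ---------------------------------------------------------------------------

def _agglomerate(dist: np.ndarray, labels: Sequence[str], method: str, metric: str) -> LinkageTree:
    """Agglomerate a square distance matrix.

    ``method`` is ``"complete"`` (furthest neighbour: new distance is the
    max of the merged pair's) or ``"ward"`` (Lance-Williams on squared
    distances; ``dist`` must already be squared Euclidean, and heights are
    reported as square roots).

    Ties in the minimum inter-cluster distance resolve by the
    lexicographically smallest (min leaf label, max leaf label) of the
    candidate pair.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    d = dist.astype(float).copy()
    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    tag: dict[int, str] = {i: labels[i] for i in range(n)}  # smallest leaf label
    index: dict[int, int] = {i: i for i in range(n)}  # cluster id -> matrix row
    merges: list[Merge] = []
    next_id = n
    for _ in range(n - 1):
        best: tuple[float, str, str] | None = None
        best_pair: tuple[int, int] | None = None
        ids = sorted(active)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                dv = d[index[a], index[b]]
                t1, t2 = sorted((tag[a], tag[b]))
                key = (dv, t1, t2)
                if best is None or key < best:
                    best = key
                    best_pair = (a, b)
        assert best_pair is not None and best is not None
        a, b = best_pair
        height = np.sqrt(best[0]) if method == "ward" else best[0]
        merges.append(Merge(a, b, float(height), active[a] + active[b]))

        ia, ib = index[a], index[b]
        na, nb = active[a], active[b]
        for c in ids:
            if c in (a, b):
                continue
            ic = index[c]
            dac, dbc = d[ia, ic], d[ib, ic]
            if method == "complete":
                new = max(dac, dbc)
            else:  # ward, Lance-Williams on squared distances
                nc = active[c]
                new = (
                    (na + nc) * dac + (nb + nc) * dbc - nc * d[ia, ib]
                ) / (na + nb + nc)
            d[ia, ic] = d[ic, ia] = new
        # merged cluster reuses row ia
        new_tag = min(tag[a], tag[b])
        size = active[a] + active[b]
        del active[a], active[b], index[a], index[b], tag[a], tag[b]
        active[next_id] = size
        index[next_id] = ia
        tag[next_id] = new_tag
        next_id += 1
    return LinkageTree(tuple(labels), tuple(merges), method=method, metric=metric)


def complete_linkage_bruteforce(
    dist: np.ndarray, labels: Sequence[str]
) -> LinkageTree:
    """Oracle: complete linkage by recomputing max leaf-pair distances.

    At every step the inter-cluster distance is recomputed from scratch as
    the maximum over all leaf pairs (no Lance-Williams update); same
    tie-break as the engine. Intended for small instances in tests.
    """
    n = len(labels)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[Merge] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        best_pair = None
        ids = sorted(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                dv = max(dist[i, j] for i in clusters[a] for j in clusters[b])
                t1, t2 = sorted(
                    (
                        min(labels[i] for i in clusters[a]),
                        min(labels[i] for i in clusters[b]),
                    )
                )
                key = (dv, t1, t2)
                if best is None or key < best:
                    best, best_pair = key, (a, b)
        a, b = best_pair  # type: ignore[misc]
        merges.append(Merge(a, b, float(best[0]), len(clusters[a]) + len(clusters[b])))  # type: ignore[index]
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return LinkageTree(tuple(labels), tuple(merges), method="complete", metric="precomputed")


# ---------------------------------------------------------------------------
# Distances and public clustering entry points
# ---------------------------------------------------------------------------

def correlation_distance_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """1 - Pearson r between rows; zero-variance rows are an error."""
    values = profiles.to_numpy(dtype=float)
    sd = values.std(axis=1)
    flat = [str(profiles.index[i]) for i in np.flatnonzero(sd == 0)]
    if flat:
        raise ValueError(f"zero-variance profile(s), correlation undefined: {flat}")
    r = np.corrcoef(values)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def tissue_clustering(table: RelExpressionTable) -> LinkageTree:
    """Ward clustering of tissues on Euclidean distances over gene profiles."""
    profiles = table.profile_matrix().T  # tissue x gene
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 tissues to cluster")
    diff = profiles.to_numpy()[:, None, :] - profiles.to_numpy()[None, :, :]
    sq = (diff**2).sum(axis=2)  # squared Euclidean, as Ward requires
    return _agglomerate(sq, [str(t) for t in profiles.index], method="ward", metric="euclidean")


def gene_clustering(table: RelExpressionTable) -> LinkageTree:
    """Complete-linkage clustering of genes on correlation distance."""
    profiles = table.profile_matrix()  # gene x tissue
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    d = correlation_distance_matrix(profiles)
    return _agglomerate(
        d, [str(g) for g in profiles.index], method="complete", metric="one_minus_pearson"
    )


# ---------------------------------------------------------------------------
# Heatmap rendering
# ---------------------------------------------------------------------------

def render_heatmap(
    table: RelExpressionTable,
    tissue_tree: LinkageTree,
    gene_tree: LinkageTree,
    out: str | Path,
) -> dict[str, Path]:
    """Render the clustered log2 fold-change heatmap and its sidecars.

    Rows (genes) and columns (tissues) follow dendrogram leaf order. The
    diverging palette runs red (decreased) through white (no change, the
    calibrator column) to blue (increased), symmetric about 0. Writes the
    image, the plotted matrix as TSV, and both dendrograms as Newick.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    profiles = table.profile_matrix()
    gene_labels = set(map(str, profiles.index))
    tissue_labels = set(map(str, profiles.columns))
    bad_genes = sorted(set(gene_tree.leaves) ^ gene_labels)
    bad_tissues = sorted(set(tissue_tree.leaves) ^ tissue_labels)
    if bad_genes or bad_tissues:
        raise ValueError(
            f"tree/table label mismatch — genes: {bad_genes}, tissues: {bad_tissues}"
        )
    ordered = profiles.loc[gene_tree.leaf_order(), tissue_tree.leaf_order()]

    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    vmax = max(float(np.abs(ordered.to_numpy()).max()), 1e-9)
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * ordered.shape[1], 1.0 + 0.35 * ordered.shape[0])
    )
    mesh = ax.pcolormesh(ordered.to_numpy(), cmap="RdBu", vmin=-vmax, vmax=vmax)
    ax.set_xticks(np.arange(ordered.shape[1]) + 0.5, ordered.columns)
    ax.set_yticks(np.arange(ordered.shape[0]) + 0.5, ordered.index)
    ax.invert_yaxis()
    fig.colorbar(mesh, ax=ax, label="log2 fold change vs calibrator")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)

    matrix_path = out.with_suffix(".matrix.tsv")
    ordered.rename_axis("gene").to_csv(matrix_path, sep="\t")
    tissue_newick = out.with_suffix(".tissues.nwk")
    tissue_newick.write_text(tissue_tree.to_newick() + "\n")
    gene_newick = out.with_suffix(".genes.nwk")
    gene_newick.write_text(gene_tree.to_newick() + "\n")
    return {
        "image": out,
        "matrix": matrix_path,
        "tissue_newick": tissue_newick,
        "gene_newick": gene_newick,
    }
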