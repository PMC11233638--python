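"""Hamming-distance clustering of lobule connectivity patterns.

Each lobule's column of the binary connectivity matrix (over the cells with
at least one identified connection) is a binary fingerprint; the normalized
Hamming distance between two columns is the fraction of cells on which they
disagree.  Lobules are agglomerated with unweighted average linkage (UPGMA),
which yields an ultrametric dendrogram whose clades group lobules that tend
to innervate the same CN neurons.  Zone concordance asks whether lobules of
the same transverse zone always merge before joining any other zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .connectivity import (
    ConnectivityDataset,
    Lobule,
    TABLE_LOBULES,
    Zone,
)

#: Zone assignment of each clustered lobule used by the concordance check.
#: IX is assigned posterior and X nodular (each lobule gets one zone here,
#: by its dominant contribution in the mapping rule).
LEAF_ZONES: dict[str, Zone] = {
    Lobule.III.column: Zone.ANTERIOR,
    Lobule.IV_V.column: Zone.ANTERIOR,
    Lobule.VI_VII.column: Zone.CENTRAL,
    Lobule.VIII.column: Zone.POSTERIOR,
    Lobule.IX.column: Zone.POSTERIOR,
    Lobule.X.column: Zone.NODULAR,
}


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")


@dataclass(frozen=True)
class Clade:
    """Node of a binary merge tree.  Leaves carry a name; internal nodes a
    pair of children and the merge height (cophenetic diameter)."""

    name: str | None = None
    children: tuple["Clade", "Clade"] | None = None
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        return self.children[0].leaves() + self.children[1].leaves()


def hamming_matrix(
    dataset: ConnectivityDataset,
    labels: Iterable[Lobule] = TABLE_LOBULES,
    normalized: bool = True,
    axis: str = "lobules",
) -> DistanceMatrix:
    """Pairwise Hamming distances between connectivity fingerprints.

    Computed over the cells with >= 1 connected lobule.  ``axis='lobules'``
    compares lobule columns (the clustergram's column dendrogram);
    ``axis='cells'`` compares cell rows.  Normalized distances divide the
    mismatch count by the fingerprint length.
    """
    labels = list(labels)
    cells = dataset.connected_cells()
    if not cells:
        raise ValueError("no cells with connected lobules: empty analysis set")
    binary = np.array(
        [[int(c.connected.get(lob, False)) for lob in labels] for c in cells]
    )
    if axis == "lobules":
        mat = binary.T  # rows = lobule fingerprints over cells
        names = tuple(lob.column for lob in labels)
    elif axis == "cells":
        mat = binary
        names = tuple(c.cell_id for c in cells)
    else:
        raise ValueError(f"unknown axis: {axis!r}")
    diff = (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(float)
    if normalized:
        diff /= mat.shape[1]
    return DistanceMatrix(labels=names, values=diff)


def upgma(dm: DistanceMatrix) -> Clade:
    """Agglomerate with unweighted average linkage (UPGMA).

    At each step the closest cluster pair merges at their current distance;
    the merged cluster's distance to any other cluster is the size-weighted
    mean of its members' distances (i.e. the plain average over all leaf
    pairs).  Ties are broken by the lexicographic order of the clusters'
    representative labels (smallest leaf name), so output is deterministic.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    clusters: dict[int, Clade] = {i: Clade(name=dm.labels[i]) for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    reps: dict[int, str] = {i: dm.labels[i] for i in range(n)}
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): float(dm.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        # closest pair, lexicographic tie-break on representative labels
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted(reps[i] for i in kv[0]))),
        )
        (pair, h) = best
        i, j = sorted(pair)
        merged = Clade(children=(clusters[i], clusters[j]), height=h)
        new_sizes = sizes[i] + sizes[j]
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (sizes[i] * dik + sizes[j] * djk) / new_sizes
        del dist[pair]
        del clusters[i], clusters[j], sizes[i], sizes[j]
        clusters[next_id] = merged
        sizes[next_id] = new_sizes
        reps[next_id] = min(reps.pop(i), reps.pop(j))
        next_id += 1
    return next(iter(clusters.values()))


def to_newick(tree: Clade) -> str:
    """Serialize an ultrametric tree as Newick text.

    Under the half-height convention a leaf sits at distance height/2 from
    its parent's merge point, so each branch length is
    (parent height - child height) / 2.  '/' in leaf names becomes '_'.
    """

    def render(node: Clade, parent_height: float) -> str:
        length = (parent_height - node.height) / 2.0
        if node.is_leaf:
            return f"{node.name.replace('/', '_')}:{length:.12g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{length:.12g}"

    if tree.is_leaf:
        return f"{tree.name.replace('/', '_')};"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    return f"({inner});"


def cophenetic_heights(tree: Clade) -> dict[frozenset[str], float]:
    """Merge height for every leaf pair (the cophenetic distance)."""
    out: dict[frozenset[str], float] = {}

    def walk(node: Clade) -> list[str]:
        if node.is_leaf:
            return [node.name]  # type: ignore[list-item]
        left = walk(node.children[0])
        right = walk(node.children[1])
        for a in left:
            for b in right:
                out[frozenset((a, b))] = node.height
        return left + right

    walk(tree)
    return out


@dataclass(frozen=True)
class ConcordanceReport:
    concordant: bool
    violations: tuple[dict, ...] = field(default_factory=tuple)


def zone_concordance(tree: Clade, zone_of: Mapping[str, Zone] | None = None) -> ConcordanceReport:
    """Check that within-zone leaf pairs merge no later than cross-zone pairs.

    True iff for every pair of leaves in the same zone, their merge height
    is <= the minimal merge height between either leaf and any leaf of a
    different zone.  A single-zone leaf set is vacuously concordant.
    """
    if zone_of is None:
        zone_of = LEAF_ZONES
    leaves = tree.leaves()
    for leaf in leaves:
        if leaf not in zone_of:
            raise ValueError(f"leaf {leaf!r} has no zone assignment")
    coph = cophenetic_heights(tree)
    violations = []
    for a in leaves:
        for b in leaves:
            if a >= b or zone_of[a] != zone_of[b]:
                continue
            within_h = coph[frozenset((a, b))]
            for c in leaves:
                if zone_of[c] == zone_of[a]:
                    continue
                for anchor in (a, b):
                    cross_h = coph[frozenset((anchor, c))]
                    if within_h > cross_h:
                        violations.append(
                            {
                                "within_pair": (a, b),
                                "within_height": within_h,
                                "cross_pair": (anchor, c),
                                "cross_height": cross_h,
                            }
                        )
    return ConcordanceReport(concordant=not violations, violations=tuple(violations))


def cluster_heatmap(dataset: ConnectivityDataset, path: str, labels: Sequence[Lobule] = TABLE_LOBULES) -> None:
    """Write a clustergram-style heatmap (rows = cells, columns = lobules,
    red = connected, gray = unconnected), with both axes ordered by their
    UPGMA dendrograms."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    col_tree = upgma(hamming_matrix(dataset, labels, axis="lobules"))
    row_tree = upgma(hamming_matrix(dataset, labels, axis="cells"))
    col_order = col_tree.leaves()
    row_order = row_tree.leaves()
    cells = {c.cell_id: c for c in dataset.connected_cells()}
    col_lobs = {lob.column: lob for lob in labels}
    grid = np.array(
        [
            [int(cells[r].connected.get(col_lobs[c], False)) for c in col_order]
            for r in row_order
        ]
    )
    fig, ax = plt.subplots(figsize=(4, 8))
    ax.imshow(grid, aspect="auto", cmap=ListedColormap(["lightgray", "crimson"]), vmin=0, vmax=1)
    ax.set_xticks(range(len(col_order)), col_order, rotation=45)
    ax.set_yticks([])
    ax.set_xlabel("lobule")
    ax.set_ylabel("CN neuron")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
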