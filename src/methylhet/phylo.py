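"""Phylo-epigenetic trees: methylation distances, neighbor joining, RF.

Sample trees are inferred from methylation distance matrices by neighbor
joining and compared with externally supplied (e.g. copy-number-derived)
trees through the unrooted Robinson-Foulds distance.  Tree handling is
delegated to dendropy; this module supplies the distance metrics, input
validation and the negative-branch clean-up convention.
"""

from __future__ import annotations

import io as _io
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd
from dendropy.calculate import treecompare

_METRICS = ("euclidean", "manhattan", "1-pearson")


def methylation_distance_matrix(
    beta: pd.DataFrame, metric: str = "euclidean", min_shared: int = 10
) -> pd.DataFrame:
    """Pairwise sample distances from a features x samples beta matrix.

    Each pair uses its pairwise-complete features; a pair sharing fewer
    than ``min_shared`` features is an error.  Metrics: ``euclidean``,
    ``manhattan``, ``1-pearson`` (one minus the Pearson correlation,
    range [0, 2]).
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    cols = list(beta.columns)
    arr = beta.to_numpy(dtype=float)
    n = len(cols)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(arr[:, i]) | np.isnan(arr[:, j]))
            if ok.sum() < min_shared:
                raise ValueError(
                    f"samples {cols[i]} and {cols[j]} share only {int(ok.sum())} features"
                )
            x, y = arr[ok, i], arr[ok, j]
            if metric == "euclidean":
                d = np.sqrt(np.sum((x - y) ** 2))
            elif metric == "manhattan":
                d = np.sum(np.abs(x - y))
            else:
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    raise ValueError("constant profile; 1-pearson undefined")
                d = 1.0 - np.corrcoef(x, y)[0, 1]
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=cols, columns=cols)


def neighbor_joining(dist: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Standard Saitou-Nei NJ (Q-matrix criterion) as implemented in
    dendropy; on an additive matrix it reproduces the generating topology
    and branch lengths.  Negative estimated branch lengths (possible on
    non-additive input) are clamped to zero with the deficit transferred
    to the adjacent branches so path lengths through the node are
    approximately preserved.
    """
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    arr = dist.to_numpy(dtype=float)
    if list(dist.columns) != labels:
        raise ValueError("distance matrix rows and columns must match")
    if not np.allclose(arr, arr.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")

    buf = _io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for lab, row in zip(labels, arr):
        buf.write(lab + "," + ",".join(f"{v:.17g}" for v in row) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=buf, delimiter=",")
    tree = pdm.nj_tree()
    # the NJ tree is unrooted; merge the artificial degree-2 seed node so
    # branch lengths match the unrooted topology (three-point formula at n=3)
    if len(tree.seed_node.child_nodes()) == 2:
        tree.collapse_basal_bifurcation()

    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            deficit = edge.length
            edge.length = 0.0
            for child in edge.head_node.child_nodes():
                if child.edge.length is not None:
                    child.edge.length = max(0.0, child.edge.length + deficit)
    tree.is_rooted = False
    return tree


def tree_distance_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-to-leaf patristic (path-length) distances of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=labels, columns=labels)


def robinson_foulds(
    tree1: dendropy.Tree, tree2: dendropy.Tree
) -> tuple[int, float]:
    """Unrooted Robinson-Foulds distance and its normalized form.

    RF counts non-trivial bipartitions present in exactly one tree; for
    fully resolved trees on n leaves the maximum is 2(n - 3), which is
    used for normalization.  Trees must share their leaf label set.
    """
    leaves1 = {l.taxon.label for l in tree1.leaf_node_iter()}
    leaves2 = {l.taxon.label for l in tree2.leaf_node_iter()}
    if leaves1 != leaves2:
        raise ValueError("trees must have identical leaf sets")
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(
        data=tree1.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    t2 = dendropy.Tree.get(
        data=tree2.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    for t in (t1, t2):
        t.is_rooted = False
        t.encode_bipartitions()
    rf = int(treecompare.symmetric_difference(t1, t2))
    n = len(leaves1)
    max_rf = 2 * (n - 3)
    rf_norm = rf / max_rf if max_rf > 0 else 0.0
    return rf, min(rf_norm, 1.0)


def check_four_point(dist: pd.DataFrame, atol: float = 1e-9) -> bool:
    """Does a distance matrix satisfy the four-point (additivity) condition?

    For every leaf quartet {i,j,k,l} the two largest of the three pairings
    d(i,j)+d(k,l), d(i,k)+d(j,l), d(i,l)+d(j,k) must be equal.
    """
    from itertools import combinations

    labels = list(dist.index)
    d = dist.to_numpy(dtype=float)
    idx = {l: i for i, l in enumerate(labels)}
    for quartet in combinations(labels, 4):
        i, j, k, l = (idx[q] for q in quartet)
        sums = sorted([d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k]])
        if abs(sums[2] - sums[1]) > atol:
            return False
    return True
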