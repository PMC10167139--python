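"""Phylogeny utilities: Newick I/O, pruning and Brownian-motion covariance.

Trees are held as :class:`dendropy.Tree` objects. Tip labels are normalized
(whitespace stripped, internal spaces replaced by underscores) so that trait
tables and phylogenies from different sources can be matched symmetrically.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np

from .exceptions import SingularCovarianceError, TreeMismatchError


def normalize_label(label: str) -> str:
    """Canonical species label: stripped, spaces -> underscores."""
    return "_".join(str(label).split())


def read_newick(path_or_string) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Accepts a file path or a raw Newick string. Tip labels are normalized;
    a missing branch length on any non-root edge is an error.
    """
    text = str(path_or_string)
    if "(" in text and ";" in text:
        src = io.StringIO(text)
    else:
        src = open(text)
    with src:
        tree = dendropy.Tree.get(file=src, schema="newick", preserve_underscores=True)
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = normalize_label(leaf.taxon.label)
    _check_branch_lengths(tree)
    return tree


def _check_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise TreeMismatchError("tree has edges without branch lengths")
        if edge.length < 0:
            raise TreeMismatchError(f"negative branch length {edge.length}")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_tree(tree: dendropy.Tree, species) -> dendropy.Tree:
    """Prune a tree to exactly the requested tip set.

    Degree-2 internal nodes left by the pruning are collapsed with their
    branch lengths summed, so root-to-tip path lengths of retained tips are
    preserved. Requesting species absent from the tree is an error naming
    every absentee (no silent drop).
    """
    wanted = {normalize_label(s) for s in species}
    present = set(tip_labels(tree))
    absent = sorted(wanted - present)
    if absent:
        raise TreeMismatchError(f"species not found in tree: {absent}")
    pruned = tree.clone(depth=1)
    keep = [t for t in pruned.taxon_namespace if t.label in wanted]
    pruned.retain_taxa(keep)  # suppresses unifurcations, summing edge lengths
    pruned.purge_taxon_namespace()
    return pruned


def root_to_tip_distances(tree: dendropy.Tree) -> dict[str, float]:
    """Sum of branch lengths from the root to each tip."""
    dist: dict[str, float] = {}
    # a root (stem) edge left by pruning counts toward every tip's depth
    depth = {tree.seed_node: tree.seed_node.edge.length or 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            dist[node.taxon.label] = depth[node]
    return dist


def phylo_vcv(tree: dendropy.Tree, order: list[str] | None = None,
              jitter: float = 0.0) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion phylogenetic covariance matrix C.

    ``C[i, j]`` is the shared root-to-MRCA path length of tips i and j and
    ``C[i, i]`` the root-to-tip length. ``order`` fixes the row order
    (defaults to sorted tip labels). A non-positive-definite C (e.g. all-zero
    branch lengths) raises :class:`SingularCovarianceError`; passing a small
    ``jitter`` adds it to the diagonal as a remediation.
    """
    labels = order if order is not None else sorted(tip_labels(tree))
    present = set(tip_labels(tree))
    absent = sorted(set(labels) - present)
    if absent:
        raise TreeMismatchError(f"species not found in tree: {absent}")

    depth = root_to_tip_distances(tree)
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    C = np.zeros((n, n))
    for lab in labels:
        C[idx[lab], idx[lab]] = depth[lab]

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in idx}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = pdm.patristic_distance(taxa[a], taxa[b])
            shared = 0.5 * (depth[a] + depth[b] - d)
            C[idx[a], idx[b]] = C[idx[b], idx[a]] = shared

    if jitter:
        C = C + jitter * np.eye(n)
    eigmin = float(np.linalg.eigvalsh(C).min())
    if eigmin <= 1e-12 * max(1.0, float(np.abs(C).max())):
        raise SingularCovarianceError(
            "phylogenetic covariance is not positive definite "
            f"(min eigenvalue {eigmin:.3g}); consider the jitter option"
        )
    return C, labels
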