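"""Shared-call similarity, hierarchical clustering and marker-bootstrap
support.

Similarity between two samples is the fraction of markers at which both
were called and the calls agree; markers with a no-call on either side do
not enter the denominator.  For complete m-marker profiles the resulting
distance (1 - similarity) is quantized at 1/m per SNP difference.

Support values are ordinary Felsenstein bootstraps: markers are resampled
with replacement, the tree is rebuilt, and each internal node's support is
the percentage of replicate trees containing exactly its leaf set.  With a
couple of dozen markers only clades separated by very few differences can
reach high support — the granularity, not the clustering, is the limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform

from .errors import ParameterError, UndefinedResultError, ValidationError
from .types import GenotypeMatrix

_LINKAGES = ("average", "complete", "single")


def similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Shared-call similarity of two profiles; NaN when nothing is comparable.

    matches / comparable, where comparable counts positions called in both
    profiles.  Returns ``float("nan")`` (flagged undefined) when the two
    profiles share no called marker.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError(f"profile length mismatch: {a.size} vs {b.size}")
    both = (a >= 0) & (b >= 0)
    comparable = int(both.sum())
    if comparable == 0:
        return float("nan")
    return float(np.count_nonzero(both & (a == b))) / comparable


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise shared-call similarity with unit diagonal.

    ``values[i, j]`` is NaN for pairs with zero comparable markers; such
    pairs are listed in ``undefined_pairs`` and block clustering until the
    caller resolves them.
    """

    sample_ids: list[str]
    values: np.ndarray

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.values[i, j]):
                    out.append((self.sample_ids[i], self.sample_ids[j]))
        return out

    def distances(self) -> np.ndarray:
        """Square distance matrix 1 - similarity (NaN propagates)."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d


def similarity_matrix(matrix: GenotypeMatrix) -> SimilarityMatrix:
    """All-pairs shared-call similarity for a genotype matrix."""
    calls = matrix.calls
    n = matrix.n_samples
    called = calls >= 0
    values = np.ones((n, n))
    # row-chunked to keep the boolean intermediates modest on big panels
    chunk = max(1, 2_000_000 // max(1, n * matrix.n_markers))
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        a = calls[start:stop, None, :]
        ca = called[start:stop, None, :]
        both = ca & called[None, :, :]
        comp = both.sum(axis=2)
        match = (both & (a == calls[None, :, :])).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            values[start:stop, :] = np.where(comp > 0, match / np.maximum(comp, 1), np.nan)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(sample_ids=matrix.sample_ids, values=values)


@dataclass
class ClusterTree:
    """Agglomerative merge tree over samples.

    Wraps a SciPy linkage matrix: row k merges two nodes into internal node
    ``n + k`` at height ``linkage[k, 2]``.  ``supports`` maps internal node
    index to bootstrap percentage once attached.
    """

    linkage: np.ndarray
    sample_ids: list[str]
    method: str = "average"
    supports: dict[int, float] | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)

    def clade_leaf_sets(self) -> dict[int, frozenset[str]]:
        """Leaf-ID set under each internal node (indices n .. 2n-2)."""
        n = self.n_leaves
        sets: dict[int, frozenset[str]] = {
            i: frozenset([sid]) for i, sid in enumerate(self.sample_ids)
        }
        for k, row in enumerate(self.linkage):
            sets[n + k] = sets[int(row[0])] | sets[int(row[1])]
        return {i: s for i, s in sets.items() if i >= n}


def hierarchical_cluster(
    sim: SimilarityMatrix, linkage: str = "average"
) -> ClusterTree:
    """Agglomerative clustering of 1 - similarity distances.

    Undefined similarities must be resolved by the caller first; imputing
    them would fabricate relatedness, so they raise instead.  SciPy's
    linkage is deterministic for a fixed input ordering, which fixes the
    tie rule.
    """
    if linkage not in _LINKAGES:
        raise ParameterError(f"linkage must be one of {_LINKAGES}")
    und = sim.undefined_pairs
    if und:
        raise UndefinedResultError(
            f"undefined similarity for pairs {und[:5]}; resolve before clustering"
        )
    if len(sim.sample_ids) < 2:
        raise ParameterError("need at least two samples to cluster")
    condensed = squareform(sim.distances(), checks=False)
    Z = _hier.linkage(condensed, method=linkage)
    return ClusterTree(linkage=Z, sample_ids=list(sim.sample_ids), method=linkage)


def cut_clusters(tree: ClusterTree, height: float) -> dict[str, int]:
    """Flat cluster labels obtained by cutting the tree at a height."""
    labels = _hier.fcluster(tree.linkage, t=height, criterion="distance")
    return dict(zip(tree.sample_ids, (int(x) for x in labels)))


def bootstrap_support(
    matrix: GenotypeMatrix,
    tree: ClusterTree,
    replicates: int = 1000,
    seed: int = 0,
    linkage: str | None = None,
) -> dict[int, float]:
    """Felsenstein marker-bootstrap support for each internal node.

    Markers are resampled with replacement ``replicates`` times; each
    replicate matrix is re-clustered and a node of the reference tree is
    "recovered" when some replicate clade has exactly the same leaf set.
    Supports (percentages) are attached to ``tree.supports`` and returned.

    Pairs left with no comparable marker by a resampling draw are assigned
    the maximum distance 1.0 for that replicate (noted, not imputed, in the
    reference tree itself).
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    if matrix.n_markers < 2:
        raise ParameterError("bootstrap over a single marker is degenerate")
    if linkage is None:
        linkage = tree.method
    rng = np.random.default_rng(seed)
    ref_clades = tree.clade_leaf_sets()
    hits = {node: 0 for node in ref_clades}
    m = matrix.n_markers
    for _ in range(replicates):
        draw = rng.integers(0, m, size=m)
        calls = matrix.calls[:, draw]
        sim = _similarity_from_calls(calls, matrix.sample_ids)
        d = sim.distances()
        d[np.isnan(d)] = 1.0
        condensed = squareform(d, checks=False)
        Z = _hier.linkage(condensed, method=linkage)
        rep_tree = ClusterTree(linkage=Z, sample_ids=list(matrix.sample_ids))
        rep_clades = set(rep_tree.clade_leaf_sets().values())
        for node, leafset in ref_clades.items():
            if leafset in rep_clades:
                hits[node] += 1
    supports = {node: 100.0 * h / replicates for node, h in hits.items()}
    tree.supports = supports
    return supports


def _similarity_from_calls(calls: np.ndarray, sample_ids: Sequence[str]) -> SimilarityMatrix:
    n = calls.shape[0]
    called = calls >= 0
    both = called[:, None, :] & called[None, :, :]
    comp = both.sum(axis=2)
    match = (both & (calls[:, None, :] == calls[None, :, :])).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(comp > 0, match / np.maximum(comp, 1), np.nan)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(sample_ids=list(sample_ids), values=values)


# ---------------------------------------------------------------------------
# Newick / NEXUS export
# ---------------------------------------------------------------------------


def export_newick(tree: ClusterTree, include_support: bool = True) -> str:
    """Render the merge tree as a newick string.

    Branch lengths are differences of merge heights; bootstrap supports,
    when attached, appear as internal node labels.  Leaf names containing
    newick-special characters are quoted.
    """
    n = tree.n_leaves
    root = _hier.to_tree(tree.linkage)

    def esc(name: str) -> str:
        if any(c in name for c in "(),:;'\" \t"):
            return "'" + name.replace("'", "''") + "'"
        return name

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{esc(tree.sample_ids[node.id])}:{length:.10g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        label = ""
        if include_support and tree.supports is not None:
            # scipy's to_tree numbers internal nodes n + linkage-row already
            sup = tree.supports.get(node.id)
            if sup is not None:
                label = f"{sup:.10g}"
        return f"({left},{right}){label}:{length:.10g}"

    if root.is_leaf():
        return f"{esc(tree.sample_ids[root.id])}:0;"
    left = walk(root.left, root.dist)
    right = walk(root.right, root.dist)
    label = ""
    if include_support and tree.supports is not None:
        sup = tree.supports.get(root.id)
        if sup is not None:
            label = f"{sup:.10g}"
    return f"({left},{right}){label};"


def export_nexus(tree: ClusterTree, include_support: bool = True) -> str:
    """NEXUS wrapper around the newick tree (taxa block + trees block)."""
    taxa = "\n".join(f"\t\t{_nexus_name(s)}" for s in tree.sample_ids)
    nwk = export_newick(tree, include_support=include_support)
    return (
        "#NEXUS\n"
        "BEGIN TAXA;\n"
        f"\tDIMENSIONS NTAX={tree.n_leaves};\n"
        "\tTAXLABELS\n"
        f"{taxa}\n"
        "\t;\n"
        "END;\n"
        "BEGIN TREES;\n"
        f"\tTREE tree1 = {nwk}\n"
        "END;\n"
    )


def _nexus_name(name: str) -> str:
    if any(c in name for c in "(),:; \t"):
        return "'" + name.replace("'", "''") + "'"
    return name


__all__ = [
    "SimilarityMatrix",
    "ClusterTree",
    "similarity",
    "similarity_matrix",
    "hierarchical_cluster",
    "cut_clusters",
    "bootstrap_support",
    "export_newick",
    "export_nexus",
]
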