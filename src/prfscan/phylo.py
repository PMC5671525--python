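"""Distance-based relatedness: neighbor joining and midpoint rooting.

The relatedness ordering among polyproteins (which virus is whose closest
relative) is recovered from p-distances with neighbor joining.  This is a
deliberate lightweight stand-in for full Bayesian phylogenetics: the claims
checked downstream are sister/nearest-relative orderings, not posterior
probabilities.
"""

from __future__ import annotations

from pathlib import Path

from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

__all__ = ["neighbor_joining", "midpoint_root", "nearest_neighbor", "write_newick", "read_newick"]


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard NJ agglomeration; deterministic (labels processed in
    lexicographic order); negative branch lengths clamped to zero."""
    if len(dm.ids) < 3:
        raise ValueError(f"neighbor joining needs at least 3 taxa, got {len(dm.ids)}")
    order = sorted(dm.ids)
    dm = dm.filter(order)
    tree = _skbio_nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    With all-zero branch lengths the diameter is zero and the root lands at
    a deterministic (first-traversal) edge.
    """
    tips = list(tree.tips())
    if len(tips) == 2:
        return tree.root_at_midpoint()
    rooted = tree.root_at_midpoint()
    return rooted


def nearest_neighbor(dm: DistanceMatrix, focal: str) -> str:
    """The minimum-distance taxon to ``focal``; ties break lexicographically."""
    if focal not in dm.ids:
        raise KeyError(f"unknown label {focal!r}")
    best: tuple[float, str] | None = None
    for other in sorted(dm.ids):
        if other == focal:
            continue
        d = dm[focal, other]
        if best is None or (d, other) < best:
            best = (d, other)
    assert best is not None
    return best[1]


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
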