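"""Network construction: fiber-count gating, hemisphere split, averaging.

A white-matter connection is adopted only when its streamline count
exceeds a threshold (default: fiber number > 3), which suppresses
spurious connections from noisy deterministic tractography. Whole-brain
90-node networks are then split into two 45-node hemispheric networks
(inter-hemispheric edges discarded), with the right hemisphere reordered
so that row i is the homologue of left row i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FiberCountMatrix, NodeTable, WeightedNetwork

__all__ = ["HemispherePair", "apply_fn_threshold", "split_hemispheres", "group_average"]


@dataclass
class HemispherePair:
    """Left and right hemispheric networks of one subject.

    Right-hemisphere nodes are homologue-aligned: ``right.weights[i, j]``
    connects the mirror regions of ``left`` rows i and j.
    """

    left: WeightedNetwork
    right: WeightedNetwork
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.left.n_nodes != self.right.n_nodes:
            raise ValueError("left and right must have the same node count")

    def __iter__(self):
        yield "L", self.left
        yield "R", self.right


def apply_fn_threshold(
    fa: WeightedNetwork, fn: FiberCountMatrix, threshold: int = 3
) -> WeightedNetwork:
    """Keep edge weights only where the fiber count strictly exceeds
    ``threshold``; a count equal to the threshold removes the edge."""
    if fa.n_nodes != fn.n_nodes:
        raise ValueError(
            f"dimension mismatch: FA {fa.n_nodes} nodes vs FN {fn.n_nodes}"
        )
    w = np.where(fn.counts > threshold, fa.weights, 0.0)
    return WeightedNetwork(w, list(fa.node_ids), list(fa.hemisphere_tags))


def split_hemispheres(whole: WeightedNetwork, nodes: NodeTable) -> HemispherePair:
    """Discard inter-hemispheric edges and return the two within-
    hemisphere principal submatrices, right homologue-aligned to left."""
    if whole.n_nodes != nodes.n_regions:
        raise ValueError(
            f"network has {whole.n_nodes} nodes but table has {nodes.n_regions}"
        )
    left_idx = nodes.hemisphere_index("L")
    homol = nodes.homologue_positions()
    right_idx = homol[left_idx]  # mirror of each left node, in left order
    names = nodes.node_labels()

    def _sub(idx, tag):
        w = whole.weights[np.ix_(idx, idx)]
        return WeightedNetwork(w, [names[i] for i in idx], [tag] * len(idx))

    return HemispherePair(_sub(left_idx, "L"), _sub(right_idx, "R"))


def group_average(
    nets: list[WeightedNetwork], mode: str = "include_zeros"
) -> WeightedNetwork:
    """Elementwise mean network across subjects.

    ``include_zeros`` (default) averages absent edges as true zeros, so
    an edge present in half the cohort at FA 0.5 averages to 0.25;
    ``nonzero_only`` averages only over subjects possessing the edge.
    """
    if not nets:
        raise ValueError("cannot average an empty list of networks")
    n = nets[0].n_nodes
    for net in nets:
        if net.n_nodes != n:
            raise ValueError("all networks must share the node set")
    stack = np.stack([net.weights for net in nets])
    if mode == "include_zeros":
        avg = stack.mean(axis=0)
    elif mode == "nonzero_only":
        present = (stack > 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            avg = np.where(present > 0, stack.sum(axis=0) / np.maximum(present, 1), 0.0)
    else:
        raise ValueError(f"unknown average mode: {mode!r}")
    return WeightedNetwork(avg, list(nets[0].node_ids), list(nets[0].hemisphere_tags))
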