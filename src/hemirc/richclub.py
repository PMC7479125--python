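"""Weighted rich-club analysis of hemispheric connectomes.

The weighted rich-club coefficient at degree level k,

    phi_w(k) = W_{>k} / sum of the E_{>k} strongest weights in the network,

takes the total weight W among the subgraph of nodes with degree > k and
divides it by the maximum that many (E_{>k}) edges could weigh anywhere
in the network, so phi_w(k) is a ratio in [0, 1]. Because dense, heavy
connectivity among high-degree nodes also arises from the degree
sequence alone, phi is normalized by its mean over an ensemble of
degree-preserving Maslov–Sneppen rewired surrogates; phi_norm(k) > 1
over a range of k indicates rich-club organization.

Hubs are the top fraction (default 16%, i.e. 7 of 45) of nodes by
degree; edges are then rich-club (hub-hub), feeder (hub-peripheral) or
local (peripheral-peripheral), and per-class connectivity density and
strength summarize each compartment.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .io import WeightedNetwork

__all__ = [
    "RichClubCurve",
    "HubPartition",
    "EdgeClassification",
    "EDGE_CLASSES",
    "nodal_degree",
    "nodal_strength",
    "weighted_rich_club",
    "maslov_rewire",
    "normalized_rich_club",
    "select_hubs",
    "classify_edges",
    "class_density",
    "class_strength",
    "derive_seed",
]

EDGE_CLASSES = ("rich_club", "feeder", "local")


def derive_seed(master: int, *tokens) -> int:
    """Stable per-task seed below 2**31 from a master seed and labels."""
    key = "|".join(str(t) for t in tokens)
    return (int(master) ^ zlib.crc32(key.encode())) % (2**31 - 1)


@dataclass
class RichClubCurve:
    """phi_w(k) and, when normalized, the null mean and phi_norm.

    Undefined levels (subgraph with < 2 nodes or no edges) are masked,
    never imputed as zero.
    """

    k_values: np.ndarray
    phi: np.ndarray
    defined_mask: np.ndarray
    phi_null_mean: np.ndarray | None = None
    phi_null_std: np.ndarray | None = None
    phi_norm: np.ndarray | None = None
    n_null: int = 0

    def defined_k(self) -> np.ndarray:
        return self.k_values[self.defined_mask]


@dataclass
class HubPartition:
    """Hub / peripheral split of a node set."""

    hub_ids: list[str]
    peripheral_ids: list[str]
    hub_index: np.ndarray
    peripheral_index: np.ndarray
    fraction: float = 0.16

    def __post_init__(self) -> None:
        if set(self.hub_ids) & set(self.peripheral_ids):
            raise ValueError("hub and peripheral sets must be disjoint")

    @property
    def n_nodes(self) -> int:
        return len(self.hub_ids) + len(self.peripheral_ids)

    def is_hub_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[self.hub_index] = True
        return mask


@dataclass
class EdgeClassification:
    """Per-edge rich-club / feeder / local labels for existing edges."""

    i_idx: np.ndarray
    j_idx: np.ndarray
    labels: np.ndarray  # strings from EDGE_CLASSES
    n_nodes: int

    @property
    def n_edges(self) -> int:
        return len(self.labels)

    def mask(self, class_label: str) -> np.ndarray:
        if class_label not in EDGE_CLASSES:
            raise ValueError(f"unknown edge class: {class_label!r}")
        return self.labels == class_label

    def counts(self) -> dict:
        return {c: int(np.sum(self.labels == c)) for c in EDGE_CLASSES}


def nodal_degree(net: WeightedNetwork) -> np.ndarray:
    """Number of edges attached to each node (weights ignored)."""
    return np.count_nonzero(net.weights > 0, axis=1)


def nodal_strength(net: WeightedNetwork) -> np.ndarray:
    """Sum of edge weights attached to each node."""
    return net.weights.sum(axis=1)


def _edge_arrays(net: WeightedNetwork):
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    present = net.weights[iu, ju] > 0
    return iu[present], ju[present], net.weights[iu, ju][present]


def weighted_rich_club(net: WeightedNetwork, degree_cut: str = "greater") -> RichClubCurve:
    """phi_w(k) for k = 0 .. max degree - 1.

    ``degree_cut`` selects club membership: ``"greater"`` (default, the
    van den Heuvel-Sporns convention: degree > k) or ``"greater_equal"``
    (degree >= k). Levels where the club has fewer than 2 nodes or no
    edges are masked as undefined.
    """
    if degree_cut not in ("greater", "greater_equal"):
        raise ValueError(f"unknown degree_cut: {degree_cut!r}")
    deg = nodal_degree(net)
    i_idx, j_idx, w = _edge_arrays(net)
    dmax = int(deg.max()) if deg.size else 0
    k_values = np.arange(max(dmax, 1))
    n_k = len(k_values)
    phi = np.full(n_k, np.nan)
    defined = np.zeros(n_k, dtype=bool)
    if w.size == 0:
        return RichClubCurve(k_values, phi, defined)
    # an edge survives level k iff both endpoint degrees exceed k, i.e.
    # iff min(deg_i, deg_j) > k -- so per-k totals reduce to bincounts
    edge_level = np.minimum(deg[i_idx], deg[j_idx])  # edge alive for k < level
    cnt = np.bincount(edge_level, minlength=n_k + 2)
    wsum = np.bincount(edge_level, weights=w, minlength=n_k + 2)
    # suffix sums: E_{>k} = sum over levels > k (shift index for >=k)
    e_gt = np.cumsum(cnt[::-1])[::-1]
    w_gt = np.cumsum(wsum[::-1])[::-1]
    n_gt = np.cumsum(np.bincount(deg, minlength=n_k + 2)[::-1])[::-1]  # #deg >= i
    off = 1 if degree_cut == "greater" else 0
    w_sorted = np.sort(w)[::-1]
    cum_top = np.concatenate([[0.0], np.cumsum(w_sorted)])
    for k in k_values:
        e_k = int(e_gt[k + off])
        s_k = int(n_gt[k + off])
        if s_k < 2 or e_k == 0:
            continue
        phi[k] = w_gt[k + off] / cum_top[e_k]
        defined[k] = True
    return RichClubCurve(k_values, phi, defined)


def maslov_rewire(
    net: WeightedNetwork,
    n_swap_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
) -> WeightedNetwork:
    """Degree-preserving double-edge-swap surrogate network.

    Repeatedly picks two edges (a,b), (c,d) and rewires them to (a,d),
    (c,b) when that creates neither self-loops nor multi-edges. Each
    edge keeps its weight through the swap, so both the degree sequence
    and the multiset of edge weights (hence total strength) are
    preserved exactly. ``n_swap_per_edge * n_edges`` successful swaps
    are attempted, with a capped number of tries so that swap-free
    graphs (e.g. stars) terminate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    i_idx, j_idx, w = _edge_arrays(net)
    m = len(w)
    n = net.n_nodes
    if m < 2:
        warnings.warn("fewer than 2 edges; returning an unrewired copy", stacklevel=2)
        return net.copy()
    if n_swap_per_edge == 0:
        return net.copy()
    adj = net.weights > 0
    u = i_idx.copy()
    v = j_idx.copy()
    w = w.copy()
    target = n_swap_per_edge * m
    max_tries = 50 * target
    done = tries = 0
    chunk = 1024
    while done < target and tries < max_tries:
        e1 = rng.integers(0, m, size=chunk)
        e2 = rng.integers(0, m, size=chunk)
        flip = rng.random(size=chunk) < 0.5
        for t in range(chunk):
            if done >= target or tries >= max_tries:
                break
            tries += 1
            a, b = u[e1[t]], v[e1[t]]
            c, d = (u[e2[t]], v[e2[t]]) if not flip[t] else (v[e2[t]], u[e2[t]])
            # propose (a,d) and (c,b)
            if a == d or c == b or a == c or b == d:
                continue
            if adj[a, d] or adj[c, b]:
                continue
            adj[a, b] = adj[b, a] = False
            adj[c, d] = adj[d, c] = False
            adj[a, d] = adj[d, a] = True
            adj[c, b] = adj[b, c] = True
            u[e1[t]], v[e1[t]] = a, d
            u[e2[t]], v[e2[t]] = c, b
            done += 1
    if done < target:
        warnings.warn(
            f"reached swap attempt cap with {done}/{target} swaps done", stacklevel=2
        )
    out = np.zeros((n, n))
    out[u, v] = w
    out[v, u] = w
    return WeightedNetwork(out, list(net.node_ids), list(net.hemisphere_tags))


def normalized_rich_club(
    net: WeightedNetwork,
    n_null: int = 1000,
    seed: int | np.random.Generator = 0,
    n_swap_per_edge: int = 10,
    degree_cut: str = "greater",
) -> RichClubCurve:
    """phi_norm(k) = phi(k) / mean phi over rewired surrogates.

    Degree-preserving rewiring keeps the node set S_k at every level, so
    every surrogate curve lives on the same k grid; levels where any
    surrogate phi is undefined are masked in the normalized curve.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    curve = weighted_rich_club(net, degree_cut=degree_cut)
    null_phi = np.full((n_null, len(curve.k_values)), np.nan)
    null_defined = np.ones(len(curve.k_values), dtype=bool)
    for r in range(n_null):
        surrogate = maslov_rewire(net, n_swap_per_edge=n_swap_per_edge, seed=rng)
        c = weighted_rich_club(surrogate, degree_cut=degree_cut)
        null_phi[r, : len(c.phi)] = c.phi
        null_defined &= np.pad(
            c.defined_mask, (0, len(curve.k_values) - len(c.defined_mask))
        )
    defined = curve.defined_mask & null_defined
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        null_mean = np.where(defined, np.nanmean(null_phi, axis=0), np.nan)
        null_std = np.where(defined, np.nanstd(null_phi, axis=0, ddof=1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_norm = np.where(defined, curve.phi / null_mean, np.nan)
    return RichClubCurve(
        curve.k_values, curve.phi, defined, null_mean, null_std, phi_norm, n_null
    )


def select_hubs(avg_net: WeightedNetwork, fraction: float = 0.16) -> HubPartition:
    """Top floor(fraction * n) nodes by degree (16% of 45 -> 7 hubs).

    Ties at the cut are broken by higher nodal strength, then by node
    order — deterministic and documented.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = avg_net.n_nodes
    n_hubs = int(np.floor(fraction * n))
    deg = nodal_degree(avg_net)
    stren = nodal_strength(avg_net)
    order = np.lexsort((np.arange(n), -stren, -deg))
    hub_idx = np.sort(order[:n_hubs])
    periph_idx = np.sort(order[n_hubs:])
    ids = np.asarray(avg_net.node_ids, dtype=object)
    return HubPartition(
        hub_ids=list(ids[hub_idx]),
        peripheral_ids=list(ids[periph_idx]),
        hub_index=hub_idx,
        peripheral_index=periph_idx,
        fraction=fraction,
    )


def classify_edges(net: WeightedNetwork, hubs: HubPartition) -> EdgeClassification:
    """Label every existing edge rich-club, feeder or local."""
    if hubs.n_nodes != net.n_nodes:
        raise ValueError(
            f"partition covers {hubs.n_nodes} nodes but network has {net.n_nodes}"
        )
    i_idx, j_idx, _ = _edge_arrays(net)
    is_hub = hubs.is_hub_mask()
    n_hub_ends = is_hub[i_idx].astype(int) + is_hub[j_idx].astype(int)
    labels = np.empty(len(i_idx), dtype=object)
    labels[n_hub_ends == 2] = "rich_club"
    labels[n_hub_ends == 1] = "feeder"
    labels[n_hub_ends == 0] = "local"
    return EdgeClassification(i_idx, j_idx, labels.astype("U9"), net.n_nodes)


def class_density(
    net: WeightedNetwork, cls: EdgeClassification, class_label: str
) -> float:
    """Edges of a class over ALL possible edges of the hemispheric
    network, n(n-1)/2 — the three class densities sum to the overall
    network density."""
    n = net.n_nodes
    possible = n * (n - 1) / 2
    return float(np.sum(cls.mask(class_label)) / possible) if possible else 0.0


def class_strength(
    net: WeightedNetwork, cls: EdgeClassification, class_label: str
) -> float:
    """Total FA weight over the edges of a class (each undirected edge
    counted once)."""
    m = cls.mask(class_label)
    return float(np.sum(net.weights[cls.i_idx[m], cls.j_idx[m]]))
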