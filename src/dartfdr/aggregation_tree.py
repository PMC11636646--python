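"""Stage I of DART: build a constrained aggregation tree from a distance matrix.

The aggregation tree has ``L`` layers.  The bottom layer holds one singleton
node per hypothesis; each higher layer ``l`` is formed by greedily merging the
closest node pairs of layer ``l - 1`` subject to two constraints:

* the diameter (maximum pairwise distance among member hypotheses) of every
  node on layer ``l`` stays at or below a layer threshold ``g(l)``, and
* every node aggregates at most ``M`` children.

The tree defines the testing structure consumed by
:mod:`dartfdr.recursive_testing`: nodes group hypotheses that are close in the
supplied metric and therefore likely share null/alternative status.
"""

from __future__ import annotations

import heapq
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "TreeConfig",
    "TreeNode",
    "AggregationTree",
    "build_layer",
    "build_tree",
    "construct_tree",
    "default_num_layers",
    "default_grid",
    "select_layer_thresholds",
    "TreeConstructionError",
]


class TreeConstructionError(ValueError):
    """Raised for malformed distance input or infeasible tree configuration."""


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------


class DistanceMatrix:
    """Symmetric nonnegative pairwise distance matrix with hypothesis ids.

    Parameters
    ----------
    ids
        Ordered hypothesis identifiers (coerced to ``str``).
    values
        Square ``(m, m)`` array of pairwise distances.  Must be symmetric
        (to numerical tolerance), have a zero diagonal, and contain only
        finite nonnegative entries.
    """

    __slots__ = ("ids", "values")

    def __init__(self, ids: Sequence, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        ids = tuple(str(i) for i in ids)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise TreeConstructionError(
                f"distance matrix must be square, got shape {values.shape}"
            )
        m = values.shape[0]
        if m < 2:
            raise TreeConstructionError("need at least 2 hypotheses")
        if len(ids) != m:
            raise TreeConstructionError(
                f"{len(ids)} ids supplied for a {m}x{m} distance matrix"
            )
        if len(set(ids)) != m:
            raise TreeConstructionError("hypothesis ids must be unique")
        if not np.all(np.isfinite(values)):
            raise TreeConstructionError("distance matrix contains non-finite entries")
        if np.any(values < 0):
            raise TreeConstructionError("distances must be nonnegative")
        if not np.allclose(values, values.T, rtol=1e-8, atol=1e-10):
            raise TreeConstructionError("distance matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-10):
            raise TreeConstructionError("distance matrix diagonal must be zero")
        values = (values + values.T) / 2.0  # enforce exact symmetry
        np.fill_diagonal(values, 0.0)
        self.ids = ids
        self.values = values

    @property
    def m(self) -> int:
        return self.values.shape[0]

    def offdiagonal(self) -> np.ndarray:
        """Upper-triangular off-diagonal distances as a flat array."""
        iu, ju = np.triu_indices(self.m, 1)
        return self.values[iu, ju]

    @classmethod
    def from_coordinates(cls, ids: Sequence, coords: np.ndarray) -> "DistanceMatrix":
        """Euclidean distance matrix from an ``(m, k)`` coordinate array."""
        from scipy.spatial.distance import pdist, squareform

        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 1:
            coords = coords[:, None]
        return cls(ids, squareform(pdist(coords)))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DistanceMatrix(m={self.m})"


# ---------------------------------------------------------------------------
# Configuration and node containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeConfig:
    """Tuning parameters of tree construction.

    Attributes
    ----------
    max_node_size
        ``M``, the maximum number of children per node.  2 or 3 recommended;
        larger values are accepted with a warning because they weaken the
        procedure's stability (rejecting one large node rejects many
        hypotheses at once).
    min_top_nodes
        ``c_m``, the desired minimum number of nodes on the top layer.  Values
        below 35 trigger a warning: with too few top-layer nodes the
        asymptotic error control of the testing stage becomes unreliable.
    num_layers
        ``L``.  ``None`` derives the default ``max(1, floor(log_M(m / c_m)))``.
    grid
        Candidate distance thresholds ``G`` for layer-threshold selection.
        ``None`` uses the deciles of the off-diagonal distance distribution.
    """

    max_node_size: int = 2
    min_top_nodes: int = 35
    num_layers: int | None = None
    grid: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.max_node_size < 2:
            raise TreeConstructionError("max_node_size must be >= 2")
        if self.max_node_size > 3:
            warnings.warn(
                "max_node_size > 3 is allowed but not recommended: large nodes "
                "make rejections coarse and unstable",
                UserWarning,
                stacklevel=2,
            )
        if self.min_top_nodes < 1:
            raise TreeConstructionError("min_top_nodes must be >= 1")
        if self.min_top_nodes < 35:
            warnings.warn(
                "min_top_nodes < 35: error control on the top layer may be "
                "unreliable",
                UserWarning,
                stacklevel=2,
            )
        if self.num_layers is not None and self.num_layers < 1:
            raise TreeConstructionError("num_layers must be >= 1")
        if self.grid is not None:
            g = tuple(float(x) for x in self.grid)
            if len(g) == 0:
                raise TreeConstructionError("threshold grid must be nonempty")
            if any(x <= 0 for x in g):
                raise TreeConstructionError("grid thresholds must be positive")
            object.__setattr__(self, "grid", tuple(sorted(set(g))))


@dataclass(frozen=True)
class TreeNode:
    """One node of the aggregation tree.

    ``members`` are 0-based hypothesis positions (sorted); ``children`` are
    node ids on the layer below (empty on layer 1).  ``diameter`` is the
    maximum pairwise distance among members (0 for singletons).
    """

    node_id: str
    layer: int
    members: tuple[int, ...]
    children: tuple[str, ...]
    diameter: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class AggregationTree:
    """An ``L``-layer aggregation tree over ``m`` hypotheses.

    ``layers[0]`` is the bottom (singleton) layer; ``thresholds[0]`` is 0 by
    convention since nothing is aggregated on layer 1.
    """

    ids: tuple[str, ...]
    layers: tuple[tuple[TreeNode, ...], ...]
    thresholds: tuple[float, ...]
    config: TreeConfig

    @property
    def m(self) -> int:
        return len(self.ids)

    @property
    def num_layers(self) -> int:
        return len(self.layers)

    def nodes_at(self, layer: int) -> tuple[TreeNode, ...]:
        """Nodes on 1-based layer ``layer``."""
        return self.layers[layer - 1]

    def node_lookup(self) -> dict[str, TreeNode]:
        return {n.node_id: n for layer in self.layers for n in layer}

    # -- validation ---------------------------------------------------------

    def validate(self, distance: DistanceMatrix | None = None) -> None:
        """Check all structural invariants; raise ``TreeConstructionError``.

        With ``distance`` given, node diameters and layer thresholds are also
        verified against the matrix.
        """
        m = self.m
        if len(self.thresholds) != self.num_layers:
            raise TreeConstructionError("one threshold required per layer")
        if self.thresholds[0] != 0.0:
            raise TreeConstructionError("g(1) must be 0")
        if any(
            b < a for a, b in zip(self.thresholds[1:], self.thresholds[2:])
        ) or any(t <= 0 for t in self.thresholds[1:]):
            raise TreeConstructionError(
                "layer thresholds must be positive and non-decreasing"
            )
        bottom = self.layers[0]
        if sorted(n.members[0] for n in bottom) != list(range(m)) or any(
            n.size != 1 or n.children for n in bottom
        ):
            raise TreeConstructionError("layer 1 must be the singleton partition")
        prev_count = None
        lookup = self.node_lookup()
        for li, layer in enumerate(self.layers, start=1):
            seen: list[int] = []
            for node in layer:
                if node.layer != li:
                    raise TreeConstructionError("node layer index mismatch")
                seen.extend(node.members)
                if li >= 2:
                    if not 1 <= len(node.children) <= self.config.max_node_size:
                        raise TreeConstructionError(
                            f"node {node.node_id} has {len(node.children)} children"
                        )
                    child_members: list[int] = []
                    for cid in node.children:
                        child = lookup[cid]
                        if child.layer != li - 1:
                            raise TreeConstructionError("child on wrong layer")
                        child_members.extend(child.members)
                    if sorted(child_members) != list(node.members):
                        raise TreeConstructionError(
                            f"node {node.node_id} members != union of children"
                        )
                if distance is not None:
                    sub = distance.values[np.ix_(node.members, node.members)]
                    dia = float(sub.max()) if node.size > 1 else 0.0
                    if not math.isclose(dia, node.diameter, rel_tol=1e-9, abs_tol=1e-12):
                        raise TreeConstructionError(
                            f"node {node.node_id} stored diameter is wrong"
                        )
                    if dia > self.thresholds[li - 1] * (1 + 1e-12):
                        raise TreeConstructionError(
                            f"node {node.node_id} diameter exceeds g({li})"
                        )
            if sorted(seen) != list(range(m)):
                raise TreeConstructionError(f"layer {li} is not a partition of [m]")
            if prev_count is not None and len(layer) > prev_count:
                raise TreeConstructionError("layer sizes must be non-increasing")
            prev_count = len(layer)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-ready representation (stable key order)."""
        return {
            "ids": list(self.ids),
            "thresholds": [float(t) for t in self.thresholds],
            "config": {
                "max_node_size": self.config.max_node_size,
                "min_top_nodes": self.config.min_top_nodes,
                "num_layers": self.num_layers,
                "grid": list(self.config.grid) if self.config.grid else None,
            },
            "layers": [
                [
                    {
                        "node_id": n.node_id,
                        "layer": n.layer,
                        "members": [self.ids[i] for i in n.members],
                        "children": list(n.children),
                        "diameter": float(n.diameter),
                    }
                    for n in layer
                ]
                for layer in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "AggregationTree":
        ids = tuple(str(i) for i in payload["ids"])
        pos = {h: i for i, h in enumerate(ids)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            cfg = payload.get("config", {})
            config = TreeConfig(
                max_node_size=cfg.get("max_node_size", 2),
                min_top_nodes=cfg.get("min_top_nodes", 35),
                num_layers=cfg.get("num_layers"),
                grid=tuple(cfg["grid"]) if cfg.get("grid") else None,
            )
        layers = []
        for layer in payload["layers"]:
            layers.append(
                tuple(
                    TreeNode(
                        node_id=str(n["node_id"]),
                        layer=int(n["layer"]),
                        members=tuple(sorted(pos[str(h)] for h in n["members"])),
                        children=tuple(str(c) for c in n["children"]),
                        diameter=float(n["diameter"]),
                    )
                    for n in layer
                )
            )
        tree = cls(
            ids=ids,
            layers=tuple(layers),
            thresholds=tuple(float(t) for t in payload["thresholds"]),
            config=config,
        )
        tree.validate()
        return tree


# ---------------------------------------------------------------------------
# Greedy constrained aggregation
# ---------------------------------------------------------------------------


def _node_linkage(D: np.ndarray, nodes: Sequence[TreeNode]) -> np.ndarray:
    """Complete-linkage matrix between nodes; diagonal holds node diameters."""
    n = len(nodes)
    m = D.shape[0]
    if all(len(nd.members) == 1 for nd in nodes):
        idx = np.fromiter((nd.members[0] for nd in nodes), dtype=np.intp, count=n)
        return D[np.ix_(idx, idx)]
    lab = np.empty(m, dtype=np.intp)
    for k, nd in enumerate(nodes):
        lab[list(nd.members)] = k
    order = np.argsort(lab, kind="stable")
    counts = np.bincount(lab, minlength=n)
    starts = np.zeros(n, dtype=np.intp)
    np.cumsum(counts[:-1], out=starts[1:])
    rows = np.maximum.reduceat(D[order], starts, axis=0)
    return np.maximum.reduceat(rows[:, order], starts, axis=1)


def _sorted_feasible_edges(
    link: np.ndarray, minu: np.ndarray, maxu: np.ndarray, gmax: float
):
    """All node pairs with merged diameter <= gmax, sorted by the greedy key.

    The greedy key is (merged diameter, min member of the union, max member of
    the union, node indices); the member components give a deterministic
    tie-break among equidistant feasible pairs.
    """
    n = link.shape[0]
    dia = np.diag(link)
    iu, ju = np.triu_indices(n, 1)
    dd = np.maximum(link[iu, ju], np.maximum(dia[iu], dia[ju]))
    keep = dd <= gmax
    iu, ju, dd = iu[keep], ju[keep], dd[keep]
    emin = np.minimum(minu[iu], minu[ju])
    emax = np.maximum(maxu[iu], maxu[ju])
    order = np.lexsort((ju, iu, emax, emin, dd))
    return dd[order], emin[order], emax[order], iu[order], ju[order]


def _greedy_groups(
    link: np.ndarray,
    minu: np.ndarray,
    maxu: np.ndarray,
    g: float,
    M: int,
    edges=None,
) -> list[tuple[list[int], float]]:
    """Greedily merge nodes under diameter bound ``g`` and child bound ``M``.

    ``link`` is the complete-linkage matrix between current-layer nodes with
    node diameters on the diagonal.  Repeatedly merges the feasible pair with
    the smallest merged diameter; a group formed on this layer keeps absorbing
    further groups while its child count stays below ``M``.  Returns
    ``(child_indices, diameter)`` per resulting group, sorted by smallest
    member for deterministic node numbering.
    """
    n = link.shape[0]
    if edges is None:
        edges = _sorted_feasible_edges(link, minu, maxu, g)
    dd_s, emin_s, emax_s, ei_s, ej_s = edges
    n_edges = len(dd_s)

    cap = 2 * n
    alive = np.zeros(cap, dtype=bool)
    alive[:n] = True
    cc = np.ones(cap, dtype=np.intp)
    dia = np.zeros(cap)
    dia[:n] = np.diag(link)
    gmin = np.empty(cap, dtype=np.intp)
    gmax_arr = np.empty(cap, dtype=np.intp)
    gmin[:n] = minu
    gmax_arr[:n] = maxu
    children: dict[int, list[int]] = {i: [i] for i in range(n)}

    # full merged-diameter matrix between groups, kept only when M > 2 (a
    # merged pair is already saturated when M == 2, so no new pairs arise)
    BD = None
    if M > 2:
        BD = np.full((cap, cap), np.inf)
        BD[:n, :n] = np.maximum(link, np.maximum(dia[:n, None], dia[None, :n]))

    heap: list[tuple] = []
    ptr = 0
    next_id = n
    n_mergeable = n  # groups with child count < M

    while n_mergeable >= 2:
        # next candidate from the pre-sorted initial edges
        while ptr < n_edges:
            if dd_s[ptr] > g:
                ptr = n_edges
                break
            if alive[ei_s[ptr]] and alive[ej_s[ptr]]:
                break
            ptr += 1
        cand_init = None
        if ptr < n_edges:
            cand_init = (
                dd_s[ptr],
                emin_s[ptr],
                emax_s[ptr],
                int(ei_s[ptr]),
                int(ej_s[ptr]),
            )
        # next candidate among pairs created by earlier merges
        while heap and not (alive[heap[0][3]] and alive[heap[0][4]]):
            heapq.heappop(heap)
        cand_new = heap[0] if heap else None

        if cand_init is None and cand_new is None:
            break
        if cand_new is None or (cand_init is not None and cand_init[:3] <= cand_new[:3]):
            d, _, _, a, b = cand_init
            ptr += 1
        else:
            d, _, _, a, b = heapq.heappop(heap)

        nid = next_id
        next_id += 1
        alive[a] = alive[b] = False
        alive[nid] = True
        cc[nid] = cc[a] + cc[b]
        dia[nid] = d
        gmin[nid] = min(gmin[a], gmin[b])
        gmax_arr[nid] = max(gmax_arr[a], gmax_arr[b])
        children[nid] = children.pop(a) + children.pop(b)
        n_mergeable -= 2
        if cc[nid] < M:
            n_mergeable += 1
        if BD is not None:
            new_row = np.maximum(
                np.maximum(BD[a, :next_id], BD[b, :next_id]), dia[nid]
            )
            new_row[nid] = 0.0
            BD[nid, :next_id] = new_row
            BD[:next_id, nid] = new_row
            if cc[nid] < M:
                for c in np.flatnonzero(alive[:nid]):
                    if cc[nid] + cc[c] > M:
                        continue
                    dc = float(BD[nid, c])
                    if dc <= g:
                        heapq.heappush(
                            heap,
                            (
                                dc,
                                int(min(gmin[nid], gmin[c])),
                                int(max(gmax_arr[nid], gmax_arr[c])),
                                nid,
                                int(c),
                            ),
                        )

    groups = [
        (children[i], float(dia[i]))
        for i in range(next_id)
        if alive[i]
    ]
    groups.sort(key=lambda gr: min(gr[0]))
    return groups


def build_layer(
    prev_nodes: Sequence[TreeNode],
    distance: DistanceMatrix,
    g: float,
    M: int,
) -> tuple[TreeNode, ...]:
    """Aggregate one layer into the next under ``dia <= g`` and ``|C| <= M``.

    Every node of ``prev_nodes`` becomes the child of exactly one returned
    node; nodes that cannot merge are carried up as single-child nodes.
    """
    if g < 0:
        raise TreeConstructionError("distance threshold g must be >= 0")
    if M < 2:
        raise TreeConstructionError("max node size M must be >= 2")
    all_members = sorted(i for nd in prev_nodes for i in nd.members)
    if all_members != list(range(distance.m)):
        raise TreeConstructionError(
            "previous-layer nodes do not partition the hypothesis set of the "
            "distance matrix"
        )
    layer = prev_nodes[0].layer + 1
    link = _node_linkage(distance.values, prev_nodes)
    minu = np.fromiter((nd.members[0] for nd in prev_nodes), dtype=np.intp)
    maxu = np.fromiter((nd.members[-1] for nd in prev_nodes), dtype=np.intp)
    groups = _greedy_groups(link, minu, maxu, g, M)
    nodes = []
    for k, (child_idx, dia) in enumerate(groups):
        kids = sorted(child_idx, key=lambda i: prev_nodes[i].members[0])
        members = tuple(sorted(i for ci in kids for i in prev_nodes[ci].members))
        nodes.append(
            TreeNode(
                node_id=f"L{layer}N{k}",
                layer=layer,
                members=members,
                children=tuple(prev_nodes[ci].node_id for ci in kids),
                diameter=dia if len(members) > 1 else 0.0,
            )
        )
    return tuple(nodes)


def _singleton_layer(m: int) -> tuple[TreeNode, ...]:
    return tuple(
        TreeNode(node_id=f"L1N{i}", layer=1, members=(i,), children=(), diameter=0.0)
        for i in range(m)
    )


def build_tree(
    distance: DistanceMatrix,
    config: TreeConfig,
    thresholds: Sequence[float],
) -> AggregationTree:
    """Build the full aggregation tree given thresholds ``g(2..L)``.

    ``thresholds`` must be positive and non-decreasing; the number of layers
    is ``len(thresholds) + 1``.
    """
    thresholds = [float(t) for t in thresholds]
    if any(t <= 0 for t in thresholds):
        raise TreeConstructionError("thresholds g(2..L) must be positive")
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise TreeConstructionError("thresholds g(2..L) must be non-decreasing")
    layers = [_singleton_layer(distance.m)]
    for g in thresholds:
        layers.append(build_layer(layers[-1], distance, g, config.max_node_size))
    tree = AggregationTree(
        ids=distance.ids,
        layers=tuple(layers),
        thresholds=(0.0, *thresholds),
        config=config,
    )
    return tree


def default_num_layers(m: int, M: int, c_m: int) -> int:
    """Default layer count ``max(1, floor(log_M(m) - log_M(c_m)))``.

    The floor keeps at least ``c_m * M`` hypotheses' worth of nodes above the
    top layer so the top layer is not too coarse; the result is clamped to 1
    (a single-layer tree reduces DART to the bottom-layer step-up test).
    """
    if m < 2 or M < 2 or c_m < 1:
        raise TreeConstructionError("need m >= 2, M >= 2, c_m >= 1")
    L = 0
    while c_m * M ** (L + 1) <= m:
        L += 1
    return max(1, L)


def default_grid(distance: DistanceMatrix) -> tuple[float, ...]:
    """Default threshold grid: deciles of the nearest-neighbour distance.

    Each greedy aggregation step merges a node with (roughly) its nearest
    partner, so the scale on which diameter caps meaningfully bite is the
    nearest-neighbour distance distribution — not the full pairwise
    distribution, whose bulk quantiles sit orders of magnitude above any
    plausible co-status neighbourhood and would licence trees whose nodes
    mix unrelated hypotheses.  The grid is the 10%..90% deciles of each
    hypothesis's distance to its nearest neighbour, deduplicated.
    """
    nn = np.partition(distance.values + np.diag(np.full(distance.m, np.inf)), 0, axis=1)[:, 0]
    qs = np.percentile(nn, np.arange(10, 100, 10))
    vals = sorted({float(q) for q in qs if q > 0})
    if not vals:
        raise TreeConstructionError(
            "all nearest-neighbour distances are zero; no usable threshold grid"
        )
    return tuple(vals)


def select_layer_thresholds(
    distance: DistanceMatrix, config: TreeConfig
) -> tuple[float, ...]:
    """Recursively pick ``g(2..L)`` from the grid, maximizing candidate nodes.

    For each layer the grid is restricted to values at or above the previous
    layer's threshold; each value is scored by the number of nodes it would
    create with at least two children (the nodes the testing stage could
    actually test), and the best-scoring value wins with ties broken toward
    the smaller threshold.  If no grid value yields any merge the tree is
    truncated at the current depth with a warning.
    """
    m = distance.m
    M = config.max_node_size
    L = config.num_layers or default_num_layers(m, M, config.min_top_nodes)
    G = config.grid or default_grid(distance)
    prev = _singleton_layer(m)
    thresholds: list[float] = []
    g_prev = 0.0
    for ell in range(2, L + 1):
        G_ell = [g for g in G if g >= g_prev]
        if not G_ell:
            warnings.warn(
                f"threshold grid exhausted before layer {ell}; tree truncated "
                f"at {ell - 1} layers",
                UserWarning,
                stacklevel=2,
            )
            break
        link = _node_linkage(distance.values, prev)
        minu = np.fromiter((nd.members[0] for nd in prev), dtype=np.intp)
        maxu = np.fromiter((nd.members[-1] for nd in prev), dtype=np.intp)
        edges = _sorted_feasible_edges(link, minu, maxu, max(G_ell))
        best_g = None
        best_count = -1
        for g in G_ell:
            groups = _greedy_groups(link, minu, maxu, g, M, edges=edges)
            count = sum(1 for ch, _ in groups if len(ch) >= 2)
            if count > best_count:
                best_g, best_count = g, count
        if best_count == 0:
            warnings.warn(
                f"no grid threshold aggregates anything on layer {ell}; tree "
                f"truncated at {ell - 1} layers",
                UserWarning,
                stacklevel=2,
            )
            break
        thresholds.append(best_g)
        g_prev = best_g
        prev = build_layer(prev, distance, best_g, M)
    return tuple(thresholds)


def construct_tree(
    distance: DistanceMatrix, config: TreeConfig | None = None
) -> AggregationTree:
    """Tune layer thresholds and build the aggregation tree in one call."""
    config = config or TreeConfig()
    thresholds = select_layer_thresholds(distance, config)
    return build_tree(distance, config, thresholds)
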