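"""Stage II of DART: recursive bottom-up testing on the aggregation tree.

Layer 1 applies a step-up threshold to the individual hypothesis P-values
(essentially the Benjamini-Hochberg rule restricted to the search interval
``[alpha_m, alpha]`` with ``alpha_m = 1 / (m log m)``).  Each higher layer
re-tests the hypotheses that survived so far, grouped into *dynamic nodes*:
tree nodes minus all previously rejected hypotheses.  A dynamic node with at
least two children still contributing unrejected hypotheses is a *candidate*
and receives an aggregated node P-value via the Gaussian (Stouffer)
combination of its members' original P-values.  The layer threshold solves a
step-up criterion whose numerator accumulates the expected false discoveries
of all layers and whose denominator counts all discoveries, keeping the
estimated false discovery proportion at or below the nominal level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import cauchy, chi2, norm

from .aggregation_tree import AggregationTree, TreeNode

__all__ = [
    "HypothesisPValues",
    "RunConfig",
    "DynamicNode",
    "LayerResult",
    "DartResult",
    "stouffer_node_pvalue",
    "aggregate_pvalues",
    "form_dynamic_nodes",
    "layer_threshold",
    "run_dart",
    "default_alpha_m",
    "TestingError",
]


class TestingError(ValueError):
    """Raised for malformed testing input or inconsistent configuration."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HypothesisPValues:
    """Per-hypothesis P-values with identifiers."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        if vals.ndim != 1 or len(vals) != len(self.ids):
            raise TestingError("ids and P-values must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise TestingError("hypothesis ids must be unique")
        if np.any(~np.isfinite(vals)):
            raise TestingError("P-values contain missing or non-finite entries")
        if np.any((vals < 0) | (vals > 1)):
            raise TestingError("P-values must lie in [0, 1]")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "HypothesisPValues":
        """Build from a table with columns ``id`` and ``pvalue``."""
        cols = {c.lower(): c for c in frame.columns}
        if "id" not in cols or "pvalue" not in cols:
            raise TestingError("P-value table needs columns 'id' and 'pvalue'")
        return cls(
            ids=tuple(frame[cols["id"]].astype(str)),
            values=frame[cols["pvalue"]].to_numpy(dtype=float),
        )

    def reindex(self, ids: Sequence[str]) -> np.ndarray:
        """Return values aligned to ``ids``; the id sets must agree."""
        pos = {h: i for i, h in enumerate(self.ids)}
        try:
            idx = [pos[str(h)] for h in ids]
        except KeyError as exc:
            raise TestingError(f"hypothesis id {exc} missing from P-value table")
        if len(ids) != len(self.ids):
            raise TestingError(
                f"P-value table has {len(self.ids)} hypotheses, expected {len(ids)}"
            )
        return self.values[idx]


def default_alpha_m(m: int) -> float:
    """Lower end of the threshold search interval: ``1 / (m log m)``."""
    if m < 2:
        raise TestingError("need at least 2 hypotheses")
    return 1.0 / (m * math.log(m))


@dataclass(frozen=True)
class RunConfig:
    """Testing-stage configuration.

    Attributes
    ----------
    alpha
        Nominal FDR level in (0, 1).
    alpha_m
        Lower bound of the threshold search interval.  ``None`` resolves to
        ``1 / (m log m)`` once the problem size is known; must stay below
        ``alpha``.
    p_clip
        Two-sided clipping bound applied before the Gaussian quantile
        transform, guarding against infinite z-scores at P-values of 0 or 1.
    aggregator
        Node P-value combination rule: ``"gaussian"`` (default, the only rule
        with supported error control), ``"fisher"`` or ``"cauchy"``.
    """

    alpha: float = 0.05
    alpha_m: float | None = None
    p_clip: float = 1e-15
    aggregator: str = "gaussian"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise TestingError("alpha must lie in (0, 1)")
        if not 0 < self.p_clip < 0.5:
            raise TestingError("p_clip must lie in (0, 0.5)")
        if self.aggregator not in ("gaussian", "fisher", "cauchy"):
            raise TestingError(f"unknown aggregator {self.aggregator!r}")
        if self.alpha_m is not None and not 0 < self.alpha_m < self.alpha:
            raise TestingError("alpha_m must satisfy 0 < alpha_m < alpha")

    def resolve(self, m: int) -> "RunConfig":
        """Fill in ``alpha_m`` for a problem of size ``m``."""
        if self.alpha_m is not None:
            return self
        am = default_alpha_m(m)
        if am >= self.alpha:
            raise TestingError(
                f"search floor alpha_m = 1/(m log m) = {am:.4g} is not below "
                f"alpha = {self.alpha}; increase alpha or m, or set alpha_m "
                "explicitly"
            )
        return replace(self, alpha_m=am)


@dataclass(frozen=True)
class DynamicNode:
    """A tree node with previously rejected hypotheses removed.

    ``members`` lists the remaining (unrejected) hypothesis positions;
    ``effective_children`` counts children still contributing at least one
    unrejected hypothesis.  Only candidates (``effective_children >= 2``, or
    any unrejected singleton on layer 1) are tested.
    """

    source: str
    members: tuple[int, ...]
    effective_children: int
    node_pvalue: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class LayerResult:
    """Audit record of one testing layer."""

    layer: int
    candidates: tuple[DynamicNode, ...]
    threshold: float | None
    rejected_nodes: tuple[DynamicNode, ...]
    rejected_hypotheses: tuple[int, ...]

    @property
    def num_candidates(self) -> int:
        return len(self.candidates)

    @property
    def candidate_size_total(self) -> int:
        """Total number of hypotheses across candidate dynamic nodes."""
        return sum(c.size for c in self.candidates)


@dataclass(frozen=True)
class DartResult:
    """Final rejection set plus the full layer-by-layer trace."""

    ids: tuple[str, ...]
    alpha: float
    alpha_m: float
    layers: tuple[LayerResult, ...]

    @property
    def rejected_indices(self) -> tuple[int, ...]:
        return tuple(i for lr in self.layers for i in lr.rejected_hypotheses)

    @property
    def rejected_ids(self) -> tuple[str, ...]:
        return tuple(self.ids[i] for i in self.rejected_indices)

    @property
    def n_rejections(self) -> int:
        return sum(len(lr.rejected_hypotheses) for lr in self.layers)

    def rejection_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.ids), dtype=bool)
        mask[list(self.rejected_indices)] = True
        return mask

    def rejection_table(self) -> pd.DataFrame:
        """One row per rejected hypothesis: id, layer, node, node P-value,
        layer threshold."""
        rows = []
        for lr in self.layers:
            for node in lr.rejected_nodes:
                for i in node.members:
                    rows.append(
                        {
                            "id": self.ids[i],
                            "rejected_layer": lr.layer,
                            "node_id": node.source,
                            "node_pvalue": node.node_pvalue,
                            "threshold": lr.threshold,
                        }
                    )
        frame = pd.DataFrame(
            rows,
            columns=["id", "rejected_layer", "node_id", "node_pvalue", "threshold"],
        )
        return frame

    def trace_dict(self) -> dict:
        """JSON-ready per-layer audit trail."""
        return {
            "alpha": self.alpha,
            "alpha_m": self.alpha_m,
            "n_rejections": self.n_rejections,
            "layers": [
                {
                    "layer": lr.layer,
                    "num_candidates": lr.num_candidates,
                    "threshold": lr.threshold,
                    "n_rejected_nodes": len(lr.rejected_nodes),
                    "n_rejected_hypotheses": len(lr.rejected_hypotheses),
                    "rejected_node_ids": [n.source for n in lr.rejected_nodes],
                }
                for lr in self.layers
            ],
        }


# ---------------------------------------------------------------------------
# Node P-value aggregation
# ---------------------------------------------------------------------------


def stouffer_node_pvalue(pvalues: Sequence[float], p_clip: float = 1e-15) -> float:
    """Gaussian (Stouffer) combination of member P-values.

    Computes ``Phi_bar( sum_j Phi_bar^{-1}(p_j) / sqrt(k) )`` where
    ``Phi_bar`` is the standard normal complementary CDF.  Inputs are clipped
    to ``[p_clip, 1 - p_clip]`` first; a singleton returns its (clipped)
    input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise TestingError("cannot aggregate an empty set of P-values")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise TestingError("P-values must lie in [0, 1]")
    p = np.clip(p, p_clip, 1.0 - p_clip)
    z = norm.isf(p)
    return float(norm.sf(z.sum() / math.sqrt(p.size)))


def aggregate_pvalues(
    pvalues: Sequence[float], method: str = "gaussian", p_clip: float = 1e-15
) -> float:
    """Combine member P-values into a node P-value.

    Only the Gaussian rule carries the procedure's error-control guarantees;
    Fisher and Cauchy (ACAT) combinations are provided for exploration.
    """
    if method == "gaussian":
        return stouffer_node_pvalue(pvalues, p_clip)
    p = np.clip(np.asarray(pvalues, dtype=float), p_clip, 1.0 - p_clip)
    if p.size == 0:
        raise TestingError("cannot aggregate an empty set of P-values")
    if method == "fisher":
        stat = -2.0 * np.log(p).sum()
        return float(chi2.sf(stat, df=2 * p.size))
    if method == "cauchy":
        stat = np.tan((0.5 - p) * np.pi).mean()
        return float(cauchy.sf(stat))
    raise TestingError(f"unknown aggregator {method!r}")


# ---------------------------------------------------------------------------
# Dynamic nodes
# ---------------------------------------------------------------------------


def form_dynamic_nodes(
    tree: AggregationTree,
    layer: int,
    rejected: np.ndarray,
    pvalues: np.ndarray,
    config: RunConfig,
    _z: np.ndarray | None = None,
) -> tuple[DynamicNode, ...]:
    """Candidate dynamic nodes of one layer, given earlier rejections.

    ``rejected`` is a boolean mask over hypotheses.  On layer 1 every
    unrejected singleton is a candidate; on higher layers a node qualifies
    only if at least two of its children still contribute an unrejected
    hypothesis (a single-child dynamic node was already tested below).  Node
    P-values always aggregate the *original* bottom-layer P-values of the
    remaining members.
    """
    nodes = tree.nodes_at(layer)
    gaussian = config.aggregator == "gaussian"
    if gaussian and _z is None:
        _z = norm.isf(np.clip(pvalues, config.p_clip, 1.0 - config.p_clip))
    if layer == 1:
        keep = [n for n in nodes if not rejected[n.members[0]]]
        if gaussian:
            # a singleton's Gaussian aggregate is its own (clipped) P-value
            idx = [n.members[0] for n in keep]
            pvs = np.clip(pvalues[idx], config.p_clip, 1.0 - config.p_clip)
        else:
            pvs = [
                aggregate_pvalues(
                    [pvalues[n.members[0]]], config.aggregator, config.p_clip
                )
                for n in keep
            ]
        return tuple(
            DynamicNode(
                source=n.node_id,
                members=(n.members[0],),
                effective_children=1,
                node_pvalue=float(pv),
            )
            for n, pv in zip(keep, pvs)
        )

    lookup = {n.node_id: n for n in tree.nodes_at(layer - 1)}
    shells: list[tuple[TreeNode, tuple[int, ...], int]] = []
    for node in nodes:
        members = tuple(i for i in node.members if not rejected[i])
        if not members:
            continue
        eff = sum(
            1
            for cid in node.children
            if any(not rejected[i] for i in lookup[cid].members)
        )
        if eff < 2:
            continue
        shells.append((node, members, eff))
    if gaussian:
        stats = np.array(
            [_z[list(members)].sum() / math.sqrt(len(members)) for _, members, _ in shells]
        )
        pvs = norm.sf(stats) if len(shells) else np.empty(0)
    else:
        pvs = [
            aggregate_pvalues(pvalues[list(members)], config.aggregator, config.p_clip)
            for _, members, _ in shells
        ]
    return tuple(
        DynamicNode(
            source=node.node_id,
            members=members,
            effective_children=eff,
            node_pvalue=float(pv),
        )
        for (node, members, eff), pv in zip(shells, pvs)
    )


# ---------------------------------------------------------------------------
# Layer thresholds and the full procedure
# ---------------------------------------------------------------------------


def _history_carry(history: Sequence[LayerResult], alpha_m: float) -> tuple[float, int]:
    """Accumulated numerator contribution and rejection count of past layers.

    Each past layer contributes (total candidate hypothesis count) times its
    threshold — the expected number of falsely rejected hypotheses if every
    candidate were null with a uniform node P-value.  A layer whose
    threshold was infeasible contributes ``alpha_m`` instead: the smallest
    admissible threshold, a conservative stand-in for the undefined
    quantity.
    """
    carry = 0.0
    n_rej = 0
    for lr in history:
        t = lr.threshold if lr.threshold is not None else alpha_m
        carry += lr.candidate_size_total * t
        n_rej += len(lr.rejected_hypotheses)
    return carry, n_rej


def layer_threshold(
    layer: int,
    history: Sequence[LayerResult],
    candidates: Sequence[DynamicNode],
    config: RunConfig,
) -> float | None:
    """Step-up P-value threshold for one layer, or ``None`` if infeasible.

    Finds the largest ``t`` in ``[alpha_m, alpha]`` with

    ``(sum_{l' < l} n^(l') t_hat(l') + n^(l) t)
    / max(R_prev + sum_{S candidate} |S| 1{T_S <= t}, 1) <= alpha``,

    where ``n^(l)`` is the total number of hypotheses contained in layer
    ``l``'s candidate dynamic nodes.  Both the numerator (the expected count
    of falsely rejected hypotheses when null node P-values are uniform,
    since rejecting a null node rejects all |S| members) and the denominator
    (realized discoveries) are therefore on the hypothesis scale.

    The supremum is computed exactly: the denominator is a step function of
    ``t`` with jumps at the observed node P-values, so on each step the
    criterion is linear in ``t`` and the largest feasible ``t`` is available
    in closed form.  Returning the exact supremum (rather than the largest
    feasible *observed* P-value, which rejects the same nodes) matters for
    the layers above: their numerators charge ``n^(l) * t_hat(l)``, and an
    understated threshold would under-count this layer's expected false
    rejections, leaking error budget upward.  On layer 1 with empty history
    the rejection set coincides with the classical step-up rule over the m
    singleton P-values.
    """
    if config.alpha_m is None:
        raise TestingError("config.alpha_m unresolved; call RunConfig.resolve(m)")
    alpha, alpha_m = config.alpha, config.alpha_m
    m_ell = len(candidates)
    if m_ell == 0:
        return None
    carry, n_rej_prev = _history_carry(history, alpha_m)
    pv = np.fromiter((c.node_pvalue for c in candidates), dtype=float, count=m_ell)
    sz = np.fromiter((c.size for c in candidates), dtype=float, count=m_ell)
    n_ell = float(sz.sum())
    order = np.argsort(pv, kind="stable")
    pv_sorted = pv[order]
    size_cum = np.cumsum(sz[order])
    # candidate step edges inside the search interval, scanned from above;
    # on the step [edge, next_edge) the denominator is R_prev + sizes of
    # nodes with T <= edge
    edges = np.unique(
        np.concatenate(
            [pv_sorted[(pv_sorted >= alpha_m) & (pv_sorted <= alpha)], [alpha_m]]
        )
    )
    uppers = np.append(edges[1:], alpha)
    for edge, upper in zip(edges[::-1], uppers[::-1]):
        k = int(np.searchsorted(pv_sorted, edge, side="right"))
        denom = max(n_rej_prev + (size_cum[k - 1] if k else 0.0), 1.0)
        # largest t on this step satisfying carry + n*t <= alpha*denom
        t_root = (alpha * denom - carry) / n_ell
        t_star = min(upper, t_root)
        if t_star >= edge:
            return float(min(t_star, alpha))
    return None


def run_dart(
    pvalues: HypothesisPValues | np.ndarray | Sequence[float],
    tree: AggregationTree,
    config: RunConfig | None = None,
) -> DartResult:
    """Run the full recursive testing stage on an aggregation tree.

    Layer by layer, forms candidate dynamic nodes, solves the layer
    threshold, rejects every candidate whose node P-value is at or below it
    (together with all its member hypotheses), and carries the rejections
    forward.  Rejected hypotheses are never re-tested.
    """
    config = (config or RunConfig()).resolve(tree.m)
    if isinstance(pvalues, HypothesisPValues):
        p = pvalues.reindex(tree.ids)
    else:
        p = np.asarray(pvalues, dtype=float)
        if p.shape != (tree.m,):
            raise TestingError(
                f"expected {tree.m} P-values matching the tree, got {p.shape}"
            )
        if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
            raise TestingError("P-values must be finite and lie in [0, 1]")

    z = None
    if config.aggregator == "gaussian":
        z = norm.isf(np.clip(p, config.p_clip, 1.0 - config.p_clip))

    rejected = np.zeros(tree.m, dtype=bool)
    results: list[LayerResult] = []
    for layer in range(1, tree.num_layers + 1):
        candidates = form_dynamic_nodes(tree, layer, rejected, p, config, _z=z)
        t_hat = layer_threshold(layer, results, candidates, config)
        if t_hat is None:
            rejected_nodes: tuple[DynamicNode, ...] = ()
        else:
            rejected_nodes = tuple(
                c for c in candidates if c.node_pvalue <= t_hat
            )
        new_rej = tuple(sorted(i for c in rejected_nodes for i in c.members))
        results.append(
            LayerResult(
                layer=layer,
                candidates=candidates,
                threshold=t_hat,
                rejected_nodes=rejected_nodes,
                rejected_hypotheses=new_rej,
            )
        )
        rejected[list(new_rej)] = True
    return DartResult(
        ids=tree.ids,
        alpha=config.alpha,
        alpha_m=config.alpha_m,
        layers=tuple(results),
    )
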