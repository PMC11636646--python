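"""Error and power metrics against known truth, plus the BH baseline.

``evaluate`` computes, for one DART run on simulated data:

* ``fdp`` — false rejections over total rejections (denominator floored at 1),
* ``sensitivity`` — true rejections over the number of alternatives,
* ``node_fdp`` — the weighted node-level FDP: only rejected nodes containing
  *no* alternative member count as false, weighted by node size.  A rejected
  mixed node inflates ``fdp`` but not ``node_fdp``, so ``node_fdp <= fdp``
  always.

``run_benchmark`` wires the synthetic generator, tree construction and both
testing procedures (DART and Benjamini-Hochberg) into a replicated grid over
nominal FDR levels, the experiment layout used by the package's calibration
checks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .aggregation_tree import TreeConfig, construct_tree
from .recursive_testing import (
    DartResult,
    HypothesisPValues,
    RunConfig,
    run_dart,
)
from .synthetic_data import SimulationConfig, simulate_dataset

__all__ = [
    "EvaluationSummary",
    "evaluate",
    "confusion_counts",
    "bh_reject",
    "run_benchmark",
    "summarize_benchmark",
]


@dataclass(frozen=True)
class EvaluationSummary:
    """Realized error/power metrics of one run against known truth."""

    fdp: float
    sensitivity: float
    node_fdp: float
    n_rejections: int


def _as_truth_array(truth, ids: Sequence[str]) -> np.ndarray:
    if isinstance(truth, dict):
        return np.array([bool(truth[str(h)]) for h in ids])
    arr = np.asarray(truth, dtype=bool)
    if arr.shape != (len(ids),):
        raise ValueError(
            f"truth labels have shape {arr.shape}, expected ({len(ids)},)"
        )
    return arr


def confusion_counts(rejected_mask: np.ndarray, truth: np.ndarray) -> tuple[int, int]:
    """(false rejections, true rejections) of a rejection mask."""
    return (
        int((rejected_mask & ~truth).sum()),
        int((rejected_mask & truth).sum()),
    )


def evaluate(result: DartResult, truth) -> EvaluationSummary:
    """Score a DART result against ground-truth alternative labels.

    ``truth`` is a boolean array aligned to ``result.ids`` (True marking
    alternatives) or a mapping from id to label.
    """
    truth = _as_truth_array(truth, result.ids)
    mask = result.rejection_mask()
    n_rej = int(mask.sum())
    false_rej, true_rej = confusion_counts(mask, truth)
    n_alt = int(truth.sum())
    node_false = 0
    for lr in result.layers:
        for node in lr.rejected_nodes:
            if not truth[list(node.members)].any():
                node_false += node.size
    return EvaluationSummary(
        fdp=false_rej / max(n_rej, 1),
        sensitivity=true_rej / max(n_alt, 1),
        node_fdp=node_false / max(n_rej, 1),
        n_rejections=n_rej,
    )


def bh_reject(
    pvalues: HypothesisPValues | np.ndarray | Sequence[float], alpha: float
) -> np.ndarray:
    """Classical Benjamini-Hochberg step-up rejections as a boolean mask."""
    if isinstance(pvalues, HypothesisPValues):
        p = pvalues.values
    else:
        p = np.asarray(pvalues, dtype=float)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return multipletests(p, alpha=alpha, method="fdr_bh")[0]


def _bh_summary(p: np.ndarray, truth: np.ndarray, alpha: float) -> EvaluationSummary:
    mask = bh_reject(p, alpha)
    n_rej = int(mask.sum())
    false_rej, true_rej = confusion_counts(mask, truth)
    return EvaluationSummary(
        fdp=false_rej / max(n_rej, 1),
        sensitivity=true_rej / max(int(truth.sum()), 1),
        node_fdp=float("nan"),  # node-level accounting is undefined for BH
        n_rejections=n_rej,
    )


def _replicate_seeds(seed: int | None, n_reps: int) -> np.ndarray:
    """Derive one sub-31-bit seed per replicate from a master seed."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n_reps) & 0x7FFFFFFF


def run_benchmark(
    sim_config: SimulationConfig | None = None,
    alphas: Sequence[float] = (0.05, 0.1, 0.15, 0.2),
    n_reps: int = 200,
    seed: int | None = None,
    tree_config: TreeConfig | None = None,
    methods: Sequence[str] = ("dart", "bh"),
) -> pd.DataFrame:
    """Replicated comparison of DART and BH over a grid of nominal levels.

    Per replicate: simulate a dataset, tune and build one aggregation tree
    (shared across levels, since the tree does not depend on ``alpha``), run
    every requested method at every level, and score against truth.  Returns
    one row per (replicate, level, method) with the per-run metrics and the
    replicate seed, so any row is reproducible in isolation.
    """
    sim_config = sim_config or SimulationConfig()
    tree_config = tree_config or TreeConfig()
    seeds = _replicate_seeds(seed, n_reps)
    rows = []
    for rep, rep_seed in enumerate(seeds):
        dataset = simulate_dataset(sim_config, seed=int(rep_seed))
        tree = None
        if "dart" in methods:
            tree = construct_tree(dataset.distance, tree_config)
        for alpha in alphas:
            if "dart" in methods:
                result = run_dart(dataset.pvalues, tree, RunConfig(alpha=alpha))
                summ = evaluate(result, dataset.truth)
                rows.append(
                    {
                        "rep": rep,
                        "seed": int(rep_seed),
                        "alpha": alpha,
                        "method": "dart",
                        **dataclasses.asdict(summ),
                    }
                )
            if "bh" in methods:
                summ = _bh_summary(dataset.pvalues, dataset.truth, alpha)
                rows.append(
                    {
                        "rep": rep,
                        "seed": int(rep_seed),
                        "alpha": alpha,
                        "method": "bh",
                        **dataclasses.asdict(summ),
                    }
                )
    return pd.DataFrame(rows)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Mean FDP/sensitivity with Monte-Carlo standard errors per cell."""
    grouped = results.groupby(["alpha", "method"], as_index=False)
    out = grouped.agg(
        n_reps=("rep", "count"),
        mean_fdp=("fdp", "mean"),
        se_fdp=("fdp", "sem"),
        mean_sensitivity=("sensitivity", "mean"),
        se_sensitivity=("sensitivity", "sem"),
        mean_node_fdp=("node_fdp", "mean"),
        mean_rejections=("n_rejections", "mean"),
    )
    return out
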