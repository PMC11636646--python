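"""File input/output: P-value tables, distance sources, tree JSON, results.

Distance geometry can come from three sources:

* a square numeric CSV/TSV with matching id header row and index column,
* a coordinate table (``id`` plus numeric columns; Euclidean distances are
  computed internally), or
* a newick phylogeny, whose patristic (sum of branch lengths) distances
  between leaves define the matrix.  Trees with missing branch lengths are
  rejected rather than silently defaulted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregation_tree import AggregationTree, DistanceMatrix, TreeConstructionError
from .recursive_testing import DartResult, HypothesisPValues, TestingError

__all__ = [
    "read_pvalues",
    "read_distance_matrix",
    "read_coordinates",
    "read_newick_distances",
    "read_tree_json",
    "write_tree_json",
    "write_rejections",
    "write_trace",
]


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_pvalues(path: str | Path) -> HypothesisPValues:
    """Read a per-hypothesis P-value table (columns ``id``, ``pvalue``)."""
    frame = pd.read_csv(path, sep=_sep_for(path))
    return HypothesisPValues.from_frame(frame)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square distance matrix with id header row and index column."""
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    ids = [str(c) for c in frame.columns]
    row_ids = [str(r) for r in frame.index]
    if ids != row_ids:
        raise TreeConstructionError(
            "distance matrix row and column ids do not match"
        )
    return DistanceMatrix(ids, frame.to_numpy(dtype=float))


def read_coordinates(path: str | Path) -> DistanceMatrix:
    """Read an (id, x1, x2, ...) table; Euclidean distances are computed."""
    frame = pd.read_csv(path, sep=_sep_for(path))
    if frame.shape[1] < 2:
        raise TreeConstructionError(
            "coordinate table needs an id column plus numeric coordinates"
        )
    ids = frame.iloc[:, 0].astype(str).tolist()
    coords = frame.iloc[:, 1:].to_numpy(dtype=float)
    return DistanceMatrix.from_coordinates(ids, coords)


def read_newick_distances(path: str | Path) -> DistanceMatrix:
    """Patristic distance matrix between the leaves of a newick tree."""
    import dendropy

    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises assorted parse errors
        raise TreeConstructionError(f"malformed newick file: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise TreeConstructionError(
                "newick tree has branches without lengths; patristic "
                "distances are undefined"
            )
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    m = len(ids)
    if m < 2:
        raise TreeConstructionError("newick tree must have at least 2 leaves")
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(ids, d)


def write_tree_json(tree: AggregationTree, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree.to_dict(), indent=2) + "\n")


def read_tree_json(path: str | Path) -> AggregationTree:
    return AggregationTree.from_dict(json.loads(Path(path).read_text()))


def write_rejections(result: DartResult, path: str | Path) -> None:
    """Write the rejection table as TSV (id, layer, node, node P, threshold)."""
    result.rejection_table().to_csv(path, sep="\t", index=False)


def write_trace(result: DartResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.trace_dict(), indent=2) + "\n")
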