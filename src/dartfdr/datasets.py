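"""Small built-in example datasets.

``toy_example`` is a seven-hypothesis walkthrough of the whole procedure:
two strong signals (hypotheses 1 and 3) fall on layer 1, and two moderate
signals (4 and 5) are individually unremarkable but close in space — after
hypothesis 3 is removed, they form the dynamic node {4, 5} whose aggregated
P-value clears the layer-2 threshold, so both are rejected together.  The
far-away pair {6, 7} and the leftover hypothesis 2 survive every layer.

With only seven hypotheses the threshold search floor ``1/(m log m)`` is
about 0.073, so the example runs at the nominal level 0.3 to leave a usable
search interval.
"""

from __future__ import annotations

import numpy as np

from .aggregation_tree import DistanceMatrix, TreeConfig, build_tree
from .recursive_testing import HypothesisPValues

__all__ = ["toy_example"]

# 1-D positions: cluster {1,2}, cluster {3,4,5}, far pair {6,7}
_TOY_POSITIONS = {
    "1": 0.0,
    "2": 0.5,
    "3": 3.0,
    "4": 3.4,
    "5": 3.8,
    "6": 10.0,
    "7": 10.5,
}

# strong signals at 1 and 3; moderate at 4 and 5; nulls elsewhere
_TOY_PVALUES = {
    "1": 0.01,
    "2": 0.50,
    "3": 0.08,
    "4": 0.18,
    "5": 0.18,
    "6": 0.70,
    "7": 0.90,
}

_TOY_ALPHA = 0.3
_TOY_THRESHOLDS = (1.0, 12.0)  # g(2), g(3)


def toy_example() -> dict:
    """The packaged 7-hypothesis worked example.

    Returns a dict with keys ``distance`` (:class:`DistanceMatrix`),
    ``pvalues`` (:class:`HypothesisPValues`), ``tree`` (the 3-layer
    aggregation tree with M = 3), ``alpha`` and ``thresholds``.
    """
    ids = list(_TOY_POSITIONS)
    pos = np.array([_TOY_POSITIONS[i] for i in ids])
    distance = DistanceMatrix.from_coordinates(ids, pos)
    pvalues = HypothesisPValues(
        ids=tuple(ids), values=np.array([_TOY_PVALUES[i] for i in ids])
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        config = TreeConfig(max_node_size=3, min_top_nodes=1, num_layers=3)
    tree = build_tree(distance, config, _TOY_THRESHOLDS)
    return {
        "distance": distance,
        "pvalues": pvalues,
        "tree": tree,
        "alpha": _TOY_ALPHA,
        "thresholds": _TOY_THRESHOLDS,
    }
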