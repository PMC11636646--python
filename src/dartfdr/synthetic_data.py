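"""Simulated hypothesis panels with spatial co-status structure.

The generator emulates a planar multiple-testing study: ``m`` features sit at
random 2-D locations (first coordinate Gaussian with mean 0 and variance 2,
second uniform on ``[0, 4]``), pairwise Euclidean distances define the
hypothesis geometry, and the alternative hypotheses are planted mostly in
tight spatial clusters — the regime in which distance carries information
about shared null/alternative status — plus a small standalone fraction.

Alternative P-values are two-sided tail probabilities of a unit-variance
Gaussian test statistic with mean shift ``mu``.  Null P-values come from one
of three models: exactly uniform, mildly misspecified (a heavy-tailed t
statistic evaluated against the normal reference, so the null P-values are
only asymptotically uniform), or a per-feature linear-regression Wald test.
A label-switching knob ``tau`` exchanges a fraction of alternatives with
random nulls to probe robustness when distance only partially reflects
co-status.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .aggregation_tree import DistanceMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "switch_labels",
    "SimulationError",
]


class SimulationError(ValueError):
    """Raised when a simulation configuration is infeasible."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    Defaults describe the reference design used throughout the test and
    benchmark suites: 1000 features, 50 alternatives of which 90% sit in 5
    tight spatial clusters, mean shift 3, exactly uniform nulls.
    """

    m: int = 1000
    n_alternatives: int = 50
    n_clusters: int = 5
    cluster_radius: float = 0.3
    standalone_fraction: float = 0.1
    mu: float = 3.0
    null_model: str = "uniform"  # uniform | misspecified | regression
    tau: float = 0.0
    seed: int | None = None
    coord_normal_var: float = 2.0
    coord_uniform_high: float = 4.0
    t_df: int = 10  # misspecified-null t statistic degrees of freedom
    n_obs: int = 100  # regression model sample size per feature

    def __post_init__(self):
        if self.m < 2:
            raise SimulationError("m must be >= 2")
        if not 0 <= self.n_alternatives < self.m:
            raise SimulationError("n_alternatives must lie in [0, m)")
        if self.n_alternatives and self.n_clusters < 1:
            raise SimulationError("need at least one cluster")
        if not 0 <= self.standalone_fraction <= 1:
            raise SimulationError("standalone_fraction must lie in [0, 1]")
        if not 0 <= self.tau <= 1:
            raise SimulationError("tau must lie in [0, 1]")
        if self.cluster_radius <= 0:
            raise SimulationError("cluster_radius must be positive")
        if self.null_model not in ("uniform", "misspecified", "regression"):
            raise SimulationError(f"unknown null_model {self.null_model!r}")


@dataclass(frozen=True)
class SimulatedDataset:
    """Coordinates, distances, ground truth and P-values of one replicate."""

    ids: tuple[str, ...]
    coordinates: np.ndarray  # (m, 2)
    distance: DistanceMatrix
    truth: np.ndarray  # bool, True = alternative
    pvalues: np.ndarray
    config: SimulationConfig

    @property
    def m(self) -> int:
        return len(self.ids)

    @property
    def n_alternatives(self) -> int:
        return int(self.truth.sum())

    def pvalue_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "pvalue": self.pvalues})

    def write(self, out_dir: str | Path) -> None:
        """Write coordinates.csv, pvalues.csv, truth.csv and config.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"id": self.ids, "x1": self.coordinates[:, 0], "x2": self.coordinates[:, 1]}
        ).to_csv(out / "coordinates.csv", index=False)
        self.pvalue_frame().to_csv(out / "pvalues.csv", index=False)
        pd.DataFrame(
            {"id": self.ids, "is_alternative": self.truth.astype(int)}
        ).to_csv(out / "truth.csv", index=False)
        (out / "config.json").write_text(
            json.dumps(dataclasses.asdict(self.config), indent=2) + "\n"
        )


def _balanced_sizes(total: int, k: int) -> list[int]:
    base, extra = divmod(total, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _place_alternatives(
    config: SimulationConfig, dist: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Plant clustered plus standalone alternatives; returns a boolean mask.

    Each cluster is seeded at a randomly chosen feature and filled with that
    feature's nearest unassigned neighbours, all within ``cluster_radius`` of
    the seed.  Seeds whose neighbourhood is too sparse are skipped; if no
    feasible seed remains the geometry is declared infeasible.
    """
    m = config.m
    is_alt = np.zeros(m, dtype=bool)
    n_alt = config.n_alternatives
    if n_alt == 0:
        return is_alt
    n_standalone = int(round(config.standalone_fraction * n_alt))
    n_clustered = n_alt - n_standalone
    if n_clustered > 0:
        sizes = [s for s in _balanced_sizes(n_clustered, config.n_clusters) if s > 0]
        seed_order = rng.permutation(m)
        for size in sizes:
            placed = False
            for c in seed_order:
                if is_alt[c]:
                    continue
                near = np.flatnonzero((dist[c] <= config.cluster_radius) & ~is_alt)
                if len(near) < size:
                    continue
                chosen = near[np.argsort(dist[c][near], kind="stable")[:size]]
                is_alt[chosen] = True
                placed = True
                break
            if not placed:
                raise SimulationError(
                    f"cannot place a cluster of {size} alternatives within "
                    f"radius {config.cluster_radius}; geometry infeasible"
                )
    if n_standalone > 0:
        pool = np.flatnonzero(~is_alt)
        if len(pool) < n_standalone:
            raise SimulationError("not enough null features for standalone alternatives")
        is_alt[rng.choice(pool, size=n_standalone, replace=False)] = True
    return is_alt


def _draw_pvalues(
    config: SimulationConfig, is_alt: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    m = config.m
    p = np.empty(m)
    alt = np.flatnonzero(is_alt)
    null = np.flatnonzero(~is_alt)
    if config.null_model == "regression":
        # per-feature simple regression, two-sided Wald P-value against the
        # normal reference; the slope gives the alternatives mean Wald
        # statistic ~ mu
        n = config.n_obs
        X = rng.standard_normal((n, m))
        eps = rng.standard_normal((n, m))
        beta = np.zeros(m)
        beta[alt] = config.mu / math.sqrt(n)
        Y = X * beta + eps
        sxx = (X * X).sum(axis=0)
        bhat = (X * Y).sum(axis=0) / sxx
        resid = Y - X * bhat
        s2 = (resid * resid).sum(axis=0) / (n - 1)
        zstat = bhat / np.sqrt(s2 / sxx)
        return 2.0 * norm.sf(np.abs(zstat))
    if config.null_model == "uniform":
        p[null] = rng.uniform(size=len(null))
    else:  # misspecified: heavy-tailed statistic vs. the normal reference
        z0 = rng.standard_t(config.t_df, size=len(null))
        p[null] = 2.0 * norm.sf(np.abs(z0))
    z1 = config.mu + rng.standard_normal(len(alt))
    p[alt] = 2.0 * norm.sf(np.abs(z1))
    return p


def simulate_dataset(
    config: SimulationConfig | None = None, seed: int | None = None
) -> SimulatedDataset:
    """Generate one replicate; fully reproducible from the seed.

    ``seed`` overrides ``config.seed`` when given.  If ``config.tau > 0`` the
    label-switching perturbation is applied before returning.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    m = config.m
    x1 = rng.normal(0.0, math.sqrt(config.coord_normal_var), size=m)
    x2 = rng.uniform(0.0, config.coord_uniform_high, size=m)
    coords = np.column_stack([x1, x2])
    width = len(str(m - 1))
    ids = tuple(f"h{i:0{width}d}" for i in range(m))
    distance = DistanceMatrix.from_coordinates(ids, coords)
    is_alt = _place_alternatives(config, distance.values, rng)
    p = _draw_pvalues(config, is_alt, rng)
    dataset = SimulatedDataset(
        ids=ids,
        coordinates=coords,
        distance=distance,
        truth=is_alt,
        pvalues=p,
        config=config,
    )
    if config.tau > 0:
        dataset = switch_labels(dataset, config.tau, rng)
    return dataset


def switch_labels(
    dataset: SimulatedDataset,
    tau: float,
    seed: int | np.random.Generator | None = None,
) -> SimulatedDataset:
    """Swap a fraction ``tau`` of alternatives with randomly chosen nulls.

    Both the truth label and the P-value move, so the swapped pair exchanges
    its generating status entirely.  This degrades the link between distance
    and co-status without changing the marginal P-value mixture.  ``tau = 0``
    returns the dataset unchanged.
    """
    if not 0 <= tau <= 1:
        raise SimulationError("tau must lie in [0, 1]")
    if tau == 0:
        return dataset
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    alt = np.flatnonzero(dataset.truth)
    null = np.flatnonzero(~dataset.truth)
    k = int(round(tau * len(alt)))
    if k == 0:
        return dataset
    if k > len(null):
        raise SimulationError("not enough null hypotheses to switch with")
    pick_alt = rng.choice(alt, size=k, replace=False)
    pick_null = rng.choice(null, size=k, replace=False)
    truth = dataset.truth.copy()
    p = dataset.pvalues.copy()
    truth[pick_alt], truth[pick_null] = truth[pick_null], truth[pick_alt].copy()
    p[pick_alt], p[pick_null] = p[pick_null], p[pick_alt].copy()
    return dataclasses.replace(dataset, truth=truth, pvalues=p)
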