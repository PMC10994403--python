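"""Global spatial autocorrelation of cluster-level coverage (Moran's I).

The statistic is computed on per-cluster use proportions with k-nearest-
neighbour row-standardised weights (default k = 8; a distance-band
alternative is provided).  Inference is available both from the analytic
normality-assumption moments and from a seeded permutation null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .geodata import GeoPoint, WomanRecord, pairwise_haversine_km

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "knn_weights",
    "distance_band_weights",
    "morans_i",
    "morans_i_permutation",
    "ea_proportions",
]


@dataclass
class SpatialWeights:
    """Neighbour lists with weights; optionally row-standardised."""

    neighbors: list[np.ndarray]   # indices per site
    weights: list[np.ndarray]     # matching weights per site
    row_standardized: bool

    @property
    def n(self) -> int:
        return len(self.neighbors)

    def dense(self) -> np.ndarray:
        W = np.zeros((self.n, self.n))
        for i, (nb, wt) in enumerate(zip(self.neighbors, self.weights)):
            W[i, nb] = wt
        return W

    def validate(self) -> None:
        for i, (nb, wt) in enumerate(zip(self.neighbors, self.weights)):
            if np.any(nb == i):
                raise ValueError(f"site {i} is its own neighbour")
            if np.any(wt < 0):
                raise ValueError(f"negative weight at site {i}")
            if self.row_standardized and len(wt) and abs(wt.sum() - 1.0) > 1e-9:
                raise ValueError(f"row {i} not standardised (sum {wt.sum()})")

    def to_gal(self, path: str | Path, ids: Sequence[str] | None = None) -> None:
        """Write the neighbour structure in GAL format for cross-tool checks."""
        ids = list(ids) if ids is not None else [str(i) for i in range(self.n)]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{self.n}\n")
            for i, nb in enumerate(self.neighbors):
                fh.write(f"{ids[i]} {len(nb)}\n")
                fh.write(" ".join(ids[j] for j in nb) + "\n")


@dataclass
class MoranResult:
    I: float
    expected_I: float
    z: float
    p: float
    p_perm: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside (0, 1]")


def knn_weights(points: Sequence[GeoPoint], k: int = 8) -> SpatialWeights:
    """Row-standardised k-nearest-neighbour weights on great-circle distance.

    Distance ties are broken by site index.  Duplicate locations are
    rejected because nearest-neighbour sets are then ill-defined.
    """
    n = len(points)
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n (k={k}, n={n})")
    d = pairwise_haversine_km(points)
    dup = np.argwhere(np.triu(d < 1e-9, k=1))
    if len(dup):
        raise ValueError(f"duplicate points at index pairs {dup.tolist()[:10]}")
    neighbors, weights = [], []
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, d[i]))
        nb = np.array([j for j in order if j != i][:k])
        neighbors.append(np.sort(nb))
        weights.append(np.full(k, 1.0 / k))
    w = SpatialWeights(neighbors, weights, row_standardized=True)
    w.validate()
    return w


def distance_band_weights(
    points: Sequence[GeoPoint], threshold_km: float, row_standardize: bool = True
) -> SpatialWeights:
    """Binary weights for all pairs within a distance band."""
    n = len(points)
    d = pairwise_haversine_km(points)
    neighbors, weights = [], []
    for i in range(n):
        nb = np.flatnonzero((d[i] <= threshold_km) & (np.arange(n) != i))
        neighbors.append(nb)
        if len(nb) and row_standardize:
            weights.append(np.full(len(nb), 1.0 / len(nb)))
        else:
            weights.append(np.ones(len(nb)))
    w = SpatialWeights(neighbors, weights, row_standardized=row_standardize)
    w.validate()
    return w


def _moran_stat(x: np.ndarray, W: np.ndarray, S0: float) -> float:
    xc = x - x.mean()
    return float(len(x) / S0 * (xc @ W @ xc) / (xc @ xc))


def morans_i(values: Sequence[float], w: SpatialWeights) -> MoranResult:
    """Moran's I with the analytic z-score under the normality assumption."""
    x = np.asarray(values, dtype=float)
    n = w.n
    if len(x) != n:
        raise ValueError(f"{len(x)} values for {n} sites")
    if n < 4:
        raise ValueError("need at least 4 sites")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: values are all equal")
    W = w.dense()
    S0 = float(W.sum())
    I = _moran_stat(x, W, S0)
    EI = -1.0 / (n - 1)
    S1 = 0.5 * float(((W + W.T) ** 2).sum())
    S2 = float(((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum())
    var = (n * n * S1 - n * S2 + 3.0 * S0 * S0) / (S0 * S0 * (n * n - 1.0)) - EI * EI
    z = (I - EI) / math.sqrt(var)
    p = 2.0 * float(norm.sf(abs(z)))
    return MoranResult(I=I, expected_I=EI, z=z, p=max(p, 1e-300))


def morans_i_permutation(
    values: Sequence[float],
    w: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Moran's I with a two-sided permutation p-value.

    p_perm = (1 + #{|I_perm| >= |I_obs|}) / (n_perm + 1), reproducible by seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    base = morans_i(values, w)
    x = np.asarray(values, dtype=float)
    W = w.dense()
    S0 = float(W.sum())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        xp = rng.permutation(x)
        if abs(_moran_stat(xp, W, S0)) >= abs(base.I):
            count += 1
    base.p_perm = (1.0 + count) / (n_perm + 1.0)
    return base


def ea_proportions(
    records: Sequence[WomanRecord],
    ea_locations: dict[str, GeoPoint] | None = None,
) -> tuple[list[GeoPoint], np.ndarray, list[str]]:
    """Per-EA modern-use proportions and locations, for cluster-level analysis."""
    by_ea: dict[str, list[WomanRecord]] = {}
    for r in records:
        by_ea.setdefault(r.ea_id, []).append(r)
    ids = sorted(by_ea)
    points, props = [], []
    for e in ids:
        group = by_ea[e]
        if ea_locations is not None:
            points.append(ea_locations[e])
        else:
            points.append(GeoPoint(
                float(np.mean([g.household_location.lon for g in group])),
                float(np.mean([g.household_location.lat for g in group])),
            ))
        props.append(np.mean([g.uses_modern for g in group]))
    return points, np.array(props), ids
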