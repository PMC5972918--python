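"""Neighborhood rough set primitives.

A neighborhood decision system is a finite sample set U with real-valued
conditional attributes A, a categorical decision attribute D, a metric Δ
and a radius β ≥ 0. The β-neighborhood of a sample x is
β(x) = {y ∈ U : Δ(x, y) ≤ β} — boundary-inclusive, so x ∈ β(x) always.

From the neighborhoods, for each decision class X_i:

* lower approximation  {x : β(x) ⊆ X_i}
* upper approximation  {x : β(x) ∩ X_i ≠ ∅}

The positive region Pos_B(D) is the union of lower approximations, the
boundary BN(D) is upper-union minus lower-union, precision is
ρ = |lower union| / |upper union| and roughness r = 1 − ρ. Because every
sample's neighborhood meets its own class, the upper union is always U,
so ρ = |Pos|/|U| and the negative region is empty.

Two dependency measures are exposed:

* ``paper``   K(B, D) = (1 − ρ) · |Pos_B(D)| / |U| = r·ρ ∈ [0, 0.25],
  a roughness-weighted dependency that is zero both for perfectly
  separable data (ρ = 1) and for fully mixed data (ρ = 0), peaking at
  ρ = 1/2;
* ``classic`` K(B, D) = |Pos_B(D)| / |U|, the standard neighborhood
  dependency, monotone under attribute growth for Minkowski metrics.

The greedy reduction driver accepts either. By convention K(∅, D) = 0:
with no attributes nothing is discernible and the positive region is
empty.

Distances are compared to β exactly as computed, with no epsilon padding;
samples sitting numerically on the radius are inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .dataset import ExpressionDataset

__all__ = [
    "NeighborhoodModel",
    "RegionSummary",
    "pairwise_distance",
    "build_neighborhoods",
    "compute_regions",
    "dependency",
    "sig_inner",
    "sig_outer",
]

_METRICS = {"euclidean", "manhattan", "pnorm"}


@dataclass(frozen=True)
class NeighborhoodModel:
    """Per-sample β-neighborhoods under an attribute subset and metric.

    ``adjacency[i, j]`` is True when sample j lies within radius β of
    sample i. The matrix is symmetric with a True diagonal.
    """

    beta: float
    metric: str
    p: float
    attribute_subset: tuple
    adjacency: np.ndarray  # (n, n) bool

    def neighborhood(self, i: int) -> frozenset:
        return frozenset(np.flatnonzero(self.adjacency[i]).tolist())


@dataclass(frozen=True)
class RegionSummary:
    """Approximation regions and the uncertainty measures derived from them."""

    lower: dict      # class -> frozenset of sample indices
    upper: dict      # class -> frozenset of sample indices
    positive: frozenset
    boundary: frozenset
    negative: frozenset
    precision: float   # ρ
    roughness: float   # r = 1 − ρ
    K: float           # (1 − ρ)·|Pos|/|U|, the roughness-weighted dependency
    K_classic: float   # |Pos|/|U|


def pairwise_distance(ds: ExpressionDataset, B, metric: str = "euclidean",
                      p: float = 2.0) -> np.ndarray:
    """Sample-by-sample Minkowski distance table under attribute subset B.

    Δ(x_i, x_j) = (Σ_{a∈B} |f(x_i,a) − f(x_j,a)|^p)^{1/p}, with p = 2 for
    ``euclidean`` and p = 1 for ``manhattan``. Requires p ≥ 1 so the
    triangle inequality holds.
    """
    B = list(B)
    if not B:
        raise ValueError("attribute subset B must be nonempty")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    X = ds.matrix[:, ds.positions(B)]
    if metric == "euclidean":
        return cdist(X, X, metric="euclidean")
    if metric == "manhattan":
        return cdist(X, X, metric="cityblock")
    if p < 1:
        raise ValueError(f"p must be >= 1 (triangle inequality), got {p}")
    return cdist(X, X, metric="minkowski", p=p)


def build_neighborhoods(ds: ExpressionDataset, B, beta: float,
                        metric: str = "euclidean", p: float = 2.0
                        ) -> NeighborhoodModel:
    """β-neighborhood of every sample: all samples within radius β, inclusive."""
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    d = pairwise_distance(ds, B, metric, p)
    return NeighborhoodModel(float(beta), metric, float(p), tuple(B), d <= beta)


def compute_regions(nm: NeighborhoodModel, labels) -> RegionSummary:
    """Lower/upper approximations per class and the derived measures."""
    labels = np.asarray(labels)
    n = nm.adjacency.shape[0]
    if labels.shape[0] != n:
        raise ValueError(
            f"{labels.shape[0]} labels for {n} samples in the neighborhood model"
        )
    lower, upper = {}, {}
    for c in np.unique(labels):
        in_class = labels == c
        # β(x) ⊆ X_c  <=>  no neighbor outside the class
        lo = ~(nm.adjacency & ~in_class[None, :]).any(axis=1)
        # β(x) ∩ X_c ≠ ∅
        up = (nm.adjacency & in_class[None, :]).any(axis=1)
        lower[c] = frozenset(np.flatnonzero(lo).tolist())
        upper[c] = frozenset(np.flatnonzero(up).tolist())
    pos = frozenset().union(*lower.values())
    upper_union = frozenset().union(*upper.values())
    boundary = upper_union - pos
    negative = frozenset(range(n)) - upper_union
    rho = len(pos) / len(upper_union)
    r = 1.0 - rho
    pos_frac = len(pos) / n
    return RegionSummary(lower, upper, pos, boundary, negative,
                         rho, r, r * pos_frac, pos_frac)


def dependency(ds: ExpressionDataset, B, beta: float, metric: str = "euclidean",
               labels=None, p: float = 2.0, variant: str = "paper") -> float:
    """Dependency K(B, D) of the decision on attribute subset B.

    K(∅, D) = 0 by convention. ``variant`` selects the roughness-weighted
    form (``paper``) or the plain positive-region fraction (``classic``).
    """
    if variant not in {"paper", "classic"}:
        raise ValueError(f"variant must be 'paper' or 'classic', got {variant!r}")
    if not list(B):
        return 0.0
    labels = ds.labels if labels is None else labels
    rs = compute_regions(build_neighborhoods(ds, B, beta, metric, p), labels)
    return rs.K if variant == "paper" else rs.K_classic


def sig_inner(ds: ExpressionDataset, a, B, beta: float, metric: str = "euclidean",
              labels=None, p: float = 2.0, variant: str = "paper") -> float:
    """Internal significance of a within B: K(B, D) − K(B−{a}, D).

    May be negative under the roughness-weighted measure, which is not
    monotone in B. B−{a} = ∅ uses the K(∅, D) = 0 convention.
    """
    B = list(B)
    if a not in B:
        raise ValueError(f"attribute {a!r} is not in B")
    rest = [x for x in B if x != a]
    return (dependency(ds, B, beta, metric, labels, p, variant)
            - dependency(ds, rest, beta, metric, labels, p, variant))


def sig_outer(ds: ExpressionDataset, a, B, beta: float, metric: str = "euclidean",
              labels=None, p: float = 2.0, variant: str = "paper") -> float:
    """External significance of a outside B: K(B∪{a}, D) − K(B, D)."""
    B = list(B)
    if a in B:
        raise ValueError(f"attribute {a!r} is already in B")
    return (dependency(ds, B + [a], beta, metric, labels, p, variant)
            - dependency(ds, B, beta, metric, labels, p, variant))
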