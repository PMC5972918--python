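"""Greedy forward construction of a neighborhood-rough-set reduct.

The procedure starts from the core — attributes whose individual removal
from the full candidate set C drops the dependency by more than the
significance floor ε — and then repeatedly adds the candidate with the
largest external significance until the dependency of the growing subset
matches the full-set dependency K(C, D) within ε, the pool is exhausted,
progress stalls, or an iteration cap is hit.

The stopping target K_full = K(C, D) is computed once on the initial
candidate set and frozen: removing chosen attributes from the pool never
changes the target, only the pool. A drifting target would make the stop
condition ill-defined.

Because the roughness-weighted dependency is non-monotone, the target may
be unreachable; a three-iteration no-progress guard (no candidate moves K
by more than ε) plus the pool/iteration caps guarantee termination with a
reported stop reason. Ties on significance break toward the lowest column
index, so the whole procedure is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import ExpressionDataset
from . import nrs

logger = logging.getLogger(__name__)

__all__ = ["ReductionResult", "find_core", "forward_reduce", "verify_reduct",
           "backward_prune"]

DEFAULT_EPSILON = 1e-5  # significance floor

_STAGNATION_LIMIT = 3


@dataclass(frozen=True)
class ReductionResult:
    """Outcome of a greedy reduct search.

    ``trace`` holds one record per forward addition (after the core):
    the number of candidates scored, the chosen attribute, its external
    significance, and K(red, D) after the addition.
    """

    red: tuple              # ordered selected attribute ids
    core: tuple             # indispensable attributes, ascending column order
    trace: tuple            # per-iteration dicts
    K_full: float           # frozen target K(C, D)
    K_red: float            # dependency of the final selection
    stop_reason: str        # target-reached | pool-exhausted | stagnation | max-iterations
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "red": list(self.red),
            "core": list(self.core),
            "trace": [dict(t) for t in self.trace],
            "K_full": self.K_full,
            "K_red": self.K_red,
            "stop_reason": self.stop_reason,
            "config": dict(self.config),
        }


def _dep(ds, B, cfg):
    return nrs.dependency(ds, B, cfg["beta"], cfg["metric"], None, cfg["p"],
                          cfg["variant"])


def find_core(ds: ExpressionDataset, C, beta: float, metric: str = "euclidean",
              labels=None, epsilon: float = DEFAULT_EPSILON, p: float = 2.0,
              variant: str = "paper") -> list:
    """Attributes of C whose internal significance exceeds ε.

    Returned in ascending column order (deterministic). These are the
    indispensable attributes: any reduct must contain them.
    """
    C = list(C)
    if not C:
        raise ValueError("candidate set C must be nonempty")
    order = np.argsort(ds.positions(C), kind="stable")
    core = []
    for idx in order:
        a = C[int(idx)]
        s = nrs.sig_inner(ds, a, C, beta, metric, labels, p, variant)
        if s > epsilon:
            core.append(a)
    return core


def forward_reduce(ds: ExpressionDataset, C, beta: float,
                   metric: str = "euclidean", labels=None,
                   epsilon: float = DEFAULT_EPSILON, max_iter: int | None = None,
                   p: float = 2.0, variant: str = "paper",
                   prune: bool = False) -> ReductionResult:
    """Greedy forward reduct search over candidate set C.

    Never raises once C is valid: degenerate inputs yield a result whose
    ``stop_reason`` explains the exit. ``prune=True`` applies a backward
    pass removing attributes whose internal significance is ≤ ε, which
    enforces the second reduct condition (no individually removable
    member).
    """
    C = list(C)
    if not C:
        raise ValueError("candidate set C must be nonempty")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if max_iter is None:
        max_iter = len(C)
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    cfg = {"beta": float(beta), "metric": metric, "p": float(p),
           "variant": variant, "epsilon": float(epsilon),
           "max_iter": int(max_iter), "prune": bool(prune)}
    if labels is not None:
        ds = ExpressionDataset(ds.matrix, labels, ds.attribute_ids, ds.sample_ids)

    K_full = _dep(ds, C, cfg)  # frozen target, never recomputed
    core = find_core(ds, C, beta, metric, None, epsilon, p, variant)
    red = list(core)
    pool = [a for a in C if a not in red]
    trace = []
    K_red = _dep(ds, red, cfg)
    stop = None
    stagnant = 0
    it = 0
    while True:
        if abs(K_red - K_full) <= epsilon:
            stop = "target-reached"
            break
        if not pool:
            stop = "pool-exhausted"
            break
        if it >= max_iter:
            stop = "max-iterations"
            break
        # score every remaining candidate; ties -> lowest column index
        gains = np.array([
            nrs.sig_outer(ds, a, red, beta, metric, None, p, variant)
            for a in pool
        ])
        pool_pos = ds.positions(pool)
        best = min(range(len(pool)), key=lambda i: (-gains[i], pool_pos[i]))
        a_k = pool.pop(best)
        red.append(a_k)
        K_red = _dep(ds, red, cfg)
        trace.append({
            "iteration": it + 1,
            "candidates_evaluated": len(gains),
            "chosen": a_k,
            "sig_outer": float(gains[best]),
            "K_red": float(K_red),
        })
        stagnant = stagnant + 1 if np.all(np.abs(gains) <= epsilon) else 0
        it += 1
        if stagnant >= _STAGNATION_LIMIT:
            stop = "stagnation"
            break
    logger.info("forward_reduce: |red|=%d stop=%s K_red=%.6f K_full=%.6f",
                len(red), stop, K_red, K_full)
    if prune and red:
        red = backward_prune(ds, red, beta, metric, None, epsilon, p, variant,
                             protect=core)
        K_red = _dep(ds, red, cfg)
    return ReductionResult(tuple(red), tuple(core), tuple(trace),
                           float(K_full), float(K_red), stop, cfg)


def backward_prune(ds: ExpressionDataset, B, beta: float,
                   metric: str = "euclidean", labels=None,
                   epsilon: float = DEFAULT_EPSILON, p: float = 2.0,
                   variant: str = "paper", protect=()) -> list:
    """Remove attributes with internal significance ≤ ε until none remain.

    Greedy additions can be individually redundant in hindsight; this pass
    restores the no-removable-member property. ``protect`` (normally the
    core) is never removed. Selection order of survivors is preserved.
    """
    B = list(B)
    protect = set(protect)
    changed = True
    while changed and len(B) > 1:
        changed = False
        # examine later picks first so earlier selections survive ties
        for a in reversed(B):
            if a in protect or len(B) == 1:
                continue
            s = nrs.sig_inner(ds, a, B, beta, metric, labels, p, variant)
            if s <= epsilon:
                B.remove(a)
                changed = True
    return B


def verify_reduct(ds: ExpressionDataset, B, C, beta: float,
                  metric: str = "euclidean", labels=None,
                  epsilon: float = DEFAULT_EPSILON, p: float = 2.0,
                  variant: str = "paper"):
    """Check the two reduct conditions for B ⊆ C.

    condition1: K(B, D) matches K(C, D) within ε (dependency preserved);
    condition2: every member's removal drops K by more than ε (no
    redundant member). Returns (is_reduct, condition1, condition2).
    """
    B, C = list(B), list(C)
    if not set(B) <= set(C):
        raise ValueError("B must be a subset of C")
    KB = nrs.dependency(ds, B, beta, metric, labels, p, variant)
    KC = nrs.dependency(ds, C, beta, metric, labels, p, variant)
    condition1 = abs(KB - KC) <= epsilon
    condition2 = bool(B) and all(
        nrs.sig_inner(ds, a, B, beta, metric, labels, p, variant) > epsilon
        for a in B
    )
    return condition1 and condition2, condition1, condition2
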