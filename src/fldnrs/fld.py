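"""Fisher linear discriminant stage.

Two complementary uses of the Fisher criterion live here:

* the full multivariate discriminant — between/within-class scatter
  matrices S_B and S_W, the generalized eigenproblem S_W^{-1} S_B w = λ w,
  and the projection X' = WᵀX onto the leading discriminant directions;
* the per-gene Fisher score — the same Rayleigh quotient evaluated one
  attribute at a time, used to rank original genes and keep the top M as
  the candidate subset for the rough-set reduction stage. Ranking (rather
  than projecting) preserves original gene identities, which is what a
  gene-selection result must report.

With far more genes than samples S_W is singular (rank ≤ n − c); a small
ridge is added before inversion, see :func:`solve_fld`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .dataset import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ScatterPair",
    "ProjectionModel",
    "compute_scatter",
    "fisher_criterion",
    "solve_fld",
    "project",
    "fisher_score_per_gene",
    "select_top_genes",
]


@dataclass(frozen=True)
class ScatterPair:
    """Between-class (S_B) and within-class (S_W) scatter matrices.

    S_B = Σ_i n_i (μ_i − μ)(μ_i − μ)ᵀ and
    S_W = Σ_i Σ_{x∈ω_i} (x − μ_i)(x − μ_i)ᵀ, where μ_i are the class
    centroids and μ the global centroid. Their sum equals the total
    scatter Σ_j (x_j − μ)(x_j − μ)ᵀ, and rank(S_B) ≤ c − 1.
    """

    S_B: np.ndarray
    S_W: np.ndarray
    class_centroids: np.ndarray  # (c, T)
    global_centroid: np.ndarray  # (T,)
    class_sizes: np.ndarray      # (c,)
    n_samples: int


@dataclass(frozen=True)
class ProjectionModel:
    """Top-k eigenpairs of the (regularized) discriminant eigenproblem.

    Columns of ``W`` are unit-norm eigenvectors with the sign fixed so the
    largest-magnitude component is positive; ``regularization`` records
    the ridge γ that was actually added to S_W.
    """

    W: np.ndarray           # (T, k)
    eigenvalues: np.ndarray  # (k,), descending
    k: int
    regularization: float


def compute_scatter(ds: ExpressionDataset) -> ScatterPair:
    """Class centroids and the between/within-class scatter matrices."""
    classes = ds.classes
    if classes.size < 2:
        raise ValueError("Fisher criterion needs at least 2 classes")
    X = ds.matrix
    mu = X.mean(axis=0)
    centroids = np.empty((classes.size, X.shape[1]))
    sizes = np.empty(classes.size, dtype=int)
    T = X.shape[1]
    S_B = np.zeros((T, T))
    S_W = np.zeros((T, T))
    for i, c in enumerate(classes):
        Xi = X[ds.labels == c]
        sizes[i] = Xi.shape[0]
        mi = Xi.mean(axis=0)
        centroids[i] = mi
        d = mi - mu
        S_B += sizes[i] * np.outer(d, d)
        R = Xi - mi
        S_W += R.T @ R
    return ScatterPair(S_B, S_W, centroids, mu, sizes, X.shape[0])


def fisher_criterion(sp: ScatterPair, w: np.ndarray):
    """Between/within scatter of the projection onto ``w`` and their ratio.

    Returns (J_B, J_W, ratio) with J_B = wᵀS_B w / n, J_W = wᵀS_W w / n.
    The ratio is invariant to rescaling of ``w``.
    """
    w = np.asarray(w, dtype=float)
    if not np.any(w):
        raise ValueError("direction w must be nonzero")
    n = sp.n_samples
    J_B = float(w @ sp.S_B @ w) / n
    J_W = float(w @ sp.S_W @ w) / n
    if J_W <= 0:
        raise ValueError("degenerate direction: w'S_W w = 0, ratio undefined")
    return J_B, J_W, J_B / J_W


def _auto_gamma(S_W: np.ndarray) -> float:
    T = S_W.shape[0]
    return 1e-6 * float(np.trace(S_W)) / T


def solve_fld(sp: ScatterPair, k: int = 1, gamma="auto") -> ProjectionModel:
    """Solve S_W^{-1} S_B w = λ w, keeping the k largest eigenvalues.

    When S_W is numerically singular (the usual case with more genes than
    samples) a ridge γ·I is added first; ``gamma="auto"`` uses
    γ = 1e-6 · trace(S_W)/T. Solved as the symmetric-definite generalized
    problem S_B w = λ (S_W + γI) w, so eigenvalues are real and
    nonnegative up to round-off.
    """
    T = sp.S_W.shape[0]
    if not 1 <= k <= T:
        raise ValueError(f"k must be in [1, {T}], got {k}")
    # rank check: the unregularized inverse exists only for nonsingular S_W
    rank = np.linalg.matrix_rank(sp.S_W, hermitian=True)
    if rank == T:
        g = 0.0
    else:
        g = _auto_gamma(sp.S_W) if gamma == "auto" else float(gamma)
        if g <= 0:
            raise ValueError("S_W is singular; a positive ridge gamma is required")
    if not np.any(sp.S_B):
        logger.warning("S_B is zero (all class centroids coincide); "
                       "returning canonical basis vectors with zero eigenvalues")
        W = np.eye(T)[:, :k]
        return ProjectionModel(W, np.zeros(k), k, g)
    SWg = sp.S_W + g * np.eye(T)
    evals, evecs = scipy.linalg.eigh(sp.S_B, SWg)
    order = np.argsort(evals)[::-1][:k]
    evals = np.clip(evals[order], 0.0, None)
    W = evecs[:, order]
    W = W / np.linalg.norm(W, axis=0)
    # deterministic sign: largest-magnitude component positive
    for j in range(W.shape[1]):
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return ProjectionModel(W, evals, k, g)


def project(ds: ExpressionDataset, pm: ProjectionModel) -> ExpressionDataset:
    """Project samples onto the discriminant directions: X' = WᵀX.

    Returns an n_samples x k dataset with synthetic attribute ids
    ``fld_1 … fld_k``; labels are carried through unchanged.
    """
    if pm.W.shape[0] != ds.n_attributes:
        raise ValueError(
            f"projection expects {pm.W.shape[0]} attributes, dataset has "
            f"{ds.n_attributes}"
        )
    return ExpressionDataset(
        ds.matrix @ pm.W,
        ds.labels,
        tuple(f"fld_{j + 1}" for j in range(pm.k)),
        ds.sample_ids,
    )


def fisher_score_per_gene(ds: ExpressionDataset) -> np.ndarray:
    """Univariate Fisher score per attribute.

    score(g) = Σ_i n_i (μ_{i,g} − μ_g)² / Σ_i Σ_{x∈ω_i} (x_g − μ_{i,g})²,
    i.e. the single discriminant eigenvalue of the one-column problem. A
    gene whose class means differ but whose within-class variance is zero
    scores +inf (perfect separator) and ranks first.
    """
    classes = ds.classes
    if classes.size < 2:
        raise ValueError("Fisher score needs at least 2 classes")
    X = ds.matrix
    mu = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c in classes:
        Xi = X[ds.labels == c]
        mi = Xi.mean(axis=0)
        between += Xi.shape[0] * (mi - mu) ** 2
        within += ((Xi - mi) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = between / within
    degenerate = (within == 0) & (between > 0)
    if degenerate.any():
        ids = [ds.attribute_ids[j] for j in np.flatnonzero(degenerate)]
        logger.info("genes with zero within-class variance rank first: %s", ids)
        score[degenerate] = np.inf
    score[(within == 0) & (between == 0)] = 0.0
    return score


def select_top_genes(scores: np.ndarray, M: int, attribute_ids=None) -> list:
    """Ids of the M highest-scoring attributes, descending score order.

    Ties break toward the lower column index. ``attribute_ids`` defaults
    to 1-based position strings.
    """
    scores = np.asarray(scores, dtype=float)
    if not 1 <= M <= scores.size:
        raise ValueError(f"M must be in [1, {scores.size}], got {M}")
    if attribute_ids is None:
        attribute_ids = [str(j + 1) for j in range(scores.size)]
    # stable sort on negated scores implements the index tie-break
    order = np.argsort(-scores, kind="stable")[:M]
    return [attribute_ids[j] for j in order]
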