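"""High-level modelling interface: build a selector from data, fit, inspect.

``FLDNRSModel`` wraps the whole two-stage gene-selection procedure —
Fisher-score filtering to a candidate subset, then greedy
neighborhood-rough-set reduction — behind a construct/fit/results
workflow. ``fit()`` returns an :class:`FLDNRSResults` carrying the
selected genes, the per-step dependency trace, diagnostics and a
``summary()`` table; cross-validated evaluation and trace plotting hang
off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dataset as ds_mod
from . import evaluate as ev_mod
from . import fld as fld_mod
from . import reduction as red_mod
from .dataset import ExpressionDataset

__all__ = ["FLDNRSModel", "FLDNRSResults"]


class FLDNRSModel:
    """Two-stage gene selector for a labelled expression matrix.

    Parameters
    ----------
    data : ExpressionDataset
        Samples x genes with one class label per sample.
    beta : float
        Neighborhood radius in normalized attribute space.
    epsilon : float
        Significance floor; also the tolerance of the stopping rule.
    metric, p : str, float
        Minkowski metric for neighborhoods.
    fld_mode : {"score", "projection", "off"}
        ``score`` ranks original genes by univariate Fisher score and
        keeps the top ``top_m`` as candidates (default; preserves gene
        identities). ``projection`` replaces genes by the top-``k``
        discriminant projections. ``off`` skips the filter: all genes are
        candidates (pure rough-set selection).
    top_m : int
        Candidate-set size in ``score`` mode.
    k : int or None
        Retained directions in ``projection`` mode; default c − 1.
    normalize : {"minmax", "zscore", "none"}
        Per-gene scaling applied (after dropping constant columns) before
        distances are computed. One shared radius is only meaningful on
        commensurable scales, hence min-max by default.
    dependency : {"paper", "classic"}
        Roughness-weighted dependency (1−ρ)·|Pos|/|U|, or the plain
        positive-region fraction |Pos|/|U| (monotone; recommended for
        routine use).
    """

    def __init__(self, data: ExpressionDataset, *, beta: float = 0.15,
                 epsilon: float = red_mod.DEFAULT_EPSILON,
                 metric: str = "euclidean", p: float = 2.0,
                 fld_mode: str = "score", top_m: int = 50, k: int | None = None,
                 gamma="auto", normalize: str = "minmax",
                 dependency: str = "paper", max_iter: int | None = None,
                 prune: bool = False):
        if fld_mode not in {"score", "projection", "off"}:
            raise ValueError(f"fld_mode must be score|projection|off, got {fld_mode!r}")
        if normalize not in {"minmax", "zscore", "none"}:
            raise ValueError(f"normalize must be minmax|zscore|none, got {normalize!r}")
        self.data = data
        self.beta = float(beta)
        self.epsilon = float(epsilon)
        self.metric = metric
        self.p = float(p)
        self.fld_mode = fld_mode
        self.top_m = int(top_m)
        self.k = k
        self.gamma = gamma
        self.normalize = normalize
        self.dependency = dependency
        self.max_iter = max_iter
        self.prune = prune

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label",
                       **kwargs) -> "FLDNRSModel":
        """Build from a samples x genes DataFrame with a label column."""
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not in DataFrame")
        labels = df[label_column].to_numpy()
        mat = df.drop(columns=[label_column])
        data = ExpressionDataset(mat.to_numpy(dtype=float), labels,
                                 tuple(str(c) for c in mat.columns),
                                 tuple(str(i) for i in df.index))
        return cls(data, **kwargs)

    # -- pipeline stages -------------------------------------------------

    def _preprocess(self):
        ds, removed = ds_mod.drop_constant_columns(self.data)
        if self.normalize == "minmax":
            ds = ds_mod.minmax_normalize(ds)
        elif self.normalize == "zscore":
            ds = ds_mod.zscore_normalize(ds)
        return ds, removed

    def _candidates(self, ds: ExpressionDataset):
        """Apply the discriminant filter; return (working dataset, C, scores)."""
        if self.fld_mode == "off":
            return ds, list(ds.attribute_ids), None
        if self.fld_mode == "score":
            scores = fld_mod.fisher_score_per_gene(ds)
            m = min(self.top_m, ds.n_attributes)
            C = fld_mod.select_top_genes(scores, m, list(ds.attribute_ids))
            return ds, C, scores
        k = self.k if self.k is not None else max(1, ds.n_classes - 1)
        sp = fld_mod.compute_scatter(ds)
        pm = fld_mod.solve_fld(sp, k=k, gamma=self.gamma)
        proj = fld_mod.project(ds, pm)
        # projected coordinates are re-scaled so one beta still applies
        proj, _ = ds_mod.drop_constant_columns(proj)
        if self.normalize == "minmax":
            proj = ds_mod.minmax_normalize(proj)
        elif self.normalize == "zscore":
            proj = ds_mod.zscore_normalize(proj)
        return proj, list(proj.attribute_ids), pm.eigenvalues

    def fit(self) -> "FLDNRSResults":
        """Run preprocessing, the discriminant filter and the reduction."""
        ds, removed = self._preprocess()
        work, C, scores = self._candidates(ds)
        res = red_mod.forward_reduce(
            work, C, self.beta, self.metric, None, self.epsilon,
            self.max_iter, self.p, self.dependency, self.prune)
        return FLDNRSResults(self, work, res, tuple(C), removed,
                             None if scores is None else np.asarray(scores))


@dataclass
class FLDNRSResults:
    """Fitted selection: the reduct, its provenance and diagnostics."""

    model: FLDNRSModel
    working_data: ExpressionDataset
    reduction: red_mod.ReductionResult
    candidates: tuple
    removed_constant: list
    fisher_scores: np.ndarray | None = None

    @property
    def selected(self) -> tuple:
        """Selected attribute ids, in selection order."""
        return self.reduction.red

    @property
    def core(self) -> tuple:
        return self.reduction.core

    @property
    def K_red(self) -> float:
        return self.reduction.K_red

    @property
    def K_full(self) -> float:
        return self.reduction.K_full

    @property
    def stop_reason(self) -> str:
        return self.reduction.stop_reason

    def trace_frame(self) -> pd.DataFrame:
        """Per-iteration forward-search trace as a DataFrame."""
        return pd.DataFrame([dict(t) for t in self.reduction.trace])

    def evaluate(self, classifier: str = "svm", folds=10, seed: int = 0,
                 data: ExpressionDataset | None = None) -> ev_mod.EvaluationReport:
        """Cross-validated accuracy of the selected subset.

        Projection-mode selections are evaluated on the projected working
        data; otherwise on ``data`` (default: the working data, so the
        evaluation sees the same normalization the selection saw).
        """
        ds = data if data is not None else self.working_data
        return ev_mod.cross_validate(ds, list(self.selected), classifier,
                                     folds, seed)

    def verify(self):
        """Reduct conditions of the selection against the candidate set."""
        m = self.model
        return red_mod.verify_reduct(
            self.working_data, list(self.selected), list(self.candidates),
            m.beta, m.metric, None, m.epsilon, m.p, m.dependency)

    def to_dict(self) -> dict:
        d = self.reduction.to_dict()
        d["candidates"] = list(self.candidates)
        d["removed_constant_columns"] = list(self.removed_constant)
        d["config"].update({
            "fld_mode": self.model.fld_mode, "top_m": self.model.top_m,
            "k": self.model.k, "normalize": self.model.normalize,
            "dependency": self.model.dependency,
        })
        return d

    def save(self, path) -> None:
        ds_mod.write_result(self, path)

    def summary(self) -> str:
        """Plain-text summary table of the fitted selection."""
        m = self.model
        lines = [
            "Gene selection via Fisher filtering + neighborhood rough set",
            "=" * 60,
            f"samples: {self.working_data.n_samples:>5}    "
            f"genes (after preprocessing): {self.working_data.n_attributes}",
            f"classes: {self.working_data.n_classes:>5}    "
            f"constant columns removed: {len(self.removed_constant)}",
            f"fld_mode: {m.fld_mode}   top_m: {m.top_m}   "
            f"normalize: {m.normalize}",
            f"metric: {m.metric} (p={m.p:g})   beta: {m.beta:g}   "
            f"epsilon: {m.epsilon:g}   dependency: {m.dependency}",
            "-" * 60,
            f"candidate set size |C|: {len(self.candidates)}",
            f"dependency target K(C,D): {self.K_full:.6f}",
            f"selected reduct size:     {len(self.selected)}",
            f"dependency K(red,D):      {self.K_red:.6f}",
            f"core size: {len(self.core)}   stop reason: {self.stop_reason}",
            "-" * 60,
            "selection order: " + ", ".join(map(str, self.selected)),
            "=" * 60,
        ]
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Dependency K(red, D) after each forward addition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tf = self.trace_frame()
        if not tf.empty:
            ax.plot(tf["iteration"], tf["K_red"], marker="o",
                    label="K(red, D)")
        ax.axhline(self.K_full, ls="--", color="gray", label="K(C, D) target")
        ax.set_xlabel("forward-search iteration")
        ax.set_ylabel("dependency K")
        ax.legend()
        return ax
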