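"""Synthetic expression matrices with planted ground truth.

Emulates the regime of public tumor microarray sets — few samples, many
genes, two classes — so the whole selection pipeline can be exercised and
scored without external downloads. Informative genes get a
class-conditional Gaussian mean shift of ``effect_size`` within-class
standard deviations; the rest are class-independent noise. Optional
extras mirror nuisances of real matrices: identically-zero columns and
blocks of near-duplicate (correlated) genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import ExpressionDataset

__all__ = ["SyntheticSpec", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Defaults follow the small-n / moderate-T two-class regime used
    throughout the package's own evaluation: 60 samples, 200 genes, 10
    informative with a 2-SD mean shift.
    """

    n_samples: int = 60
    n_genes: int = 200
    n_informative: int = 10
    class_proportions: tuple = (0.5, 0.5)
    effect_size: float = 2.0     # mean shift in within-class SD units
    noise_sd: float = 1.0
    n_zero_columns: int = 0
    correlation_block_size: int | None = None
    heavy_tails: bool = False    # Student-t (3 df) noise instead of Gaussian
    seed: int = 0

    def __post_init__(self):
        if self.n_informative + self.n_zero_columns > self.n_genes:
            raise ValueError("n_informative + n_zero_columns exceeds n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.ndim != 1 or props.size < 2 or (props <= 0).any() or \
                not np.isclose(props.sum(), 1.0):
            raise ValueError(
                "class_proportions must be >= 2 positive fractions summing to 1"
            )


def _class_counts(n: int, proportions) -> np.ndarray:
    """Largest-remainder apportionment of n samples over the classes."""
    props = np.asarray(proportions, dtype=float)
    raw = props * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    if (counts == 0).any():
        raise ValueError(f"a class received 0 of {n} samples; adjust proportions")
    return counts


def generate(spec: SyntheticSpec):
    """Draw one dataset from the spec.

    Returns ``(dataset, truth)`` where ``truth`` is the set of attribute
    ids of the planted informative genes. Column order is shuffled
    (seed-deterministically) so column position carries no information;
    zero columns are appended last to keep their ids predictable.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec.n_samples, spec.class_proportions)
    labels = np.repeat(np.arange(counts.size), counts)

    n_noise = spec.n_genes - spec.n_zero_columns
    if spec.heavy_tails:
        X = rng.standard_t(3, size=(spec.n_samples, n_noise)) * spec.noise_sd
    else:
        X = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, n_noise))

    # class-conditional shift for informative genes: class i mean = i * effect
    shift = spec.effect_size * spec.noise_sd
    X[:, :spec.n_informative] += np.outer(labels, np.ones(spec.n_informative)) * shift

    if spec.correlation_block_size:
        b = spec.correlation_block_size
        # duplicate each informative gene into a noisy block of b genes,
        # overwriting trailing noise columns
        avail = n_noise - spec.n_informative
        n_dup = min(spec.n_informative * (b - 1), avail)
        src = np.tile(np.arange(spec.n_informative), b - 1)[:n_dup]
        dup = X[:, src] + rng.normal(0, 0.1 * spec.noise_sd,
                                     size=(spec.n_samples, n_dup))
        X[:, n_noise - n_dup:] = dup

    perm = rng.permutation(n_noise)
    X = X[:, perm]
    truth_cols = np.flatnonzero(np.isin(perm, np.arange(spec.n_informative)))

    if spec.n_zero_columns:
        X = np.hstack([X, np.zeros((spec.n_samples, spec.n_zero_columns))])

    ids = tuple(str(j + 1) for j in range(spec.n_genes))
    ds = ExpressionDataset(X, labels, ids)
    truth = {ids[j] for j in truth_cols}
    return ds, truth
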