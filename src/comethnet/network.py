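"""Weighted co-methylation network: correlation adjacency and topological
overlap.

The adjacency between two genes is a transform of their Pearson correlation
across all samples (both cytosine-variant groups pooled), optionally raised
to a soft-threshold power.  The topological overlap measure (TOM) then
rewards gene pairs that share neighbours:

    TOM(i, j) = (sum_{v != i,j} A(i,v) A(j,v) + A(i,j))
                / (min(k_i, k_j) - A(i,j) + 1),        i != j
    TOM(i, i) = 1

with connectivity ``k_i = sum_{v != i} A(i, v)``.  For adjacency weights in
[0, 1] the TOM is also in [0, 1], and ``1 - TOM`` is the dissimilarity fed
to the clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import MethylationMatrix

__all__ = [
    "AdjacencyMatrix",
    "TOMMatrix",
    "DissimMatrix",
    "correlation_adjacency",
    "tom_similarity",
    "tom_dissimilarity",
]

_SYM_TOL = 1e-12
_RANGE_TOL = 1e-9

TRANSFORMS = ("abs", "signed_half", "clamp_zero")


def _check_square_symmetric(values: np.ndarray, name: str) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite entries")
    if np.abs(values - values.T).max() > _SYM_TOL:
        raise ValueError(f"{name} is not symmetric within {_SYM_TOL}")


@dataclass
class AdjacencyMatrix:
    """Symmetric gene x gene weights in [0, 1] with a zero diagonal
    (so connectivity sums exclude self-edges)."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_square_symmetric(self.values, "adjacency")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match matrix size")
        if self.values.min() < -_RANGE_TOL or self.values.max() > 1 + _RANGE_TOL:
            raise ValueError("adjacency entries must lie in [0, 1]")
        if np.abs(np.diag(self.values)).max() > 0:
            raise ValueError("adjacency diagonal must be zero")
        self.values = np.clip(self.values, 0.0, 1.0)


@dataclass
class TOMMatrix:
    """Topological overlap similarity; diagonal exactly 1."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_square_symmetric(self.values, "TOM")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match matrix size")
        if not np.all(np.diag(self.values) == 1.0):
            raise ValueError("TOM diagonal must be exactly 1")


@dataclass
class DissimMatrix:
    """Elementwise ``1 - TOM``; zero diagonal."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        _check_square_symmetric(self.values, "dissimilarity")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match matrix size")
        if np.abs(np.diag(self.values)).max() > 0:
            raise ValueError("dissimilarity diagonal must be zero")


def correlation_adjacency(
    m: MethylationMatrix,
    genes: list[str],
    transform: str = "abs",
    power: float = 1.0,
) -> AdjacencyMatrix:
    """Pearson-correlation adjacency over all samples for a gene set.

    ``transform`` maps signed correlations onto [0, 1]: ``abs`` -> |r|
    (unsigned network, the default), ``signed_half`` -> (1 + r) / 2,
    ``clamp_zero`` -> max(r, 0); the result is raised to ``power``.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a co-methylation network")
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")
    if power <= 0:
        raise ValueError("power must be positive")
    missing = [g for g in genes if g not in m.data.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    if len(set(genes)) != len(genes):
        raise ValueError("gene set contains duplicates")

    x = m.data.loc[genes].to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = [genes[i] for i in np.nonzero(sd == 0)[0]]
    if flat:
        raise ValueError(f"zero-variance genes: {flat[:5]}")

    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    if transform == "abs":
        a = np.abs(r)
    elif transform == "signed_half":
        a = (1.0 + r) / 2.0
    else:
        a = np.maximum(r, 0.0)
    a = a ** power
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(gene_ids=list(genes), values=a)


def tom_similarity(a: AdjacencyMatrix) -> TOMMatrix:
    """Weighted topological overlap of an adjacency matrix (see module
    docstring for the formula)."""
    A = a.values
    k = A.sum(axis=1)  # diagonal is zero, so this is sum over v != i
    shared = A @ A  # (i,j) term: sum_v A(i,v) A(j,v); v=i and v=j add zero
    numer = shared + A
    denom = np.minimum.outer(k, k) - A + 1.0
    t = numer / denom
    t = (t + t.T) / 2.0
    t = np.clip(t, 0.0, 1.0)
    np.fill_diagonal(t, 1.0)
    return TOMMatrix(gene_ids=list(a.gene_ids), values=t)


def tom_dissimilarity(t: TOMMatrix) -> DissimMatrix:
    """Elementwise ``1 - TOM`` with an exactly zero diagonal."""
    d = 1.0 - t.values
    np.fill_diagonal(d, 0.0)
    return DissimMatrix(gene_ids=list(t.gene_ids), values=d)
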