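"""Shared helpers: RNG handling, edge vectorization, correlation utilities."""

from __future__ import annotations

import numpy as np


def rng_from(seed) -> np.random.Generator:
    """Return a Generator; passes through an existing Generator unchanged."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seed(rng: np.random.Generator, lo: int = 0, hi: int = 2**31 - 1) -> int:
    return int(rng.integers(lo, hi))


def edge_index(n_nodes: int):
    """Canonical edge order: node pairs (i, j) with i < j, row-major.

    All modules that exchange vectorized connectivity features use this order,
    so feature k always refers to the same node pair.
    """
    return np.triu_indices(n_nodes, k=1)


def vectorize_edges(mat: np.ndarray) -> np.ndarray:
    i, j = edge_index(mat.shape[-1])
    return mat[..., i, j]


def unvectorize_edges(vec: np.ndarray, n_nodes: int) -> np.ndarray:
    i, j = edge_index(n_nodes)
    out = np.zeros(vec.shape[:-1] + (n_nodes, n_nodes), dtype=float)
    out[..., i, j] = vec
    out[..., j, i] = vec
    return out


def check_symmetric_zero_diag(mat: np.ndarray, name: str = "matrix", tol: float = 1e-10):
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square, got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=tol):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(mat), 0.0, atol=tol):
        raise ValueError(f"{name} must have a zero diagonal")


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(a, b)[0, 1])


def fisher_z(r) -> np.ndarray:
    r = np.clip(np.asarray(r, float), -1 + 1e-12, 1 - 1e-12)
    return np.arctanh(r)


def congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def zscore_cols(x: np.ndarray, mean=None, sd=None, ddof: int = 0):
    """Column z-score; returns (z, mean, sd). sd of 0 raises."""
    x = np.asarray(x, float)
    if mean is None:
        mean = np.nanmean(x, axis=0)
    if sd is None:
        sd = np.nanstd(x, axis=0, ddof=ddof)
    if np.any(sd == 0):
        raise ValueError("zero-variance column; z-score undefined")
    return (x - mean) / sd, mean, sd
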