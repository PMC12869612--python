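"""Shared numeric helpers: Fisher z, edge vectorization, seeding."""

from __future__ import annotations

from typing import Sequence

import numpy as np

#: correlations are clipped to this magnitude before atanh so degenerate
#: (perfectly correlated) windows map to a large finite z instead of +/-inf
R_CLIP = 1.0 - 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform atanh(r), with |r| clipped to R_CLIP."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def inverse_fisher_z(z: np.ndarray | float) -> np.ndarray | float:
    return np.tanh(z)


def n_edges(n: int) -> int:
    """Number of unordered node pairs m = n(n-1)/2."""
    return n * (n - 1) // 2


def vectorize_upper(mat: np.ndarray) -> np.ndarray:
    """Row-major upper triangle (k=1) of a square matrix as a 1-D vector."""
    mat = np.asarray(mat)
    n = mat.shape[0]
    iu = np.triu_indices(n, k=1)
    return mat[iu]


def unvectorize_upper(vec: np.ndarray, n: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`, producing a symmetric matrix."""
    vec = np.asarray(vec)
    if vec.size != n_edges(n):
        raise ValueError(f"vector length {vec.size} != n(n-1)/2 for n={n}")
    out = np.full((n, n), diag, dtype=float)
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


def edge_index_pairs(n: int) -> list[tuple[int, int]]:
    """(i, j) node pairs in the row-major upper-triangle order, i < j."""
    iu = np.triu_indices(n, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def edge_names(node_names: Sequence[str]) -> list[str]:
    """Edge labels '<A>-<B>' in upper-triangle order for named nodes."""
    return [f"{node_names[i]}-{node_names[j]}" for i, j in edge_index_pairs(len(node_names))]


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic stream of child seeds (< 2**31) from one parent seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def check_correlation_matrix(mat: np.ndarray, name: str = "matrix", atol: float = 1e-8) -> None:
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=atol):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=atol):
        raise ValueError(f"{name} must have unit diagonal")
    if np.any(np.abs(mat) > 1 + atol):
        raise ValueError(f"{name} entries must lie in [-1, 1]")


def nearest_correlation_psd(mat: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Eigenvalue-clipped projection to a positive semidefinite correlation matrix."""
    mat = np.asarray(mat, dtype=float)
    sym = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, eps, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out
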