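"""Derivation of GM and WM functional networks from static FC.

ROI-level static FC (full-scan Pearson correlation) is clustered with
K-means using correlation distance on each ROI's connectivity profile; the
number of networks is selected by a Dice-coefficient cross-validation over
co-clustering adjacency matrices: the FC matrix is clustered independently
in ``nf`` folds (distinct random initialization streams), ROI indices are
split into chunks of size ``cs``, and for every chunk pair the cs x cs
adjacency sub-blocks are compared across all fold pairs with the Dice
overlap.  The K at the highest (local-peak) mean Dice gives the most stable
partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from ._utils import check_correlation_matrix, spawn_seeds
from .cohort import TISSUES, CohortTimeSeries


@dataclass
class StaticFC:
    """Symmetric ROI correlation matrix for one tissue."""

    tissue: str
    matrix: np.ndarray
    scope: str = "subject"  # or "group-average"

    def validate(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        check_correlation_matrix(self.matrix, name=f"{self.tissue} sFC")


@dataclass
class NetworkPartition:
    """ROI -> network assignment for one tissue."""

    tissue: str
    k: int
    assignment: np.ndarray
    distortion: float

    def validate(self) -> None:
        sizes = np.bincount(self.assignment, minlength=self.k)
        if self.assignment.min() < 0 or self.assignment.max() >= self.k:
            raise ValueError("assignment indices out of range")
        if np.any(sizes == 0):
            raise ValueError(f"network {int(np.argmin(sizes))} is empty")

    @property
    def network_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)


@dataclass
class StabilityProfile:
    """Mean Dice stability per candidate K, and the selected K."""

    k_values: np.ndarray
    dice_per_k: np.ndarray
    nf: int
    cs: int
    n_replications: int
    selected_k: int


def compute_static_fc(
    series: np.ndarray,
    tissue: str = "GM",
    roi_tissue: np.ndarray | None = None,
) -> StaticFC:
    """Full-length Pearson correlation among ROIs of one tissue.

    ``series`` is an ROI x time matrix.  If ``roi_tissue`` is given, rows are
    restricted to ROIs whose label equals ``tissue``.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a 2-D ROI x time matrix")
    if roi_tissue is not None:
        series = series[np.asarray(roi_tissue) == tissue]
    if series.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    sd = series.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(f"zero-variance ROI at index {int(np.argmax(sd == 0))}")
    mat = np.corrcoef(series)
    np.fill_diagonal(mat, 1.0)
    return StaticFC(tissue=tissue, matrix=mat, scope="subject")


def average_fc(fcs: Sequence[StaticFC]) -> StaticFC:
    """Entrywise mean of same-tissue FC matrices (the group-average sFC)."""
    if not fcs:
        raise ValueError("no matrices to average")
    tissue = fcs[0].tissue
    shape = fcs[0].matrix.shape
    for fc in fcs:
        if fc.tissue != tissue:
            raise ValueError(f"mixed tissues: {fc.tissue!r} vs {tissue!r}")
        if fc.matrix.shape != shape:
            raise ValueError("FC matrices differ in dimension")
    mean = np.mean([fc.matrix for fc in fcs], axis=0)
    np.fill_diagonal(mean, 1.0)
    return StaticFC(tissue=tissue, matrix=mean, scope="group-average")


def _standardize_rows(mat: np.ndarray) -> np.ndarray:
    """Center and scale rows so squared Euclidean distance tracks 1 - Pearson."""
    x = mat - mat.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant connectivity profile; correlation distance undefined")
    return x / sd


def _relabel_first_occurrence(labels: np.ndarray) -> np.ndarray:
    """Canonical labels: clusters numbered by first appearance order."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def kmeans_partition(
    fc: StaticFC,
    k: int,
    n_replications: int = 50,
    seed: int = 0,
) -> NetworkPartition:
    """Cluster ROI connectivity profiles into ``k`` networks.

    Correlation distance is realised as squared Euclidean distance on
    row-standardized profiles; the best of ``n_replications`` k-means++
    runs (lowest distortion) is kept.  Deterministic for a fixed seed, and
    the replication seed stream is prefix-stable, so distortion is
    non-increasing in ``n_replications``.
    """
    n_roi = fc.matrix.shape[0]
    if not (2 <= k <= n_roi):
        raise ValueError(f"need 2 <= k <= n_roi, got k={k}, n_roi={n_roi}")
    x = _standardize_rows(fc.matrix)
    best = None
    for child in spawn_seeds(seed, n_replications):
        km = KMeans(n_clusters=k, n_init=1, init="k-means++", random_state=child)
        km.fit(x)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    labels = _relabel_first_occurrence(best.labels_)
    part = NetworkPartition(
        tissue=fc.tissue, k=k, assignment=labels, distortion=float(best.inertia_)
    )
    part.validate()
    return part


def coassignment_adjacency(assignment: np.ndarray) -> np.ndarray:
    """Binary adjacency: a(i, j) = 1 iff ROIs i and j share a cluster."""
    a = np.asarray(assignment)
    return (a[:, None] == a[None, :]).astype(np.uint8)


def dice_adjacency(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a AND b| / (|a| + |b|) over off-diagonal entries.

    Returns 1.0 when both matrices are empty (all-zero) by convention.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("adjacency matrices must be binary")
    mask = ~np.eye(a.shape[0], dtype=bool) if a.ndim == 2 and a.shape[0] == a.shape[1] else None
    return _dice_counts(a.astype(bool), b.astype(bool), mask)


def _dice_counts(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None) -> float:
    if mask is not None:
        a = a[mask]
        b = b[mask]
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def stability_select_k(
    fc: StaticFC,
    k_range: Sequence[int],
    nf: int = 8,
    cs: int = 30,
    n_replications: int = 50,
    seed: int = 0,
) -> StabilityProfile:
    """Dice cross-validation of K-means partitions over candidate K.

    For each K: the FC matrix is clustered ``nf`` times with independent
    initialization streams; co-clustering adjacency matrices are built; ROI
    indices are randomly permuted and split into chunks of size ``cs``; for
    every unordered chunk pair the cs x cs adjacency sub-blocks are compared
    across all unordered fold pairs with the Dice coefficient (cells on the
    ROI self-diagonal excluded); the mean over chunk and fold pairs is the
    stability at K.  The selected K is the local-peak maximum of the Dice
    curve (global argmax if no interior local maximum exists).
    """
    n_roi = fc.matrix.shape[0]
    k_values = np.asarray(sorted(int(k) for k in k_range))
    if k_values.size == 0:
        raise ValueError("empty k_range")
    if nf < 2:
        raise ValueError("need nf >= 2 folds")
    if cs > n_roi:
        raise ValueError(f"chunk size {cs} exceeds n_roi {n_roi}")
    if k_values[0] < 2 or k_values[-1] > n_roi - 1:
        raise ValueError("k_range must lie within [2, n_roi - 1]")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_roi)
    n_chunks = n_roi // cs
    chunks = [perm[i * cs : (i + 1) * cs] for i in range(n_chunks)]
    fold_seeds_per_k = {
        int(k): spawn_seeds(int(rng.integers(2**31 - 1)), nf) for k in k_values
    }

    dice_per_k = np.empty(k_values.size)
    for ki, k in enumerate(k_values):
        adjacencies = []
        for fs in fold_seeds_per_k[int(k)]:
            # each fold randomizes both the initialization stream and the ROI
            # presentation order; the latter breaks exact floating-point ties
            # between symmetric local optima that would otherwise make an
            # ambiguous merge look perfectly reproducible
            fold_rng = np.random.default_rng(fs)
            order = fold_rng.permutation(n_roi)
            fold_fc = StaticFC(fc.tissue, fc.matrix[np.ix_(order, order)], fc.scope)
            labels_perm = kmeans_partition(fold_fc, int(k), n_replications, seed=fs).assignment
            labels = np.empty(n_roi, dtype=int)
            labels[order] = labels_perm
            adjacencies.append(coassignment_adjacency(labels))
        scores = []
        for ci in range(n_chunks):
            for cj in range(ci, n_chunks):
                rows, cols = chunks[ci], chunks[cj]
                mask = rows[:, None] != cols[None, :]  # drop ROI self-pairs
                blocks = [adj[np.ix_(rows, cols)].astype(bool) for adj in adjacencies]
                for f in range(nf):
                    for g in range(f + 1, nf):
                        scores.append(_dice_counts(blocks[f], blocks[g], mask))
        dice_per_k[ki] = float(np.mean(scores))

    selected = k_values[_local_peak_argmax(dice_per_k)]
    return StabilityProfile(
        k_values=k_values,
        dice_per_k=dice_per_k,
        nf=nf,
        cs=cs,
        n_replications=n_replications,
        selected_k=int(selected),
    )


def _local_peak_argmax(values: np.ndarray) -> int:
    """Index of the highest interior local maximum; global argmax fallback.

    Ties between equal peaks resolve to the smallest index.
    """
    if values.size < 3:
        return int(np.argmax(values))
    peaks = [
        i
        for i in range(1, values.size - 1)
        if values[i] >= values[i - 1] and values[i] >= values[i + 1]
    ]
    if not peaks:
        return int(np.argmax(values))
    best = max(peaks, key=lambda i: (values[i], -i))
    return int(best)


def extract_network_timecourses(
    cohort: CohortTimeSeries,
    gm: NetworkPartition,
    wm: NetworkPartition,
) -> tuple[np.ndarray, list[str]]:
    """Mean member-ROI time course per network, GM networks first.

    Returns an (n_subjects, K1 + K2, T) array and the network name list
    ``["GM1", ..., "WM1", ...]``.
    """
    gm_idx = cohort.tissue_indices("GM")
    wm_idx = cohort.tissue_indices("WM")
    if gm.assignment.size != gm_idx.size or wm.assignment.size != wm_idx.size:
        raise ValueError("partition does not cover its tissue's ROI set")
    names = [f"GM{i + 1}" for i in range(gm.k)] + [f"WM{i + 1}" for i in range(wm.k)]
    out = np.empty((cohort.n_subjects, gm.k + wm.k, cohort.n_timepoints))
    for net in range(gm.k):
        members = gm_idx[gm.assignment == net]
        out[:, net, :] = cohort.data[:, members, :].mean(axis=1)
    for net in range(wm.k):
        members = wm_idx[wm.assignment == net]
        out[:, gm.k + net, :] = cohort.data[:, members, :].mean(axis=1)
    return out, names
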