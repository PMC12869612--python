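"""Recurring FNC states: cosine K-means over pooled windows, elbow selection.

Windowed FNC vectors from all subjects are pooled (temporal order ignored)
and clustered with K-means under cosine distance; centroids are arithmetic
means of member windows (not re-normalized) and are the dFNC states.  The
number of states is chosen from the within/between cluster-distance ratio
curve at its point of maximum curvature (the elbow).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._utils import spawn_seeds
from .dfnc import WindowedFNC


@dataclass
class StateModel:
    """Group-level dFNC states and per-window assignments."""

    ks: int
    centroids: np.ndarray  # ks x m, z-scale
    labels: dict[str, np.ndarray]  # subject -> per-window state indices (0-based)
    distortion: float
    elbow_profile: "ElbowProfile | None" = None

    def pooled_labels(self) -> np.ndarray:
        return np.concatenate(list(self.labels.values()))


@dataclass
class ElbowProfile:
    """Within/between distance ratio per candidate number of states."""

    ks_values: np.ndarray
    ratio: np.ndarray
    selected_ks: int
    clear_elbow: bool = True


def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return x / norms


def _cosine_distances(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """1 - cosine similarity between each row of x and each centroid."""
    return 1.0 - _unit_rows(x) @ _unit_rows(centroids).T


def _kmeans_pp_init(x: np.ndarray, ks: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under cosine distance."""
    n = x.shape[0]
    centers = [x[rng.integers(n)]]
    for _ in range(1, ks):
        d = _cosine_distances(x, np.array(centers)).min(axis=1)
        d = np.clip(d, 0.0, None)
        total = d.sum()
        if total <= 0:
            centers.append(x[rng.integers(n)])
            continue
        centers.append(x[rng.choice(n, p=d / total)])
    return np.array(centers)


def _cosine_kmeans_once(
    x: np.ndarray, ks: int, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float]:
    centroids = _kmeans_pp_init(x, ks, rng)
    labels = np.full(x.shape[0], -1)
    for _ in range(max_iter):
        dist = _cosine_distances(x, centroids)
        new_labels = dist.argmin(axis=1)
        for c in range(ks):  # re-seed empty clusters at the worst-fit point
            if not np.any(new_labels == c):
                new_labels[dist.min(axis=1).argmax()] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(ks):
            centroids[c] = x[labels == c].mean(axis=0)
    distortion = float(_cosine_distances(x, centroids)[np.arange(x.shape[0]), labels].sum())
    return labels, centroids, distortion


def cluster_states(
    windowed: Sequence[WindowedFNC],
    ks: int,
    n_replications: int = 50,
    seed: int = 0,
) -> StateModel:
    """Cluster pooled windows into ``ks`` states (best of ``n_replications``)."""
    x = np.vstack([w.windows for w in windowed])
    if x.shape[0] < ks:
        raise ValueError("fewer pooled windows than requested states")
    if np.unique(x, axis=0).shape[0] < ks:
        raise ValueError("fewer distinct window vectors than requested states")
    if ks == 1:
        centroids = x.mean(axis=0, keepdims=True)
        labels_flat = np.zeros(x.shape[0], dtype=int)
        distortion = float(_cosine_distances(x, centroids)[:, 0].sum())
    else:
        best = None
        for child in spawn_seeds(seed, n_replications):
            res = _cosine_kmeans_once(x, ks, np.random.default_rng(child))
            if best is None or res[2] < best[2]:
                best = res
        labels_flat, centroids, distortion = best
    labels: dict[str, np.ndarray] = {}
    offset = 0
    for w in windowed:
        labels[w.subject] = labels_flat[offset : offset + w.n_windows].astype(int)
        offset += w.n_windows
    return StateModel(ks=ks, centroids=centroids, labels=labels, distortion=distortion)


def _within_between_ratio(
    x: np.ndarray, labels: np.ndarray, centroids: np.ndarray
) -> float:
    within = float(
        _cosine_distances(x, centroids)[np.arange(x.shape[0]), labels].mean()
    )
    ks = centroids.shape[0]
    pair = _cosine_distances(centroids, centroids)[np.triu_indices(ks, k=1)]
    between = float(pair.mean()) if pair.size else np.nan
    return within / between if between and between > 0 else np.inf


def elbow_select_ks(
    windowed: Sequence[WindowedFNC],
    ks_range: Sequence[int] = range(2, 16),
    n_replications: int = 20,
    seed: int = 0,
    return_profile: bool = False,
    flat_tol: float = 0.3,
):
    """Pick the number of states at the elbow of the within/between curve.

    The ratio of mean within-cluster distance to mean between-centroid
    distance is computed per candidate ks; the selected ks maximizes the
    discrete second difference (curvature) of the curve.  With fewer than 3
    candidates the curvature is undefined and the argmin of the ratio is
    returned.  A near-flat curve — relative range below ``flat_tol``, i.e.
    no pronounced drop anywhere — is flagged as having no clear elbow
    (genuinely clustered pools show drops of most of the curve's height).
    """
    ks_values = np.asarray(sorted(int(k) for k in ks_range))
    if ks_values.size == 0:
        raise ValueError("empty ks_range")
    x = np.vstack([w.windows for w in windowed])
    seeds = spawn_seeds(seed, ks_values.size)
    ratios = np.empty(ks_values.size)
    for i, ks in enumerate(ks_values):
        model = cluster_states(windowed, int(ks), n_replications, seed=seeds[i])
        ratios[i] = _within_between_ratio(x, model.pooled_labels(), model.centroids)
    span = ratios.max() - ratios.min()
    clear = bool(span > flat_tol * max(abs(ratios).max(), 1e-12))
    if ks_values.size < 3:
        sel = int(ks_values[int(np.argmin(ratios))])
    else:
        curvature = ratios[:-2] - 2 * ratios[1:-1] + ratios[2:]
        sel = int(ks_values[1 + int(np.argmax(curvature))])
    if not clear:
        warnings.warn("within/between ratio curve is nearly flat; no clear elbow")
    profile = ElbowProfile(ks_values=ks_values, ratio=ratios, selected_ks=sel, clear_elbow=clear)
    return (sel, profile) if return_profile else sel


def state_sfnc_correlation(model: StateModel, sfnc_mean: np.ndarray) -> np.ndarray:
    """Pearson correlation between each state centroid and the grand-mean sFNC."""
    sfnc_mean = np.asarray(sfnc_mean, dtype=float)
    if sfnc_mean.size != model.centroids.shape[1]:
        raise ValueError("sFNC vector length does not match centroid edge count")
    out = np.empty(model.ks)
    for s in range(model.ks):
        c = model.centroids[s]
        if c.std() == 0 or sfnc_mean.std() == 0:
            warnings.warn(f"zero-variance vector; correlation undefined for state {s + 1}")
            out[s] = np.nan
        else:
            out[s] = np.corrcoef(c, sfnc_mean)[0, 1]
    return out


def strongest_edges(
    centroid: np.ndarray,
    fraction: float,
    network_names: Sequence[str] | None = None,
):
    """Top ``ceil(fraction * m)`` edges of a state by absolute value.

    Returns a DataFrame with network-pair names (when given), the signed
    value, and the sign; ties in absolute value break by edge index.
    """
    import pandas as pd

    from ._utils import edge_index_pairs

    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    centroid = np.asarray(centroid, dtype=float)
    m = centroid.size
    n_top = int(np.ceil(fraction * m))
    order = np.argsort(-np.abs(centroid), kind="stable")[:n_top]
    n_net = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    pairs = edge_index_pairs(n_net)
    rows = []
    for e in order:
        i, j = pairs[e]
        rows.append(
            {
                "edge": e,
                "net_a": network_names[i] if network_names else f"N{i + 1}",
                "net_b": network_names[j] if network_names else f"N{j + 1}",
                "value": centroid[e],
                "sign": "+" if centroid[e] >= 0 else "-",
            }
        )
    return pd.DataFrame(rows, columns=["edge", "net_a", "net_b", "value", "sign"])
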