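"""Temporal statistics of state sequences: occupancy, transitions, change rate.

Frame-occupancy probability is the pooled fraction of a group's windows in
each state.  For a subject with w windows there are w - 1 consecutive pairs:
the joint matrix counts each ordered pair (i, j) divided by the total pair
count (its entries sum to 1), the conditional matrix divides each joint
count by the number of times i appears as a transition source (rows of
visited sources sum to 1), and the state-changing probability is the
fraction of pairs whose two states differ.  Group summaries average over
subjects; conditional rows from unvisited sources are excluded from the
group mean (the count of contributing subjects is reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TemporalStats:
    """Per-group occupancy, transition matrices, and change probabilities."""

    n_states: int
    occupancy: dict[str, np.ndarray]
    joint: dict[str, np.ndarray]  # group-averaged joint matrices
    conditional: dict[str, np.ndarray]  # group-averaged conditional matrices
    conditional_support: dict[str, np.ndarray]  # contributing subjects per row
    changing_probability: dict[str, float]


def frame_probability(
    labels: dict[str, np.ndarray],
    group: dict[str, str],
    n_states: int,
) -> dict[str, np.ndarray]:
    """Pooled per-group fraction of windows occupying each state."""
    counts: dict[str, np.ndarray] = {}
    for sid, seq in labels.items():
        g = group[sid]
        seq = np.asarray(seq, dtype=int)
        if seq.min() < 0 or seq.max() >= n_states:
            raise ValueError(f"subject {sid!r} has state labels outside [0, {n_states})")
        counts.setdefault(g, np.zeros(n_states))
        counts[g] += np.bincount(seq, minlength=n_states)
    out = {}
    for g, c in counts.items():
        total = c.sum()
        if total == 0:
            raise ValueError(f"group {g!r} has no frames")
        out[g] = c / total
    return out


def transition_matrices(
    seq: np.ndarray, n_states: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint and conditional transition matrices for one state sequence.

    Returns ``(joint, conditional, visited)`` where ``visited[i]`` marks
    states occurring as a transition source; conditional rows for unvisited
    sources are all-zero.
    """
    seq = np.asarray(seq, dtype=int)
    if seq.size < 2:
        raise ValueError("need a sequence of at least 2 windows")
    counts = np.zeros((n_states, n_states))
    np.add.at(counts, (seq[:-1], seq[1:]), 1.0)
    total = seq.size - 1
    joint = counts / total
    source = counts.sum(axis=1)  # occurrences as a transition source
    visited = source > 0
    conditional = np.zeros_like(counts)
    conditional[visited] = counts[visited] / source[visited, None]
    return joint, conditional, visited


def average_transition(
    per_subject: list[tuple[np.ndarray, np.ndarray]] | list[np.ndarray],
    visited_masks: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Entrywise mean of per-subject conditional matrices.

    Rows are averaged over the subjects that visited the source state;
    returns ``(mean, support)`` where ``support[i]`` is the number of
    contributing subjects (rows with zero support are NaN).
    """
    if not per_subject:
        raise ValueError("no subjects to average")
    mats = [np.asarray(m, dtype=float) for m in per_subject]
    n_states = mats[0].shape[0]
    if visited_masks is None:
        visited_masks = [m.sum(axis=1) > 0 for m in mats]
    acc = np.zeros((n_states, n_states))
    support = np.zeros(n_states)
    for m, v in zip(mats, visited_masks):
        acc[v] += m[v]
        support += v.astype(float)
    mean = np.full((n_states, n_states), np.nan)
    rows = support > 0
    mean[rows] = acc[rows] / support[rows, None]
    return mean, support


def changing_probability(seq: np.ndarray) -> float:
    """Fraction of consecutive window pairs whose state changes."""
    seq = np.asarray(seq, dtype=int)
    if seq.size < 2:
        raise ValueError("need a sequence of at least 2 windows")
    return float(np.mean(seq[:-1] != seq[1:]))


def compute_temporal_stats(
    labels: dict[str, np.ndarray],
    group: dict[str, str],
    n_states: int,
) -> TemporalStats:
    """All temporal summaries, grouped by the subjects' group labels."""
    missing = [sid for sid in labels if sid not in group]
    if missing:
        raise ValueError(f"subjects without group assignment: {missing[:3]}")
    occupancy = frame_probability(labels, group, n_states)
    by_group: dict[str, list[str]] = {}
    for sid in labels:
        by_group.setdefault(group[sid], []).append(sid)
    joint_avg, cond_avg, support, change = {}, {}, {}, {}
    for g, sids in by_group.items():
        joints, conds, viss, chs = [], [], [], []
        for sid in sids:
            j, c, v = transition_matrices(labels[sid], n_states)
            joints.append(j)
            conds.append(c)
            viss.append(v)
            chs.append(changing_probability(labels[sid]))
        joint_avg[g] = np.mean(joints, axis=0)
        cond_avg[g], support[g] = average_transition(conds, viss)
        change[g] = float(np.mean(chs))
    return TemporalStats(
        n_states=n_states,
        occupancy=occupancy,
        joint=joint_avg,
        conditional=cond_avg,
        conditional_support=support,
        changing_probability=change,
    )
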