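"""Synthetic resting-state cohort generator with planted ground truth.

The generator emulates the statistical structure the downstream pipeline is
designed to recover:

* band-limited multivariate signals (frequency-domain masking of white noise,
  default passband 0.01-0.15 Hz at TR = 0.802 s);
* a planted ROI -> network block structure, separately for GM and WM: every
  ROI is its network's latent signal plus independent ROI noise;
* a latent state sequence per subject — a first-order Markov chain with
  uniform off-diagonal mass and a self-transition probability set by the mean
  dwell — where each state imposes its own inter-network correlation matrix;
* group effects as additive shifts, on the Fisher-z scale, of chosen edges in
  chosen states for chosen groups;
* additive age and sex effects on edge z-values;
* observation noise at the ROI level.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import (
    check_correlation_matrix,
    fisher_z,
    inverse_fisher_z,
    nearest_correlation_psd,
    unvectorize_upper,
    vectorize_upper,
)
from .cohort import GM, WM, CohortTimeSeries

AGE_CENTER = 40.0  # covariate effects are applied around this age


@dataclass
class GroupEffect:
    """Additive z-scale shift on one edge of one state for one group."""

    group: str
    state: int
    edge: tuple[int, int]
    shift: float


@dataclass
class CovariateEffects:
    """Additive age/sex coefficients applied to edge z-values.

    ``age`` is per year (centered at AGE_CENTER), ``sex`` is the 0/1 contrast
    (centered at 0.5).  ``edges`` restricts the effect to a subset of
    network-pair indices; ``None`` applies it to every edge.
    """

    age: float = 0.0
    sex: float = 0.0
    edges: list[tuple[int, int]] | None = None


@dataclass
class SynthConfig:
    """Full description of a synthetic cohort; see module docstring."""

    n_subjects_per_group: dict[str, int]
    n_roi_gm: int = 60
    n_roi_wm: int = 40
    n_timepoints: int = 361
    sampling_interval_s: float = 0.802
    passband_hz: tuple[float, float] = (0.01, 0.15)
    k1_true: int = 6
    k2_true: int = 4
    ks_true: int = 4
    dwell_mean_windows: float = 27.0
    window_length_tr: int = 45
    step_tr: int = 1
    state_covariances: list[np.ndarray] | None = None
    state_strength: float = 1.0
    subject_state_jitter_z: float = 0.0
    group_effects: list[GroupEffect] = field(default_factory=list)
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    noise_sd: float = 0.5
    seed: int = 0

    @property
    def n_networks(self) -> int:
        return self.k1_true + self.k2_true

    def validate(self) -> None:
        if not self.n_subjects_per_group:
            raise ValueError("n_subjects_per_group must name at least one group")
        for g, n in self.n_subjects_per_group.items():
            if n < 1:
                raise ValueError(f"group {g!r} must have >= 1 subject")
        if self.k1_true > self.n_roi_gm or self.k2_true > self.n_roi_wm:
            raise ValueError("planted network count exceeds ROI count for its tissue")
        if min(self.k1_true, self.k2_true) < 1:
            raise ValueError("k1_true and k2_true must be positive")
        if self.ks_true < 1:
            raise ValueError("ks_true must be positive")
        if self.dwell_mean_windows < 1:
            raise ValueError("dwell_mean_windows must be >= 1")
        low, high = self.passband_hz
        if not (0 < low < high):
            raise ValueError("passband must satisfy 0 < low < high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (3 <= self.window_length_tr <= self.n_timepoints):
            raise ValueError("window_length_tr must lie in [3, n_timepoints]")
        if self.state_covariances is not None:
            if len(self.state_covariances) != self.ks_true:
                raise ValueError("state_covariances must supply one matrix per state")
            for s, cov in enumerate(self.state_covariances):
                cov = np.asarray(cov, dtype=float)
                if cov.shape != (self.n_networks, self.n_networks):
                    raise ValueError(
                        f"state covariance {s} has shape {cov.shape}, "
                        f"expected ({self.n_networks}, {self.n_networks})"
                    )
                w = np.linalg.eigvalsh((cov + cov.T) / 2)
                if w.min() < -1e-8:
                    raise ValueError(f"state covariance {s} is not positive semidefinite")
        for eff in self.group_effects:
            if eff.group not in self.n_subjects_per_group:
                raise ValueError(f"group effect references unknown group {eff.group!r}")
            if not (0 <= eff.state < self.ks_true):
                raise ValueError(f"group effect references unknown state {eff.state}")
            a, b = eff.edge
            if not (0 <= a < b < self.n_networks):
                raise ValueError(f"group effect edge {eff.edge} out of range (need i<j)")

    def resolved_state_correlations(self) -> list[np.ndarray]:
        """State covariances normalized to correlation form (unit diagonal)."""
        if self.state_covariances is None:
            return make_state_correlations(
                self.ks_true, self.n_networks, seed=self.seed, strength=self.state_strength
            )
        out = []
        for cov in self.state_covariances:
            cov = np.asarray(cov, dtype=float)
            d = np.sqrt(np.diag(cov))
            if np.any(d <= 0):
                raise ValueError("state covariance has non-positive diagonal")
            corr = cov / np.outer(d, d)
            np.fill_diagonal(corr, 1.0)
            out.append(corr)
        return out


@dataclass
class GroundTruth:
    """Everything planted by :func:`generate_cohort`, for recovery scoring."""

    roi_to_network: dict[str, np.ndarray]
    network_names: list[str]
    state_correlations: list[np.ndarray]
    true_centroids: np.ndarray  # ks x m, z-scale
    state_sequence: dict[str, np.ndarray]  # window-aligned modal labels
    tr_state_sequence: dict[str, np.ndarray]  # per-timepoint labels
    group_effect_table: pd.DataFrame
    window_length_tr: int
    step_tr: int


def make_state_correlations(
    ks: int,
    n_networks: int,
    seed: int = 0,
    max_pairwise_r: float = 0.3,
    strength: float = 1.0,
    ridge: float = 0.6,
    fixed_norm: bool = False,
    zero_edges: Sequence[tuple[int, int]] | None = None,
    max_tries: int = 500,
) -> list[np.ndarray]:
    """Draw ``ks`` well-separated inter-network correlation matrices.

    Each matrix is a rank-2-plus-ridge random covariance normalized to
    correlation form; sets are resampled until the pairwise Pearson
    correlation between their off-diagonal vectors stays below
    ``max_pairwise_r`` (so planted states are distinguishable downstream).
    ``strength`` scales the off-diagonal magnitudes toward zero.  With
    ``fixed_norm`` the factor loadings of every network are placed on a
    sphere of squared radius 2, which makes the minimum eigenvalue at
    least ``ridge / (2 + ridge)`` for every draw — eigenvalue slack that
    guarantees additive edge shifts on top of a state stay positive
    definite (a z-shift ``s`` moves a correlation by at most
    ``2 tanh(s/2)``).  ``zero_edges`` lists vertex-disjoint network pairs
    whose loadings are orthogonalized so their baseline correlation is
    exactly zero in every state — shifts planted on them are then realized
    uniformly, free of tanh compression against a nonzero baseline.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        mats = []
        for _ in range(ks):
            a = rng.standard_normal((n_networks, 2))
            if fixed_norm:
                a *= np.sqrt(2.0) / np.linalg.norm(a, axis=1, keepdims=True)
            if zero_edges is not None:
                for i, j in zero_edges:
                    a[j] -= (a[j] @ a[i]) / (a[i] @ a[i]) * a[i]
                    if fixed_norm and np.linalg.norm(a[j]) > 0:
                        a[j] *= np.sqrt(2.0) / np.linalg.norm(a[j])
            cov = a @ a.T + ridge * np.eye(n_networks)
            d = np.sqrt(np.diag(cov))
            corr = cov / np.outer(d, d)
            corr = np.eye(n_networks) + strength * (corr - np.eye(n_networks))
            np.fill_diagonal(corr, 1.0)
            mats.append(corr)
        if ks == 1:
            return mats
        vecs = np.array([vectorize_upper(m) for m in mats])
        rmax = np.abs(np.corrcoef(vecs))[np.triu_indices(ks, k=1)].max()
        if rmax < max_pairwise_r:
            return mats
    raise RuntimeError(
        f"could not draw {ks} state correlation matrices with pairwise |r| < {max_pairwise_r}"
    )


def round_robin_matchings(n: int) -> list[list[tuple[int, int]]]:
    """1-factorization of the complete graph on ``n`` (even) nodes.

    Returns ``n - 1`` perfect matchings that together cover every node pair
    exactly once (circle method: one node fixed, the rest rotate).
    """
    if n % 2 != 0:
        raise ValueError("need an even number of nodes")
    ring = list(range(1, n))
    out = []
    for _ in range(n - 1):
        pairs = [tuple(sorted((0, ring[0])))]
        for i in range(1, n // 2):
            pairs.append(tuple(sorted((ring[i], ring[-i]))))
        out.append(pairs)
        ring = ring[1:] + ring[:1]
    return out


def matching_state_correlations(
    ks: int,
    n_networks: int,
    value: float = 0.45,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[tuple[int, int]]]:
    """States with edge-disjoint supports plus a reserved null matching.

    State ``s`` places ``+/-value`` (random signs) on the edges of the
    ``s``-th matching of a 1-factorization of the network graph, zero
    elsewhere: the states are exactly orthogonal in edge space and each
    matrix has minimum eigenvalue ``1 - value``.  The next unused matching
    is returned as a set of edges whose baseline correlation is zero in
    every state — shifting them by ``s`` on the z-scale keeps every matrix
    positive definite whenever ``value + tanh(s) < 1``, and their zero
    baseline decouples them from the states' own edges.
    """
    matchings = round_robin_matchings(n_networks)
    if ks + 1 > len(matchings):
        raise ValueError(f"need {ks + 1} disjoint matchings, only {len(matchings)} exist")
    if not (0 < value < 1):
        raise ValueError("value must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    mats = []
    for s in range(ks):
        mat = np.eye(n_networks)
        for i, j in matchings[s]:
            v = value * (1 if rng.random() < 0.5 else -1)
            mat[i, j] = mat[j, i] = v
        mats.append(mat)
    return mats, matchings[ks]


#: designated effect edges for the planted-recovery experiment: five
#: vertex-disjoint network pairs, three shifted up and two down in TLE
RECOVERY_EDGES: tuple[tuple[int, int], ...] = ((0, 4), (1, 7), (2, 9), (3, 5), (6, 8))
RECOVERY_SIGNS: tuple[int, ...] = (1, 1, 1, -1, -1)


def effect_recovery_config(
    n_subjects_per_group: dict[str, int] | None = None,
    seed: int = 0,
    shift: float = 0.5,
    ks: int = 4,
    dwell_mean_windows: float = 60.0,
    window_length_tr: int = 45,
    n_timepoints: int = 722,
    subject_state_jitter_z: float = 0.15,
) -> SynthConfig:
    """Cohort configuration for the planted group-effect recovery experiment.

    Group effects are planted on five vertex-disjoint edges of the last
    state (the analysis's "state 4" when ``ks = 4``): three shifted up and
    two down by ``shift`` on the Fisher-z scale in the TLE group.  The
    states are drawn with fixed-norm factor loadings and ridge 2, which
    bounds every state's minimum eigenvalue below by 0.5; a z-shift ``s``
    moves a correlation by at most ``2 tanh(s/2)`` (0.49 at the default
    0.5), so the shifted state is positive definite for every seed and the
    planted shifts are realized exactly, never blurred by a PSD repair.
    The effect edges' factor loadings are orthogonalized so their baseline
    correlation is zero in every state, making the realized shift uniform
    across edges.  The scan length defaults to two concatenated runs'
    worth of timepoints, and subjects carry idiosyncratic z-scale state
    jitter — realistic between-subject variability that dominates the
    small cross-edge coupling of the dual-regression estimator.
    """
    if n_subjects_per_group is None:
        n_subjects_per_group = {"HC": 25, "TLE": 25}
    states = make_state_correlations(
        ks, 10, seed=seed, ridge=2.0, fixed_norm=True, zero_edges=RECOVERY_EDGES
    )
    effects = [
        GroupEffect("TLE", ks - 1, e, s * shift)
        for e, s in zip(RECOVERY_EDGES, RECOVERY_SIGNS)
    ]
    return SynthConfig(
        n_subjects_per_group=n_subjects_per_group,
        n_roi_gm=60,
        n_roi_wm=40,
        k1_true=6,
        k2_true=4,
        ks_true=ks,
        n_timepoints=n_timepoints,
        window_length_tr=window_length_tr,
        dwell_mean_windows=dwell_mean_windows,
        state_covariances=states,
        subject_state_jitter_z=subject_state_jitter_z,
        group_effects=effects,
        seed=seed,
    )


def plant_block_fc(n_roi: int, k: int, within_r: float, between_r: float) -> np.ndarray:
    """Block-structured correlation matrix with ``k`` near-equal blocks.

    Within-block entries are ``within_r``, between-block entries
    ``between_r``, diagonal 1.  Used as a noiseless fixture for partition
    and stability tests.
    """
    if not (0 <= between_r < within_r <= 1):
        raise ValueError("need 0 <= between_r < within_r <= 1 (blocks not identifiable otherwise)")
    if not (1 <= k <= n_roi):
        raise ValueError("need 1 <= k <= n_roi")
    mat = np.full((n_roi, n_roi), float(between_r))
    for block in np.array_split(np.arange(n_roi), k):
        mat[np.ix_(block, block)] = within_r
    np.fill_diagonal(mat, 1.0)
    return mat


def block_assignment(n_roi: int, k: int) -> np.ndarray:
    """Network index per ROI for the contiguous near-equal block layout."""
    out = np.empty(n_roi, dtype=int)
    for i, block in enumerate(np.array_split(np.arange(n_roi), k)):
        out[block] = i
    return out


def bandlimited_noise(
    rng: np.random.Generator,
    n_series: int,
    n_timepoints: int,
    sampling_interval_s: float,
    passband_hz: tuple[float, float],
) -> np.ndarray:
    """Rows of unit-variance noise whose spectrum is confined to the passband."""
    freqs = np.fft.rfftfreq(n_timepoints, d=sampling_interval_s)
    low, high = passband_hz
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():
        raise ValueError("passband contains no resolvable frequency bins")
    spec = np.fft.rfft(rng.standard_normal((n_series, n_timepoints)), axis=1)
    spec[:, ~mask] = 0.0
    x = np.fft.irfft(spec, n=n_timepoints, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    x /= x.std(axis=1, keepdims=True)
    return x


def band_power_fraction(
    x: np.ndarray, sampling_interval_s: float, passband_hz: tuple[float, float]
) -> float:
    """Fraction of non-DC spectral power inside the passband (rows pooled)."""
    x = np.atleast_2d(x)
    x = x - x.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(x, axis=1)) ** 2
    freqs = np.fft.rfftfreq(x.shape[1], d=sampling_interval_s)
    mask = (freqs >= passband_hz[0]) & (freqs <= passband_hz[1])
    total = spec[:, 1:].sum()
    return float(spec[:, mask].sum() / total) if total > 0 else 0.0


def _sym_sqrt(mat: np.ndarray) -> np.ndarray:
    """Symmetric positive-semidefinite matrix square root."""
    w, v = np.linalg.eigh(mat)
    return (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T


def _whiten_rows(x: np.ndarray) -> np.ndarray:
    """ZCA whitening so the empirical row covariance is exactly the identity."""
    x = x - x.mean(axis=1, keepdims=True)
    cov = x @ x.T / x.shape[1]
    w, v = np.linalg.eigh(cov)
    inv_sqrt = (v / np.sqrt(w)) @ v.T
    return inv_sqrt @ x


def _markov_sequence(
    rng: np.random.Generator, length: int, ks: int, dwell_mean: float
) -> np.ndarray:
    if ks == 1:
        return np.zeros(length, dtype=int)
    p_stay = 1.0 - 1.0 / dwell_mean
    seq = np.empty(length, dtype=int)
    seq[0] = rng.integers(ks)
    for t in range(1, length):
        if rng.random() < p_stay:
            seq[t] = seq[t - 1]
        else:
            others = [s for s in range(ks) if s != seq[t - 1]]
            seq[t] = others[rng.integers(ks - 1)]
    return seq


def _modal_window_labels(tr_seq: np.ndarray, length: int, step: int, ks: int) -> np.ndarray:
    n_windows = (tr_seq.size - length) // step + 1
    out = np.empty(n_windows, dtype=int)
    for w in range(n_windows):
        counts = np.bincount(tr_seq[w * step : w * step + length], minlength=ks)
        out[w] = int(np.argmax(counts))  # ties -> lowest state index
    return out


def _subject_state_matrices(
    base: list[np.ndarray],
    group: str,
    age: float,
    sex: int,
    effects: list[GroupEffect],
    cov_eff: CovariateEffects,
    repair: bool = True,
    jitter_z: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Per-subject state correlation matrices with group/covariate z-shifts.

    ``jitter_z`` adds independent N(0, jitter_z^2) z-scale perturbations to
    every edge of every state — idiosyncratic between-subject variability
    in state connectivity.
    """
    n_net = base[0].shape[0]
    out = []
    for s, corr in enumerate(base):
        z = fisher_z(vectorize_upper(corr)).copy()
        pairs = {(i, j): idx for idx, (i, j) in enumerate(_edge_pairs(n_net))}
        for eff in effects:
            if eff.group == group and eff.state == s:
                z[pairs[tuple(sorted(eff.edge))]] += eff.shift
        if jitter_z > 0:
            if rng is None:
                raise ValueError("jitter requires a random generator")
            z += jitter_z * rng.standard_normal(z.size)
        if cov_eff.age or cov_eff.sex:
            shift = cov_eff.age * (age - AGE_CENTER) + cov_eff.sex * (sex - 0.5)
            if cov_eff.edges is None:
                z += shift
            else:
                for e in cov_eff.edges:
                    z[pairs[tuple(sorted(e))]] += shift
        mat = unvectorize_upper(inverse_fisher_z(z), n_net, diag=1.0)
        if repair and np.linalg.eigvalsh(mat).min() < 1e-10:
            repaired = nearest_correlation_psd(mat)
            delta = np.abs(repaired - mat).max()
            # jitter-induced repairs are routine, subject-random, and small;
            # only a systematic (jitter-free) repair distorts planted effects
            if delta > 0.01 and jitter_z == 0:
                warnings.warn(
                    f"state {s}: planted shifts made the correlation matrix "
                    f"indefinite; PSD repair moved entries by up to {delta:.3f}"
                )
            mat = repaired
        out.append(mat)
    return out


def _edge_pairs(n: int) -> list[tuple[int, int]]:
    iu = np.triu_indices(n, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def generate_cohort(config: SynthConfig) -> tuple[CohortTimeSeries, GroundTruth]:
    """Generate a cohort with planted networks, states, and group effects."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    base_corrs = config.resolved_state_correlations()
    for s, corr in enumerate(base_corrs):
        check_correlation_matrix(corr, name=f"state correlation {s}")

    n_net = config.n_networks
    gm_assign = block_assignment(config.n_roi_gm, config.k1_true)
    wm_assign = block_assignment(config.n_roi_wm, config.k2_true)
    network_names = [f"GM{i + 1}" for i in range(config.k1_true)] + [
        f"WM{i + 1}" for i in range(config.k2_true)
    ]
    # ROI -> combined network index (GM networks first, then WM)
    roi_network = np.concatenate([gm_assign, wm_assign + config.k1_true])
    roi_ids = [f"GM_{i + 1:03d}" for i in range(config.n_roi_gm)] + [
        f"WM_{i + 1:03d}" for i in range(config.n_roi_wm)
    ]
    roi_tissue = np.array([GM] * config.n_roi_gm + [WM] * config.n_roi_wm)

    subjects: list[str] = []
    groups: list[str] = []
    ages: list[float] = []
    sexes: list[int] = []
    data = []
    tr_seqs: dict[str, np.ndarray] = {}
    win_seqs: dict[str, np.ndarray] = {}

    T = config.n_timepoints
    dwell_tr = config.dwell_mean_windows * config.step_tr
    for group, n_sub in config.n_subjects_per_group.items():
        for i in range(n_sub):
            sid = f"{group}{i + 1:03d}"
            age = float(rng.uniform(20, 60))
            sex = int(rng.integers(2))
            state_mats = _subject_state_matrices(
                base_corrs,
                group,
                age,
                sex,
                config.group_effects,
                config.covariate_effects,
                jitter_z=config.subject_state_jitter_z,
                rng=rng,
            )
            # symmetric PSD square root (not Cholesky): a local perturbation of
            # a state matrix stays local in its root, so windows straddling a
            # state switch do not smear planted effects onto unrelated edges
            chols = [_sym_sqrt(m) for m in state_mats]
            seq = _markov_sequence(rng, T, config.ks_true, dwell_tr)
            # One independent band-limited innovation stream per state, each
            # whitened over its own timepoints: the realized covariance within
            # a state's frames equals that state's matrix (covariance imposed
            # at the window scale, not merely in expectation), and segments of
            # different states are uncorrelated, so windows straddling a
            # switch carry the mixture covariance with no cross-state terms.
            u = np.empty((n_net, T))
            for s in range(config.ks_true):
                idx = np.flatnonzero(seq == s)
                if idx.size == 0:
                    continue
                es = bandlimited_noise(
                    rng, n_net, T, config.sampling_interval_s, config.passband_hz
                )[:, idx]
                if idx.size >= 2 * n_net:
                    es = _whiten_rows(es)
                u[:, idx] = chols[s] @ es
            x = u[roi_network]
            if config.noise_sd > 0:
                x = x + config.noise_sd * bandlimited_noise(
                    rng, roi_network.size, T, config.sampling_interval_s, config.passband_hz
                )
            subjects.append(sid)
            groups.append(group)
            ages.append(age)
            sexes.append(sex)
            data.append(x)
            tr_seqs[sid] = seq
            win_seqs[sid] = _modal_window_labels(
                seq, config.window_length_tr, config.step_tr, config.ks_true
            )

    cohort = CohortTimeSeries(
        data=np.array(data),
        roi_ids=roi_ids,
        roi_tissue=roi_tissue,
        subjects=subjects,
        group=np.array(groups),
        age=np.array(ages),
        sex=np.array(sexes),
        sampling_interval_s=config.sampling_interval_s,
    )
    cohort.validate()

    centroids = np.array([fisher_z(vectorize_upper(c)) for c in base_corrs])
    effect_table = pd.DataFrame(
        [
            {
                "group": e.group,
                "state": e.state,
                "edge_i": min(e.edge),
                "edge_j": max(e.edge),
                "shift": e.shift,
            }
            for e in config.group_effects
        ],
        columns=["group", "state", "edge_i", "edge_j", "shift"],
    )
    truth = GroundTruth(
        roi_to_network={GM: gm_assign, WM: wm_assign},
        network_names=network_names,
        state_correlations=base_corrs,
        true_centroids=centroids,
        state_sequence=win_seqs,
        tr_state_sequence=tr_seqs,
        group_effect_table=effect_table,
        window_length_tr=config.window_length_tr,
        step_tr=config.step_tr,
    )
    return cohort, truth
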