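"""Static and sliding-window FNC, with Fisher z and covariate regression.

FNC is the Pearson correlation between network-averaged time courses.  The
dynamic variant recomputes it in rectangular sliding windows (default step
1 TR, no taper), Fisher z-transforms the correlations, and summarizes each
connection by its standard deviation across windows (dFNC-STD).  The window
length is selected by maximizing a Fisher discriminant ratio between groups
of per-subject mean dFNC-STD values over a grid of candidate lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._utils import fisher_z, n_edges, vectorize_upper


@dataclass
class WindowedFNC:
    """Sequence of vectorized, z-scale inter-network correlations."""

    subject: str
    window_length_tr: int
    step_tr: int
    windows: np.ndarray  # w x m

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_edges(self) -> int:
        return self.windows.shape[1]


@dataclass
class FNCSummary:
    """Per-subject edge vectors summarizing FNC (static mean or dynamic STD)."""

    kind: str  # "static-mean" | "dynamic-std"
    values: np.ndarray  # n_subjects x m
    subjects: list[str]
    group: np.ndarray


@dataclass
class FdrWindowProfile:
    """Discriminability score per candidate window length."""

    window_lengths_tr: np.ndarray
    j_scores: np.ndarray
    selected_length_tr: int
    discriminative: bool = True
    variant: str = "canonical"


def _pearson_edges(block: np.ndarray) -> np.ndarray:
    """Vectorized upper-triangle Pearson correlations of an n x t block."""
    sd = block.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(f"constant time course at network index {int(np.argmax(sd == 0))}")
    return vectorize_upper(np.corrcoef(block))


def static_fnc(network_tcs: np.ndarray) -> np.ndarray:
    """Full-length FNC vector (z-scale) for one subject's network x time matrix."""
    network_tcs = np.asarray(network_tcs, dtype=float)
    if network_tcs.ndim != 2 or network_tcs.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two networks")
    return fisher_z(_pearson_edges(network_tcs))


def sliding_window_fnc(
    network_tcs: np.ndarray,
    window_length_tr: int,
    step_tr: int = 1,
    subject: str = "",
) -> WindowedFNC:
    """Windowed FNC: rectangular windows, Pearson per window, Fisher z.

    The number of windows is ``floor((T - L) / step) + 1``.
    """
    network_tcs = np.asarray(network_tcs, dtype=float)
    n_net, T = network_tcs.shape
    L = int(window_length_tr)
    if L < 3:
        raise ValueError("window length must be >= 3 timepoints")
    if L > T:
        raise ValueError(f"window length {L} exceeds series length {T}")
    w = (T - L) // step_tr + 1
    out = np.empty((w, n_edges(n_net)))
    for i in range(w):
        start = i * step_tr
        try:
            out[i] = _pearson_edges(network_tcs[:, start : start + L])
        except ValueError as exc:
            raise ValueError(f"subject {subject!r}, window {i}: {exc}") from exc
    return WindowedFNC(
        subject=subject, window_length_tr=L, step_tr=step_tr, windows=fisher_z(out)
    )


def regress_covariates(
    windowed: Sequence[WindowedFNC],
    age: np.ndarray,
    sex: np.ndarray,
) -> list[WindowedFNC]:
    """OLS removal of age and sex effects from edge z-values.

    Each subject's covariates are repeated over its windows; per edge, the
    pooled z-values are regressed on [intercept, age, sex] and replaced by
    residual + intercept, preserving the grand mean.
    """
    if len(windowed) < 3:
        raise ValueError("need at least 3 subjects for covariate regression")
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if age.size != len(windowed) or sex.size != len(windowed):
        raise ValueError("one age and sex value per subject required")
    counts = [w.n_windows for w in windowed]
    design = np.column_stack(
        [
            np.ones(sum(counts)),
            np.repeat(age, counts),
            np.repeat(sex, counts),
        ]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design (e.g. a single sex present)")
    stacked = np.vstack([w.windows for w in windowed])
    beta, *_ = np.linalg.lstsq(design, stacked, rcond=None)
    fitted = design @ beta
    # residual plus the intercept evaluated at the mean covariates, so the
    # grand mean of every edge is preserved
    cleaned = stacked - fitted + fitted.mean(axis=0)
    out = []
    offset = 0
    for w, c in zip(windowed, counts):
        out.append(
            WindowedFNC(
                subject=w.subject,
                window_length_tr=w.window_length_tr,
                step_tr=w.step_tr,
                windows=cleaned[offset : offset + c],
            )
        )
        offset += c
    return out


def dfnc_std(windowed: WindowedFNC) -> np.ndarray:
    """Per-connection sample (n-1) standard deviation across windows."""
    if windowed.n_windows < 2:
        raise ValueError("need at least 2 windows for a standard deviation")
    return windowed.windows.std(axis=0, ddof=1)


def fdr_window_score(
    std_hc: np.ndarray,
    std_tle: np.ndarray,
    variant: str = "canonical",
) -> float:
    """Fisher discriminant ratio between two groups of scalar summaries.

    Inputs are per-subject mean dFNC-STD values (mean over all connections,
    irrespective of network pair).  The canonical form is
    ``J = (mu_a - mu_b)**2 / (var_a + var_b)``; ``variant="literal"`` gives
    the difference-of-variances form ``(mu_a - mu_b) / (var_a - var_b)``,
    which can be negative and is provided for comparison only.
    """
    a = np.asarray(std_hc, dtype=float)
    b = np.asarray(std_tle, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    mu_a, mu_b = a.mean(), b.mean()
    var_a = a.var(ddof=1) if a.size > 1 else 0.0
    var_b = b.var(ddof=1) if b.size > 1 else 0.0
    if variant == "canonical":
        num, denom = (mu_a - mu_b) ** 2, var_a + var_b
    elif variant == "literal":
        num, denom = mu_a - mu_b, var_a - var_b
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if denom == 0:
        if num == 0:
            return 0.0
        warnings.warn("zero pooled variance with unequal means; J is infinite")
        return float(np.inf)
    return float(num / denom)


def mean_std_per_subject(
    network_tcs: np.ndarray, window_length_tr: int, step_tr: int = 1
) -> np.ndarray:
    """Per-subject mean (over connections) dFNC-STD at one window length."""
    out = np.empty(network_tcs.shape[0])
    for i in range(network_tcs.shape[0]):
        wf = sliding_window_fnc(network_tcs[i], window_length_tr, step_tr, subject=str(i))
        out[i] = dfnc_std(wf).mean()
    return out


def select_window_length(
    network_tcs: np.ndarray,
    group: np.ndarray,
    grid: Sequence[int],
    hc_label: str = "HC",
    step_tr: int = 1,
    variant: str = "canonical",
) -> FdrWindowProfile:
    """Grid search of the window length maximizing group discriminability.

    ``group`` labels equal to ``hc_label`` form one class; all other labels
    are pooled into the comparison class.  Selection prefers the highest
    local peak of the J curve, falling back to the global argmax.
    """
    grid = np.asarray(sorted(int(g) for g in grid))
    if grid.size == 0:
        raise ValueError("empty window-length grid")
    group = np.asarray(group)
    hc = group == hc_label
    if not hc.any() or hc.all():
        raise ValueError("need both an HC group and a comparison group")
    j = np.empty(grid.size)
    for i, L in enumerate(grid):
        means = mean_std_per_subject(network_tcs, int(L), step_tr)
        j[i] = fdr_window_score(means[hc], means[~hc], variant=variant)
    from .networks import _local_peak_argmax

    sel = grid[_local_peak_argmax(j)]
    discriminative = bool(np.nanmax(j) > 1e-12)
    if not discriminative:
        warnings.warn("all window lengths give J ~ 0; selection is non-discriminative")
    return FdrWindowProfile(
        window_lengths_tr=grid,
        j_scores=j,
        selected_length_tr=int(sel),
        discriminative=discriminative,
        variant=variant,
    )
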