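"""Two-step dual regression of subject windowed FNC on group-level states.

Step 1 regresses each subject's windowed FNC matrix Y (w x m) on the group
state centroids S (k x m), treated as spatial predictors, giving per-state
temporal dynamics beta1 (k x w).  Step 2 regresses Y on those dynamics,
giving the subject-specific states beta2 (k x m).  Both steps use plain
least squares with no intercept, returning the minimal-norm solution under
rank deficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class DualRegressionResult:
    subject: str
    beta1: np.ndarray  # k x w temporal dynamics
    beta2: np.ndarray  # k x m subject-specific states
    residual_step1: float
    residual_step2: float

    @property
    def dims(self) -> dict[str, int]:
        k, w = self.beta1.shape
        return {"k": k, "w": w, "m": self.beta2.shape[1]}


def dual_regression(
    Y: np.ndarray,
    S: np.ndarray,
    subject: str = "",
    demean: bool = False,
) -> DualRegressionResult:
    """Estimate per-subject temporal dynamics and states from group states.

    Parameters
    ----------
    Y : ndarray, shape (w, m)
        One subject's windowed FNC (windows by edges, z-scale).
    S : ndarray, shape (k, m)
        Group-level state centroids.
    demean : bool
        Optionally column-demean Y and row-demean S before regression
        (off by default; the model as specified carries no constant term).
    """
    Y = np.asarray(Y, dtype=float)
    S = np.asarray(S, dtype=float)
    if Y.ndim != 2 or S.ndim != 2 or Y.shape[1] != S.shape[1]:
        raise ValueError(f"incompatible shapes Y{Y.shape}, S{S.shape}")
    k, m = S.shape
    w = Y.shape[0]
    if w < k:
        raise ValueError(f"need at least k={k} windows, got w={w}")
    if np.linalg.matrix_rank(S) < k:
        warnings.warn("state matrix S is rank deficient; minimal-norm solution returned")
    if demean:
        Y = Y - Y.mean(axis=0, keepdims=True)
        S = S - S.mean(axis=1, keepdims=True)
    # step 1: Y^T ~ S^T beta1
    beta1, res1, *_ = np.linalg.lstsq(S.T, Y.T, rcond=None)
    r1 = float(np.linalg.norm(Y.T - S.T @ beta1))
    # step 2: Y ~ beta1^T beta2
    if np.linalg.matrix_rank(beta1) < k:
        warnings.warn("temporal dynamics beta1 are rank deficient; minimal-norm solution returned")
    beta2, res2, *_ = np.linalg.lstsq(beta1.T, Y, rcond=None)
    r2 = float(np.linalg.norm(Y - beta1.T @ beta2))
    return DualRegressionResult(
        subject=subject, beta1=beta1, beta2=beta2, residual_step1=r1, residual_step2=r2
    )


def group_states(
    results: dict[str, DualRegressionResult],
    group: dict[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Entrywise mean of subject-specific states (beta2) within each group.

    ``group`` maps subject id -> group label; if omitted, a single group
    "all" is formed.
    """
    if not results:
        raise ValueError("no dual-regression results to average")
    if group is None:
        group = {sid: "all" for sid in results}
    by_group: dict[str, list[np.ndarray]] = {}
    for sid, res in results.items():
        if sid not in group:
            raise ValueError(f"subject {sid!r} has no group assignment")
        by_group.setdefault(group[sid], []).append(res.beta2)
    out = {}
    for g, mats in by_group.items():
        if not mats:
            raise ValueError(f"group {g!r} is empty")
        out[g] = np.mean(mats, axis=0)
    return out
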