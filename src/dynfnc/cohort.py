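"""In-memory cohort container: per-subject ROI-by-time matrices with metadata.

A cohort bundles everything the pipeline consumes: one ROI x time matrix per
subject (all subjects share the ROI set and timepoint count), a GM/WM tissue
label per ROI, a group label per subject (e.g. HC / lTLE / rTLE), age and sex
covariates, and the sampling interval (TR) in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GM = "GM"
WM = "WM"
TISSUES = (GM, WM)


@dataclass
class CohortTimeSeries:
    """ROI time courses and metadata for every subject in a study.

    Parameters
    ----------
    data : ndarray, shape (n_subjects, n_roi, n_timepoints)
        ROI signals in arbitrary units.
    roi_ids : list of str
        One identifier per ROI.
    roi_tissue : ndarray of str
        "GM" or "WM" per ROI.
    subjects : list of str
        Subject identifiers.
    group : ndarray of str
        Group label per subject.
    age : ndarray of float
        Age in years per subject.
    sex : ndarray of int
        Binary sex code per subject (0/1).
    sampling_interval_s : float
        TR in seconds.
    mean_fd : ndarray or None
        Optional mean framewise displacement (mm) per subject; callers may
        use it with :meth:`motion_ok` to mirror motion-based exclusion.
    """

    data: np.ndarray
    roi_ids: list[str]
    roi_tissue: np.ndarray
    subjects: list[str]
    group: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    sampling_interval_s: float
    mean_fd: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_tissue = np.asarray(self.roi_tissue)
        self.group = np.asarray(self.group)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=int)

    # -- shape accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(str(g), None)
        return list(seen)

    def tissue_indices(self, tissue: str) -> np.ndarray:
        if tissue not in TISSUES:
            raise ValueError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
        return np.flatnonzero(self.roi_tissue == tissue)

    def subject_indices(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.group == group)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check shape consistency and reject zero-variance ROI signals."""
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (subject, roi, time), got {self.data.ndim}-D")
        n_sub, n_roi, n_t = self.data.shape
        if len(self.roi_ids) != n_roi or self.roi_tissue.size != n_roi:
            raise ValueError("roi_ids / roi_tissue length does not match data")
        if len(self.subjects) != n_sub or self.group.size != n_sub:
            raise ValueError("subject metadata length does not match data")
        if self.age.size != n_sub or self.sex.size != n_sub:
            raise ValueError("covariate length does not match number of subjects")
        bad = set(np.unique(self.roi_tissue)) - set(TISSUES)
        if bad:
            raise ValueError(f"unknown tissue labels {sorted(bad)}")
        if n_t < 3:
            raise ValueError("need at least 3 timepoints")
        sd = self.data.std(axis=2)
        if np.any(sd == 0):
            s, r = np.argwhere(sd == 0)[0]
            raise ValueError(
                f"zero-variance signal: ROI {self.roi_ids[r]!r} in subject {self.subjects[s]!r}"
            )

    def motion_ok(self, threshold_mm: float = 0.3) -> np.ndarray:
        """Boolean mask of subjects with mean FD below ``threshold_mm``.

        Mirrors a mean-framewise-displacement exclusion rule as a flag the
        caller applies; subjects without FD information pass.
        """
        if self.mean_fd is None:
            return np.ones(self.n_subjects, dtype=bool)
        return np.asarray(self.mean_fd) <= threshold_mm

    def select_subjects(self, mask: np.ndarray) -> "CohortTimeSeries":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CohortTimeSeries(
            data=self.data[idx],
            roi_ids=list(self.roi_ids),
            roi_tissue=self.roi_tissue.copy(),
            subjects=[self.subjects[i] for i in idx],
            group=self.group[idx],
            age=self.age[idx],
            sex=self.sex[idx],
            sampling_interval_s=self.sampling_interval_s,
            mean_fd=None if self.mean_fd is None else np.asarray(self.mean_fd)[idx],
        )
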