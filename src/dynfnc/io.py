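"""Readers and writers for the pipeline's delimited-text interchange formats.

All stage artifacts are tab-separated tables with a header row so they can
be inspected and joined by edge or network name.  A cohort on disk is a
manifest (subject id, group, age, sex, file path), an ROI label table, and
one matrix file per subject (rows = timepoints, columns = ROI ids).  An
optional NIfTI ingestion path extracts ROI time courses from a 4-D image
plus an integer label volume.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTimeSeries
from .networks import NetworkPartition, StabilityProfile
from .dfnc import FdrWindowProfile, WindowedFNC
from .states import ElbowProfile, StateModel
from .synth import GroundTruth

SEP = "\t"


# ---------------------------------------------------------------- cohort
def write_cohort(cohort: CohortTimeSeries, out_dir: str | Path) -> Path:
    """Write a cohort as manifest + ROI labels + per-subject matrices."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(cohort.subjects):
        fname = f"{sid}.tsv"
        df = pd.DataFrame(cohort.data[i].T, columns=cohort.roi_ids)
        df.to_csv(out_dir / fname, sep=SEP, index=False, float_format="%.10g")
        row = {
            "subject_id": sid,
            "group": cohort.group[i],
            "age": cohort.age[i],
            "sex": int(cohort.sex[i]),
            "path": fname,
        }
        if cohort.mean_fd is not None:
            row["mean_fd"] = float(cohort.mean_fd[i])
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "manifest.tsv", sep=SEP, index=False)
    pd.DataFrame({"roi_id": cohort.roi_ids, "tissue": cohort.roi_tissue}).to_csv(
        out_dir / "roi_labels.tsv", sep=SEP, index=False
    )
    with open(out_dir / "sampling.json", "w") as fh:
        json.dump({"sampling_interval_s": cohort.sampling_interval_s}, fh)
    return out_dir / "manifest.tsv"


def load_cohort(manifest_path: str | Path) -> CohortTimeSeries:
    """Load a cohort from a manifest; validates shapes and signal variance."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep=SEP)
    required = {"subject_id", "group", "age", "sex", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")
    labels = pd.read_csv(base / "roi_labels.tsv", sep=SEP)
    roi_ids = labels["roi_id"].astype(str).tolist()
    tr = 1.0
    if (base / "sampling.json").exists():
        with open(base / "sampling.json") as fh:
            tr = float(json.load(fh)["sampling_interval_s"])
    data = []
    for _, row in manifest.iterrows():
        path = base / str(row["path"])
        if not path.exists():
            raise FileNotFoundError(f"manifest row {row['subject_id']!r}: missing file {path}")
        df = pd.read_csv(path, sep=SEP)
        if list(df.columns) != roi_ids:
            raise ValueError(
                f"subject {row['subject_id']!r}: ROI columns do not match roi_labels.tsv"
            )
        data.append(df.to_numpy(dtype=float).T)
    shapes = {d.shape for d in data}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent matrix shapes across subjects: {sorted(shapes)}")
    cohort = CohortTimeSeries(
        data=np.array(data),
        roi_ids=roi_ids,
        roi_tissue=labels["tissue"].to_numpy(),
        subjects=manifest["subject_id"].astype(str).tolist(),
        group=manifest["group"].to_numpy(),
        age=manifest["age"].to_numpy(dtype=float),
        sex=manifest["sex"].to_numpy(dtype=int),
        sampling_interval_s=tr,
        mean_fd=manifest["mean_fd"].to_numpy(dtype=float) if "mean_fd" in manifest else None,
    )
    cohort.validate()
    return cohort


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "roi_to_network": {t: a.tolist() for t, a in truth.roi_to_network.items()},
        "network_names": truth.network_names,
        "state_correlations": [c.tolist() for c in truth.state_correlations],
        "true_centroids": truth.true_centroids.tolist(),
        "state_sequence": {s: seq.tolist() for s, seq in truth.state_sequence.items()},
        "tr_state_sequence": {s: seq.tolist() for s, seq in truth.tr_state_sequence.items()},
        "group_effect_table": truth.group_effect_table.to_dict(orient="records"),
        "window_length_tr": truth.window_length_tr,
        "step_tr": truth.step_tr,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        roi_to_network={t: np.array(a) for t, a in payload["roi_to_network"].items()},
        network_names=payload["network_names"],
        state_correlations=[np.array(c) for c in payload["state_correlations"]],
        true_centroids=np.array(payload["true_centroids"]),
        state_sequence={s: np.array(q) for s, q in payload["state_sequence"].items()},
        tr_state_sequence={s: np.array(q) for s, q in payload["tr_state_sequence"].items()},
        group_effect_table=pd.DataFrame(
            payload["group_effect_table"],
            columns=["group", "state", "edge_i", "edge_j", "shift"],
        ),
        window_length_tr=payload["window_length_tr"],
        step_tr=payload["step_tr"],
    )


# ---------------------------------------------------------------- NIfTI
def extract_roi_from_nifti(
    image_path: str | Path,
    label_path: str | Path,
    atlas_ids: list[int] | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Mean time course per labeled region of a 4-D NIfTI image.

    Returns an (n_roi, T) matrix and the label ids used (sorted).  Labels
    present in the volume but absent from ``atlas_ids`` (when given) are
    excluded with a warning, as are empty labels.
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    lab = nib.load(str(label_path))
    if img.shape[:3] != lab.shape[:3]:
        raise ValueError(f"grid mismatch: image {img.shape[:3]} vs labels {lab.shape[:3]}")
    vol = np.asarray(img.dataobj, dtype=float).reshape(-1, img.shape[3])
    labels = np.asarray(lab.dataobj).astype(int).reshape(-1)
    present = [int(v) for v in np.unique(labels) if v != 0]
    if atlas_ids is not None:
        unknown = sorted(set(present) - set(atlas_ids))
        if unknown:
            warnings.warn(f"label ids not in atlas table, excluded: {unknown}")
        present = [v for v in atlas_ids if v in present]
        empty = sorted(set(atlas_ids) - set(present))
        if empty:
            warnings.warn(f"atlas labels with no voxels, dropped: {empty}")
    out = np.empty((len(present), img.shape[3]))
    for i, v in enumerate(present):
        out[i] = vol[labels == v].mean(axis=0)
    return out, present


# ---------------------------------------------------------------- stage tables
def write_partition(
    gm: NetworkPartition, wm: NetworkPartition, roi_ids: list[str], path: str | Path
) -> None:
    tissue = ["GM"] * gm.assignment.size + ["WM"] * wm.assignment.size
    network = np.concatenate([gm.assignment + 1, wm.assignment + 1])
    pd.DataFrame({"roi_id": roi_ids, "tissue": tissue, "network": network}).to_csv(
        path, sep=SEP, index=False
    )


def load_partition(path: str | Path) -> tuple[NetworkPartition, NetworkPartition]:
    df = pd.read_csv(path, sep=SEP)
    parts = []
    for tissue in ("GM", "WM"):
        sub = df[df["tissue"] == tissue]
        assign = sub["network"].to_numpy(dtype=int) - 1
        parts.append(
            NetworkPartition(
                tissue=tissue, k=int(assign.max()) + 1, assignment=assign, distortion=np.nan
            )
        )
    return parts[0], parts[1]


def write_stability(profile: StabilityProfile, path: str | Path) -> None:
    pd.DataFrame({"k": profile.k_values, "mean_dice": profile.dice_per_k}).to_csv(
        path, sep=SEP, index=False
    )


def write_window_profile(profile: FdrWindowProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"window_length_tr": profile.window_lengths_tr, "j_score": profile.j_scores}
    ).to_csv(path, sep=SEP, index=False)


def write_windowed(
    windowed: list[WindowedFNC], edge_names: list[str], out_dir: str | Path
) -> None:
    """One wide TSV per subject: rows = windows, columns = edge names."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for w in windowed:
        pd.DataFrame(w.windows, columns=edge_names).to_csv(
            out_dir / f"{w.subject}_windows.tsv", sep=SEP, index=False, float_format="%.8g"
        )
    meta = {
        "window_length_tr": windowed[0].window_length_tr,
        "step_tr": windowed[0].step_tr,
        "subjects": [w.subject for w in windowed],
    }
    with open(out_dir / "windows.json", "w") as fh:
        json.dump(meta, fh)


def load_windowed(out_dir: str | Path) -> tuple[list[WindowedFNC], list[str]]:
    out_dir = Path(out_dir)
    with open(out_dir / "windows.json") as fh:
        meta = json.load(fh)
    out = []
    edge_names: list[str] = []
    for sid in meta["subjects"]:
        df = pd.read_csv(out_dir / f"{sid}_windows.tsv", sep=SEP)
        edge_names = list(df.columns)
        out.append(
            WindowedFNC(
                subject=sid,
                window_length_tr=meta["window_length_tr"],
                step_tr=meta["step_tr"],
                windows=df.to_numpy(dtype=float),
            )
        )
    return out, edge_names


def write_centroids(model: StateModel, edge_names: list[str], path: str | Path) -> None:
    df = pd.DataFrame(model.centroids, columns=edge_names)
    df.insert(0, "state", np.arange(1, model.ks + 1))
    df.to_csv(path, sep=SEP, index=False, float_format="%.8g")


def load_centroids(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep=SEP)
    edge_names = [c for c in df.columns if c != "state"]
    return df[edge_names].to_numpy(dtype=float), edge_names


def write_state_labels(model: StateModel, path: str | Path) -> None:
    rows = []
    for sid, seq in model.labels.items():
        for w, s in enumerate(seq):
            rows.append({"subject_id": sid, "window": w, "state": int(s) + 1})
    pd.DataFrame(rows).to_csv(path, sep=SEP, index=False)


def load_state_labels(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep=SEP)
    out = {}
    for sid, sub in df.groupby("subject_id", sort=False):
        out[str(sid)] = sub.sort_values("window")["state"].to_numpy(dtype=int) - 1
    return out


def write_elbow(profile: ElbowProfile, path: str | Path) -> None:
    pd.DataFrame({"ks": profile.ks_values, "within_between_ratio": profile.ratio}).to_csv(
        path, sep=SEP, index=False
    )


def write_matrix_table(
    mat: np.ndarray, path: str | Path, columns: list[str], index_name: str = "state"
) -> None:
    df = pd.DataFrame(mat, columns=columns)
    df.insert(0, index_name, np.arange(1, mat.shape[0] + 1))
    df.to_csv(path, sep=SEP, index=False, float_format="%.8g")
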