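"""End-to-end dFNC state analysis as a model / results pair.

:class:`DFNCStateAnalysis` is built from a :class:`~dynfnc.cohort.CohortTimeSeries`
plus stage parameters; :meth:`~DFNCStateAnalysis.fit` runs the pipeline

    GM/WM network derivation -> window-length selection -> sliding-window
    FNC (Fisher z, covariate regression) -> state clustering -> dual
    regression -> temporal statistics -> edge-wise group tests

and returns a :class:`DFNCStateResults` carrying every stage product, a
``summary()`` table, and a ``save()`` writer for the delimited artifacts.
All randomness derives from the single seed passed to ``fit``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import dfnc as dfnc_mod
from . import io as io_mod
from ._utils import edge_names as make_edge_names
from ._utils import spawn_seeds
from .cohort import CohortTimeSeries
from .dualreg import DualRegressionResult, dual_regression, group_states
from .networks import (
    NetworkPartition,
    StabilityProfile,
    average_fc,
    compute_static_fc,
    extract_network_timecourses,
    kmeans_partition,
    stability_select_k,
)
from .states import StateModel, cluster_states, elbow_select_ks, state_sfnc_correlation
from .stats import EdgeTestResult, edge_tests
from .temporal import TemporalStats, compute_temporal_stats


class DFNCStateAnalysis:
    """Dynamic FNC state model for a GM+WM resting-state cohort.

    Parameters mirror the pipeline stages.  ``k_gm`` / ``k_wm`` fix the
    network counts (skipping Dice stability selection); ``window_length_tr``
    fixes the sliding-window length (skipping the discriminability grid
    search); ``ks`` fixes the number of states (skipping the elbow).  The
    remaining parameters carry the study-scale defaults: K candidates 5-20,
    8 folds, chunk size 30, 50 selection / 100 final replications, window
    grid 10-100 TR in steps of 5, step 1 TR, state candidates 2-15 with 50
    replications, BH threshold q = 0.05.
    """

    def __init__(
        self,
        cohort: CohortTimeSeries,
        *,
        k_gm: int | None = None,
        k_wm: int | None = None,
        k_range: Sequence[int] = range(5, 21),
        nf: int = 8,
        cs: int = 30,
        select_replications: int = 50,
        final_replications: int = 100,
        window_length_tr: int | None = None,
        window_grid: Sequence[int] = range(10, 101, 5),
        step_tr: int = 1,
        ks: int | None = None,
        ks_range: Sequence[int] = range(2, 16),
        state_replications: int = 50,
        elbow_replications: int = 20,
        q: float = 0.05,
        fdr_variant: str = "canonical",
        ttest_equal_var: bool = False,
        hc_label: str = "HC",
        regress_covariates: bool = True,
    ) -> None:
        cohort.validate()
        self.cohort = cohort
        self.k_gm = k_gm
        self.k_wm = k_wm
        self.k_range = list(k_range)
        self.nf = nf
        self.cs = cs
        self.select_replications = select_replications
        self.final_replications = final_replications
        self.window_length_tr = window_length_tr
        self.window_grid = list(window_grid)
        self.step_tr = step_tr
        self.ks = ks
        self.ks_range = list(ks_range)
        self.state_replications = state_replications
        self.elbow_replications = elbow_replications
        self.q = q
        self.fdr_variant = fdr_variant
        self.ttest_equal_var = ttest_equal_var
        self.hc_label = hc_label
        self.regress_covariates = regress_covariates

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, **kwargs) -> "DFNCStateAnalysis":
        """Construct from an on-disk cohort manifest (see :mod:`dynfnc.io`)."""
        return cls(io_mod.load_cohort(manifest_path), **kwargs)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> "DFNCStateResults":
        """Run every pipeline stage; deterministic for a fixed seed."""
        seeds = spawn_seeds(seed, 6)
        cohort = self.cohort

        # 1. networks per tissue
        partitions: dict[str, NetworkPartition] = {}
        stability: dict[str, StabilityProfile | None] = {}
        for tissue, fixed_k, stage_seed in (
            ("GM", self.k_gm, seeds[0]),
            ("WM", self.k_wm, seeds[1]),
        ):
            fcs = [
                compute_static_fc(cohort.data[i], tissue=tissue, roi_tissue=cohort.roi_tissue)
                for i in range(cohort.n_subjects)
            ]
            avg = average_fc(fcs)
            if fixed_k is None:
                n_roi = avg.matrix.shape[0]
                k_range = [k for k in self.k_range if 2 <= k <= n_roi - 1]
                prof = stability_select_k(
                    avg,
                    k_range,
                    nf=self.nf,
                    cs=min(self.cs, n_roi),
                    n_replications=self.select_replications,
                    seed=stage_seed,
                )
                stability[tissue] = prof
                k = prof.selected_k
            else:
                stability[tissue] = None
                k = fixed_k
            partitions[tissue] = kmeans_partition(
                avg, k, n_replications=self.final_replications, seed=stage_seed
            )

        net_tcs, network_names = extract_network_timecourses(
            cohort, partitions["GM"], partitions["WM"]
        )
        edge_labels = make_edge_names(network_names)

        # 2. window length
        if self.window_length_tr is None:
            grid = [g for g in self.window_grid if 3 <= g <= cohort.n_timepoints]
            window_profile = dfnc_mod.select_window_length(
                net_tcs,
                cohort.group,
                grid,
                hc_label=self.hc_label,
                step_tr=self.step_tr,
                variant=self.fdr_variant,
            )
            L = window_profile.selected_length_tr
        else:
            window_profile = None
            L = self.window_length_tr

        # 3. windowed FNC + covariate regression
        windowed = [
            dfnc_mod.sliding_window_fnc(net_tcs[i], L, self.step_tr, subject=cohort.subjects[i])
            for i in range(cohort.n_subjects)
        ]
        static_raw = [
            dfnc_mod.WindowedFNC(
                subject=cohort.subjects[i],
                window_length_tr=cohort.n_timepoints,
                step_tr=self.step_tr,
                windows=dfnc_mod.static_fnc(net_tcs[i])[None, :],
            )
            for i in range(cohort.n_subjects)
        ]
        if self.regress_covariates:
            windowed = dfnc_mod.regress_covariates(windowed, cohort.age, cohort.sex)
            static_raw = dfnc_mod.regress_covariates(static_raw, cohort.age, cohort.sex)
        static_z = np.vstack([s.windows[0] for s in static_raw])
        dstd = np.vstack([dfnc_mod.dfnc_std(w) for w in windowed])

        # 4. states
        if self.ks is None:
            ks, elbow = elbow_select_ks(
                windowed,
                [k for k in self.ks_range if k <= sum(w.n_windows for w in windowed)],
                n_replications=self.elbow_replications,
                seed=seeds[2],
                return_profile=True,
            )
        else:
            ks, elbow = self.ks, None
        state_model = cluster_states(
            windowed, ks, n_replications=self.state_replications, seed=seeds[3]
        )
        state_model.elbow_profile = elbow

        # 5. dual regression and group states
        dr: dict[str, DualRegressionResult] = {}
        for w in windowed:
            dr[w.subject] = dual_regression(w.windows, state_model.centroids, subject=w.subject)
        group_map = {sid: str(g) for sid, g in zip(cohort.subjects, cohort.group)}
        per_group_states = group_states(dr, group_map)

        # 6. temporal statistics (per group and for pooled TLE)
        pooled_map = {
            sid: (g if g == self.hc_label else "TLE") for sid, g in group_map.items()
        }
        temporal = compute_temporal_stats(state_model.labels, group_map, ks)
        temporal_pooled = compute_temporal_stats(state_model.labels, pooled_map, ks)

        # 7. edge-wise group tests: HC vs pooled non-HC, per context
        hc_mask = cohort.group == self.hc_label
        tests: dict[str, EdgeTestResult] = {}
        if hc_mask.any() and not hc_mask.all():
            tests["sFNC"] = edge_tests(
                static_z[hc_mask],
                static_z[~hc_mask],
                context="sFNC",
                edge_names=edge_labels,
                q=self.q,
                equal_var=self.ttest_equal_var,
            )
            tests["dFNC-STD"] = edge_tests(
                dstd[hc_mask],
                dstd[~hc_mask],
                context="dFNC-STD",
                edge_names=edge_labels,
                q=self.q,
                equal_var=self.ttest_equal_var,
            )
            beta2 = np.stack([dr[sid].beta2 for sid in cohort.subjects])
            for s in range(ks):
                tests[f"state {s + 1}"] = edge_tests(
                    beta2[hc_mask, s, :],
                    beta2[~hc_mask, s, :],
                    context=f"state {s + 1}",
                    edge_names=edge_labels,
                    q=self.q,
                    equal_var=self.ttest_equal_var,
                )

        return DFNCStateResults(
            model=self,
            seed=seed,
            network_names=network_names,
            edge_names=edge_labels,
            partitions=partitions,
            stability=stability,
            network_timecourses=net_tcs,
            window_profile=window_profile,
            window_length_tr=L,
            windowed=windowed,
            static_fnc=static_z,
            dfnc_std=dstd,
            state_model=state_model,
            dual_regression=dr,
            group_states=per_group_states,
            temporal=temporal,
            temporal_pooled=temporal_pooled,
            edge_tests=tests,
        )


@dataclass
class DFNCStateResults:
    """Every product of a fitted dFNC state analysis."""

    model: DFNCStateAnalysis
    seed: int
    network_names: list[str]
    edge_names: list[str]
    partitions: dict[str, NetworkPartition]
    stability: dict[str, StabilityProfile | None]
    network_timecourses: np.ndarray
    window_profile: dfnc_mod.FdrWindowProfile | None
    window_length_tr: int
    windowed: list[dfnc_mod.WindowedFNC]
    static_fnc: np.ndarray
    dfnc_std: np.ndarray
    state_model: StateModel
    dual_regression: dict[str, DualRegressionResult]
    group_states: dict[str, np.ndarray]
    temporal: TemporalStats
    temporal_pooled: TemporalStats
    edge_tests: dict[str, EdgeTestResult] = field(default_factory=dict)

    # ------------------------------------------------------------------
    def state_sfnc_correlation(self) -> np.ndarray:
        """Correlation of each state centroid with the grand-mean sFNC."""
        return state_sfnc_correlation(self.state_model, self.static_fnc.mean(axis=0))

    def significant_edge_counts(self) -> pd.DataFrame:
        rows = []
        for ctx, res in self.edge_tests.items():
            sig = res.table[res.table["significant"]]
            rows.append(
                {
                    "context": ctx,
                    "n_significant": len(sig),
                    "n_increased": int((sig["direction"] == "increased").sum()),
                    "n_decreased": int((sig["direction"] == "decreased").sum()),
                }
            )
        return pd.DataFrame(rows, columns=["context", "n_significant", "n_increased", "n_decreased"])

    def summary(self) -> str:
        """Plain-text overview of the fitted analysis."""
        c = self.model.cohort
        lines = [
            "Dynamic FNC state analysis",
            "==========================",
            f"subjects: {c.n_subjects} "
            + ", ".join(f"{g}={int((c.group == g).sum())}" for g in c.groups),
            f"ROIs: {c.n_roi} (GM={c.tissue_indices('GM').size}, "
            f"WM={c.tissue_indices('WM').size}); timepoints: {c.n_timepoints}; "
            f"TR: {c.sampling_interval_s:g} s",
            f"networks: GM K1={self.partitions['GM'].k}, WM K2={self.partitions['WM'].k}"
            + "".join(
                f" ({t} Dice {p.dice_per_k[list(p.k_values).index(p.selected_k)]:.3f} at K={p.selected_k})"
                for t, p in self.stability.items()
                if p is not None
            ),
            f"window length: {self.window_length_tr} TR"
            + (
                f" (J={self.window_profile.j_scores.max():.4g} over grid "
                f"{self.window_profile.window_lengths_tr[0]}-{self.window_profile.window_lengths_tr[-1]})"
                if self.window_profile is not None
                else " (fixed)"
            ),
            f"windows per subject: {self.windowed[0].n_windows}; edges: {len(self.edge_names)}",
            f"states: ks={self.state_model.ks}"
            + (
                ""
                if self.state_model.elbow_profile is None
                else f" (elbow over {self.state_model.elbow_profile.ks_values[0]}"
                f"-{self.state_model.elbow_profile.ks_values[-1]})"
            ),
            "state-sFNC correlation: "
            + ", ".join(f"{r:+.2f}" for r in self.state_sfnc_correlation()),
            "state-changing probability: "
            + ", ".join(f"{g}={p:.3f}" for g, p in self.temporal.changing_probability.items()),
        ]
        counts = self.significant_edge_counts()
        if len(counts):
            lines.append(f"significant edges at q={self.model.q:g}:")
            for _, row in counts.iterrows():
                lines.append(
                    f"  {row['context']}: {row['n_significant']} "
                    f"({row['n_increased']} increased, {row['n_decreased']} decreased in TLE)"
                )
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, out_dir: str | Path) -> Path:
        """Write all stage tables to ``out_dir`` (tab-separated text)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        c = self.model.cohort
        gm_ids = [c.roi_ids[i] for i in c.tissue_indices("GM")]
        wm_ids = [c.roi_ids[i] for i in c.tissue_indices("WM")]
        io_mod.write_partition(
            self.partitions["GM"], self.partitions["WM"], gm_ids + wm_ids, out / "partition.tsv"
        )
        for tissue, prof in self.stability.items():
            if prof is not None:
                io_mod.write_stability(prof, out / f"stability_{tissue}.tsv")
        if self.window_profile is not None:
            io_mod.write_window_profile(self.window_profile, out / "window_profile.tsv")
        io_mod.write_windowed(self.windowed, self.edge_names, out / "windows")
        io_mod.write_centroids(self.state_model, self.edge_names, out / "state_centroids.tsv")
        io_mod.write_state_labels(self.state_model, out / "state_labels.tsv")
        if self.state_model.elbow_profile is not None:
            io_mod.write_elbow(self.state_model.elbow_profile, out / "elbow_profile.tsv")
        pd.DataFrame(
            {"subject_id": list(c.subjects), "group": c.group}
        ).to_csv(out / "groups.tsv", sep="\t", index=False)
        for g, mat in self.group_states.items():
            io_mod.write_matrix_table(mat, out / f"group_state_{g}.tsv", self.edge_names)
        occ = pd.DataFrame(self.temporal.occupancy).T
        occ.columns = [f"state{s + 1}" for s in range(self.state_model.ks)]
        occ.index.name = "group"
        occ.to_csv(out / "occupancy.tsv", sep="\t")
        for g in self.temporal.conditional:
            io_mod.write_matrix_table(
                self.temporal.conditional[g],
                out / f"transition_conditional_{g}.tsv",
                [f"state{s + 1}" for s in range(self.state_model.ks)],
            )
        pd.DataFrame(
            [{"group": g, "changing_probability": p} for g, p in
             self.temporal.changing_probability.items()]
        ).to_csv(out / "changing_probability.tsv", sep="\t", index=False)
        for ctx, res in self.edge_tests.items():
            safe = ctx.replace(" ", "_")
            res.table.to_csv(out / f"edge_tests_{safe}.tsv", sep="\t", index=False)
        self.significant_edge_counts().to_csv(
            out / "significant_edge_counts.tsv", sep="\t", index=False
        )
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
        return out
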