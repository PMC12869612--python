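"""Sliding-window FNC, covariate regression, and window-length selection."""

import numpy as np
import pytest

from dynfnc.dfnc import (
    WindowedFNC,
    dfnc_std,
    fdr_window_score,
    regress_covariates,
    select_window_length,
    sliding_window_fnc,
    static_fnc,
)


class TestStaticFNC:
    def test_closed_form_half_correlation(self, rng):
        # two series engineered to correlate at exactly 0.5
        n = 4000
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        b = a * 0.5 + b * np.sqrt(0.75)
        # orthogonalize the residual exactly so corr(a, y) == 0.5
        a0 = (a - a.mean()) / a.std()
        r = b - (b @ a0) / n * a0 * (n / (a0 @ a0)) * 1.0
        r = r - r.mean()
        y = 0.5 * a0 + np.sqrt(0.75) * r / r.std()
        z = static_fnc(np.vstack([a0, y]))
        assert z[0] == pytest.approx(np.arctanh(0.5), abs=1e-10)

    def test_identical_pair_clipped_finite(self):
        x = np.sin(np.linspace(0, 10, 100))
        z = static_fnc(np.vstack([x, x]))
        assert np.isfinite(z[0])
        assert z[0] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_orthogonal_sinusoids_give_zero(self):
        t = np.arange(200)
        x = np.sin(2 * np.pi * 5 * t / 200)
        y = np.cos(2 * np.pi * 5 * t / 200)
        assert static_fnc(np.vstack([x, y]))[0] == pytest.approx(0.0, abs=1e-10)


class TestSlidingWindow:
    def test_window_count_is_t_minus_l_plus_one(self, rng):
        tcs = rng.standard_normal((3, 361))
        wf = sliding_window_fnc(tcs, 45, 1)
        assert wf.n_windows == 317  # 361 - 45 + 1
        assert wf.n_edges == 3

    def test_full_length_window_equals_static(self, rng):
        tcs = rng.standard_normal((4, 120))
        wf = sliding_window_fnc(tcs, 120, 1)
        assert wf.n_windows == 1
        assert np.allclose(wf.windows[0], static_fnc(tcs))

    def test_constant_window_rejected_with_context(self):
        tcs = np.vstack([np.r_[np.ones(10), np.arange(10.0)], np.arange(20.0)])
        with pytest.raises(ValueError, match="window 0"):
            sliding_window_fnc(tcs, 5, 1, subject="s1")

    def test_too_short_or_long_window_rejected(self, rng):
        tcs = rng.standard_normal((2, 50))
        with pytest.raises(ValueError):
            sliding_window_fnc(tcs, 2, 1)
        with pytest.raises(ValueError):
            sliding_window_fnc(tcs, 51, 1)


class TestDfncStd:
    def test_identical_windows_give_zero(self):
        wf = WindowedFNC("s", 10, 1, np.tile([0.3, -0.2], (8, 1)))
        assert np.allclose(dfnc_std(wf), 0.0)

    def test_two_valued_sequence_closed_form(self):
        a = 0.7
        w = 10
        vals = np.tile([a, -a], w // 2)[:, None]
        wf = WindowedFNC("s", 10, 1, vals)
        assert dfnc_std(wf)[0] == pytest.approx(a * np.sqrt(w / (w - 1)))

    def test_invariant_to_window_order(self, rng):
        win = rng.standard_normal((30, 6))
        perm = rng.permutation(30)
        assert np.allclose(
            dfnc_std(WindowedFNC("s", 5, 1, win)), dfnc_std(WindowedFNC("s", 5, 1, win[perm]))
        )

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            dfnc_std(WindowedFNC("s", 5, 1, np.zeros((1, 3))))


class TestRegressCovariates:
    def _windowed(self, values, n_windows=4):
        return [
            WindowedFNC(f"s{i}", 10, 1, np.tile(v, (n_windows, 1))) for i, v in enumerate(values)
        ]

    def test_planted_age_slope_removed(self, rng):
        n = 60
        age = rng.uniform(20, 60, n)
        sex = rng.integers(0, 2, n)
        beta = 0.02
        base = rng.standard_normal((n, 3)) * 0.1
        base[:, 1] += beta * age
        windowed = self._windowed(base)
        out = regress_covariates(windowed, age, sex)
        resid = np.vstack([w.windows[0] for w in out])
        assert abs(np.corrcoef(resid[:, 1], age)[0, 1]) < 0.05

    def test_constant_values_unchanged(self, rng):
        n = 10
        windowed = self._windowed([np.array([0.4, -0.1])] * n)
        out = regress_covariates(windowed, rng.uniform(20, 60, n), rng.integers(0, 2, n))
        assert np.allclose(np.vstack([w.windows for w in out]), [0.4, -0.1], atol=1e-10)

    def test_grand_mean_preserved(self, rng):
        n = 20
        vals = [rng.standard_normal(5) for _ in range(n)]
        windowed = self._windowed(vals)
        out = regress_covariates(windowed, rng.uniform(20, 60, n), rng.integers(0, 2, n))
        before = np.vstack([w.windows for w in windowed]).mean(axis=0)
        after = np.vstack([w.windows for w in out]).mean(axis=0)
        assert np.allclose(before, after, atol=1e-10)

    def test_single_sex_design_rejected(self, rng):
        windowed = self._windowed([rng.standard_normal(3) for _ in range(5)])
        with pytest.raises(ValueError, match="rank"):
            regress_covariates(windowed, rng.uniform(20, 60, 5), np.ones(5))


class TestFdrWindowScore:
    def test_identical_groups_give_zero(self, rng):
        x = rng.standard_normal(20) * 0.1 + 0.5
        assert fdr_window_score(x, x.copy()) == 0.0

    def test_arithmetic_from_canonical_formula(self):
        d = np.sqrt(0.005)  # two-point samples with ddof-1 variance 0.01
        hc = np.array([0.3 - d, 0.3 + d])
        tle = np.array([0.1 - d, 0.1 + d])
        # J = (0.3 - 0.1)^2 / (0.01 + 0.01) = 2.0
        assert fdr_window_score(hc, tle) == pytest.approx(2.0)

    def test_group_exchange_invariance_canonical_only(self):
        a = np.array([0.3, 0.4, 0.5])
        b = np.array([0.1, 0.15, 0.2])
        assert fdr_window_score(a, b) == pytest.approx(fdr_window_score(b, a))
        # the literal printed form can go negative when the lower-mean group
        # has the higher variance, unlike the canonical ratio
        lo_var = np.array([0.30, 0.31, 0.32])
        hi_var = np.array([0.0, 0.1, 0.2])
        assert fdr_window_score(lo_var, hi_var, variant="literal") < 0
        assert fdr_window_score(lo_var, hi_var) > 0

    def test_zero_variance_sentinel(self):
        with pytest.warns(UserWarning, match="infinite"):
            j = fdr_window_score(np.array([0.3, 0.3]), np.array([0.1, 0.1]))
        assert np.isinf(j)


class TestSelectWindowLength:
    def test_singleton_grid(self, rng):
        tcs = rng.standard_normal((6, 3, 100))
        group = np.array(["HC", "HC", "HC", "TLE", "TLE", "TLE"])
        prof = select_window_length(tcs, group, [30])
        assert prof.selected_length_tr == 30

    def test_identical_groups_flagged_non_discriminative(self, rng):
        base = rng.standard_normal((3, 3, 100))
        tcs = np.concatenate([base, base])  # TLE subjects duplicate HC exactly
        group = np.array(["HC"] * 3 + ["TLE"] * 3)
        with pytest.warns(UserWarning, match="non-discriminative"):
            prof = select_window_length(tcs, group, [20, 40])
        assert not prof.discriminative
        assert np.allclose(prof.j_scores, 0.0, atol=1e-20)

    def test_grouplabels_required(self, rng):
        tcs = rng.standard_normal((4, 3, 80))
        with pytest.raises(ValueError, match="comparison group"):
            select_window_length(tcs, np.array(["HC"] * 4), [20])

    def test_state_scale_group_difference_peaks_inside_grid(self):
        """A dwell-scale group contrast is best separated at an interior window length."""
        from dynfnc import GroupEffect, SynthConfig, generate_cohort
        from dynfnc.networks import NetworkPartition, extract_network_timecourses
        from dynfnc.synth import make_state_correlations

        edges = ((0, 3), (1, 4), (2, 5))
        states = make_state_correlations(
            2, 6, seed=21, ridge=2.0, fixed_norm=True, zero_edges=edges
        )
        # TLE has opposite-sign state contrast on three edges: a purely
        # state-scale group difference, invisible to any single window
        effects = [GroupEffect("TLE", 0, e, 0.5) for e in edges] + [
            GroupEffect("TLE", 1, e, -0.5) for e in edges
        ]
        cfg = SynthConfig(
            n_subjects_per_group={"HC": 20, "TLE": 20},
            n_roi_gm=24,
            n_roi_wm=12,
            k1_true=4,
            k2_true=2,
            ks_true=2,
            n_timepoints=450,
            window_length_tr=40,
            dwell_mean_windows=40,
            state_covariances=states,
            subject_state_jitter_z=0.1,
            group_effects=effects,
            seed=21,
        )
        cohort, truth = generate_cohort(cfg)
        gm = NetworkPartition("GM", 4, truth.roi_to_network["GM"], 0.0)
        wm = NetworkPartition("WM", 2, truth.roi_to_network["WM"], 0.0)
        tcs, _ = extract_network_timecourses(cohort, gm, wm)
        grid = [10, 40, 90, 180]
        prof = select_window_length(tcs, cohort.group, grid)
        assert prof.discriminative
        sel_j = prof.j_scores[list(prof.window_lengths_tr).index(prof.selected_length_tr)]
        assert sel_j > prof.j_scores[0] and sel_j > prof.j_scores[-1]
        assert 10 < prof.selected_length_tr < 180
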