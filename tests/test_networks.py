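"""Static FC, K-means partitioning, and Dice stability selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from dynfnc.networks import (
    StaticFC,
    average_fc,
    coassignment_adjacency,
    compute_static_fc,
    dice_adjacency,
    extract_network_timecourses,
    kmeans_partition,
    stability_select_k,
)
from dynfnc.synth import block_assignment, plant_block_fc


class TestStaticFC:
    def test_identical_and_opposite_signals(self, rng):
        x = rng.standard_normal(20)
        fc = compute_static_fc(np.vstack([x, x, -x]))
        assert fc.matrix[0, 1] == pytest.approx(1.0)
        assert fc.matrix[0, 2] == pytest.approx(-1.0)

    def test_matches_hand_computed_pearson(self):
        """Entry-by-entry agreement with the explicit covariance/sigma formula."""
        series = np.array(
            [[1.0, 2.0, 3.0, 4.0, 5.0], [2.0, 1.0, 4.0, 3.0, 6.0], [5.0, 3.0, 2.0, 1.0, 1.0]]
        )
        fc = compute_static_fc(series)
        for i in range(3):
            for j in range(3):
                xi = series[i] - series[i].mean()
                xj = series[j] - series[j].mean()
                expected = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                assert fc.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_roi_rejected(self):
        series = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            compute_static_fc(series)

    def test_tissue_mask_restricts_rows(self, rng):
        series = rng.standard_normal((4, 30))
        tissue = np.array(["GM", "WM", "GM", "WM"])
        fc = compute_static_fc(series, tissue="WM", roi_tissue=tissue)
        assert fc.matrix.shape == (2, 2)


class TestAverageFC:
    def test_identity_and_cancellation(self, rng):
        m = np.corrcoef(rng.standard_normal((4, 50)))
        fc = StaticFC("GM", m)
        assert np.allclose(average_fc([fc]).matrix, m)
        neg = StaticFC("GM", -m + 2 * np.eye(4) * m[0, 0])
        neg.matrix = -m.copy()
        np.fill_diagonal(neg.matrix, 1.0)
        avg = average_fc([fc, neg])
        off = avg.matrix[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)
        assert np.all(np.diag(avg.matrix) == 1.0)

    def test_entrywise_mean_of_three(self, rng):
        mats = [np.corrcoef(rng.standard_normal((3, 40))) for _ in range(3)]
        avg = average_fc([StaticFC("WM", m) for m in mats])
        assert np.allclose(avg.matrix, np.mean(mats, axis=0))
        assert avg.scope == "group-average"

    def test_mixed_tissues_rejected(self, rng):
        a = StaticFC("GM", np.eye(3))
        b = StaticFC("WM", np.eye(3))
        with pytest.raises(ValueError, match="mixed tissues"):
            average_fc([a, b])


class TestKmeansPartition:
    def test_forced_blocks_recovered_exactly(self):
        fc = StaticFC("GM", plant_block_fc(4, 2, 1.0, 0.0))
        part = kmeans_partition(fc, 2, n_replications=5, seed=0)
        assert part.assignment[0] == part.assignment[1]
        assert part.assignment[2] == part.assignment[3]
        assert part.assignment[0] != part.assignment[2]

    def test_planted_six_blocks_ari_one(self):
        fc = StaticFC("GM", plant_block_fc(60, 6, 0.8, 0.1))
        part = kmeans_partition(fc, 6, n_replications=20, seed=1)
        assert adjusted_rand_score(block_assignment(60, 6), part.assignment) == 1.0

    def test_distortion_non_increasing_in_replications(self):
        rng = np.random.default_rng(7)
        noisy = plant_block_fc(30, 3, 0.7, 0.2) + 0.05 * rng.standard_normal((30, 30))
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 1.0)
        fc = StaticFC("GM", np.clip(noisy, -1, 1))
        d = [kmeans_partition(fc, 5, n_replications=r, seed=3).distortion for r in (1, 5, 20)]
        assert d[0] >= d[1] >= d[2]

    def test_invalid_k_rejected(self):
        fc = StaticFC("GM", plant_block_fc(6, 2, 0.9, 0.0))
        with pytest.raises(ValueError):
            kmeans_partition(fc, 1)
        with pytest.raises(ValueError):
            kmeans_partition(fc, 7)


class TestDiceAdjacency:
    def test_identity_and_disjoint(self):
        a = coassignment_adjacency(np.array([0, 0, 1, 1]))
        assert dice_adjacency(a, a) == 1.0
        b = np.zeros((4, 4), dtype=int)
        b[0, 2] = b[2, 0] = 1
        a2 = np.zeros((4, 4), dtype=int)
        a2[0, 1] = a2[1, 0] = 1
        assert dice_adjacency(a2, b) == 0.0

    def test_hand_enumerated_overlap(self):
        # |a| = 4, |b| = 6, overlap 2 (off-diagonal counts) -> 2*2/(4+6) = 0.4
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = 1
        a[2, 3] = a[3, 2] = 1
        b = np.zeros((4, 4), dtype=int)
        b[0, 1] = b[1, 0] = 1
        b[0, 2] = b[2, 0] = 1
        b[1, 3] = b[3, 1] = 1
        assert dice_adjacency(a, b) == pytest.approx(0.4)

    def test_all_zero_convention(self):
        z = np.zeros((3, 3), dtype=int)
        assert dice_adjacency(z, z) == 1.0

    def test_shape_mismatch_and_non_binary_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dice_adjacency(np.zeros((3, 3)), np.zeros((4, 4)))
        with pytest.raises(ValueError, match="binary"):
            dice_adjacency(np.full((3, 3), 0.5), np.zeros((3, 3)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = coassignment_adjacency(rng.integers(0, 3, size=8))
        b = coassignment_adjacency(rng.integers(0, 3, size=8))
        d = dice_adjacency(a, b)
        assert d == dice_adjacency(b, a)
        assert 0.0 <= d <= 1.0


class TestStabilitySelection:
    def test_noiseless_two_blocks_perfectly_stable_at_two(self):
        fc = StaticFC("GM", plant_block_fc(40, 2, 0.9, 0.0))
        prof = stability_select_k(fc, [2, 3, 4], nf=4, cs=20, n_replications=8, seed=2)
        assert prof.dice_per_k[0] == pytest.approx(1.0)
        assert prof.dice_per_k[1] < 1.0 and prof.dice_per_k[2] < 1.0

    def test_planted_block_count_selected(self):
        fc = StaticFC("GM", plant_block_fc(60, 6, 0.9, 0.05))
        prof = stability_select_k(fc, range(2, 13), nf=8, cs=30, n_replications=8, seed=3)
        assert prof.selected_k == 6
        at6 = prof.dice_per_k[list(prof.k_values).index(6)]
        assert at6 == pytest.approx(1.0)

    def test_oversized_chunk_rejected(self):
        fc = StaticFC("GM", plant_block_fc(10, 2, 0.9, 0.0))
        with pytest.raises(ValueError, match="chunk"):
            stability_select_k(fc, [2, 3], nf=2, cs=11, n_replications=2, seed=0)


class TestNetworkTimecourses:
    def test_single_roi_network_passthrough_and_cancellation(self, three_state_cohort):
        cfg, cohort, truth = three_state_cohort
        from dynfnc.networks import NetworkPartition

        gm = NetworkPartition("GM", cfg.k1_true, truth.roi_to_network["GM"], 0.0)
        wm = NetworkPartition("WM", cfg.k2_true, truth.roi_to_network["WM"], 0.0)
        tcs, names = extract_network_timecourses(cohort, gm, wm)
        assert tcs.shape == (cohort.n_subjects, cfg.k1_true + cfg.k2_true, cfg.n_timepoints)
        assert names[0] == "GM1" and names[-1] == f"WM{cfg.k2_true}"
        # each network time course is the arithmetic mean of its member ROIs
        gm_idx = cohort.tissue_indices("GM")
        members = gm_idx[truth.roi_to_network["GM"] == 0]
        assert np.allclose(tcs[0, 0], cohort.data[0, members].mean(axis=0))
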