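"""Cosine K-means state clustering, elbow selection, state characterization."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from dynfnc.dfnc import WindowedFNC
from dynfnc.states import (
    StateModel,
    cluster_states,
    elbow_select_ks,
    state_sfnc_correlation,
    strongest_edges,
)


def make_pool(centroids, counts, noise, rng, n_subjects=4):
    """Pooled WindowedFNC objects drawn around given centroids."""
    vecs, labels = [], []
    for c, n in zip(centroids, counts):
        vecs.append(c + noise * rng.standard_normal((n, c.size)))
        labels.extend([len(labels) and None] * 0)
    x = np.vstack(vecs)
    true = np.concatenate([[i] * n for i, n in enumerate(counts)])
    perm = rng.permutation(x.shape[0])
    x, true = x[perm], true[perm]
    split = np.array_split(np.arange(x.shape[0]), n_subjects)
    windowed = [
        WindowedFNC(f"s{i}", 10, 1, x[idx]) for i, idx in enumerate(split)
    ]
    true_split = [true[idx] for idx in split]
    return windowed, np.concatenate(true_split)


def matched_accuracy(true, pred, k):
    conf = np.zeros((k, k))
    np.add.at(conf, (true, pred), 1)
    r, c = linear_sum_assignment(-conf)
    return conf[r, c].sum() / conf.sum()


class TestClusterStates:
    def test_single_state_centroid_is_pooled_mean(self, rng):
        x = rng.standard_normal((50, 8))
        windowed = [WindowedFNC("a", 5, 1, x[:30]), WindowedFNC("b", 5, 1, x[30:])]
        model = cluster_states(windowed, 1, n_replications=3, seed=0)
        assert np.allclose(model.centroids[0], x.mean(axis=0))

    def test_noiseless_copies_recovered_exactly(self, rng):
        base = rng.standard_normal((3, 12)) * 2
        windowed, true = make_pool(base, [40, 40, 40], 0.0, rng)
        model = cluster_states(windowed, 3, n_replications=5, seed=1)
        assert model.distortion == pytest.approx(0.0, abs=1e-9)
        pred = np.concatenate([model.labels[w.subject] for w in windowed])
        assert matched_accuracy(true, pred, 3) == 1.0

    def test_well_separated_states_recovered(self, rng):
        base = rng.standard_normal((3, 20)) * 2
        windowed, true = make_pool(base, [100, 80, 120], 0.4, rng)
        model = cluster_states(windowed, 3, n_replications=10, seed=2)
        pred = np.concatenate([model.labels[w.subject] for w in windowed])
        assert matched_accuracy(true, pred, 3) >= 0.95
        conf = np.zeros((3, 3))
        np.add.at(conf, (true, pred), 1)
        r, c = linear_sum_assignment(-conf)
        for ri, ci in zip(r, c):
            assert np.corrcoef(base[ri], model.centroids[ci])[0, 1] >= 0.95

    def test_degenerate_pool_rejected(self):
        x = np.tile([1.0, 2.0, 3.0], (10, 1))
        with pytest.raises(ValueError, match="distinct"):
            cluster_states([WindowedFNC("s", 5, 1, x)], 2)

    def test_deterministic_given_seed(self, rng):
        base = rng.standard_normal((2, 10))
        windowed, _ = make_pool(base, [30, 30], 0.5, rng)
        m1 = cluster_states(windowed, 2, n_replications=5, seed=9)
        m2 = cluster_states(windowed, 2, n_replications=5, seed=9)
        assert np.array_equal(m1.centroids, m2.centroids)
        assert all(np.array_equal(m1.labels[s], m2.labels[s]) for s in m1.labels)


class TestElbow:
    def test_planted_four_state_pool(self, rng):
        base = rng.standard_normal((4, 15)) * 2
        windowed, _ = make_pool(base, [80, 80, 80, 80], 0.3, rng)
        assert elbow_select_ks(windowed, range(2, 9), n_replications=5, seed=3) == 4

    def test_single_gaussian_flagged_flat(self, rng):
        x = rng.standard_normal((200, 10))
        windowed = [WindowedFNC("s", 5, 1, x)]
        with pytest.warns(UserWarning, match="flat|elbow"):
            _, prof = elbow_select_ks(
                windowed, range(2, 7), n_replications=4, seed=4, return_profile=True
            )
        assert not prof.clear_elbow

    def test_short_range_falls_back_to_argmin(self, rng):
        base = rng.standard_normal((2, 10)) * 2
        windowed, _ = make_pool(base, [50, 50], 0.2, rng)
        sel = elbow_select_ks(windowed, [2, 3], n_replications=4, seed=5)
        assert sel in (2, 3)


class TestStateCharacterization:
    def test_sfnc_correlation_identity_and_antipode(self, rng):
        v = rng.standard_normal(12)
        model = StateModel(ks=2, centroids=np.vstack([v, -v]), labels={}, distortion=0.0)
        r = state_sfnc_correlation(model, v)
        assert r[0] == pytest.approx(1.0)
        assert r[1] == pytest.approx(-1.0)

    def test_zero_variance_centroid_flagged(self, rng):
        model = StateModel(
            ks=1, centroids=np.zeros((1, 6)), labels={}, distortion=0.0
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            r = state_sfnc_correlation(model, rng.standard_normal(6))
        assert np.isnan(r[0])

    def test_constructed_state_most_similar_to_sfnc(self, rng):
        sfnc = rng.standard_normal(15)
        others = rng.standard_normal((2, 15)) * 2
        model = StateModel(
            ks=3,
            centroids=np.vstack([sfnc + 0.05 * rng.standard_normal(15), others]),
            labels={},
            distortion=0.0,
        )
        r = state_sfnc_correlation(model, sfnc)
        assert np.argmax(r) == 0


class TestStrongestEdges:
    def test_ceiling_count_at_one_percent(self, rng):
        vec = rng.standard_normal(231)  # 22 networks
        out = strongest_edges(vec, 0.01)
        assert len(out) == 3  # ceil(2.31)

    def test_dominant_entry_ranked_first_with_sign(self):
        vec = np.array([0.1, -0.9, 0.2])
        out = strongest_edges(vec, 0.34, network_names=["A", "B", "C"])
        assert out.iloc[0]["edge"] == 1
        assert out.iloc[0]["sign"] == "-"
        assert out.iloc[0]["net_a"] == "A" and out.iloc[0]["net_b"] == "C"

    def test_zero_vector_ties_break_by_index(self):
        out = strongest_edges(np.zeros(10), 0.25)
        assert list(out["edge"]) == [0, 1, 2]
        assert np.all(out["value"] == 0.0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            strongest_edges(np.ones(6), 1.5)
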