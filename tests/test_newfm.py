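"""Neuro-fuzzy base learner: update rule, convergence, defuzzification,
feature selection, serialization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zoomnn import NEWFM


# ---------------------------------------------------------------------------
# pure-Python reference of the training step rule (independent of the
# compiled kernel; used to pin its semantics bit-exactly)

def _mu_ref(x, crow, j, m, halfw):
    if m == 1:
        left, right = crow[0] - halfw, crow[0] + halfw
    else:
        left = crow[j - 1] if j > 0 else crow[0] - (crow[1] - crow[0])
        right = crow[j + 1] if j < m - 1 else crow[m - 1] + (crow[m - 1] - crow[m - 2])
    c = crow[j]
    if x < left or x > right:
        return 0.0
    rise = 1.0 if c <= left else (x - left) / (c - left)
    fall = 1.0 if right <= c else (right - x) / (right - c)
    return min(max(min(rise, fall), 0.0), 1.0)


def _fit_ref(X, y, m=3, alpha=0.1, delta=0.1, max_epochs=50, patience=3):
    f = X.shape[1]
    lo, hi = X.min(0), X.max(0)
    grid = lo[:, None] + (hi - lo)[:, None] * np.arange(m) / (m - 1)
    centers = np.repeat(grid[:, None, :], 2, axis=1).astype(float)
    weights = np.zeros_like(centers)
    halfw = hi - lo

    def accuracy():
        correct = 0
        for i in range(len(y)):
            s = [0.0, 0.0]
            for q in range(f):
                for cls in range(2):
                    b = sum(
                        weights[q, cls, j] * _mu_ref(X[i, q], centers[q, cls], j, m, halfw[q])
                        for j in range(m)
                    )
                    s[cls] += min(b, 1.0)
            correct += (1 if s[1] > s[0] else 0) == y[i]
        return correct / len(y)

    best, stall = -1.0, 0
    for _ in range(max_epochs):
        for i in range(len(y)):
            lab, opp = y[i], 1 - y[i]
            for q in range(f):
                x = X[i, q]
                mus_t = [_mu_ref(x, centers[q, lab], j, m, halfw[q]) for j in range(m)]
                mus_o = [_mu_ref(x, centers[q, opp], j, m, halfw[q]) for j in range(m)]
                wt, wo = int(np.argmax(mus_t)), int(np.argmax(mus_o))
                cn = centers[q, lab, wt] + alpha * (x - centers[q, lab, wt])
                if wt > 0:
                    cn = max(cn, centers[q, lab, wt - 1])
                if wt < m - 1:
                    cn = min(cn, centers[q, lab, wt + 1])
                centers[q, lab, wt] = cn
                weights[q, lab, wt] = min(1.0, weights[q, lab, wt] + delta)
                weights[q, opp, wo] = max(0.0, weights[q, opp, wo] - delta)
        acc = accuracy()
        if acc > best:
            best, stall = acc, 0
        else:
            stall += 1
            if stall >= patience:
                break
    return centers, weights


class TestInitialization:
    def test_centers_evenly_spaced(self):
        m = NEWFM.from_ranges([(0.0, 1.0)], n_mfs=3)
        assert np.allclose(m.centers_[0, 0], [0.0, 0.5, 1.0])
        assert np.allclose(m.centers_[0, 1], [0.0, 0.5, 1.0])

    def test_zero_weights_give_zero_bswfm(self):
        m = NEWFM.from_ranges([(0.0, 1.0), (2.0, 4.0)])
        x = np.array([[0.3, 2.5], [0.9, 3.9]])
        assert np.all(m.bswfm(x) == 0.0)

    def test_degenerate_range_padded_and_flagged(self):
        m = NEWFM.from_ranges([(1.0, 1.0)])
        assert m.degenerate_ranges_ == [0]
        assert m.ranges_[0, 0] < 1.0 < m.ranges_[0, 1]

    def test_no_features_rejected(self):
        with pytest.raises(ValueError):
            NEWFM.from_ranges(np.empty((0, 2)))


class TestTrainingRule:
    @pytest.mark.parametrize("seed", range(5))
    def test_kernel_matches_pure_python_step_rule(self, seed):
        """The compiled trainer reproduces an independently written
        pure-Python implementation of the update rule bit-for-bit."""
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, size=(12, 3))
        y = (rng.uniform(size=12) > 0.5).astype(int)
        if len(set(y)) < 2:
            y[0] = 1 - y[0]
        model = NEWFM(max_epochs=20).fit(X, y)
        c_ref, w_ref = _fit_ref(X, y, max_epochs=20)
        assert np.array_equal(model.centers_, c_ref)
        assert np.array_equal(model.weights_, w_ref)

    def test_separable_data_reaches_perfect_accuracy(self, separable_1d):
        X, y = separable_1d
        model = NEWFM(max_epochs=50).fit(X, y)
        assert model.train_accuracy_ == 1.0
        assert model.epochs_run_ <= 50
        assert np.array_equal(model.predict(X), y)

    def test_training_is_deterministic(self, separable_1d):
        X, y = separable_1d
        a = NEWFM().fit(X, y).to_dict()
        b = NEWFM().fit(X, y).to_dict()
        assert a == b

    def test_duplicated_instances_preserve_decision_sign_pattern(self, separable_1d):
        X, y = separable_1d
        m1 = NEWFM(max_epochs=30, patience=10 ** 9).fit(X, y)
        m2 = NEWFM(max_epochs=30, patience=10 ** 9).fit(np.repeat(X, 2, 0), np.repeat(y, 2))
        grid = np.linspace(0, 1, 21)[:, None]
        assert np.array_equal(m1.predict(grid), m2.predict(grid))

    def test_single_class_data_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            NEWFM().fit(np.array([[0.0], [1.0]]), np.array([0, 0]))


class TestClassification:
    def test_zero_class1_weights_always_predict_class0(self):
        m = NEWFM.from_ranges([(0.0, 1.0)])
        m.weights_[0, 0, :] = 0.5  # class 0 active, class 1 silent
        x = np.linspace(0, 1, 11)[:, None]
        assert np.all(m.predict(x) == 0)

    def test_mirrored_model_classifies_mirrored_points_oppositely(self):
        """A model whose class curves are mirror images about the feature
        midpoint must make mirror-opposite decisions."""
        m = NEWFM.from_ranges([(0.0, 1.0)])
        m.weights_[0, 0] = [1.0, 0.0, 0.0]  # class 0 peaks at x=0
        m.weights_[0, 1] = [0.0, 0.0, 1.0]  # class 1 peaks at x=1
        for x in (0.1, 0.25, 0.4):
            p, p_mirror = m.predict([[x]])[0], m.predict([[1 - x]])[0]
            assert {p, p_mirror} == {0, 1}


class TestDefuzzification:
    def test_pure_class0_membership_maps_to_zero(self):
        m = NEWFM.from_ranges([(0.0, 1.0)])
        m.weights_[0, 0] = [1.0, 1.0, 1.0]
        assert m.tsd([[0.5]])[0] == pytest.approx(0.0)

    def test_balanced_memberships_map_to_half(self):
        m = NEWFM.from_ranges([(0.0, 1.0)])
        m.weights_[0, :, :] = 0.7
        assert m.tsd([[0.3]])[0] == pytest.approx(0.5)

    def test_zero_denominator_maps_to_half(self):
        m = NEWFM.from_ranges([(0.0, 1.0)])
        assert m.tsd([[0.5]])[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_tsd_and_classify_agree_on_random_models(self, seed):
        """sign(tsd - 1/2) must match the class decision whenever some
        membership is active."""
        rng = np.random.default_rng(seed)
        n_f = rng.integers(1, 6)
        ranges = np.sort(rng.uniform(-5, 5, size=(n_f, 2)), axis=1)
        ranges[:, 1] += 0.1
        m = NEWFM.from_ranges(ranges)
        m.weights_[:] = rng.uniform(0, 1, m.weights_.shape)
        m.centers_[:] = np.sort(
            rng.uniform(ranges[:, 0, None, None], ranges[:, 1, None, None], (n_f, 2, 3)),
            axis=-1,
        )
        m._refresh_supports()
        X = rng.uniform(ranges[:, 0], ranges[:, 1], size=(50, n_f))
        b = m.bswfm(X)
        den = b.sum(axis=(1, 2))
        t = m.tsd(X)
        pred = m.predict(X)
        decisive = (den > 1e-12) & (np.abs(t - 0.5) > 1e-12)
        assert np.array_equal(t[decisive] > 0.5, pred[decisive] == 1)
        assert np.all((t >= 0) & (t <= 1))


class TestBoundsProperty:
    @given(st.integers(0, 10 ** 6))
    def test_bswfm_and_tsd_always_bounded(self, seed):
        rng = np.random.default_rng(seed)
        m = NEWFM.from_ranges([(-1.0, 1.0), (0.0, 2.0)])
        m.weights_[:] = rng.uniform(0, 3, m.weights_.shape)  # even >1 weights
        m.weights_ = np.clip(m.weights_, 0, 1)
        X = rng.uniform(-3, 3, size=(20, 2))  # including out-of-range inputs
        b = m.bswfm(X)
        assert np.all((b >= 0) & (b <= 1))
        t = m.tsd(X)
        assert np.all((t >= 0) & (t <= 1))


class TestFeatureSelection:
    def test_identical_class_curves_rank_last(self):
        m = NEWFM.from_ranges([(0.0, 1.0), (0.0, 1.0)])
        m.weights_[0, 0] = [1.0, 0, 0]
        m.weights_[0, 1] = [0, 0, 1.0]  # feature 0 discriminates
        m.weights_[1, :, :] = 0.5  # feature 1: identical curves
        m.feature_importances_ = m._non_overlap_areas()
        assert m.feature_importances_[1] == pytest.approx(0.0)
        assert m.select_features(2) == [0, 1]

    def test_all_features_kept_is_a_permutation(self, separable_1d):
        X, y = separable_1d
        X2 = np.hstack([X, X ** 2, 1 - X])
        m = NEWFM().fit(X2, y)
        assert sorted(m.select_features(3)) == [0, 1, 2]

    def test_separable_feature_beats_noise(self):
        """Across 20 seeded datasets the informative feature must win the
        top rank at least 18 times."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x_sep = np.array([0.1, 0.2, 0.8, 0.9])
            x_noise = rng.uniform(0, 1, 4)
            X = np.column_stack([x_noise, x_sep])  # informative one is index 1
            y = np.array([0, 0, 1, 1])
            m = NEWFM().fit(X, y)
            wins += m.select_features(1) == [1]
        assert wins >= 18

    def test_zero_keep_rejected(self, separable_1d):
        X, y = separable_1d
        m = NEWFM().fit(X, y)
        with pytest.raises(ValueError):
            m.select_features(0)


class TestSerialization:
    def test_round_trip_is_bit_exact(self, separable_1d):
        import json

        X, y = separable_1d
        m = NEWFM(n_select=1).fit(np.hstack([X, 1 - X]), y)
        blob = json.dumps(m.to_dict())
        m2 = NEWFM.from_dict(json.loads(blob))
        assert np.array_equal(m.centers_, m2.centers_)
        assert np.array_equal(m.weights_, m2.weights_)
        assert m.selected_ == m2.selected_
        grid = np.linspace(-1, 2, 31)
        probe = np.column_stack([grid, 1 - grid])
        assert np.array_equal(m.predict(probe), m2.predict(probe))
        assert np.array_equal(m.tsd(probe), m2.tsd(probe))

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="format"):
            NEWFM.from_dict({"format": "else"})
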