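"""Fold assignment, pseudo-trials, regularized LDA and searchlight decoding."""

import numpy as np
import pytest

from rpsdecode.core import DesignConfig, ResponseSymbol
from rpsdecode.decode import (
    DecoderConfig,
    StreamKind,
    assign_folds,
    decode_timecourse,
    lda_fit,
    lda_predict,
    make_pseudo_trials,
    searchlight,
    searchlight_neighbors,
    stream_labels,
)
from rpsdecode.layout import SensorLayout
from rpsdecode.preprocess import BinnedFeatures, Phase

from conftest import N, P, R, S, session_from_responses

PHASE_OF_BIN = tuple(
    p for p in (Phase.DECISION, Phase.RESPONSE, Phase.FEEDBACK) for _ in range(p.n_bins)
)


# --- label streams --------------------------------------------------------

def test_stream_labels_current_and_previous():
    session = session_from_responses([(R, P), (S, R), (N, S), (P, P)])
    own = stream_labels(session, 1, StreamKind.OWN_CURRENT)
    assert own.trial_indices.tolist() == [0, 1, 3]  # no-response game excluded
    assert own.labels.tolist() == [0, 2, 1]

    opp = stream_labels(session, 1, StreamKind.OPPONENT_CURRENT)
    assert opp.labels.tolist() == [1, 0, 2, 1]

    prev = stream_labels(session, 1, StreamKind.OWN_PREVIOUS)
    # game 1 undefined; game 3's predecessor is game 2 (S); game 4's is NO_RESPONSE
    assert prev.trial_indices.tolist() == [1, 2]
    assert prev.labels.tolist() == [0, 2]

    opp_prev = stream_labels(session, 2, StreamKind.OPPONENT_PREVIOUS)
    assert opp_prev.trial_indices.tolist() == [1, 2]  # player 2's opponent is player 1


# --- folds ----------------------------------------------------------------

def test_assign_folds_exact_division():
    labels = np.repeat([0, 1, 2], 100)
    folds = assign_folds(labels, 10, seed=0)
    for k in range(10):
        counts = np.bincount(labels[folds == k], minlength=3)
        assert counts.tolist() == [10, 10, 10]


def test_assign_folds_deterministic_and_balanced():
    rng = np.random.default_rng(0)
    labels = np.concatenate([np.zeros(160), np.ones(158), np.full(162, 2)]).astype(int)
    rng.shuffle(labels)
    a = assign_folds(labels, 10, seed=5)
    b = assign_folds(labels, 10, seed=5)
    np.testing.assert_array_equal(a, b)
    for c in range(3):
        sizes = np.bincount(a[labels == c], minlength=10)
        assert sizes.max() - sizes.min() <= 1


def test_assign_folds_insufficient_class_errors():
    labels = np.array([0] * 30 + [1] * 30 + [2] * 5)
    with pytest.raises(ValueError, match="class counts"):
        assign_folds(labels, 10, seed=0)


# --- pseudo-trials --------------------------------------------------------

def test_pseudo_trials_counts_and_means():
    rng = np.random.default_rng(1)
    cfg = DecoderConfig(seed=2, n_folds=3)
    n = 240  # 80 per fold, enough for disjoint groups of 4 per class
    labels = np.tile([0, 1, 2], n // 3)
    folds = np.repeat([0, 1, 2], n // 3)
    features = rng.standard_normal((n, 5, 4))
    pX, py = make_pseudo_trials(features, labels, folds, cfg)
    assert len(pX) == 3
    for X, y in zip(pX, py):
        assert X.shape == (60, 5, 4)
        assert np.bincount(y, minlength=3).tolist() == [20, 20, 20]


def test_pseudo_trials_of_identical_trials_equal_that_value():
    features = np.full((40, 3, 2), 6.5)
    labels = np.zeros(40, dtype=int)
    labels[20:] = 1
    folds = np.tile([0, 1], 20)
    pX, _ = make_pseudo_trials(features, labels, folds, DecoderConfig(seed=0, n_folds=2))
    for X in pX:
        np.testing.assert_allclose(X, 6.5)


def test_pseudo_trials_small_pool_resamples_with_warning():
    features = np.random.default_rng(3).standard_normal((9, 2, 1))
    labels = np.array([0, 1, 2] * 3)
    folds = np.zeros(9, dtype=int)
    cfg = DecoderConfig(seed=1, n_folds=10)  # n_folds unused here; pools of 3 < 4
    with pytest.warns(UserWarning, match="with replacement"):
        pX, py = make_pseudo_trials(features, labels, folds, cfg)
    assert pX[0].shape[0] == 60 and np.bincount(py[0]).tolist() == [20, 20, 20]


def test_pseudo_trials_empty_pool_errors():
    features = np.zeros((4, 2, 1))
    labels = np.array([0, 0, 1, 1])
    folds = np.array([0, 0, 1, 1])
    with pytest.raises(ValueError, match="fold 0 has no trials of class 1"):
        make_pseudo_trials(features, labels, folds, DecoderConfig(n_folds=2))


# --- LDA ------------------------------------------------------------------

def _brute_force_lda_predict(Xtr, ytr, Xte, lam):
    """Explicit matrix-formula discriminants, written independently."""
    classes = sorted(set(ytr))
    p = Xtr.shape[1]
    mus = {c: Xtr[ytr == c].mean(axis=0) for c in classes}
    S = np.zeros((p, p))
    for c in classes:
        diff = Xtr[ytr == c] - mus[c]
        S += diff.T @ diff
    sigma = S / (len(ytr) - len(classes))
    sigma_reg = (1 - lam) * sigma + lam * (np.trace(sigma) / p) * np.eye(p)
    inv = np.linalg.inv(sigma_reg)
    preds = []
    for x in Xte:
        scores = [x @ inv @ mus[c] - 0.5 * mus[c] @ inv @ mus[c] for c in classes]
        preds.append(classes[int(np.argmax(scores))])
    return np.array(preds)


def test_lda_matches_brute_force_matrix_formulas():
    rng = np.random.default_rng(4)
    for trial in range(5):
        Xtr = rng.standard_normal((30, 5))
        ytr = rng.integers(0, 3, 30)
        Xte = rng.standard_normal((12, 5))
        clf = lda_fit(Xtr, ytr, lam=0.01)
        scores = Xte @ clf.weights + clf.biases
        expected = _brute_force_lda_predict(Xtr, ytr, Xte, 0.01)
        np.testing.assert_array_equal(lda_predict(clf, Xte), expected)
        # score margins agree to tight numerical tolerance, not just argmax
        mus = np.stack([Xtr[ytr == c].mean(axis=0) for c in clf.classes])
        S = sum(
            (Xtr[ytr == c] - mus[i]).T @ (Xtr[ytr == c] - mus[i])
            for i, c in enumerate(clf.classes)
        )
        sigma = S / (len(ytr) - len(clf.classes))
        sigma_reg = 0.99 * sigma + 0.01 * (np.trace(sigma) / 5) * np.eye(5)
        ref = Xte @ np.linalg.inv(sigma_reg) @ mus.T - 0.5 * np.einsum(
            "kp,pq,kq->k", mus, np.linalg.inv(sigma_reg), mus
        )
        np.testing.assert_allclose(scores, ref, rtol=1e-8)


def test_lda_matches_sklearn_shrinkage_convention():
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(5)
    X = rng.standard_normal((120, 8)) + rng.integers(0, 3, 120)[:, None] * 0.5
    y = np.tile([0, 1, 2], 40)
    Xte = rng.standard_normal((60, 8))
    ours = lda_predict(lda_fit(X, y, lam=0.2), Xte)
    sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.2).fit(X, y)
    agreement = np.mean(ours == sk.predict(Xte))
    assert agreement > 0.95  # identical covariance model; ties may differ


def test_lda_separable_blobs_and_shuffled_labels():
    rng = np.random.default_rng(6)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    y = np.tile([0, 1, 2], 60)
    X = centers[y] + rng.standard_normal((180, 2)) * 0.3
    clf = lda_fit(X[:120], y[:120], lam=0.01)
    assert np.mean(lda_predict(clf, X[120:]) == y[120:]) == 1.0

    accs = []
    for rep in range(30):
        y_shuf = rng.permutation(y[:120])
        clf = lda_fit(X[:120], y_shuf, lam=0.01)
        accs.append(np.mean(lda_predict(clf, X[120:]) == y[120:]))
    assert abs(np.mean(accs) - 1 / 3) < 0.08


def test_lda_duplicated_training_set_same_boundary():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((60, 4))
    y = np.tile([0, 1, 2], 20)
    Xte = rng.standard_normal((40, 4))
    a = lda_fit(X, y, lam=0.05)
    b = lda_fit(np.vstack([X, X]), np.concatenate([y, y]), lam=0.05)
    np.testing.assert_array_equal(lda_predict(a, Xte), lda_predict(b, Xte))


def test_lda_rejects_single_class():
    with pytest.raises(ValueError, match="2 classes"):
        lda_fit(np.zeros((10, 3)), np.zeros(10, dtype=int))


# --- time-resolved decoding ----------------------------------------------

def _toy_layout(n):
    pos = np.column_stack([np.linspace(-1, 1, n), np.zeros(n)])
    return SensorLayout(tuple(f"c{i}" for i in range(n)), pos)


def _binned_with_signal(labels, amp_by_bin, n_channels=6, seed=0):
    """Binned features whose class signal lives on channel 0, scaled per bin."""
    rng = np.random.default_rng(seed)
    n = len(labels)
    data = rng.standard_normal((n, n_channels, 20))
    patterns = np.array([1.0, -1.0, 0.5])
    data[:, 0, :] += patterns[labels][:, None] * np.asarray(amp_by_bin)
    return BinnedFeatures(
        data=data,
        bin_edges_ms=np.arange(21) * 250.0,
        phase_of_bin=PHASE_OF_BIN,
        layout=_toy_layout(n_channels),
    )


def _stream(labels):
    from rpsdecode.decode import LabelStream

    labels = np.asarray(labels)
    return LabelStream(StreamKind.OWN_CURRENT, labels, np.arange(labels.size))


def test_decode_timecourse_recovers_signal_bins():
    rng = np.random.default_rng(8)
    labels = rng.integers(0, 3, 300)
    amp = np.zeros(20)
    amp[10:] = 4.0
    binned = _binned_with_signal(labels, amp, seed=9)
    curve = decode_timecourse(binned, _stream(labels), DecoderConfig(seed=1))
    assert curve.accuracy.shape == (20,)
    assert np.all(curve.accuracy[10:] > 0.9)
    # pseudo-trial resampling reuses trials, so per-bin chance accuracy is
    # noisy; individual bins stay within a wide band, the mean much closer
    assert np.all(np.abs(curve.accuracy[:10] - 1 / 3) < 0.25)
    assert abs(curve.accuracy[:10].mean() - 1 / 3) < 0.08


def test_decode_timecourse_chance_without_signal():
    rng = np.random.default_rng(10)
    labels = rng.integers(0, 3, 300)
    binned = _binned_with_signal(labels, np.zeros(20), seed=11)
    curve = decode_timecourse(binned, _stream(labels), DecoderConfig(seed=2))
    assert abs(curve.accuracy.mean() - 1 / 3) < 0.05


def test_uninformative_button_positions_decode_at_chance():
    """Labels uncorrelated with the injected class signal (e.g. motor/button
    codes under remapping) stay at chance even when the signal is strong."""
    rng = np.random.default_rng(12)
    labels = rng.integers(0, 3, 300)
    binned = _binned_with_signal(labels, np.full(20, 4.0), seed=13)
    buttons = rng.integers(0, 3, 300)  # independent of the response classes
    curve = decode_timecourse(binned, _stream(buttons), DecoderConfig(seed=3))
    assert abs(curve.accuracy.mean() - 1 / 3) < 0.05


def test_training_invariant_to_test_fold_content():
    """Leakage guard: altering test-fold trials never changes training pseudo-trials."""
    rng = np.random.default_rng(14)
    n = 120
    labels = np.tile([0, 1, 2], n // 3)
    folds = np.repeat(np.arange(4), n // 4)
    features = rng.standard_normal((n, 6, 20))
    cfg = DecoderConfig(seed=4, n_folds=4)
    pX_a, py_a = make_pseudo_trials(features, labels, folds, cfg)

    corrupted = features.copy()
    corrupted[folds == 0] = 1e6  # blow up the test fold only
    pX_b, py_b = make_pseudo_trials(corrupted, labels, folds, cfg)
    for k in range(1, 4):
        np.testing.assert_array_equal(pX_a[k], pX_b[k])
        np.testing.assert_array_equal(py_a[k], py_b[k])
    assert not np.allclose(pX_a[0], pX_b[0])


# --- searchlight ----------------------------------------------------------

def test_searchlight_clusters_have_4_or_5_neighbors():
    from rpsdecode.layout import SensorLayout as SL
    from rpsdecode.synth import _sub_layout
    from rpsdecode.layout import biosemi64_layout

    layout = biosemi64_layout()
    clusters = searchlight_neighbors(layout, k_neighbors=5, radius_cap=0.5)
    sizes = {len(v) for v in clusters.values()}
    assert sizes <= {5, 6}  # main channel + 4 or 5 neighbors


def test_searchlight_localizes_signal_and_collapses_windows():
    rng = np.random.default_rng(16)
    labels = rng.integers(0, 3, 240)
    n_ch = 8
    binned = _binned_with_signal(labels, np.full(20, 3.0), n_channels=n_ch, seed=17)
    result = searchlight(
        binned, _stream(labels), DecoderConfig(seed=5), k_neighbors=2, radius_cap=5.0
    )
    assert result.accuracy.shape == (n_ch, 5)
    best = np.argmax(result.accuracy.mean(axis=1))
    # signal lives on channel 0; only clusters containing it decode well
    assert best <= 2
    far = result.accuracy[n_ch - 1]
    assert abs(far.mean() - 1 / 3) < 0.1
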