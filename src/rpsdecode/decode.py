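"""Time-resolved multivariate decoding of game responses from binned EEG.

Four label streams are decoded from the same 20-bin feature space: the
player's own response, the opponent's response, and both players' responses
on the immediately preceding game. For each stream the pipeline is:

1. drop trials whose label is undefined (first game for previous-trial
   streams) or a no-response;
2. stratified 10-fold split;
3. within each fold and class, average groups of 4 trials into 20
   pseudo-trials to raise the signal-to-noise ratio;
4. per time bin, train a regularized (shrinkage λ = 0.01) linear
   discriminant classifier on the pseudo-trials of 9 folds and test on the
   left-out fold's pseudo-trials;
5. report balanced accuracy (mean per-class recall) per bin; chance for
   the three-class problem is 1/3.

A channel searchlight repeats the same decoding on each channel plus its
4-5 nearest neighbors and collapses the 20 bins into five 1-s windows,
yielding an accuracy topography.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .core import ANSWERED, Outcome, ResponseSymbol, SessionLog
from .layout import SensorLayout
from .preprocess import BinnedFeatures, Phase

__all__ = [
    "StreamKind",
    "LabelStream",
    "DecoderConfig",
    "DecodingCurve",
    "SearchlightResult",
    "stream_labels",
    "assign_folds",
    "make_pseudo_trials",
    "LDAClassifier",
    "lda_fit",
    "lda_predict",
    "decode_timecourse",
    "searchlight",
]

CHANCE_LEVEL = 1.0 / 3.0


class StreamKind(Enum):
    """What the classifier is asked to read out from the neural pattern."""

    OWN_CURRENT = "own_current"
    OPPONENT_CURRENT = "opponent_current"
    OWN_PREVIOUS = "own_previous"
    OPPONENT_PREVIOUS = "opponent_previous"


@dataclass(frozen=True)
class LabelStream:
    """Per-trial class labels for one stream, with undefined trials removed.

    ``trial_indices`` maps each label back to its game (0-based) in the
    session, so features and labels can be aligned after exclusions.
    """

    kind: StreamKind
    labels: np.ndarray  # class indices 0..2 (rock, paper, scissors)
    trial_indices: np.ndarray

    def __post_init__(self) -> None:
        if self.labels.shape != self.trial_indices.shape:
            raise ValueError("labels and trial_indices must align")
        if self.labels.size and not np.isin(self.labels, [0, 1, 2]).all():
            raise ValueError("labels must be class indices 0..2")


def stream_labels(session: SessionLog, player: int, kind: StreamKind) -> LabelStream:
    """Extract one label stream for one player of a session.

    No-response games are removed (they carry no class), and for
    previous-trial streams the first game of the session is undefined.
    Previous-trial labels cross block boundaries: the predecessor is the
    immediately preceding game of the session.
    """
    own = player
    other = 2 if player == 1 else 1
    source = own if kind in (StreamKind.OWN_CURRENT, StreamKind.OWN_PREVIOUS) else other
    responses = session.responses(source)
    lag = kind in (StreamKind.OWN_PREVIOUS, StreamKind.OPPONENT_PREVIOUS)

    class_index = {sym: i for i, sym in enumerate(ANSWERED)}
    labels, idx = [], []
    for t in range(len(session)):
        sym = responses[t - 1] if lag else responses[t]
        if lag and t == 0:
            continue
        if not sym.answered:
            continue
        labels.append(class_index[sym])
        idx.append(t)
    return LabelStream(kind, np.asarray(labels, dtype=int), np.asarray(idx, dtype=int))


@dataclass(frozen=True)
class DecoderConfig:
    """Cross-validated decoder settings (defaults follow the analysis design)."""

    lam: float = 0.01
    n_folds: int = 10
    pseudo_per_fold_class: int = 20
    trials_per_pseudo: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def assign_folds(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Class-stratified fold assignment, seed-reproducible.

    Within each class, fold sizes differ by at most one.
    """
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=3)
    short = [c for c, n in enumerate(counts) if 0 < n < n_folds]
    if short or labels.size < n_folds:
        raise ValueError(
            f"need >= {n_folds} trials per class for {n_folds}-fold CV; "
            f"class counts {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(labels.size, dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros((labels.size, 1)), labels)):
        folds[test_idx] = k
    return folds


def make_pseudo_trials(
    features: np.ndarray,
    labels: np.ndarray,
    folds: np.ndarray,
    cfg: DecoderConfig,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Average same-fold, same-class trials into pseudo-trials.

    For every fold and class, ``pseudo_per_fold_class`` pseudo-trials are
    formed; each averages ``trials_per_pseudo`` distinct trials sampled
    uniformly without replacement from that fold-class pool (with
    replacement across pseudo-trials, since the pool is typically smaller
    than the total draw). Pools smaller than ``trials_per_pseudo`` fall
    back to sampling with replacement and emit a warning.

    Returns per-fold arrays ``(pseudo_features, pseudo_labels)``, each fold
    holding ``pseudo_per_fold_class * n_classes`` balanced pseudo-trials.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = np.unique(labels)
    n_folds = int(folds.max()) + 1
    out_X: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    for k in range(n_folds):
        fold_X, fold_y = [], []
        for c in classes:
            pool = np.flatnonzero((folds == k) & (labels == c))
            if pool.size == 0:
                raise ValueError(f"fold {k} has no trials of class {c}")
            replace = pool.size < cfg.trials_per_pseudo
            if replace:
                warnings.warn(
                    f"fold {k} class {c}: pool of {pool.size} < "
                    f"{cfg.trials_per_pseudo}; sampling with replacement",
                    stacklevel=2,
                )
            for _ in range(cfg.pseudo_per_fold_class):
                pick = rng.choice(pool, size=cfg.trials_per_pseudo, replace=replace)
                fold_X.append(features[pick].mean(axis=0))
                fold_y.append(c)
        out_X.append(np.stack(fold_X))
        out_y.append(np.asarray(fold_y))
    return out_X, out_y


@dataclass(frozen=True)
class LDAClassifier:
    classes: np.ndarray
    weights: np.ndarray  # (n_features, n_classes)
    biases: np.ndarray  # (n_classes,)


def lda_fit(X: np.ndarray, y: np.ndarray, lam: float = 0.01) -> LDAClassifier:
    """Fit a linear discriminant with trace-normalized covariance shrinkage.

    The pooled within-class covariance Σ is regularized as
    ``(1 - λ)·Σ + λ·(tr(Σ)/p)·I`` and class assignment uses the linear
    discriminant score with equal priors, so the classifier depends on the
    data only through class means and the pooled covariance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set must contain >= 2 classes")
    n, p = X.shape
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    scatter = np.zeros((p, p))
    for c, mu in zip(classes, means):
        d = X[y == c] - mu
        scatter += d.T @ d
    cov = scatter / (n - classes.size)
    cov_reg = (1.0 - lam) * cov + lam * (np.trace(cov) / p) * np.eye(p)
    try:
        inv_means = np.linalg.solve(cov_reg, means.T)  # (p, k)
    except np.linalg.LinAlgError:
        raise ValueError(
            "regularized covariance is singular; use lam > 0"
        ) from None
    biases = -0.5 * np.einsum("kp,pk->k", means, inv_means)
    return LDAClassifier(classes=classes, weights=inv_means, biases=biases)


def lda_predict(clf: LDAClassifier, X: np.ndarray) -> np.ndarray:
    """Predict by maximal discriminant score (ties go to the first class)."""
    scores = np.asarray(X, dtype=float) @ clf.weights + clf.biases
    return clf.classes[np.argmax(scores, axis=1)]


@dataclass(frozen=True)
class DecodingCurve:
    """Balanced accuracy per time bin for one participant and stream."""

    accuracy: np.ndarray  # (n_bins,)
    kind: StreamKind
    phase_of_bin: tuple[Phase, ...]
    participant: str = ""

    def bins_of_phase(self, phase: Phase) -> np.ndarray:
        return np.array([i for i, p in enumerate(self.phase_of_bin) if p is phase])


def _balanced_accuracy(true: np.ndarray, pred: np.ndarray, classes: np.ndarray) -> float:
    recalls = [np.mean(pred[true == c] == c) for c in classes if (true == c).any()]
    return float(np.mean(recalls))


def decode_timecourse(
    binned: BinnedFeatures, stream: LabelStream, cfg: DecoderConfig
) -> DecodingCurve:
    """Cross-validated decoding accuracy of one stream for every time bin.

    Pseudo-trials are constructed once per fold over the full
    channels-x-bins representation; each bin is then decoded from its
    channel pattern alone. Both training and test sets consist of
    pseudo-trials, and test folds never contribute to training pools.
    """
    features = binned.data[stream.trial_indices]
    folds = assign_folds(stream.labels, cfg.n_folds, cfg.seed)
    pseudo_X, pseudo_y = make_pseudo_trials(features, stream.labels, folds, cfg)
    classes = np.unique(stream.labels)

    n_bins = binned.n_bins
    accuracy = np.empty(n_bins)
    for b in range(n_bins):
        true_all, pred_all = [], []
        for k in range(cfg.n_folds):
            train_X = np.concatenate(
                [pseudo_X[j][:, :, b] for j in range(cfg.n_folds) if j != k]
            )
            train_y = np.concatenate(
                [pseudo_y[j] for j in range(cfg.n_folds) if j != k]
            )
            clf = lda_fit(train_X, train_y, cfg.lam)
            pred = lda_predict(clf, pseudo_X[k][:, :, b])
            true_all.append(pseudo_y[k])
            pred_all.append(pred)
        accuracy[b] = _balanced_accuracy(
            np.concatenate(true_all), np.concatenate(pred_all), classes
        )
    return DecodingCurve(accuracy=accuracy, kind=stream.kind, phase_of_bin=binned.phase_of_bin)


@dataclass(frozen=True)
class SearchlightResult:
    """Per-channel decoding accuracy, collapsed into 1-s windows."""

    accuracy: np.ndarray  # (n_channels, n_windows)
    channel_names: tuple[str, ...]
    window_edges_ms: np.ndarray
    kind: StreamKind
    window_width_ms: int = 1000


def searchlight_neighbors(
    layout: SensorLayout, k_neighbors: int = 5, radius_cap: float = 0.5
) -> dict[str, list[int]]:
    """Channel clusters: each channel plus its k nearest neighbors.

    The k-th neighbor is dropped when it lies beyond ``radius_cap``
    normalized units, so clusters hold the main channel plus 4-5 neighbors
    (never fewer than ``k_neighbors - 1``).
    """
    if k_neighbors >= layout.n_channels:
        raise ValueError("k_neighbors must be smaller than the channel count")
    dist = layout.distances()
    clusters: dict[str, list[int]] = {}
    for i, name in enumerate(layout.channel_names):
        order = np.argsort(dist[i])
        nbrs = [j for j in order if j != i][:k_neighbors]
        if dist[i, nbrs[-1]] > radius_cap and len(nbrs) > 1:
            nbrs = nbrs[:-1]
        clusters[name] = [i] + nbrs
    return clusters


def searchlight(
    binned: BinnedFeatures,
    stream: LabelStream,
    cfg: DecoderConfig,
    k_neighbors: int = 5,
    radius_cap: float = 0.5,
    bins_per_window: int = 4,
) -> SearchlightResult:
    """Repeat the time-resolved decoding on local channel clusters.

    Per-bin accuracies of each cluster are averaged within consecutive
    1-s windows (4 bins of 250 ms), giving one topography per window.
    """
    clusters = searchlight_neighbors(binned.layout, k_neighbors, radius_cap)
    n_bins = binned.n_bins
    if n_bins % bins_per_window:
        raise ValueError("bins do not divide evenly into windows")
    n_windows = n_bins // bins_per_window
    acc = np.empty((binned.layout.n_channels, n_windows))
    for i, name in enumerate(binned.layout.channel_names):
        sub = BinnedFeatures(
            data=binned.data[:, clusters[name], :],
            bin_edges_ms=binned.bin_edges_ms,
            phase_of_bin=binned.phase_of_bin,
            layout=_sub_layout(binned.layout, clusters[name]),
        )
        curve = decode_timecourse(sub, stream, cfg)
        acc[i] = curve.accuracy.reshape(n_windows, bins_per_window).mean(axis=1)
    edges = np.arange(n_windows + 1) * float(bins_per_window * 250)
    return SearchlightResult(
        accuracy=acc,
        channel_names=binned.layout.channel_names,
        window_edges_ms=edges,
        kind=stream.kind,
    )


def _sub_layout(layout: SensorLayout, idx: list[int]) -> SensorLayout:
    return SensorLayout(
        tuple(layout.channel_names[i] for i in idx), layout.positions[idx]
    )
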