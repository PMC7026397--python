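"""Regularized linear decoding of the attentional spotlight from windowed MUA.

A ridge regression (squared-norm penalty on the non-intercept weights) maps
mean firing rates in 50 ms windows to continuous (x, y) attention estimates;
the same readout, collapsed by quadrant sign, yields a four-class output.
Cross-temporal accuracy matrices, out-of-fold continuous trajectories, and
post-stimulus four-class decoding are built on this single decoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .synth import LANDMARKS, N_TIME_BINS, TIME_START_MS, Session

logger = logging.getLogger(__name__)

#: Grid of regularization strengths searched when ``lam='auto'``.
LAMBDA_GRID = np.logspace(-1, 5, 13)


@dataclass(frozen=True)
class WindowSpec:
    """A feature window: ``width_ms`` of activity centered on ``center_ms``."""

    center_ms: int
    width_ms: int = 50
    step_ms: int = 10

    def __post_init__(self):
        if self.width_ms <= 0:
            raise ValueError("window width must be positive")
        lo = self.center_ms - self.width_ms // 2
        hi = lo + self.width_ms
        if lo < TIME_START_MS or hi > TIME_START_MS + N_TIME_BINS:
            raise ValueError(
                f"window [{lo}, {hi}) ms outside recorded span "
                f"[{TIME_START_MS}, {TIME_START_MS + N_TIME_BINS})"
            )


@dataclass
class DecoderModel:
    """Fitted affine map from channel rates (Hz) to (x, y) degrees."""

    weights: np.ndarray                 # (n_channels + 1, 2); row 0 = intercept
    lam: float
    train_window: WindowSpec | None = None
    train_trial_ids: np.ndarray | None = None

    @property
    def intercept(self) -> np.ndarray:
        return self.weights[0]

    @property
    def coef(self) -> np.ndarray:
        return self.weights[1:]


@dataclass
class CrossTemporalMatrix:
    train_times_ms: np.ndarray
    test_times_ms: np.ndarray
    accuracy: np.ndarray                # (n_train, n_test) in [0, 1]
    n_repeats: int = 10


@dataclass
class AttentionTrajectory:
    """Decoded (x, y) spotlight positions of one trial on a regular time grid."""

    trial_id: int
    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x_deg, self.y_deg])


def quadrant_of(x, y):
    """Screen quadrant (1..4) of a point: 1 UR, 2 UL, 3 LL, 4 LR.

    Zero coordinates are assigned to the positive side (x >= 0 is right,
    y >= 0 is up), so (0, 0) maps to the upper-right quadrant by convention.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    q = np.where(
        x >= 0,
        np.where(y >= 0, 1, 4),
        np.where(y >= 0, 2, 3),
    )
    if q.ndim == 0:
        return int(q)
    return q


def _resolve_trial_ids(session: Session, trial_ids) -> np.ndarray:
    if trial_ids is None:
        return np.arange(session.n_trials)
    return np.asarray(trial_ids, dtype=int)


def window_features(session: Session, window: WindowSpec, trial_ids=None) -> np.ndarray:
    """Mean firing rate (Hz) per channel in ``window`` -> (n_trials, n_channels)."""
    ids = _resolve_trial_ids(session, trial_ids)
    lo = window.center_ms - window.width_ms // 2 - TIME_START_MS
    hi = lo + window.width_ms
    counts = session.spikes[ids, :, lo:hi]
    return counts.sum(axis=2) / (window.width_ms * 1e-3)


def window_feature_tensor(session: Session, centers_ms, width_ms: int = 50,
                          trial_ids=None) -> np.ndarray:
    """Features for many window centers at once -> (n_trials, n_windows, n_channels).

    Uses a cumulative sum over time so the cost is independent of window width.
    """
    ids = _resolve_trial_ids(session, trial_ids)
    centers = np.asarray(centers_ms, dtype=int)
    starts = centers - width_ms // 2 - TIME_START_MS
    ends = starts + width_ms
    if starts.min() < 0 or ends.max() > N_TIME_BINS:
        raise ValueError("requested windows extend outside the recorded span")
    counts = session.spikes[ids].astype(np.int64)
    csum = np.concatenate(
        [np.zeros(counts.shape[:2] + (1,), dtype=np.int64), counts.cumsum(axis=2)],
        axis=2,
    )
    sums = csum[:, :, ends] - csum[:, :, starts]           # (n, ch, W)
    return np.transpose(sums, (0, 2, 1)) / (width_ms * 1e-3)


def fit_decoder(features: np.ndarray, targets_xy: np.ndarray, lam: float,
                train_window: WindowSpec | None = None,
                train_trial_ids=None) -> DecoderModel:
    """Closed-form penalized least squares fit of the (x, y) decoder.

    The squared-norm penalty applies to the non-intercept weights only. With
    ``lam=0`` a rank-deficient design raises ``numpy.linalg.LinAlgError``.
    """
    X = np.asarray(features, dtype=float)
    Y = np.asarray(targets_xy, dtype=float)
    if X.ndim != 2 or Y.shape[0] != X.shape[0]:
        raise ValueError("features and targets must have matching first dimension")
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    A = Z.T @ Z
    penalty = np.eye(p + 1)
    penalty[0, 0] = 0.0
    A = A + lam * penalty
    b = Z.T @ Y
    if lam == 0:
        if np.linalg.matrix_rank(Z) < p + 1:
            raise np.linalg.LinAlgError(
                "design matrix is rank deficient and lam=0; add regularization"
            )
        W = np.linalg.solve(A, b)
    else:
        W = scipy.linalg.solve(A, b, assume_a="pos")
    if not np.all(np.isfinite(W)):
        raise np.linalg.LinAlgError("non-finite decoder weights")
    return DecoderModel(weights=W, lam=float(lam), train_window=train_window,
                        train_trial_ids=None if train_trial_ids is None
                        else np.asarray(train_trial_ids))


def readout_xy(model: DecoderModel, features: np.ndarray) -> np.ndarray:
    """Continuous (x, y) readout of the decoder for feature rows."""
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.coef.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match decoder "
            f"({model.coef.shape[0]} channels)"
        )
    out = X @ model.coef + model.intercept
    return out[0] if single else out


def select_lambda(features: np.ndarray, targets_xy: np.ndarray,
                  grid=LAMBDA_GRID, n_folds: int = 5,
                  rng: np.random.Generator | None = None) -> float:
    """Pick a ridge strength by K-fold cross-validated (x, y) squared error."""
    rng = np.random.default_rng(0) if rng is None else rng
    X = np.asarray(features, dtype=float)
    Y = np.asarray(targets_xy, dtype=float)
    n = X.shape[0]
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    errs = np.zeros(len(grid))
    for k in range(n_folds):
        test = folds[k]
        train = np.concatenate([folds[j] for j in range(n_folds) if j != k])
        for gi, lam in enumerate(grid):
            model = fit_decoder(X[train], Y[train], lam)
            pred = readout_xy(model, X[test])
            errs[gi] += np.sum((pred - Y[test]) ** 2)
    return float(grid[int(np.argmin(errs))])


def cued_landmark_targets(session: Session, trial_ids) -> np.ndarray:
    """(x, y) coordinates of the cued landmark for each trial."""
    return np.array(
        [LANDMARKS[session.trials[i].cued_quadrant] for i in trial_ids], dtype=float
    )


def cross_temporal_accuracy(session: Session, train_centers_ms, test_centers_ms,
                            lam="auto", n_repeats: int = 10, split: float = 0.7,
                            rng: np.random.Generator | None = None,
                            width_ms: int = 50, trial_ids=None,
                            clearance_ms: int = 50) -> CrossTemporalMatrix:
    """Four-class quadrant accuracy for every (train time, test time) pair.

    Hit trials only; the decoder is trained on a random 70% of them with the
    cued-landmark coordinates as targets and tested on the remaining 30%, the
    split being redrawn on each of ``n_repeats`` repeats. Trials whose target
    falls before the end of the test grid (plus ``clearance_ms``) are excluded
    so that evoked target responses do not leak into the tested windows.
    """
    rng = np.random.default_rng() if rng is None else rng
    train_centers = np.asarray(train_centers_ms, dtype=int)
    test_centers = np.asarray(test_centers_ms, dtype=int)

    if trial_ids is None:
        min_target = int(test_centers.max() + width_ms // 2 + clearance_ms)
        trial_ids = session.trial_indices(outcome="hit", min_target_ms=min_target)
    trial_ids = np.asarray(trial_ids, dtype=int)
    n = len(trial_ids)
    if n < 10:
        raise ValueError(f"need at least 10 hit trials, got {n}")

    all_centers = np.union1d(train_centers, test_centers)
    feats = window_feature_tensor(session, all_centers, width_ms, trial_ids)
    train_pos = np.searchsorted(all_centers, train_centers)
    test_pos = np.searchsorted(all_centers, test_centers)

    targets = cued_landmark_targets(session, trial_ids)
    labels = np.array([session.trials[i].cued_quadrant for i in trial_ids])

    if lam == "auto":
        lam = select_lambda(feats[:, train_pos[0], :], targets, rng=rng)
    lam = float(lam)

    n_train = int(round(split * n))
    acc = np.zeros((len(train_centers), len(test_centers)))
    for _ in range(n_repeats):
        order = rng.permutation(n)
        tr, te = order[:n_train], order[n_train:]
        assert len(np.intersect1d(tr, te)) == 0  # no train/test leakage
        Zte = feats[te][:, test_pos, :]          # (n_te, n_test, ch)
        for i, wpos in enumerate(train_pos):
            model = fit_decoder(feats[tr, wpos, :], targets[tr], lam)
            pred = Zte @ model.coef + model.intercept       # (n_te, n_test, 2)
            q = quadrant_of(pred[..., 0], pred[..., 1])
            acc[i] += (q == labels[te, None]).mean(axis=0)
    acc /= n_repeats
    return CrossTemporalMatrix(
        train_times_ms=train_centers,
        test_times_ms=test_centers,
        accuracy=acc,
        n_repeats=n_repeats,
    )


def decode_trajectory(session: Session, step_ms: int = 10, lam="auto",
                      n_folds: int = 10, rng: np.random.Generator | None = None,
                      width_ms: int = 50, pre_cue_start_ms: int = -500) -> list[AttentionTrajectory]:
    """Out-of-fold continuous (x, y) trajectories for every hit trial.

    The decoder is trained on the 50 ms of activity immediately preceding the
    target of the training trials, then applied throughout the pre-cue window
    and the cue-to-target interval of held-out trials, using a K-fold rotation
    so no trial is decoded by a model that saw it.
    """
    rng = np.random.default_rng() if rng is None else rng
    half = width_ms // 2
    hit_ids = session.trial_indices(outcome="hit")
    usable, skipped = [], []
    for i in hit_ids:
        t = session.trials[i].timeline.target_ms
        if t - width_ms >= TIME_START_MS and t <= TIME_START_MS + N_TIME_BINS:
            usable.append(i)
        else:
            skipped.append(i)
    if skipped:
        logger.info("decode_trajectory: skipped %d trials with out-of-span targets",
                    len(skipped))
    usable = np.asarray(usable, dtype=int)
    if len(usable) < n_folds:
        raise ValueError("not enough hit trials for the requested fold rotation")

    # Pre-target training features: each trial contributes its own window.
    train_feats = np.stack([
        window_features(
            session,
            WindowSpec(session.trials[i].timeline.target_ms - half, width_ms),
            [i],
        )[0]
        for i in usable
    ])
    targets = cued_landmark_targets(session, usable)

    if lam == "auto":
        lam = select_lambda(train_feats, targets, rng=rng)
    lam = float(lam)

    order = rng.permutation(len(usable))
    folds = np.array_split(order, n_folds)
    trajectories: list[AttentionTrajectory] = []
    for k, test in enumerate(folds):
        train = np.concatenate([folds[j] for j in range(n_folds) if j != k])
        assert len(np.intersect1d(train, test)) == 0
        model = fit_decoder(train_feats[train], targets[train], lam)
        for j in test:
            i = usable[j]
            t_end = min(session.trials[i].timeline.target_ms,
                        TIME_START_MS + N_TIME_BINS) - half
            centers = np.arange(pre_cue_start_ms, t_end + 1, step_ms)
            feats = window_feature_tensor(session, centers, width_ms, [i])[0]
            pred = readout_xy(model, feats)
            trajectories.append(
                AttentionTrajectory(
                    trial_id=session.trials[i].trial_id,
                    t_ms=centers,
                    x_deg=pred[:, 0],
                    y_deg=pred[:, 1],
                )
            )
    trajectories.sort(key=lambda tr: tr.trial_id)
    return trajectories


# ---------------------------------------------------------------------------
# Post-stimulus four-class decoding
# ---------------------------------------------------------------------------

def _event_table(session: Session, event: str):
    """(trial index, event time, event quadrant, event xy) for decodable events.

    Targets are taken from hit trials; distractors from all distractor trials.
    Workspace distractors are binned to the quadrant containing them. Events
    whose 50-100 ms post-stimulus window leaves the recorded span are dropped.
    """
    rows = []
    span_end = TIME_START_MS + N_TIME_BINS
    for i, tr in enumerate(session.trials):
        if event == "target":
            if tr.outcome != "hit":
                continue
            t, quad = tr.timeline.target_ms, tr.cued_quadrant
            xy = LANDMARKS[quad]
        elif event == "distractor":
            if tr.timeline.distractor_ms is None:
                continue
            t, quad = tr.timeline.distractor_ms, tr.distractor_quadrant
            xy = tr.distractor_xy if tr.distractor_xy is not None else LANDMARKS[quad]
        else:
            raise ValueError(f"unknown event {event!r}")
        if t + 100 > span_end:
            continue
        rows.append((i, t, quad, xy))
    if not rows:
        return (np.empty(0, int), np.empty(0, int), np.empty(0, int),
                np.empty((0, 2)))
    idx, times, quads, xys = zip(*rows)
    return (np.asarray(idx), np.asarray(times), np.asarray(quads),
            np.asarray(xys, dtype=float))


def _event_features(session: Session, idx, times, window_offset_ms):
    lo, hi = window_offset_ms
    width = hi - lo
    center = lo + width // 2
    return np.stack([
        window_features(session, WindowSpec(int(t) + center, width), [i])[0]
        for i, t in zip(idx, times)
    ])


def event_decoding_predictions(session: Session, event: str, lam="auto",
                               n_folds: int = 10,
                               rng: np.random.Generator | None = None,
                               window_offset_ms: tuple[int, int] = (50, 100)):
    """Predicted quadrant for each decodable event of the session.

    One decoder underlies both readouts: it is trained on the 50-100 ms
    post-target activity of hit trials with the cued-landmark coordinates as
    targets (the target sits at the cued landmark). Target events are
    predicted out-of-fold through a K-fold rotation; distractor events are
    predicted by a decoder trained on all target events (which never include
    the tested distractor windows) and scored against the quadrant containing
    the distractor. Returns ``(trial_indices, event_times_ms, true_quadrant,
    predicted_quadrant)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    tr_idx, tr_times, _, tr_xys = _event_table(session, "target")
    if len(tr_idx) < max(n_folds, 10):
        raise ValueError(f"only {len(tr_idx)} decodable target events for training")
    train_feats = _event_features(session, tr_idx, tr_times, window_offset_ms)
    if lam == "auto":
        lam = select_lambda(train_feats, tr_xys, rng=rng)
    lam = float(lam)

    if event == "target":
        idx, times, quads = tr_idx, tr_times, _event_table(session, "target")[2]
        n = len(idx)
        pred_quads = np.zeros(n, dtype=int)
        order = rng.permutation(n)
        folds = np.array_split(order, n_folds)
        for k, test in enumerate(folds):
            train = np.concatenate([folds[j] for j in range(n_folds) if j != k])
            model = fit_decoder(train_feats[train], tr_xys[train], lam)
            pred = readout_xy(model, train_feats[test])
            pred_quads[test] = quadrant_of(pred[:, 0], pred[:, 1])
        return idx, times, quads, pred_quads

    if event != "distractor":
        raise ValueError(f"unknown event {event!r}")
    idx, times, quads, _ = _event_table(session, "distractor")
    if len(idx) == 0:
        raise ValueError("no decodable distractor events")
    model = fit_decoder(train_feats, tr_xys, lam)
    feats = _event_features(session, idx, times, window_offset_ms)
    pred = readout_xy(model, feats)
    return idx, times, quads, quadrant_of(pred[:, 0], pred[:, 1])


def stimulus_decoding_accuracy(session: Session, event: str, trial_subset=None,
                               lam="auto", n_folds: int = 10,
                               rng: np.random.Generator | None = None,
                               min_trials: int = 5) -> float:
    """Four-class accuracy of event-location decoding, optionally on a subset.

    The decoder machinery is cross-validated over all decodable events of the
    session; the accuracy is then evaluated on ``trial_subset`` (trial
    indices). Subsets with fewer than ``min_trials`` events return NaN (a
    sentinel consumed by the phase-bin sweep).
    """
    idx, _, quads, preds = event_decoding_predictions(session, event, lam=lam,
                                                     n_folds=n_folds, rng=rng)
    correct = preds == quads
    if trial_subset is None:
        return float(correct.mean())
    mask = np.isin(idx, np.asarray(trial_subset, dtype=int))
    if mask.sum() < min_trials:
        return float("nan")
    return float(correct[mask].mean())
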