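import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attnspot import decoding, synth
from attnspot.decoding import (
    WindowSpec,
    cross_temporal_accuracy,
    decode_trajectory,
    event_decoding_predictions,
    fit_decoder,
    quadrant_of,
    readout_xy,
    stimulus_decoding_accuracy,
    window_feature_tensor,
    window_features,
)

from conftest import make_session


def _toy_session(spikes, cued=None):
    """Session wrapper around a raw spike tensor for feature-extraction tests."""
    n = spikes.shape[0]
    trials = [
        synth.Trial(
            trial_id=i,
            cued_quadrant=1 if cued is None else cued[i],
            timeline=synth.TrialTimeline(fix_to_cue_ms=800, target_ms=1500),
        )
        for i in range(n)
    ]
    return synth.Session(trials=trials, spikes=spikes, geometry=synth.TaskGeometry())


# ---------------------------------------------------------------------------
# windowed features
# ---------------------------------------------------------------------------

def test_zero_tensor_gives_zero_features():
    sess = _toy_session(np.zeros((3, 48, synth.N_TIME_BINS), dtype=np.uint16))
    feats = window_features(sess, WindowSpec(700, 50))
    assert feats.shape == (3, 48)
    assert np.all(feats == 0)


def test_single_spike_in_50ms_window_is_20_hz():
    spikes = np.zeros((1, 48, synth.N_TIME_BINS), dtype=np.uint16)
    spikes[0, 7, 700 - synth.TIME_START_MS] = 1  # inside window [675, 725)
    sess = _toy_session(spikes)
    feats = window_features(sess, WindowSpec(700, 50))
    assert feats[0, 7] == pytest.approx(20.0)
    assert feats.sum() == pytest.approx(20.0)


def test_constant_rate_feature_recovers_rate():
    rng = np.random.default_rng(0)
    r = 30.0
    spikes = rng.poisson(r * 1e-3, size=(400, 48, synth.N_TIME_BINS)).astype(np.uint16)
    sess = _toy_session(spikes)
    feats = window_features(sess, WindowSpec(700, 50))
    se = np.sqrt(r / 0.05 / (400 * 48))  # Poisson SE of the grand mean
    assert feats.mean() == pytest.approx(r, abs=4 * se)


def test_window_outside_span_raises():
    with pytest.raises(ValueError):
        WindowSpec(-700, 50)
    sess = _toy_session(np.zeros((1, 48, synth.N_TIME_BINS), dtype=np.uint16))
    with pytest.raises(ValueError):
        window_feature_tensor(sess, [1990], width_ms=50)


def test_feature_tensor_matches_single_windows():
    rng = np.random.default_rng(1)
    spikes = rng.poisson(0.03, size=(5, 48, synth.N_TIME_BINS)).astype(np.uint16)
    sess = _toy_session(spikes)
    centers = [500, 700, 900]
    tensor = window_feature_tensor(sess, centers, 50)
    for k, c in enumerate(centers):
        np.testing.assert_allclose(tensor[:, k, :], window_features(sess, WindowSpec(c, 50)))


# ---------------------------------------------------------------------------
# ridge decoder
# ---------------------------------------------------------------------------

def test_unregularized_fit_recovers_exact_linear_map(rng):
    X = rng.normal(size=(80, 12))
    W = rng.normal(size=(12, 2))
    b = np.array([1.5, -2.0])
    Y = X @ W + b
    model = fit_decoder(X, Y, lam=0.0)
    np.testing.assert_allclose(model.coef, W, atol=1e-9)
    np.testing.assert_allclose(model.intercept, b, atol=1e-9)


def test_ridge_limit_shrinks_to_training_mean(rng):
    X = rng.normal(size=(50, 6))
    Y = rng.normal(size=(50, 2))
    model = fit_decoder(X, Y, lam=1e12)
    assert np.abs(model.coef).max() < 1e-6
    np.testing.assert_allclose(readout_xy(model, rng.normal(size=(4, 6))),
                               np.tile(Y.mean(axis=0), (4, 1)), atol=1e-4)


def test_duplicated_channels_share_weight(rng):
    X = rng.normal(size=(60, 4))
    Y = rng.normal(size=(60, 2))
    Xdup = np.column_stack([X, X[:, 0]])  # channel 0 duplicated
    model = fit_decoder(Xdup, Y, lam=3.0)
    np.testing.assert_allclose(model.coef[0], model.coef[4], atol=1e-10)


def test_rank_deficient_without_regularization_raises(rng):
    X = rng.normal(size=(30, 5))
    X = np.column_stack([X, X[:, 0]])  # exact collinearity
    Y = rng.normal(size=(30, 2))
    with pytest.raises(np.linalg.LinAlgError):
        fit_decoder(X, Y, lam=0.0)


def test_fit_matches_bruteforce_normal_equations_oracle(rng):
    # independent oracle: least squares on the penalty-augmented system
    for _ in range(5):
        n, p = 40, 10
        X = rng.normal(size=(n, p))
        Y = rng.normal(size=(n, 2))
        lam = float(rng.uniform(0.1, 30.0))
        Xaug = np.vstack([np.column_stack([np.ones(n), X]),
                          np.column_stack([np.zeros((p, 1)), np.sqrt(lam) * np.eye(p)])])
        Yaug = np.vstack([Y, np.zeros((p, 2))])
        expected, *_ = np.linalg.lstsq(Xaug, Yaug, rcond=None)
        model = fit_decoder(X, Y, lam=lam)
        np.testing.assert_allclose(model.weights, expected, atol=1e-8)


def test_readout_identities(rng):
    X = rng.normal(size=(40, 6))
    Y = rng.normal(size=(40, 2))
    model = fit_decoder(X, Y, lam=2.0)
    # zero features -> intercept
    np.testing.assert_allclose(readout_xy(model, np.zeros(6)), model.intercept)
    # mean features -> mean targets, any lam (unpenalized intercept identity)
    np.testing.assert_allclose(readout_xy(model, X.mean(axis=0)), Y.mean(axis=0),
                               atol=1e-10)
    # exact system with lam=0 reproduces the targets
    W = rng.normal(size=(6, 2))
    Yexact = X @ W
    exact = fit_decoder(X, Yexact, lam=0.0)
    np.testing.assert_allclose(readout_xy(exact, X), Yexact, atol=1e-9)


def test_readout_shape_mismatch_raises(rng):
    model = fit_decoder(rng.normal(size=(30, 6)), rng.normal(size=(30, 2)), lam=1.0)
    with pytest.raises(ValueError):
        readout_xy(model, np.zeros(5))


# ---------------------------------------------------------------------------
# quadrant readout
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x,y,expected", [
    (10, 10, 1), (-0.01, 5, 2), (-3, -3, 3), (4, -1, 4),
    (0, 0, 1), (0, -2, 4), (-1, 0, 2),
])
def test_quadrant_of_examples(x, y, expected):
    assert quadrant_of(x, y) == expected


@given(st.floats(-50, 50), st.floats(-50, 50))
@settings(max_examples=60, deadline=None)
def test_quadrant_of_sign_consistency(x, y):
    q = quadrant_of(x, y)
    assert q in (1, 2, 3, 4)
    assert (x >= 0) == (q in (1, 4))
    assert (y >= 0) == (q in (1, 2))


# ---------------------------------------------------------------------------
# cross-temporal decoding
# ---------------------------------------------------------------------------

def _shuffled_labels_session(session, seed=0):
    rng = np.random.default_rng(seed)
    trials = [dataclasses.replace(tr, cued_quadrant=int(rng.integers(1, 5)))
              for tr in session.trials]
    return dataclasses.replace(session, trials=trials)


def test_label_shuffled_accuracy_at_chance(spiking_session):
    shuffled = _shuffled_labels_session(spiking_session)
    rng = np.random.default_rng(0)
    ctm = cross_temporal_accuracy(shuffled, [700, 900], [600, 800, 1000],
                                  lam=100.0, n_repeats=10, rng=rng)
    n_eff = 36 * 10  # held-out trials per repeat times repeats (correlated; loose)
    assert abs(ctm.accuracy.mean() - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n_eff) + 0.03


def test_high_snr_on_diagonal_accuracy():
    # Absorbing exploration (identity matrix) keeps the spotlight at the cued
    # quadrant, so at the oscillation peak (theta = 0 near 912 ms for -75 deg,
    # 9 Hz) a strongly tuned session decodes nearly perfectly.
    sess = make_session(seed=9, n_trials=100, exploration_matrix=np.eye(4),
                        gain_range_hz=(400.0, 800.0))
    rng = np.random.default_rng(1)
    ctm = cross_temporal_accuracy(sess, [912], [912], lam=100.0,
                                  n_repeats=10, rng=rng)
    assert ctm.accuracy[0, 0] > 0.9


def test_window_size_accuracy_monotonicity(spiking_session):
    rng = np.random.default_rng(2)
    centers = np.arange(700, 1101, 50)
    prev = -1.0
    for width in (25, 50, 100, 150, 300):
        ctm = cross_temporal_accuracy(spiking_session, centers, centers,
                                      lam=100.0, n_repeats=5, rng=rng,
                                      width_ms=width, clearance_ms=200)
        acc = ctm.accuracy.mean()
        assert acc >= prev - 0.015
        prev = acc


def test_too_few_hits_raises():
    sess = make_session(seed=3, n_trials=45, hit_base=0.05, hit_depth=0.0)
    with pytest.raises(ValueError, match="hit trials"):
        cross_temporal_accuracy(sess, [700], [800], lam=1.0,
                                rng=np.random.default_rng(0))


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def trajectory_session():
    # targets inside the recorded span so every hit supplies a pre-target window
    return make_session(seed=8, n_trials=110,
                        cueoff_to_target_range_ms=(1200, 1600))


@pytest.fixture(scope="module")
def decoded_trajectories(trajectory_session):
    rng = np.random.default_rng(5)
    return decode_trajectory(trajectory_session, step_ms=10, lam="auto", rng=rng)


def test_trajectories_cover_hits_out_of_fold(trajectory_session, decoded_trajectories):
    hit_ids = {trajectory_session.trials[i].trial_id
               for i in trajectory_session.trial_indices(outcome="hit")}
    traj_ids = {t.trial_id for t in decoded_trajectories}
    assert traj_ids <= hit_ids
    assert len(traj_ids) == len(decoded_trajectories)  # each trial decoded once


def test_high_snr_trajectory_correlates_with_ground_truth(trajectory_session,
                                                          decoded_trajectories):
    gt = {t.trial_id: t for t in trajectory_session.ground_truth}
    rs = []
    for traj in decoded_trajectories:
        sel = (traj.t_ms >= 400)
        truth = gt[traj.trial_id]
        idx = traj.t_ms[sel] - synth.TIME_START_MS
        r = np.corrcoef(traj.x_deg[sel], truth.xy[idx, 0])[0, 1]
        rs.append(r)
    assert np.median(rs) > 0.5


def test_decoded_trajectory_oscillates_at_f_gen():
    # absorbing exploration removes the slow quadrant-wander component so the
    # per-trial spectrum isolates the within-quadrant oscillation
    sess = make_session(seed=12, n_trials=100, exploration_matrix=np.eye(4),
                        cueoff_to_target_range_ms=(1200, 1600))
    trajs = decode_trajectory(sess, step_ms=10, lam="auto",
                              rng=np.random.default_rng(3))
    spectra = []
    for traj in trajs:
        sel = (traj.t_ms >= 400) & (traj.t_ms <= 1100)
        x = traj.x_deg[sel] - traj.x_deg[sel].mean()
        if x.size < 70:
            continue
        freqs = np.fft.rfftfreq(x.size, d=0.01)
        spectra.append(np.abs(np.fft.rfft(x)) ** 2)
    power = np.mean([s for s in spectra], axis=0)
    sel = (freqs > 4) & (freqs < 20)
    assert abs(freqs[sel][np.argmax(power[sel])] - 9.0) < 1.5


def test_flat_tuning_trajectory_uninformative():
    sess = make_session(seed=4, n_trials=60, tuning_width_deg=1e5,
                        cueoff_to_target_range_ms=(1200, 1600))
    rng = np.random.default_rng(0)
    trajs = decode_trajectory(sess, step_ms=20, lam=100.0, rng=rng)
    gt = {t.trial_id: t for t in sess.ground_truth}
    rs = []
    for traj in trajs:
        truth = gt[traj.trial_id]
        idx = traj.t_ms - synth.TIME_START_MS
        rs.append(np.corrcoef(traj.x_deg, truth.xy[idx, 0])[0, 1])
    assert abs(np.mean(rs)) < 0.1


# ---------------------------------------------------------------------------
# post-stimulus decoding
# ---------------------------------------------------------------------------

def test_target_decoding_beats_chance_and_shuffle(spiking_session):
    rng = np.random.default_rng(0)
    acc = stimulus_decoding_accuracy(spiking_session, "target", rng=rng)
    assert acc > 0.5
    shuffled = _shuffled_labels_session(spiking_session, seed=1)
    acc_sh = stimulus_decoding_accuracy(shuffled, "target",
                                        rng=np.random.default_rng(0))
    assert abs(acc_sh - 0.25) < 0.12


def test_small_subset_returns_nan_sentinel(spiking_session):
    rng = np.random.default_rng(0)
    out = stimulus_decoding_accuracy(spiking_session, "target",
                                     trial_subset=[0, 1], rng=rng)
    assert np.isnan(out)


def test_distractor_accuracy_monotone_in_evoked_amplitude():
    accs = []
    for evoked in (0.0, 8.0, 40.0):
        sess = make_session(seed=11, n_trials=100, distractor_prob=1.0,
                            landmark_distractor_frac=1.0,
                            evoked_rate_hz=evoked, evoked_gain_depth=0.0,
                            cueoff_to_target_range_ms=(1300, 1550))
        accs.append(stimulus_decoding_accuracy(sess, "distractor",
                                               rng=np.random.default_rng(2)))
    assert accs[2] > accs[0] + 0.1
    assert accs[2] >= accs[1] - 0.05 and accs[1] >= accs[0] - 0.05
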