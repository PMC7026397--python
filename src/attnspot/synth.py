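"""Synthetic cued target-detection sessions with a rhythmically exploring spotlight.

The generator produces trial-structured multi-unit spike counts driven by a
latent (x, y) attention trajectory. The trajectory hops between screen
quadrants once per oscillation cycle (a first-order Markov chain over
quadrants) and swings in and out of the occupied quadrant at a configurable
alpha frequency. The oscillation phase is reset to a configurable value at cue
onset. Behavioral outcomes (hit / miss / false alarm) and reaction times are
gated by the oscillation phase at stimulus time, and stimulus-evoked spiking
transients can be phase-modulated as well, so every downstream analysis stage
can be validated against known ground truth.

Time is integer milliseconds, cue onset is t = 0, and the spike tensor spans
[-700, +2000) ms with half-open 1 ms bins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

TIME_START_MS = -700
TIME_STOP_MS = 2000
N_TIME_BINS = TIME_STOP_MS - TIME_START_MS

#: Landmark coordinates (degrees of visual angle) per quadrant label.
#: 1 = upper-right, 2 = upper-left, 3 = lower-left, 4 = lower-right.
LANDMARKS = {
    1: (10.0, 10.0),
    2: (-10.0, 10.0),
    3: (-10.0, -10.0),
    4: (10.0, -10.0),
}

#: Quadrant sharing the hemifield (same sign of x, opposite sign of y).
SAME_HEMIFIELD = {1: 4, 4: 1, 2: 3, 3: 2}
#: Quadrant across the vertical meridian at the same elevation.
OPPOSITE_HEMIFIELD = {1: 2, 2: 1, 3: 4, 4: 3}
#: Diagonally opposite quadrant.
DIAGONAL = {1: 3, 3: 1, 2: 4, 4: 2}

#: Default post-cue quadrant transition matrix, rows/columns in *canonical*
#: order [cued, same-hemifield, opposite-hemifield, diagonal], one transition
#: per oscillation cycle. The cued row of the four-position default carries a
#: strong stay probability and no diagonal transitions; the two-position
#: default makes the diagonal (second cued location) competitive.
DEFAULT_EXPLORATION_FOUR = np.array(
    [
        [0.55, 0.22, 0.23, 0.00],
        [0.50, 0.30, 0.10, 0.10],
        [0.50, 0.10, 0.30, 0.10],
        [0.40, 0.20, 0.20, 0.20],
    ]
)
DEFAULT_EXPLORATION_TWO = np.array(
    [
        [0.47, 0.16, 0.15, 0.22],
        [0.45, 0.25, 0.10, 0.20],
        [0.45, 0.10, 0.25, 0.20],
        [0.40, 0.15, 0.15, 0.30],
    ]
)
#: Pre-cue exploration is unbiased: uniform transitions between quadrants.
DEFAULT_PRE_MATRIX = np.full((4, 4), 0.25)


class ConfigurationError(ValueError):
    """Raised when generator parameters violate their constraints."""


def wrap_angle(a):
    """Wrap angles (radians) into the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = np.mod(a, 2.0 * np.pi)
    out = np.where(out > np.pi, out - 2.0 * np.pi, out)
    if out.ndim == 0:
        return float(out)
    return out


def canonical_permutation(cued_quadrant: int) -> tuple[int, int, int, int]:
    """Quadrant labels in canonical order [cued, same-hemi, opposite-hemi, diagonal]."""
    return (
        cued_quadrant,
        SAME_HEMIFIELD[cued_quadrant],
        OPPOSITE_HEMIFIELD[cued_quadrant],
        DIAGONAL[cued_quadrant],
    )


def canonical_to_quadrant_matrix(matrix_canonical: np.ndarray, cued_quadrant: int) -> np.ndarray:
    """Remap a canonical-order transition matrix onto actual quadrant labels 1-4.

    Entry (i, j) of the result is the probability of moving from quadrant i+1
    to quadrant j+1.
    """
    perm = np.asarray(canonical_permutation(cued_quadrant)) - 1
    out = np.empty((4, 4))
    out[np.ix_(perm, perm)] = np.asarray(matrix_canonical)
    return out


def _check_row_stochastic(matrix, name):
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ConfigurationError(f"{name} must be 4x4, got {matrix.shape}")
    if np.any(matrix < 0):
        raise ConfigurationError(f"{name} has negative entries")
    if np.any(np.abs(matrix.sum(axis=1) - 1.0) > 1e-12):
        raise ConfigurationError(f"{name} rows must sum to 1 within 1e-12")
    return matrix


@dataclass(frozen=True)
class TaskGeometry:
    """Screen geometry of the cued target-detection task.

    Four landmarks sit at (+/-10, +/-10) degrees (radial eccentricity
    sqrt(200) ~ 14.14 deg) around a central fixation point. In the
    two-position variant only a diagonal pair of quadrants is ever cued.
    """

    task_variant: str = "four_position"
    cued_pair: tuple[int, int] = (1, 3)
    fixation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.task_variant not in ("four_position", "two_position"):
            raise ConfigurationError(f"unknown task_variant {self.task_variant!r}")
        if self.task_variant == "two_position":
            a, b = self.cued_pair
            if DIAGONAL.get(a) != b:
                raise ConfigurationError(
                    f"cued_pair {self.cued_pair} is not a diagonal quadrant pair"
                )

    @property
    def landmark_positions(self) -> dict[int, tuple[float, float]]:
        return dict(LANDMARKS)

    @property
    def eccentricity_deg(self) -> float:
        return math.sqrt(200.0)

    def cued_quadrants(self) -> tuple[int, ...]:
        if self.task_variant == "two_position":
            return tuple(self.cued_pair)
        return (1, 2, 3, 4)


@dataclass(frozen=True)
class TrialTimeline:
    """Event times of one trial, in ms relative to cue onset."""

    fix_to_cue_ms: int
    target_ms: int
    cue_on_ms: int = 0
    cue_off_ms: int = 350
    distractor_ms: int | None = None
    distractor_kind: str = "none"  # none | uncued_landmark | workspace
    response_window_ms: tuple[int, int] = (150, 750)

    def __post_init__(self):
        if self.fix_to_cue_ms < 0 or self.target_ms < 0:
            raise ConfigurationError("event times must be nonnegative")
        if self.target_ms <= self.cue_off_ms:
            raise ConfigurationError("target must follow cue offset")
        if self.distractor_kind not in ("none", "uncued_landmark", "workspace"):
            raise ConfigurationError(f"bad distractor_kind {self.distractor_kind!r}")
        if self.distractor_ms is not None:
            if not (self.cue_off_ms < self.distractor_ms < self.target_ms):
                raise ConfigurationError(
                    "distractor must fall strictly between cue offset and target"
                )
        elif self.distractor_kind != "none":
            raise ConfigurationError("distractor_kind set without distractor_ms")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic session generator.

    ``exploration_matrix`` and ``pre_matrix`` are 4x4 row-stochastic quadrant
    transition matrices applied once per oscillation cycle; the post-cue
    matrix is expressed in canonical order relative to the cued quadrant.
    """

    n_trials: int = 500
    n_channels: int = 48
    f_gen: float = 9.0                    # spotlight oscillation frequency, Hz
    p_gen_deg: float = -75.0              # oscillation phase at cue onset, degrees
    exploration_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_EXPLORATION_FOUR.copy()
    )
    pre_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_PRE_MATRIX.copy())
    anchor_shrink: float = 0.50           # post-cue anchor = shrink * landmark
    anchor_shrink_pre: float = 0.10       # pre-cue anchors hug fixation
    within_quadrant_spread: float = 7.0   # sinusoidal displacement amplitude, deg
    tuning_width_deg: float = 4.5
    gain_range_hz: tuple[float, float] = (60.0, 120.0)   # MUA-scale rates
    baseline_range_hz: tuple[float, float] = (10.0, 20.0)
    pref_eccentricity_range_deg: tuple[float, float] = (11.0, 14.0)
    evoked_rate_hz: float = 60.0          # stimulus-evoked transient amplitude
    cue_evoked_rate_hz: float = 20.0
    evoked_gain_depth: float = 0.0        # phase modulation of evoked transients
    evoked_duration_ms: int = 100
    hit_base: float = 0.6975
    hit_depth: float = 0.0525
    fa_base: float = 0.405
    fa_depth: float = 0.045
    phi_opt_deg: float = 0.0              # behaviorally optimal phase
    rt_median_ms: float = 350.0
    rt_log_sigma: float = 0.15
    rt_phase_gain: float = 0.15
    distractor_prob: float = 0.5
    landmark_distractor_frac: float = 1.0 / 3.0
    fix_to_cue_range_ms: tuple[int, int] = (700, 1200)
    cue_duration_ms: int = 350
    cueoff_to_target_range_ms: tuple[int, int] = (350, 3300)
    response_window_ms: tuple[int, int] = (150, 750)
    seed: int | None = None

    def __post_init__(self):
        if self.f_gen <= 0:
            raise ConfigurationError("f_gen must be positive")
        if self.n_channels < 4 or self.n_channels % 4:
            raise ConfigurationError(
                "n_channels must be a positive multiple of 4 (quadrant-symmetric bank)"
            )
        _check_row_stochastic(self.exploration_matrix, "exploration_matrix")
        _check_row_stochastic(self.pre_matrix, "pre_matrix")
        if self.tuning_width_deg <= 0:
            raise ConfigurationError("tuning_width_deg must be positive")
        for name in ("gain_range_hz", "baseline_range_hz"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"{name} must be a nonnegative ascending range")
        for base, depth, name in (
            (self.hit_base, self.hit_depth, "hit"),
            (self.fa_base, self.fa_depth, "fa"),
        ):
            if not (0.0 <= base - depth and base + depth <= 1.0):
                raise ConfigurationError(f"{name}_base +/- {name}_depth must lie in [0, 1]")
        if self.evoked_rate_hz < 0 or self.cue_evoked_rate_hz < 0:
            raise ConfigurationError("evoked rates must be nonnegative")
        if not 0.0 <= self.distractor_prob <= 1.0:
            raise ConfigurationError("distractor_prob must be in [0, 1]")
        if self.within_quadrant_spread < 0:
            raise ConfigurationError("within_quadrant_spread must be nonnegative")

    @property
    def p_gen_rad(self) -> float:
        return math.radians(self.p_gen_deg)

    @property
    def phi_opt_rad(self) -> float:
        return math.radians(self.phi_opt_deg)

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.f_gen


@dataclass(frozen=True)
class Trial:
    trial_id: int
    cued_quadrant: int
    timeline: TrialTimeline
    outcome: str | None = None            # hit | miss | false_alarm
    reaction_time_ms: float | None = None
    distractor_quadrant: int | None = None
    distractor_xy: tuple[float, float] | None = None

    def __post_init__(self):
        if self.outcome == "false_alarm" and self.timeline.distractor_ms is None:
            raise ConfigurationError("false alarm requires a distractor")
        if self.outcome in ("hit", "false_alarm") and self.reaction_time_ms is None:
            raise ConfigurationError(f"outcome {self.outcome} requires a reaction time")


@dataclass
class Trajectory:
    """Ground-truth spotlight path of one trial at 1 ms resolution."""

    trial_id: int
    t_ms: np.ndarray          # (T,) int, TIME_START_MS .. TIME_STOP_MS-1
    xy: np.ndarray            # (T, 2) degrees
    quadrant: np.ndarray      # (T,) int, Markov state underlying the position
    phase: np.ndarray         # (T,) radians in (-pi, pi]


@dataclass
class Session:
    """A synthetic (or loaded) session: trials, spike tensor, ground truth."""

    trials: list[Trial]
    spikes: np.ndarray | None               # (n_trials, n_channels, N_TIME_BINS) counts
    geometry: TaskGeometry
    config: GeneratorConfig | None = None
    ground_truth: list[Trajectory] | None = None
    t_ms: np.ndarray = field(default_factory=lambda: np.arange(TIME_START_MS, TIME_STOP_MS))

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        if self.spikes is not None:
            return self.spikes.shape[1]
        return self.config.n_channels if self.config is not None else 0

    def trial_indices(self, outcome=None, with_distractor=None, min_target_ms=None):
        """Indices of trials matching the given filters."""
        idx = []
        for i, tr in enumerate(self.trials):
            if outcome is not None:
                allowed = (outcome,) if isinstance(outcome, str) else tuple(outcome)
                if tr.outcome not in allowed:
                    continue
            if with_distractor is not None:
                has = tr.timeline.distractor_ms is not None
                if has != with_distractor:
                    continue
            if min_target_ms is not None and tr.timeline.target_ms < min_target_ms:
                continue
            idx.append(i)
        return np.asarray(idx, dtype=int)

    def events(self) -> pd.DataFrame:
        """One row per trial with the event table used by the analyses."""
        rows = []
        for tr in self.trials:
            tl = tr.timeline
            rows.append(
                {
                    "trial_id": tr.trial_id,
                    "cued_quadrant": tr.cued_quadrant,
                    "cue_on_ms": tl.cue_on_ms,
                    "cue_off_ms": tl.cue_off_ms,
                    "target_ms": tl.target_ms,
                    "distractor_ms": tl.distractor_ms,
                    "distractor_kind": tl.distractor_kind,
                    "distractor_x": None if tr.distractor_xy is None else tr.distractor_xy[0],
                    "distractor_y": None if tr.distractor_xy is None else tr.distractor_xy[1],
                    "outcome": tr.outcome,
                    "rt_ms": tr.reaction_time_ms,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tuning bank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TuningBank:
    """Per-channel smooth unimodal spatial tuning of firing rate.

    Channel rate at spotlight position z is
    ``baseline + gain * exp(-|z - pref|^2 / (2 width^2))`` (Hz). The first
    half of the channels prefers the left hemifield, the second half the
    right one, mimicking two contralateral probes.
    """

    pref: np.ndarray        # (n_channels, 2)
    width_deg: float
    gain_hz: np.ndarray     # (n_channels,)
    baseline_hz: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.pref.shape[0]

    def rates(self, xy: np.ndarray) -> np.ndarray:
        """Rates (Hz) for positions ``xy`` of shape (T, 2); returns (T, n_channels)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d2 = ((xy[:, None, :] - self.pref[None, :, :]) ** 2).sum(axis=2)
        return self.baseline_hz + self.gain_hz * np.exp(-d2 / (2.0 * self.width_deg**2))

    def spatial_weight(self, xy) -> np.ndarray:
        """Normalized (0..1) tuning bump evaluated at a single location."""
        xy = np.asarray(xy, dtype=float).reshape(1, 2)
        d2 = ((xy - self.pref) ** 2).sum(axis=1)
        return np.exp(-d2 / (2.0 * self.width_deg**2))

    def channel(self, i: int) -> Callable[[float, float], float]:
        """Deterministic (x, y) -> rate function for channel ``i``."""

        def fn(x: float, y: float) -> float:
            return float(self.rates(np.array([[x, y]]))[0, i])

        return fn


def make_tuning_bank(config: GeneratorConfig, rng: np.random.Generator) -> TuningBank:
    """Draw a deterministic bank of spatially tuned channels.

    Preferred locations are biased to the periphery (eccentricities drawn
    from ``pref_eccentricity_range_deg``, mimicking the peripheral bias of
    the recorded maps) and are *symmetrized* across quadrants: a base set of
    n/4 channels (eccentricity, within-quadrant angle, gain, baseline) is
    replicated into all four quadrants by rotation, so the summed population
    drive is identical whichever quadrant the spotlight occupies and
    population-rate fluctuations reflect within-cycle displacement rather
    than which quadrant is visited. Channels are ordered left-hemifield bank
    first (contralateral coding, two probes).
    """
    n = config.n_channels
    if n % 4:
        raise ConfigurationError("n_channels must be divisible by 4")
    base = n // 4
    ecc = rng.uniform(*config.pref_eccentricity_range_deg, base)
    # strictly interior wedge angles keep rotated copies inside their quadrant
    wedge = rng.uniform(0.05, np.pi / 2.0 - 0.05, base)
    gain = rng.uniform(*config.gain_range_hz, base)
    baseline = rng.uniform(*config.baseline_range_hz, base)

    prefs, gains, baselines = [], [], []
    for quadrant_angle in (np.pi / 2.0, np.pi, 0.0, 3.0 * np.pi / 2.0):
        # order: upper-left, lower-left (left bank), upper-right, lower-right
        ang = wedge + quadrant_angle
        prefs.append(np.column_stack([ecc * np.cos(ang), ecc * np.sin(ang)]))
        gains.append(gain)
        baselines.append(baseline)
    return TuningBank(
        pref=np.concatenate(prefs),
        width_deg=config.tuning_width_deg,
        gain_hz=np.concatenate(gains),
        baseline_hz=np.concatenate(baselines),
    )


# ---------------------------------------------------------------------------
# Spotlight trajectory
# ---------------------------------------------------------------------------

def oscillation_phase(t_ms, config: GeneratorConfig, pre_cue_offset: float | None = None):
    """Ground-truth oscillation phase at time(s) ``t_ms`` (ms from cue onset).

    Post-cue (t >= 0) the phase is ``2*pi*f*t + P_gen`` -- i.e. it is reset so
    that its value at cue onset equals ``P_gen``. Pre-cue the phase runs with
    a per-trial offset ``pre_cue_offset`` (defaults to ``P_gen``), so the
    reset at the cue is visible whenever the offset differs.
    """
    t = np.asarray(t_ms, dtype=float) / 1000.0
    post = 2.0 * np.pi * config.f_gen * t + config.p_gen_rad
    if pre_cue_offset is None:
        return wrap_angle(post)
    pre = 2.0 * np.pi * config.f_gen * t + pre_cue_offset
    return wrap_angle(np.where(np.asarray(t_ms) < 0, pre, post))


def _sample_chain_states(matrix: np.ndarray, n_steps: int, start: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Forward-sample ``n_steps`` states (0-based) from a 4x4 chain, including start."""
    cum = np.cumsum(matrix, axis=1)
    states = np.empty(n_steps, dtype=np.int64)
    s = start
    states[0] = s
    u = rng.random(n_steps)
    for k in range(1, n_steps):
        s = int(np.searchsorted(cum[s], u[k]))
        s = min(s, 3)
        states[k] = s
    return states


def simulate_spotlight(trial: Trial, config: GeneratorConfig,
                       rng: np.random.Generator) -> Trajectory:
    """Simulate the 1 ms-resolution ground-truth spotlight path of one trial.

    The quadrant state is updated once per oscillation cycle: pre-cue from the
    near-uniform ``pre_matrix`` with anchors shrunk close to fixation, and
    post-cue from ``exploration_matrix`` (canonical order, remapped so that
    the cued quadrant is the reference) starting at the cued quadrant at cue
    onset. Within a cycle the position is the state's anchor plus a sinusoidal
    radial displacement at ``f_gen`` with amplitude ``within_quadrant_spread``;
    the oscillation phase at the cue-onset sample equals ``P_gen``.
    """
    t_ms = np.arange(TIME_START_MS, TIME_STOP_MS)
    period = config.period_ms

    # Cycle index of every sample; cycle k covers [k*period, (k+1)*period).
    seg = np.floor(t_ms / period).astype(int)
    seg_min, seg_max = seg[0], seg[-1]

    # Pre-cue states: uniform start, near-uniform exploration, actual labels.
    n_pre = -seg_min
    pre_states = _sample_chain_states(
        config.pre_matrix, max(n_pre, 1), int(rng.integers(4)), rng
    )[:n_pre]

    # Post-cue states: reset to the cued quadrant at cue onset.
    post_matrix = canonical_to_quadrant_matrix(config.exploration_matrix, trial.cued_quadrant)
    post_states = _sample_chain_states(
        post_matrix, seg_max + 1, trial.cued_quadrant - 1, rng
    )

    states_by_seg = np.concatenate([pre_states, post_states])  # seg_min .. seg_max
    state = states_by_seg[seg - seg_min] + 1                   # quadrant labels 1..4

    pre_offset = rng.uniform(-np.pi, np.pi)
    phase = oscillation_phase(t_ms, config, pre_cue_offset=pre_offset)

    landmarks = np.array([LANDMARKS[q] for q in (1, 2, 3, 4)])
    units = landmarks / np.linalg.norm(landmarks, axis=1, keepdims=True)
    shrink = np.where(t_ms < 0, config.anchor_shrink_pre, config.anchor_shrink)
    anchor = shrink[:, None] * landmarks[state - 1]
    disp = config.within_quadrant_spread * np.cos(phase)
    xy = anchor + disp[:, None] * units[state - 1]

    return Trajectory(trial_id=trial.trial_id, t_ms=t_ms, xy=xy,
                      quadrant=state, phase=phase)


# ---------------------------------------------------------------------------
# Spiking and outcomes
# ---------------------------------------------------------------------------

def _event_locations(trial: Trial) -> list[tuple[int, np.ndarray, float]]:
    """(time_ms, location, amplitude scale) of the evoked transients of a trial."""
    events = []
    tl = trial.timeline
    cued_lm = np.asarray(LANDMARKS[trial.cued_quadrant])
    events.append((tl.cue_on_ms, cued_lm, "cue"))
    if tl.distractor_ms is not None:
        if trial.distractor_xy is not None:
            loc = np.asarray(trial.distractor_xy)
        else:
            loc = np.asarray(LANDMARKS[trial.distractor_quadrant])
        events.append((tl.distractor_ms, loc, "distractor"))
    # Target is only displayed if the trial was not already interrupted by a
    # false alarm.
    if trial.outcome in ("hit", "miss", None):
        events.append((tl.target_ms, cued_lm, "target"))
    return events


def simulate_spikes(trajectory: Trajectory, tuning_bank: TuningBank, trial: Trial,
                    config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous-Poisson spike counts (n_channels x time bins) for one trial.

    The instantaneous rate of channel c is its tuning function evaluated along
    the spotlight path, plus 100 ms boxcar stimulus-evoked transients whose
    amplitude is scaled by ``1 + evoked_gain_depth * cos(phase - phi_opt)``
    and whose spatial profile follows each channel's tuning bump at the
    stimulated location.
    """
    rate = tuning_bank.rates(trajectory.xy)  # (T, n_channels), Hz

    for t_ev, loc, kind in _event_locations(trial):
        if t_ev is None or t_ev >= TIME_STOP_MS:
            continue
        amp = config.cue_evoked_rate_hz if kind == "cue" else config.evoked_rate_hz
        if amp == 0:
            continue
        theta = oscillation_phase(t_ev, config)
        gain = 1.0 + config.evoked_gain_depth * math.cos(theta - config.phi_opt_rad)
        gain = max(gain, 0.0)
        i0 = t_ev - TIME_START_MS
        i1 = min(i0 + config.evoked_duration_ms, N_TIME_BINS)
        rate[i0:i1] += amp * gain * tuning_bank.spatial_weight(loc)

    if np.any(rate < 0):  # impossible under the config invariants
        raise RuntimeError("negative instantaneous rate in spike simulation")
    return rng.poisson(rate.T * 1e-3).astype(np.uint16)


def outcome_probability(config: GeneratorConfig, theta: float, kind: str = "hit") -> float:
    """Configured cosine law for P(hit) / P(false alarm) at stimulus phase ``theta``."""
    if kind == "hit":
        base, depth = config.hit_base, config.hit_depth
    elif kind == "fa":
        base, depth = config.fa_base, config.fa_depth
    else:
        raise ValueError(f"unknown outcome kind {kind!r}")
    p = base + depth * math.cos(theta - config.phi_opt_rad)
    return float(min(max(p, 0.0), 1.0))


def _draw_rt(config: GeneratorConfig, theta: float, rng: np.random.Generator) -> float:
    lo, hi = config.response_window_ms
    mu = math.log(config.rt_median_ms) - config.rt_phase_gain * math.cos(
        theta - config.phi_opt_rad
    )
    rt = math.exp(rng.normal(mu, config.rt_log_sigma))
    return float(min(max(rt, lo), hi))


def simulate_outcome(trial: Trial, trajectory: Trajectory, config: GeneratorConfig,
                     rng: np.random.Generator) -> tuple[str, float | None]:
    """Draw the behavioral outcome and reaction time of a trial.

    Distractor trials are evaluated first: a false alarm at the distractor
    pre-empts the target. Hit and false-alarm probabilities follow the
    configured phase-gated cosine laws; reaction times are log-normal with a
    median decreasing at the optimal phase, clipped to the response window.
    """
    tl = trial.timeline
    if tl.distractor_ms is not None:
        theta_d = oscillation_phase(tl.distractor_ms, config)
        if rng.random() < outcome_probability(config, theta_d, "fa"):
            return "false_alarm", _draw_rt(config, theta_d, rng)
    theta_t = oscillation_phase(tl.target_ms, config)
    if rng.random() < outcome_probability(config, theta_t, "hit"):
        return "hit", _draw_rt(config, theta_t, rng)
    return "miss", None


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

def sample_timeline(config: GeneratorConfig, rng: np.random.Generator,
                    with_distractor: bool, distractor_kind: str = "none") -> TrialTimeline:
    """Draw one trial timeline from the configured ranges."""
    fix_to_cue = int(rng.integers(config.fix_to_cue_range_ms[0],
                                  config.fix_to_cue_range_ms[1] + 1))
    lo, hi = config.cueoff_to_target_range_ms
    target = config.cue_duration_ms + int(rng.integers(lo, hi + 1))
    distractor_ms = None
    if with_distractor:
        # Keep the distractor's evoked transient clear of both the cue
        # offset and the target window.
        d_lo = config.cue_duration_ms + 100
        d_hi = target - 150
        distractor_ms = int(rng.integers(d_lo, d_hi + 1))
    return TrialTimeline(
        fix_to_cue_ms=fix_to_cue,
        target_ms=target,
        cue_off_ms=config.cue_duration_ms,
        distractor_ms=distractor_ms,
        distractor_kind=distractor_kind if with_distractor else "none",
        response_window_ms=config.response_window_ms,
    )


def quadrant_of_point(x: float, y: float) -> int:
    # Zero is assigned to the positive side, matching the decoder's readout.
    if x >= 0:
        return 1 if y >= 0 else 4
    return 2 if y >= 0 else 3


def generate_session(config: GeneratorConfig, geometry: TaskGeometry | None = None,
                     seed: int | None = None, with_spikes: bool = True,
                     with_trajectories: bool | None = None) -> Session:
    """Generate a full synthetic session; identical seeds give identical sessions.

    ``with_spikes=False`` skips the spike tensor (events and outcomes only);
    ``with_trajectories=False`` additionally skips the 1 ms ground-truth paths
    (outcomes depend only on the analytic oscillation phase), which makes
    behavioral-only sessions orders of magnitude faster. Determinism holds per
    flag combination.
    """
    if geometry is None:
        geometry = TaskGeometry()
    if seed is None:
        seed = config.seed
    if with_trajectories is None:
        with_trajectories = with_spikes
    if with_spikes and not with_trajectories:
        raise ConfigurationError("spike simulation requires trajectories")
    rng = np.random.default_rng(seed)

    if config.n_trials < 40:
        warnings.warn(
            f"n_trials={config.n_trials} < 40: phase bins will be sparse",
            UserWarning,
            stacklevel=2,
        )

    bank = make_tuning_bank(config, rng)
    cued_choices = geometry.cued_quadrants()

    trials: list[Trial] = []
    trajectories: list[Trajectory] = []
    spike_list: list[np.ndarray] = []

    for trial_id in range(config.n_trials):
        cued = int(cued_choices[rng.integers(len(cued_choices))])
        with_distractor = rng.random() < config.distractor_prob
        kind = "none"
        distractor_quadrant = None
        distractor_xy = None
        if with_distractor:
            if rng.random() < config.landmark_distractor_frac:
                kind = "uncued_landmark"
                uncued = [q for q in (1, 2, 3, 4) if q != cued]
                distractor_quadrant = int(uncued[rng.integers(3)])
                distractor_xy = LANDMARKS[distractor_quadrant]
            else:
                kind = "workspace"
                distractor_xy = tuple(rng.uniform(-10.0, 10.0, 2))
                distractor_quadrant = quadrant_of_point(*distractor_xy)
        timeline = sample_timeline(config, rng, with_distractor, kind)
        trial = Trial(
            trial_id=trial_id,
            cued_quadrant=cued,
            timeline=timeline,
            distractor_quadrant=distractor_quadrant,
            distractor_xy=distractor_xy,
        )
        trajectory = simulate_spotlight(trial, config, rng) if with_trajectories else None
        outcome, rt = simulate_outcome(trial, trajectory, config, rng)
        trial = Trial(
            trial_id=trial_id,
            cued_quadrant=cued,
            timeline=timeline,
            outcome=outcome,
            reaction_time_ms=rt,
            distractor_quadrant=distractor_quadrant,
            distractor_xy=distractor_xy,
        )
        if with_spikes:
            spike_list.append(simulate_spikes(trajectory, bank, trial, config, rng))
        trials.append(trial)
        if with_trajectories:
            trajectories.append(trajectory)

    spikes = np.stack(spike_list) if with_spikes else None
    return Session(
        trials=trials,
        spikes=spikes,
        geometry=geometry,
        config=config,
        ground_truth=trajectories if with_trajectories else None,
    )
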