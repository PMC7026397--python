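"""Population "super MUA" and phase modulation of single-channel spiking.

The super MUA of a trial is the channel average of 50 ms-smoothed spiking;
its alpha-band (7-12 Hz) filtered copy defines population oscillation cycles.
Each channel's high-spiking epochs (rate strictly above 65% of the channel's
session maximum) are then related to the up (+/- pi/2 around the peak) and
down (+/- pi/2 around the trough) phases of band-passed super-MUA
oscillations over a 5-15 Hz grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal

from .synth import TIME_START_MS, Session

HIGH_SPIKING_FRACTION = 0.65
ALPHA_BAND = (7.0, 12.0)
ANALYSIS_EPOCH_MS = (500, 2100)
MIN_CONTRIBUTING_BINS = 50


@dataclass
class SuperMUATrace:
    trial_id: int
    t_ms: np.ndarray
    raw: np.ndarray                # mean smoothed rate over channels, Hz
    alpha_filtered: np.ndarray
    peak_times_ms: np.ndarray


@dataclass
class PhaseModulationProfile:
    """Per-channel spiking probability at up vs down super-MUA phases."""

    frequencies: np.ndarray        # Hz
    p_up: np.ndarray               # (n_channels, n_freq)
    p_down: np.ndarray
    n_bins_up: np.ndarray          # contributing time bins
    n_bins_down: np.ndarray

    @property
    def modulation(self) -> np.ndarray:
        return self.p_up - self.p_down

    @property
    def session_mean(self) -> np.ndarray:
        """Mean modulation over channels, NaN-aware."""
        return np.nanmean(self.modulation, axis=0)


def smoothed_channel_rates(session: Session, trial_index: int,
                           smooth_ms: int = 50) -> np.ndarray:
    """50 ms sliding-mean firing rate (Hz) per channel -> (n_channels, T)."""
    counts = session.spikes[trial_index].astype(float)
    return scipy.ndimage.uniform_filter1d(counts, smooth_ms, axis=1,
                                          mode="nearest") * 1000.0


def _bandpass(x, fs, lo, hi, order=3):
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=fs,
                              output="sos")
    return scipy.signal.sosfiltfilt(sos, x)


def smooth_and_pool(session: Session, trial_index: int,
                    smooth_ms: int = 50) -> SuperMUATrace:
    """Build the super MUA of one trial and locate its alpha-cycle peaks."""
    rates = smoothed_channel_rates(session, trial_index, smooth_ms)
    raw = rates.mean(axis=0)
    alpha = _bandpass(raw - raw.mean(), 1000.0, *ALPHA_BAND)
    min_distance = int(round(1000.0 / ALPHA_BAND[1] / 2.0))  # half cycle at 12 Hz
    peaks, _ = scipy.signal.find_peaks(alpha, distance=min_distance)
    t_ms = session.t_ms
    return SuperMUATrace(
        trial_id=session.trials[trial_index].trial_id,
        t_ms=t_ms,
        raw=raw,
        alpha_filtered=alpha,
        peak_times_ms=t_ms[peaks],
    )


def channel_session_maxima(session: Session, epoch_ms=ANALYSIS_EPOCH_MS,
                           smooth_ms: int = 50,
                           quantile: float = 0.99) -> np.ndarray:
    """Per-channel maximum spiking regime over the analysis epoch of a session.

    The "maximum regime" is a sustained level, estimated as a high quantile
    (default 99th percentile) of the smoothed rate pooled over trials rather
    than the single most extreme bin, which under Poisson variability would
    be an outlier far above any sustained rate. ``quantile=1`` recovers the
    strict maximum.
    """
    lo = epoch_ms[0] - TIME_START_MS
    hi = epoch_ms[1] - TIME_START_MS
    if quantile >= 1.0:
        maxima = np.zeros(session.n_channels)
        for i in range(session.n_trials):
            rates = smoothed_channel_rates(session, i, smooth_ms)[:, lo:hi]
            maxima = np.maximum(maxima, rates.max(axis=1))
        return maxima
    pooled = np.concatenate(
        [smoothed_channel_rates(session, i, smooth_ms)[:, lo:hi]
         for i in range(session.n_trials)],
        axis=1,
    )
    return np.quantile(pooled, quantile, axis=1)


def high_spiking_mask(channel_trace, max_rate: float | None = None,
                      fraction: float = HIGH_SPIKING_FRACTION) -> np.ndarray:
    """Binary high-spiking epochs: 1 where rate > fraction * maximum.

    The comparison is strict, so a constant positive trace (rate equal to its
    own maximum everywhere) yields an all-zero mask. An all-zero trace also
    yields an all-zero mask.
    """
    trace = np.asarray(channel_trace, dtype=float)
    if np.any(trace < 0):
        raise ValueError("spiking trace must be nonnegative")
    m = trace.max() if max_rate is None else max_rate
    return (trace > fraction * m).astype(np.uint8)


def phase_modulation(session: Session, frequencies=None,
                     epoch_ms=ANALYSIS_EPOCH_MS, smooth_ms: int = 50,
                     band_halfwidth_hz: float = 1.5,
                     trial_indices=None) -> PhaseModulationProfile:
    """Spiking-probability modulation by super-MUA phase over 5-15 Hz.

    For each frequency the pooled population rate is zero-phase band-passed
    (+/- 1.5 Hz) and its analytic (Hilbert) phase splits the epoch into up
    (within pi/2 of a peak) and down (within pi/2 of a trough) bins; per
    channel, p_up and p_down are the fractions of up/down bins that are
    high-spiking, aggregated across trials. Each channel is conditioned on
    the *leave-one-out* population signal (its own spikes excluded from the
    pool) so that a bursty channel cannot phase-lock to itself. Entries with
    fewer than 50 contributing bins per channel are NaN-masked.
    """
    if frequencies is None:
        frequencies = np.arange(5.0, 15.0 + 1e-9, 1.0)
    frequencies = np.asarray(frequencies, dtype=float)
    if trial_indices is None:
        trial_indices = range(session.n_trials)

    lo = epoch_ms[0] - TIME_START_MS
    hi = epoch_ms[1] - TIME_START_MS
    maxima = channel_session_maxima(session, epoch_ms, smooth_ms)
    n_ch = session.n_channels
    nf = len(frequencies)
    up_hits = np.zeros((n_ch, nf))
    up_bins = np.zeros((n_ch, nf))
    down_hits = np.zeros((n_ch, nf))
    down_bins = np.zeros((n_ch, nf))

    for ti in trial_indices:
        rates = smoothed_channel_rates(session, ti, smooth_ms)
        masks = (rates > HIGH_SPIKING_FRACTION * maxima[:, None])[:, lo:hi]
        total = rates.sum(axis=0)
        # stack [total, channel 0, channel 1, ...]; band-passing and the
        # Hilbert transform are linear, so the leave-one-out analytic signal
        # of channel c is (analytic(total) - analytic(rates_c)) / (n - 1).
        signals = np.vstack([total, rates])
        signals = signals - signals.mean(axis=1, keepdims=True)
        for fi, f in enumerate(frequencies):
            band = _bandpass(signals, 1000.0, f - band_halfwidth_hz,
                             f + band_halfwidth_hz)
            analytic = scipy.signal.hilbert(band, axis=1)
            loo = analytic[0][None, :] - analytic[1:]
            up = np.abs(np.angle(loo))[:, lo:hi] < np.pi / 2.0
            up_hits[:, fi] += (masks & up).sum(axis=1)
            up_bins[:, fi] += up.sum(axis=1)
            down_hits[:, fi] += (masks & ~up).sum(axis=1)
            down_bins[:, fi] += (~up).sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        p_up = np.where(up_bins >= MIN_CONTRIBUTING_BINS, up_hits / up_bins, np.nan)
        p_down = np.where(down_bins >= MIN_CONTRIBUTING_BINS,
                          down_hits / down_bins, np.nan)
    return PhaseModulationProfile(
        frequencies=frequencies,
        p_up=p_up,
        p_down=p_down,
        n_bins_up=up_bins,
        n_bins_down=down_bins,
    )
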