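"""Phase-conditioned stimulus encoding and behavior.

Each session's attention-information oscillation is summarized by a sinusoid
``MS(t) = sin(2 pi F t - P)``; stimulus events are assigned to one of ten
phase bins of that model, a 5 ms lag sweep over one cycle aligns the bin of
maximal metric with phase zero, and peak/trough summaries contrast the
contiguous thirds of the cycle around phase 0 and around +/-pi. Pooled
per-millisecond hit-rate and reaction-time series are analyzed with the same
wavelet machinery, with an f-multiplicative 1/f correction and permutation
significance obtained by reassigning target timings to outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from . import rhythm
from .synth import wrap_angle

N_PHASE_BINS = 10


@dataclass(frozen=True)
class PhaseModel:
    """Session oscillation model MS(t) = sin(2 pi F t - P), t in s from cue onset."""

    F: float            # Hz
    P: float            # radians

    def __post_init__(self):
        if not 4.0 <= self.F <= 20.0:
            raise ValueError(f"session frequency {self.F} Hz outside [4, 20]")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.F


@dataclass
class PhaseBinCurve:
    """A metric per phase bin, aligned so the maximizing bin sits at phase 0.

    ``values[k]`` is the metric in the bin whose (post-alignment) center phase
    is ``phase_centers[k] = wrap(k * 2 pi / 10)``; index 0 is the optimal bin.
    """

    values: np.ndarray          # (10,)
    n_per_bin: np.ndarray       # (10,) event counts
    optimal_lag_ms: float
    n_bins: int = N_PHASE_BINS

    @property
    def phase_centers(self) -> np.ndarray:
        return wrap_angle(np.arange(self.n_bins) * 2.0 * np.pi / self.n_bins)


def model_phase(event_time_ms, model: PhaseModel, lag_ms: float = 0.0):
    """Phase offset of the modeled wave at ``event_time_ms - lag_ms``.

    Convention: the offset decreases with time at rate 2 pi F, so that at
    t = 0 with P = 0 the offset is 0 and a quarter cycle later it is -pi/2.
    Values are wrapped into [-pi, pi).
    """
    t = (np.asarray(event_time_ms, dtype=float) - lag_ms) / 1000.0
    ph = model.P - 2.0 * np.pi * model.F * t
    out = np.mod(ph + np.pi, 2.0 * np.pi) - np.pi
    return float(out) if out.ndim == 0 else out


def assign_phase_bin(event_time_ms, model: PhaseModel, lag_ms: float = 0.0,
                     n_bins: int = N_PHASE_BINS):
    """Index (0..n_bins-1) of the phase bin containing the event.

    Bin k covers phases [-pi + k*2pi/n, -pi + (k+1)*2pi/n); the central bins
    (k = n/2 - 1, n/2) straddle phase 0.
    """
    ph = model_phase(event_time_ms, model, lag_ms)
    idx = np.floor((ph + np.pi) / (2.0 * np.pi / n_bins)).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    return int(idx) if np.ndim(idx) == 0 else idx


def metric_by_phase(event_times_ms, successes, model: PhaseModel,
                    lag_step_ms: float = 5.0, n_bins: int = N_PHASE_BINS,
                    min_per_bin: int = 1) -> PhaseBinCurve:
    """Phase-binned event metric with an optimal-lag search.

    ``successes`` holds one value per event (0/1 for rates and accuracies; any
    real value is averaged per bin). The event times are shifted over one
    oscillation period in ``lag_step_ms`` steps; the lag maximizing the
    max-bin minus min-bin discrimination is kept and the curve is rotated so
    the maximizing bin sits at phase 0. Bins with fewer than ``min_per_bin``
    events hold NaN sentinels and are ignored by the lag search.
    """
    times = np.asarray(event_times_ms, dtype=float)
    vals = np.asarray(successes, dtype=float)
    if times.size != vals.size:
        raise ValueError("event times and successes must align")
    if times.size == 0:
        raise ValueError("no events to bin")

    lags = np.arange(0.0, model.period_ms, lag_step_ms)
    best = None
    for lag in lags:
        bins = assign_phase_bin(times, model, lag, n_bins)
        counts = np.bincount(bins, minlength=n_bins).astype(float)
        sums = np.bincount(bins, weights=vals, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            means = np.where(counts >= min_per_bin, sums / counts, np.nan)
        if np.all(np.isnan(means)):
            continue
        disc = np.nanmax(means) - np.nanmin(means)
        if best is None or disc > best[0]:
            best = (disc, lag, means, counts)
    if best is None:
        occupancy = np.bincount(assign_phase_bin(times, model, 0.0, n_bins),
                                minlength=n_bins)
        raise ValueError(f"all phase bins under-populated; occupancies: {occupancy}")

    _, lag, means, counts = best
    shift = int(np.nanargmax(means))
    return PhaseBinCurve(
        values=np.roll(means, -shift),
        n_per_bin=np.roll(counts, -shift).astype(int),
        optimal_lag_ms=float(lag),
        n_bins=n_bins,
    )


def peak_trough(curve: PhaseBinCurve) -> tuple[float, float]:
    """Mean metric over the contiguous thirds of the cycle at phase 0 and +/-pi.

    With 10 bins a third rounds to 3 bins: the peak averages the aligned bin
    and its two neighbors, the trough the three bins centered on the opposite
    phase.
    """
    n = curve.n_bins
    third = max(n // 3, 1)
    half_width = third // 2
    peak_idx = [(k) % n for k in range(-half_width, third - half_width)]
    opposite = n // 2
    trough_idx = [(opposite + k) % n for k in range(-half_width, third - half_width)]
    peak = float(np.nanmean(curve.values[peak_idx]))
    trough = float(np.nanmean(curve.values[trough_idx]))
    return peak, trough


def average_curves(curves) -> PhaseBinCurve:
    """Across-session average of aligned phase-bin curves (NaN-aware)."""
    curves = list(curves)
    vals = np.nanmean(np.stack([c.values for c in curves]), axis=0)
    counts = np.stack([c.n_per_bin for c in curves]).sum(axis=0)
    return PhaseBinCurve(values=vals, n_per_bin=counts,
                         optimal_lag_ms=float(np.mean([c.optimal_lag_ms for c in curves])),
                         n_bins=curves[0].n_bins)


# ---------------------------------------------------------------------------
# Session-level metric extractors
# ---------------------------------------------------------------------------

def hit_rate_by_phase(session, model: PhaseModel, **kwargs) -> PhaseBinCurve:
    """Hit rate (hits / (hits + misses)) per phase bin of the target time."""
    times, hits = [], []
    for tr in session.trials:
        if tr.outcome in ("hit", "miss"):
            times.append(tr.timeline.target_ms)
            hits.append(1.0 if tr.outcome == "hit" else 0.0)
    return metric_by_phase(times, hits, model, **kwargs)


def fa_rate_by_phase(session, model: PhaseModel, **kwargs) -> PhaseBinCurve:
    """False-alarm rate per phase bin of the distractor time."""
    times, fas = [], []
    for tr in session.trials:
        if tr.timeline.distractor_ms is not None:
            times.append(tr.timeline.distractor_ms)
            fas.append(1.0 if tr.outcome == "false_alarm" else 0.0)
    return metric_by_phase(times, fas, model, **kwargs)


def decoding_accuracy_by_phase(session, event: str, model: PhaseModel,
                               lam="auto", rng=None, min_per_bin: int = 5,
                               **kwargs) -> PhaseBinCurve:
    """Four-class event-decoding accuracy per phase bin.

    Out-of-fold predictions are computed once across all decodable events of
    the session (they do not depend on the lag), then aggregated per bin.
    """
    from .decoding import event_decoding_predictions

    _, times, quads, preds = event_decoding_predictions(session, event, lam=lam,
                                                        rng=rng)
    return metric_by_phase(times, (preds == quads).astype(float), model,
                           min_per_bin=min_per_bin, **kwargs)


# ---------------------------------------------------------------------------
# Pooled behavioral time series
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSeries:
    t_ms: np.ndarray
    values: np.ndarray          # detrended
    raw: np.ndarray             # before detrending
    interpolated: np.ndarray    # True where no event contributed


def _boxcar(x, width):
    kernel = np.ones(width) / width
    return scipy.signal.fftconvolve(x, kernel, mode="same")


def behavior_timeseries(target_times_ms, is_hit, span_ms=(500, 2100),
                        smooth_ms: int = 50) -> BehaviorSeries:
    """Per-millisecond hit-rate series over target presentation time.

    Hit and total counts are accumulated per ms of target time, smoothed with
    a ``smooth_ms`` boxcar, and their ratio forms the rate; milliseconds
    without any (smoothed) targets are linearly interpolated and flagged. The
    series is restricted to ``span_ms`` and linearly detrended.
    """
    times = np.asarray(target_times_ms, dtype=int)
    hits = np.asarray(is_hit, dtype=float)
    if times.size == 0:
        raise ValueError("no trials")
    t_max = max(int(times.max()) + 1, span_ms[1] + 1)
    totals = np.bincount(times, minlength=t_max).astype(float)
    hit_counts = np.bincount(times, weights=hits, minlength=t_max)
    sm_tot = _boxcar(totals, smooth_ms)
    sm_hit = _boxcar(hit_counts, smooth_ms)
    t = np.arange(span_ms[0], span_ms[1] + 1)
    sm_tot = sm_tot[t]
    sm_hit = sm_hit[t]
    empty = sm_tot <= 1e-9
    rate = np.empty_like(sm_tot)
    rate[~empty] = sm_hit[~empty] / sm_tot[~empty]
    if empty.any():
        if empty.all():
            raise ValueError("no targets inside the analysis span")
        rate[empty] = np.interp(t[empty], t[~empty], rate[~empty])
    detrended = scipy.signal.detrend(rate)
    return BehaviorSeries(t_ms=t, values=detrended, raw=rate, interpolated=empty)


def rt_timeseries(target_times_ms, rts_ms, span_ms=(500, 2100),
                  smooth_ms: int = 50, min_per_bin: int = 3) -> BehaviorSeries:
    """Detrended geometric-mean reaction-time series over target time.

    Computed as exp of the smoothed mean log RT; milliseconds whose smoothed
    support falls below ``min_per_bin`` observations are merged with their
    neighbors by interpolation.
    """
    times = np.asarray(target_times_ms, dtype=int)
    rts = np.asarray(rts_ms, dtype=float)
    if times.size == 0:
        raise ValueError("no reaction times")
    t_max = max(int(times.max()) + 1, span_ms[1] + 1)
    totals = np.bincount(times, minlength=t_max).astype(float)
    log_sums = np.bincount(times, weights=np.log(rts), minlength=t_max)
    sm_tot = _boxcar(totals, smooth_ms)
    sm_log = _boxcar(log_sums, smooth_ms)
    t = np.arange(span_ms[0], span_ms[1] + 1)
    sm_tot = sm_tot[t]
    sm_log = sm_log[t]
    sparse = sm_tot * smooth_ms < min_per_bin  # smoothed support in trial counts
    gm = np.empty_like(sm_tot)
    gm[~sparse] = np.exp(sm_log[~sparse] / sm_tot[~sparse])
    if sparse.any():
        if sparse.all():
            raise ValueError("no sufficiently sampled reaction times in span")
        gm[sparse] = np.interp(t[sparse], t[~sparse], gm[~sparse])
    detrended = scipy.signal.detrend(gm)
    return BehaviorSeries(t_ms=t, values=detrended, raw=gm, interpolated=sparse)


def _series_spectrum(values, fs: float, frequencies, decimate_to: float = 250.0):
    """Time-averaged Morlet power of a series, optionally decimated first."""
    x = np.asarray(values, dtype=float)
    if fs > decimate_to:
        q = int(round(fs / decimate_to))
        x = scipy.signal.decimate(x, q, zero_phase=True)
        fs = fs / q
    coeffs, _ = rhythm.morlet_transform(x, fs, frequencies)
    return (np.abs(coeffs) ** 2).mean(axis=1)


def behavior_spectrum(target_times_ms, is_hit, n_perm: int = 200,
                      rng: np.random.Generator | None = None,
                      span_ms=(500, 2100), frequencies=None,
                      series_fn=behavior_timeseries,
                      series_values=None) -> rhythm.SpectralResult:
    """f-normalized wavelet spectrum of the pooled behavioral series.

    Significance: the per-frequency 95th percentile of the same statistic
    under random reassignment of target timings to outcomes (``n_perm``
    permutations). ``series_fn`` selects the underlying series builder so the
    same machinery serves hit rates (default) and reaction times.
    """
    rng = np.random.default_rng() if rng is None else rng
    if frequencies is None:
        frequencies = rhythm.morlet_frequencies()
    times = np.asarray(target_times_ms)
    outcomes = np.asarray(is_hit, dtype=float)

    series = series_fn(times, outcomes, span_ms=span_ms)
    raw_power = rhythm.normalize_1f(
        _series_spectrum(series.values, 1000.0, frequencies), frequencies
    )
    null = np.empty((n_perm, len(frequencies)))
    for p in range(n_perm):
        perm = rng.permutation(outcomes.size)
        s = series_fn(times, outcomes[perm], span_ms=span_ms)
        null[p] = rhythm.normalize_1f(
            _series_spectrum(s.values, 1000.0, frequencies), frequencies
        )
    threshold = np.percentile(null, 95, axis=0)
    norm = raw_power.max()
    return rhythm.SpectralResult(
        frequencies=np.asarray(frequencies),
        power=raw_power / norm if norm > 0 else raw_power,
        peak_freq_7_12=rhythm.peak_in_band(frequencies, raw_power),
        null_threshold=threshold / norm if norm > 0 else threshold,
        raw_power=raw_power,
    )
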