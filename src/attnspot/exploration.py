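"""Spatial characterization of decoded spotlight trajectories.

Trajectories are collapsed onto the four screen quadrants, first-order Markov
transition matrices are estimated by maximum-likelihood counting, post-cue
transitions are normalized by pre-cue exploration biases and remapped into the
canonical order [stay at cued, same-hemifield, opposite-hemifield, diagonal].
Occupancy heat maps and displacement distributions (with x-vs-y and
pre-vs-post Kolmogorov-Smirnov comparisons) summarize where and how far the
spotlight moves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .decoding import quadrant_of
from .synth import LANDMARKS, canonical_permutation

#: Default analysis epochs (ms from cue onset).
POST_CUE_EPOCH_MS = (500, 1200)
PRE_CUE_EPOCH_MS = (-500, -200)
DISPLACEMENT_EPOCH_MS = (500, 1250)

PRE_FLOOR_EPS = 1e-3


@dataclass
class MarkovTransitionProfile:
    raw_pre: np.ndarray         # 4x4, rows may be NaN if unvisited
    raw_post: np.ndarray
    normalized: np.ndarray      # cued row after pre normalization (4-vector, quadrant order)
    canonical: np.ndarray       # [stay, same-hemifield, opposite-hemifield, diagonal]
    cued_quadrant: int


@dataclass
class DisplacementStats:
    amplitudes: np.ndarray      # per-step Euclidean displacement, degrees
    dx: np.ndarray              # per-step |x| displacement
    dy: np.ndarray
    ks_statistic: float         # |dx| vs |dy|
    ks_pvalue: float


def quadrant_sequence(trajectory, epoch_ms=POST_CUE_EPOCH_MS) -> np.ndarray:
    """Sign-based quadrant (1..4) at each decoded step inside ``epoch_ms``."""
    sel = (trajectory.t_ms >= epoch_ms[0]) & (trajectory.t_ms <= epoch_ms[1])
    xy = trajectory.xy[sel]
    return quadrant_of(xy[:, 0], xy[:, 1])


def estimate_transitions(state_sequences) -> np.ndarray:
    """Maximum-likelihood 4x4 transition matrix from quadrant state sequences.

    Entry (i, j) is n(i -> j) / sum_k n(i -> k), counted at the sequence's own
    step resolution. Rows of states never left (no outgoing transitions) are
    NaN-flagged rather than invented.
    """
    counts = np.zeros((4, 4))
    for seq in state_sequences:
        s = np.asarray(seq, dtype=int)
        if s.size < 2:
            continue
        if np.any((s < 1) | (s > 4)):
            raise ValueError("states must be quadrant labels 1..4")
        np.add.at(counts, (s[:-1] - 1, s[1:] - 1), 1)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = counts / totals
    matrix[totals[:, 0] == 0] = np.nan
    return matrix


def normalize_and_canonicalize(raw_post: np.ndarray, raw_pre: np.ndarray,
                               cued_quadrant: int,
                               eps: float = PRE_FLOOR_EPS) -> MarkovTransitionProfile:
    """Pre-cue-normalized, canonically remapped cued-row transition profile.

    The cued-quadrant row of the post matrix is divided elementwise by the
    pre-cue row (floored at ``eps`` to keep empty pre cells finite), the row
    is re-normalized to sum to one, and the columns are remapped to the
    canonical order [stay, same-hemifield, opposite-hemifield, diagonal] of
    the cued quadrant.
    """
    raw_post = np.asarray(raw_post, dtype=float)
    raw_pre = np.asarray(raw_pre, dtype=float)
    row_post = raw_post[cued_quadrant - 1]
    row_pre = raw_pre[cued_quadrant - 1]
    if np.any(np.isnan(row_post)) or np.any(np.isnan(row_pre)):
        raise ValueError(
            f"cued quadrant {cued_quadrant} unvisited in pre- or post-cue epoch"
        )
    ratio = row_post / np.maximum(row_pre, eps)
    total = ratio.sum()
    if total <= 0:
        raise ValueError("degenerate normalized row")
    normalized = ratio / total
    perm = np.asarray(canonical_permutation(cued_quadrant)) - 1
    return MarkovTransitionProfile(
        raw_pre=raw_pre,
        raw_post=raw_post,
        normalized=normalized,
        canonical=normalized[perm],
        cued_quadrant=cued_quadrant,
    )


def sample_chain(matrix: np.ndarray, n_steps: int,
                 rng: np.random.Generator, init: int | None = None) -> np.ndarray:
    """Sample a quadrant state sequence (labels 1..4) of length ``n_steps``."""
    matrix = np.asarray(matrix, dtype=float)
    cum = np.cumsum(matrix, axis=1)
    states = np.empty(n_steps, dtype=int)
    s = int(rng.integers(4)) if init is None else init - 1
    states[0] = s + 1
    u = rng.random(n_steps)
    for k in range(1, n_steps):
        s = min(int(np.searchsorted(cum[s], u[k])), 3)
        states[k] = s + 1
    return states


# ---------------------------------------------------------------------------
# Occupancy and displacement
# ---------------------------------------------------------------------------

@dataclass
class OccupancyMap:
    density: np.ndarray         # normalized 2D histogram
    x_edges: np.ndarray
    y_edges: np.ndarray
    median_radial_deg: float
    centroid: np.ndarray        # (2,)
    centroid_shift_deg: float | None      # toward the cued landmark, if known
    extent_60_deg: float | None           # 60% cumulative extent along cued axis


def _epoch_positions(trajectories, epoch_ms):
    chunks = []
    for tr in trajectories:
        sel = (tr.t_ms >= epoch_ms[0]) & (tr.t_ms <= epoch_ms[1])
        chunks.append(tr.xy[sel])
    if not chunks:
        raise ValueError("no trajectories")
    return np.concatenate(chunks)


def occupancy_heatmap(trajectories, epoch_ms=POST_CUE_EPOCH_MS,
                      cued_quadrants=None, grid_deg: float = 0.5,
                      extent_deg: float = 20.0,
                      reference_positions=None) -> OccupancyMap:
    """Spatial density of decoded positions plus radial/axis summary scalars.

    When per-trajectory ``cued_quadrants`` are given, positions are projected
    onto each trial's fixation-to-cued-landmark axis; the centroid shift is
    the mean projection (minus the mean projection of ``reference_positions``
    -- e.g. a pre-cue epoch -- when provided) and ``extent_60_deg`` is the
    projection below which 60% of the exploration lies.
    """
    pos = _epoch_positions(trajectories, epoch_ms)
    if len(pos) < 100:
        raise ValueError(f"need >= 100 positions, got {len(pos)}")
    edges = np.arange(-extent_deg, extent_deg + grid_deg / 2.0, grid_deg)
    hist, xe, ye = np.histogram2d(pos[:, 0], pos[:, 1], bins=(edges, edges))
    density = hist / hist.sum()
    median_radial = float(np.median(np.hypot(pos[:, 0], pos[:, 1])))

    shift = None
    extent60 = None
    if cued_quadrants is not None:
        proj = _axis_projections(trajectories, epoch_ms, cued_quadrants)
        shift = float(np.mean(proj))
        if reference_positions is not None:
            shift -= float(np.mean(reference_positions))
        extent60 = float(np.quantile(proj, 0.60))
    return OccupancyMap(
        density=density,
        x_edges=xe,
        y_edges=ye,
        median_radial_deg=median_radial,
        centroid=pos.mean(axis=0),
        centroid_shift_deg=shift,
        extent_60_deg=extent60,
    )


def _axis_projections(trajectories, epoch_ms, cued_quadrants) -> np.ndarray:
    """Projections of each trajectory's positions onto its cued-landmark axis."""
    out = []
    for tr, q in zip(trajectories, cued_quadrants):
        sel = (tr.t_ms >= epoch_ms[0]) & (tr.t_ms <= epoch_ms[1])
        lm = np.asarray(LANDMARKS[int(q)], dtype=float)
        u = lm / np.linalg.norm(lm)
        out.append(tr.xy[sel] @ u)
    return np.concatenate(out)


def axis_projections(trajectories, epoch_ms, cued_quadrants) -> np.ndarray:
    return _axis_projections(trajectories, epoch_ms, cued_quadrants)


def displacement_stats(trajectories, epoch_ms=DISPLACEMENT_EPOCH_MS) -> DisplacementStats:
    """Step-to-step displacement distributions with an x-vs-y KS comparison."""
    dxs, dys = [], []
    for tr in trajectories:
        sel = (tr.t_ms >= epoch_ms[0]) & (tr.t_ms <= epoch_ms[1])
        xy = tr.xy[sel]
        if len(xy) < 2:
            continue
        d = np.diff(xy, axis=0)
        dxs.append(np.abs(d[:, 0]))
        dys.append(np.abs(d[:, 1]))
    if not dxs:
        raise ValueError("no trajectory provides >= 2 samples in the epoch")
    dx = np.concatenate(dxs)
    dy = np.concatenate(dys)
    amplitudes = np.hypot(dx, dy)
    ks = scipy.stats.ks_2samp(dx, dy)
    return DisplacementStats(
        amplitudes=amplitudes,
        dx=dx,
        dy=dy,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )


def epoch_comparison_ks(trajectories, epoch_a=PRE_CUE_EPOCH_MS,
                        epoch_b=DISPLACEMENT_EPOCH_MS):
    """Two-sample KS test between displacement amplitudes of two epochs."""
    a = displacement_stats(trajectories, epoch_a).amplitudes
    b = displacement_stats(trajectories, epoch_b).amplitudes
    ks = scipy.stats.ks_2samp(a, b)
    return float(ks.statistic), float(ks.pvalue)
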