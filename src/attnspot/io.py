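"""Plain-text (and optional npz) serialization of sessions.

A session directory holds ``events.tsv`` (one row per trial), ``config.json``
(generator parameters and geometry), the spike tensor (``spikes.npz`` by
default, or one ``spikes_trial<k>.tsv`` per trial as a text fallback) and,
for synthetic sessions, ``ground_truth.tsv``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import (
    GeneratorConfig,
    Session,
    TaskGeometry,
    Trajectory,
    Trial,
    TrialTimeline,
)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_session(session: Session, path, spikes_format: str = "npz",
                 ground_truth_step_ms: int = 1) -> Path:
    """Write a session directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    session.events().to_csv(path / "events.tsv", sep="\t", index=False)

    meta = {
        "geometry": dataclasses.asdict(session.geometry),
        "config": None if session.config is None else dataclasses.asdict(session.config),
        "t_start_ms": int(session.t_ms[0]),
        "t_stop_ms": int(session.t_ms[-1]) + 1,
        "spikes_format": spikes_format if session.spikes is not None else "none",
    }
    (path / "config.json").write_text(json.dumps(meta, indent=2, default=_jsonable))

    if session.spikes is not None:
        if spikes_format == "npz":
            np.savez_compressed(path / "spikes.npz", spikes=session.spikes)
        elif spikes_format == "tsv":
            for k in range(session.n_trials):
                np.savetxt(path / f"spikes_trial{k}.tsv", session.spikes[k],
                           fmt="%d", delimiter="\t")
        else:
            raise ValueError(f"unknown spikes_format {spikes_format!r}")

    if session.ground_truth is not None:
        frames = []
        for tr in session.ground_truth:
            sel = slice(None, None, ground_truth_step_ms)
            frames.append(pd.DataFrame({
                "trial_id": tr.trial_id,
                "t_ms": tr.t_ms[sel],
                "x_deg": tr.xy[sel, 0],
                "y_deg": tr.xy[sel, 1],
                "quadrant": tr.quadrant[sel],
                "phase_rad": tr.phase[sel],
            }))
        pd.concat(frames, ignore_index=True).to_csv(
            path / "ground_truth.tsv", sep="\t", index=False, float_format="%.5f"
        )
    return path


def load_session(path) -> Session:
    """Read back a session directory written by :func:`save_session`."""
    path = Path(path)
    meta = json.loads((path / "config.json").read_text())

    geometry = TaskGeometry(
        task_variant=meta["geometry"]["task_variant"],
        cued_pair=tuple(meta["geometry"]["cued_pair"]),
    )
    config = None
    if meta["config"] is not None:
        kwargs = dict(meta["config"])
        for key in ("exploration_matrix", "pre_matrix"):
            kwargs[key] = np.asarray(kwargs[key])
        for key, val in list(kwargs.items()):
            if isinstance(val, list):
                kwargs[key] = tuple(val)
        config = GeneratorConfig(**kwargs)

    events = pd.read_csv(path / "events.tsv", sep="\t")
    trials = []
    for _, row in events.iterrows():
        distractor_ms = None if pd.isna(row["distractor_ms"]) else int(row["distractor_ms"])
        timeline = TrialTimeline(
            fix_to_cue_ms=0,
            target_ms=int(row["target_ms"]),
            cue_off_ms=int(row["cue_off_ms"]),
            distractor_ms=distractor_ms,
            distractor_kind=row["distractor_kind"],
        )
        dxy = None
        if not pd.isna(row["distractor_x"]):
            dxy = (float(row["distractor_x"]), float(row["distractor_y"]))
        trials.append(Trial(
            trial_id=int(row["trial_id"]),
            cued_quadrant=int(row["cued_quadrant"]),
            timeline=timeline,
            outcome=row["outcome"] if isinstance(row["outcome"], str) else None,
            reaction_time_ms=None if pd.isna(row["rt_ms"]) else float(row["rt_ms"]),
            distractor_quadrant=None if dxy is None else _quadrant_of_xy(*dxy),
            distractor_xy=dxy,
        ))

    spikes = None
    if meta["spikes_format"] == "npz":
        spikes = np.load(path / "spikes.npz")["spikes"]
    elif meta["spikes_format"] == "tsv":
        spikes = np.stack([
            np.loadtxt(path / f"spikes_trial{k}.tsv", dtype=np.uint16,
                       delimiter="\t", ndmin=2)
            for k in range(len(trials))
        ])

    ground_truth = None
    gt_path = path / "ground_truth.tsv"
    if gt_path.exists():
        gt = pd.read_csv(gt_path, sep="\t")
        ground_truth = []
        for tid, grp in gt.groupby("trial_id", sort=True):
            ground_truth.append(Trajectory(
                trial_id=int(tid),
                t_ms=grp["t_ms"].to_numpy(),
                xy=grp[["x_deg", "y_deg"]].to_numpy(),
                quadrant=grp["quadrant"].to_numpy(),
                phase=grp["phase_rad"].to_numpy(),
            ))

    return Session(trials=trials, spikes=spikes, geometry=geometry,
                   config=config, ground_truth=ground_truth)


def _quadrant_of_xy(x, y):
    from .decoding import quadrant_of

    return int(quadrant_of(x, y))
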