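"""Kinematics and behavioral segmentation of larval trajectories.

Trajectories are reduced to tail speed, head speed, body length, heading
and the signed body-bend ("head") angle, then partitioned into runs
(sustained forward peristalsis), stops (tail speed near zero), head casts
(lateral head sweeps while stopped) and turn events (resumption of a run in
a new heading).  Runs are classified as up- or down-gradient by the sign of
the mean concentration change experienced during the run, which is the
quantity the chemotactic hazard model conditions on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .simulate import RUN, STOP, CAST

logger = logging.getLogger(__name__)

TURN_MARK = 3

__all__ = [
    "KinematicSeries",
    "SegmentationParams",
    "BehaviorAnnotation",
    "derive_kinematics",
    "segment_behavior",
    "classify_run_gradient",
    "turn_rate",
    "fraction_turns_toward_gradient",
    "distance_to_nearest_source",
]


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    pad_lo = np.full(w // 2, x[0]) if x.ndim == 1 else np.tile(x[0], (w // 2, 1))
    pad_hi = np.full(w - 1 - w // 2, x[-1]) if x.ndim == 1 else np.tile(x[-1], (w - 1 - w // 2, 1))
    if x.ndim == 1:
        return np.convolve(np.r_[pad_lo, x, pad_hi], kernel, mode="valid")
    return np.column_stack(
        [np.convolve(np.r_[pad_lo[:, j], x[:, j], pad_hi[:, j]], kernel, mode="valid")
         for j in range(x.shape[1])]
    )


@dataclass
class KinematicSeries:
    t: np.ndarray
    tail_speed: np.ndarray        # mm/s
    head_speed: np.ndarray        # mm/s
    body_length: np.ndarray       # mm
    heading: np.ndarray           # deg, direction tail -> centroid
    head_angle: np.ndarray        # deg, signed bend, in (-180, 180]
    head_angle_speed: np.ndarray  # deg/s, signed rate of the unwrapped bend angle
    frame_rate: float
    centroid: np.ndarray = None   # smoothed centroid (cm), for path lengths


@dataclass
class SegmentationParams:
    """Thresholds of the run/stop/cast/turn classifier.

    ``theta_stop = None`` selects the adaptive default, 0.3x the animal's
    median run tail speed (fallback 0.25 mm/s when no frames qualify).
    """

    theta_stop: float | None = None
    theta_run: float | None = None          # defaults to theta_stop
    min_stop: float = 0.5                   # s
    min_run: float = 1.0                    # s
    theta_angle: float = 20.0               # deg
    theta_cast: float = 20.0                # deg/s
    theta_turn: float = 30.0                # deg
    fallback_stop: float = 0.25             # mm/s
    heading_window: float = 0.5             # s, averaging window for net turn angle

    def resolve(self, tail_speed: np.ndarray) -> "SegmentationParams":
        p = SegmentationParams(**{**self.__dict__})
        if p.theta_stop is None:
            moving = tail_speed[tail_speed >= p.fallback_stop]
            p.theta_stop = 0.3 * float(np.median(moving)) if len(moving) else p.fallback_stop
        if p.theta_run is None:
            p.theta_run = p.theta_stop
        return p


@dataclass
class BehaviorAnnotation:
    t: np.ndarray
    states: np.ndarray            # int8 per frame: RUN/STOP/CAST/TURN_MARK
    runs: list                    # dicts: onset, offset, gradient_class
    events: list                  # dicts: stops and turns
    params: SegmentationParams
    frame_rate: float

    @property
    def turns(self) -> list:
        return [e for e in self.events if e["type"] == "turn"]

    @property
    def stops(self) -> list:
        return [e for e in self.events if e["type"] == "stop"]


def derive_kinematics(traj, smoothing_window: float = 0.3) -> KinematicSeries:
    """Kinematic series from a 3-point trajectory.

    Positions are smoothed with a moving average of ``smoothing_window``
    seconds before central differencing.  Body length uses the 3-point
    skeleton |head-centroid| + |centroid-tail| (mm).
    """
    n = len(traj)
    w = max(1, int(round(smoothing_window * traj.frame_rate)))
    if n <= w or n < 3:
        raise ValueError("trajectory shorter than the smoothing window")
    head = _smooth(traj.head, w)
    cen = _smooth(traj.centroid, w)
    tail = _smooth(traj.tail, w)

    def speed(p):  # cm -> mm/s
        return 10.0 * np.linalg.norm(
            np.gradient(p, 1.0 / traj.frame_rate, axis=0), axis=1
        )

    v1 = cen - tail
    v2 = head - cen
    heading = np.degrees(np.arctan2(v1[:, 1], v1[:, 0]))
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = (v1 * v2).sum(axis=1)
    head_angle = np.degrees(np.arctan2(cross, dot))
    head_angle = np.where(head_angle <= -180.0, head_angle + 360.0, head_angle)
    unwrapped = np.unwrap(np.radians(head_angle))
    ha_speed = np.degrees(np.gradient(unwrapped, 1.0 / traj.frame_rate))
    body_len = 10.0 * (np.linalg.norm(v2, axis=1) + np.linalg.norm(v1, axis=1))
    return KinematicSeries(
        t=traj.t,
        tail_speed=speed(tail),
        head_speed=speed(head),
        body_length=body_len,
        heading=heading,
        head_angle=head_angle,
        head_angle_speed=ha_speed,
        frame_rate=traj.frame_rate,
        centroid=cen,
    )


def _intervals(mask: np.ndarray):
    """(start, stop) index pairs of maximal True-intervals; stop exclusive."""
    m = np.asarray(mask, bool)
    if not m.any():
        return []
    d = np.diff(m.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(len(m))
    return list(zip(starts, stops))


def _circmean_deg(a: np.ndarray) -> float:
    r = np.radians(a)
    return math.degrees(math.atan2(np.sin(r).mean(), np.cos(r).mean()))


def segment_behavior(kin: KinematicSeries, params: SegmentationParams | None = None) -> BehaviorAnnotation:
    """Partition frames into RUN / STOP / CAST and emit turn events.

    A turn event is anchored at each non-RUN -> RUN transition whose net
    heading change (circular mean over ``heading_window`` on each side)
    reaches ``theta_turn``; its sign is the direction of the change.
    """
    p = (params or SegmentationParams()).resolve(kin.tail_speed)
    fr = kin.frame_rate
    n = len(kin.t)
    min_stop_f = max(1, int(round(p.min_stop * fr)))
    min_run_f = max(1, int(round(p.min_run * fr)))

    below = kin.tail_speed < p.theta_stop
    nonrun = np.zeros(n, bool)
    for a, b in _intervals(below):
        if b - a >= min_stop_f:
            nonrun[a:b] = True

    states = np.full(n, RUN, dtype=np.int8)
    for a, b in _intervals(nonrun):
        casting = (np.abs(kin.head_angle[a:b]) > p.theta_angle) | (
            np.abs(kin.head_angle_speed[a:b]) > p.theta_cast
        )
        states[a:b] = np.where(casting, CAST, STOP)

    # reportable runs must sustain min_run; shorter above-threshold fragments
    # keep RUN-state frames but are not counted as runs (merging them into
    # the stops would fuse adjacent stop intervals)
    runs = [
        {"onset": float(kin.t[a]), "offset": float(kin.t[b - 1] + 1.0 / fr),
         "i0": a, "i1": b, "gradient_class": "NONE"}
        for a, b in _intervals(~nonrun)
        if b - a >= min_run_f or (a == 0 and b == n)
    ]
    events: list = []
    wf = max(1, int(round(p.heading_window * fr)))
    for a, b in _intervals(nonrun):
        events.append({"type": "stop", "onset": float(kin.t[a]),
                       "offset": float(kin.t[b - 1] + 1.0 / fr)})
    # a turn is scored across the gap between consecutive sustained runs
    for prev, nxt in zip(runs, runs[1:]):
        a, b = prev["i1"], nxt["i0"]
        if not nonrun[a:b].any():
            continue  # no stop/cast in between: not a reorientation maneuver
        pre = _circmean_deg(kin.heading[max(0, a - wf):a])
        # skip half a window after resumption so the position-smoothing
        # transient does not dilute the post-turn heading
        skip = wf // 2
        b0 = b + skip if b + skip + 2 < n else b
        post = _circmean_deg(kin.heading[b0:min(n, b0 + wf)])
        delta = (post - pre + 180.0) % 360.0 - 180.0
        if abs(delta) >= p.theta_turn:
            states[b] = TURN_MARK
            events.append(
                {
                    "type": "turn",
                    "t": float(kin.t[b]),
                    "sign": int(math.copysign(1, delta)),
                    "net_change": float(delta),
                    "gradient_class": "NONE",
                    "toward_gradient": None,
                    "position": (float(kin.centroid[b, 0]), float(kin.centroid[b, 1])),
                    "post_heading": math.radians(post),
                }
            )
    events.sort(key=lambda e: e.get("onset", e.get("t", 0.0)))
    return BehaviorAnnotation(t=kin.t, states=states, runs=runs, events=events,
                              params=p, frame_rate=fr)


def classify_run_gradient(annotation: BehaviorAnnotation, dcdt: np.ndarray) -> BehaviorAnnotation:
    """Label each run UP/DOWN by the sign of its mean dC/dT (0 -> NONE);
    turn events inherit the class of the preceding run."""
    dcdt = np.asarray(dcdt, float)
    for run in annotation.runs:
        m = float(np.mean(dcdt[run["i0"]:run["i1"]]))
        run["gradient_class"] = "UP" if m > 0 else ("DOWN" if m < 0 else "NONE")
    for ev in annotation.turns:
        prev = [r for r in annotation.runs if r["offset"] <= ev["t"] + 1e-9]
        ev["gradient_class"] = prev[-1]["gradient_class"] if prev else "NONE"
    return annotation


def turn_rate(annotation: BehaviorAnnotation, kin: KinematicSeries) -> dict:
    """Turns per cm of run path and per minute, overall and per gradient class."""
    turns = annotation.turns
    step = np.linalg.norm(np.diff(kin.centroid, axis=0), axis=1)
    run_mask = (annotation.states == RUN) | (annotation.states == TURN_MARK)
    path_cm = float(step[run_mask[1:] & run_mask[:-1]].sum())
    total_min = (kin.t[-1] - kin.t[0] + 1.0 / kin.frame_rate) / 60.0
    out = {
        "n_turns": len(turns),
        "turns_per_cm": len(turns) / path_cm if path_cm > 0 else float("nan"),
        "turns_per_min": len(turns) / total_min,
        "run_path_cm": path_cm,
        "by_gradient_class": {},
    }
    if path_cm == 0:
        logger.warning("zero run path length; turns_per_cm undefined")
    fr = kin.frame_rate
    for cls in ("UP", "DOWN", "NONE"):
        cls_runs = [r for r in annotation.runs if r["gradient_class"] == cls]
        minutes = sum(r["offset"] - r["onset"] for r in cls_runs) / 60.0
        cm = 0.0
        for r in cls_runs:
            cm += float(step[r["i0"]:max(r["i0"], r["i1"] - 1)].sum())
        k = sum(1 for e in turns if e["gradient_class"] == cls)
        out["by_gradient_class"][cls] = {
            "n_turns": k,
            "time_min": minutes,
            "path_cm": cm,
            "turns_per_min": k / minutes if minutes > 0 else float("nan"),
            "turns_per_cm": k / cm if cm > 0 else float("nan"),
        }
    return out


def estimate_turn_hazards(annotation: BehaviorAnnotation, dcdt: np.ndarray,
                          end_window: float = 0.05) -> dict:
    """Turn hazards (events per minute of time at risk) conditioned on the
    instantaneous gradient class.

    Time at risk in each class is the run time spent with dC/dT > 0 (UP) or
    < 0 (DOWN); a run termination is assigned to the class experienced over
    the last ``end_window`` seconds of the run.  Conditioning per frame
    rather than per run label avoids the survivorship bias of whole-run
    labels: long runs typically end just after the larva has rotated into
    the down-gradient regime.
    """
    dcdt = np.asarray(dcdt, float)
    fr = annotation.frame_rate
    up_frames = down_frames = 0
    k_up = k_down = 0
    wf = max(1, int(round(end_window * fr)))
    last_idx = len(annotation.t) - 1
    for run in annotation.runs:
        seg = dcdt[run["i0"]:run["i1"]]
        up_frames += int((seg > 0).sum())
        down_frames += int((seg < 0).sum())
        if run["i1"] <= last_idx:  # run terminated within the recording
            tail_mean = float(np.mean(dcdt[max(run["i0"], run["i1"] - wf):run["i1"]]))
            if tail_mean > 0:
                k_up += 1
            elif tail_mean < 0:
                k_down += 1
    up_min = up_frames / fr / 60.0
    down_min = down_frames / fr / 60.0
    lam_up = k_up / up_min if up_min > 0 else float("nan")
    lam_down = k_down / down_min if down_min > 0 else float("nan")
    return {
        "lambda_up": lam_up,
        "lambda_down": lam_down,
        "ratio_down_up": lam_down / lam_up if lam_up and np.isfinite(lam_up) else float("nan"),
        "events_up": k_up,
        "events_down": k_down,
        "time_up_min": up_min,
        "time_down_min": down_min,
    }


def fraction_turns_toward_gradient(
    annotation: BehaviorAnnotation,
    landscape,
    t_eval: float,
    plane_height: float = 0.0,
) -> dict:
    """Fraction of turns whose post-turn heading points up the local gradient.

    A turn counts as "toward" when the post-turn heading unit vector has a
    positive dot product with the spatial gradient at the turn location;
    exact zeros are excluded.
    """
    k = n = 0
    for ev in annotation.turns:
        x, y = ev["position"]
        g = landscape.spatial_gradient((x, y, plane_height), t_eval)
        d = g[0] * math.cos(ev["post_heading"]) + g[1] * math.sin(ev["post_heading"])
        if d == 0:
            continue
        n += 1
        k += int(d > 0)
    if n == 0:
        logger.warning("no turns available; fraction toward gradient undefined")
        return {"k": 0, "n": 0, "proportion": float("nan")}
    return {"k": k, "n": n, "proportion": k / n}


def distance_to_nearest_source(
    trajectories,
    sources,
    snapshot_time: float = 150.0,
    snapshot_window: float = 1.0,
    use_3d: bool = False,
    plane_height: float = 0.0,
) -> dict:
    """Distance from each centroid to its nearest odor source.

    Returns per-larva series, the cohort mean +/- SEM time course (over
    larvae still tracked at each time point) and the per-larva snapshot
    (mean within ``snapshot_time +/- snapshot_window/2``), all in cm.
    """
    if not len(sources):
        raise ValueError("at least one source required")
    pos = np.array(
        [getattr(s, "position", s) for s in sources], dtype=float
    )
    if pos.shape[1] == 2:
        pos = np.column_stack([pos, np.zeros(len(pos))])
    series = []
    snapshots = []
    for traj in trajectories:
        c = traj.centroid
        d2 = (c[:, 0, None] - pos[None, :, 0]) ** 2 + (c[:, 1, None] - pos[None, :, 1]) ** 2
        if use_3d:
            d2 = d2 + (plane_height - pos[None, :, 2]) ** 2
        d = np.sqrt(d2).min(axis=1)
        series.append(d)
        m = np.abs(traj.t - snapshot_time) <= snapshot_window / 2.0
        snapshots.append(float(d[m].mean()) if m.any() else float("nan"))
    nmax = max(len(s) for s in series)
    mat = np.full((len(series), nmax), np.nan)
    for i, s in enumerate(series):
        mat[i, : len(s)] = s
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        count = np.sum(~np.isnan(mat), axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
        sem = np.where(count > 1, sd / np.sqrt(count), 0.0)
    return {
        "per_larva": series,
        "mean": mean,
        "sem": sem,
        "snapshot": np.asarray(snapshots),
        "snapshot_time": snapshot_time,
    }
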