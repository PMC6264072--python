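"""Flash-triggered analysis of optogenetic stimulation trials.

Kinematic series are aligned on flash onsets into trial matrices; from
those the module computes triggered averages with SEM, per-trial stop
detection (latency and duration), the stop probability with an exact
Clopper-Pearson interval, the fraction of flash time spent casting or
turning, the relation between pre-flash tail speed and stop probability,
and per-trial extrema (e.g. minimum tail speed or maximum body length
reached during the flash).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import RUN
from .segmentation import TURN_MARK, CAST
from .stats import clopper_pearson

logger = logging.getLogger(__name__)

__all__ = [
    "FlashSchedule",
    "TrialAlignedSet",
    "align_to_flashes",
    "triggered_average",
    "detect_flash_stops",
    "stop_probability",
    "casting_fraction",
    "stopprob_vs_prespeed",
    "per_trial_extrema",
]


@dataclass
class FlashSchedule:
    """Stimulation windows: strictly increasing onsets (s), durations (s),
    intensity (W/m^2, metadata only)."""

    onsets: np.ndarray
    durations: np.ndarray = None
    intensity: float = 18.0

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.durations is None:
            self.durations = np.full(len(self.onsets), 6.0)
        elif np.isscalar(self.durations):
            self.durations = np.full(len(self.onsets), float(self.durations))
        else:
            self.durations = np.asarray(self.durations, dtype=float)
        if len(self.durations) != len(self.onsets):
            raise ValueError("need one duration per onset")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("flash onsets must be strictly increasing")
        if np.any(self.onsets[1:] < self.onsets[:-1] + self.durations[:-1]):
            raise ValueError("flashes must not overlap")

    def __len__(self):
        return len(self.onsets)

    @classmethod
    def periodic(cls, n: int = 8, duration: float = 6.0, gap: float = 30.0,
                 first_onset: float = 30.0, intensity: float = 18.0):
        """The standard protocol: n flashes of ``duration`` s separated by
        ``gap`` s of no stimulation."""
        onsets = first_onset + np.arange(n) * (duration + gap)
        return cls(onsets=onsets, durations=np.full(n, duration), intensity=intensity)


@dataclass
class TrialAlignedSet:
    """trials x time matrix aligned at flash onset (t = 0)."""

    time: np.ndarray              # (T,) s relative to onset
    values: np.ndarray            # (n_trials, T)
    meta: pd.DataFrame            # per-trial metadata
    window: tuple                 # (pre, post) s

    @property
    def onset_index(self) -> int:
        return int(np.argmin(np.abs(self.time)))

    def __len__(self):
        return len(self.values)


def align_to_flashes(
    t: np.ndarray,
    series: np.ndarray,
    schedule: FlashSchedule,
    window: tuple = (5.0, 10.0),
    meta: dict | None = None,
    pre_speed_series: np.ndarray | None = None,
    gradient_class_fn=None,
) -> TrialAlignedSet:
    """Cut one series into flash-aligned trials.

    Trials whose window does not fit in the recording are dropped (with a
    logged count).  Per-trial metadata includes the pre-flash tail speed
    (mean of ``pre_speed_series`` over [-2, 0] s; defaults to the aligned
    series itself) and, optionally, the gradient class of the run
    containing the flash onset via ``gradient_class_fn(onset)``.
    """
    t = np.asarray(t, float)
    series = np.asarray(series, float)
    fr = 1.0 / np.median(np.diff(t))
    pre, post = window
    npre, npost = int(round(pre * fr)), int(round(post * fr))
    speeds = series if pre_speed_series is None else np.asarray(pre_speed_series, float)
    rows, meta_rows = [], []
    dropped = 0
    for k, (onset, dur) in enumerate(zip(schedule.onsets, schedule.durations)):
        i0 = int(round((onset - t[0]) * fr))
        if i0 - npre < 0 or i0 + npost >= len(series):
            dropped += 1
            continue
        rows.append(series[i0 - npre : i0 + npost + 1])
        pre_sl = slice(max(0, i0 - int(round(2 * fr))), i0)
        meta_rows.append(
            {
                "trial": k,
                "flash_onset": float(onset),
                "flash_duration": float(dur),
                "pre_speed": float(speeds[pre_sl].mean()),
                "gradient_class": gradient_class_fn(onset) if gradient_class_fn else "NONE",
                **(meta or {}),
            }
        )
    if dropped:
        logger.info("dropped %d partial trials", dropped)
    if not rows:
        logger.warning("no complete trials within the recording")
        values = np.empty((0, npre + npost + 1))
    else:
        values = np.vstack(rows)
    time = (np.arange(npre + npost + 1) - npre) / fr
    return TrialAlignedSet(time=time, values=values,
                           meta=pd.DataFrame(meta_rows), window=(pre, post))


def concat_aligned(sets) -> TrialAlignedSet:
    """Pool trial sets from several larvae (identical windows required)."""
    sets = [s for s in sets if len(s)]
    if not sets:
        raise ValueError("no non-empty trial sets to pool")
    ref = sets[0]
    for s in sets[1:]:
        if s.values.shape[1] != ref.values.shape[1]:
            raise ValueError("trial sets have different windows")
    return TrialAlignedSet(
        time=ref.time,
        values=np.vstack([s.values for s in sets]),
        meta=pd.concat([s.meta for s in sets], ignore_index=True),
        window=ref.window,
    )


def triggered_average(aligned: TrialAlignedSet, by: str | None = None) -> dict:
    """Pointwise mean and SEM (sd/sqrt(n)), optionally split by a metadata
    column (e.g. pre-flash gradient class)."""
    if len(aligned) == 0:
        raise ValueError("no trials to average")

    def _avg(mat):
        mean = mat.mean(axis=0)
        if len(mat) == 1:
            logger.warning("single trial: SEM reported as 0")
            sem = np.zeros_like(mean)
        else:
            sem = mat.std(axis=0, ddof=1) / np.sqrt(len(mat))
        return {"mean": mean, "sem": sem, "n": len(mat)}

    if by is None:
        return {"all": _avg(aligned.values)}
    out = {}
    for value, idx in aligned.meta.groupby(by).groups.items():
        out[value] = _avg(aligned.values[np.asarray(idx)])
    return out


def detect_flash_stops(
    annotation,
    schedule: FlashSchedule,
    min_stop: float | None = None,
    max_latency: float | None = None,
) -> pd.DataFrame:
    """Per-trial stop detection from a behavior annotation.

    A trial counts as stopped when a non-RUN interval (per the segmentation
    rules) *begins* within the flash window; latency is that interval's
    start minus the flash onset and duration the full interval length
    (stops may outlast the flash).  Stops already in progress at flash
    onset do not count as flash-evoked.  ``max_latency`` optionally narrows
    the scoring window to [onset, onset + max_latency] — useful to isolate
    command-like evoked stops from spontaneous pausing later in the flash.
    """
    t = annotation.t
    dt = 1.0 / annotation.frame_rate
    nonrun = (annotation.states != RUN) & (annotation.states != TURN_MARK)
    d = np.diff(nonrun.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if nonrun[0]:
        starts = np.r_[0, starts]
    if nonrun[-1]:
        ends = np.r_[ends, len(nonrun)]
    min_stop = annotation.params.min_stop if min_stop is None else min_stop
    rows = []
    for k, (onset, dur) in enumerate(zip(schedule.onsets, schedule.durations)):
        if onset + dur > t[-1] + dt:
            logger.info("trial %d truncated before flash end; excluded", k)
            continue
        i_on = min(len(t) - 1, max(0, int(round((onset - t[0]) / dt))))
        # require a clean half-second of running before the onset: boundary
        # jitter otherwise misclassifies stops that began just before it
        i_pre = max(0, i_on - int(round(0.5 / dt)))
        row = {"trial": k, "flash_onset": float(onset), "stopped": False,
               "latency": np.nan, "duration": np.nan,
               "running_at_onset": bool(not nonrun[i_pre:i_on + 1].any())}
        lat_limit = dur if max_latency is None else min(dur, max_latency)
        for s, e in zip(starts, ends):
            length = (e - s) * dt
            if onset <= t[s] < onset + lat_limit and length >= min_stop:
                row.update(stopped=True, latency=float(t[s] - onset), duration=float(length))
                break
        rows.append(row)
    return pd.DataFrame(rows)


def stop_probability(stopped, level: float = 0.95) -> dict:
    """Proportion of stopped trials with its exact binomial interval."""
    stopped = np.asarray(stopped, bool)
    ci = clopper_pearson(int(stopped.sum()), len(stopped), level)
    return {"k": ci.k, "n": ci.n, "proportion": ci.k / ci.n,
            "lower": ci.lower, "upper": ci.upper, "level": level}


def casting_fraction(annotation, schedule: FlashSchedule) -> pd.DataFrame:
    """Per-trial fraction of flash time spent in head-cast/turn mode."""
    t = annotation.t
    casting = (annotation.states == CAST) | (annotation.states == TURN_MARK)
    rows = []
    for k, (onset, dur) in enumerate(zip(schedule.onsets, schedule.durations)):
        m = (t >= onset) & (t < onset + dur)
        if not m.any():
            continue
        rows.append({"trial": k, "flash_onset": float(onset),
                     "fraction": float(casting[m].mean())})
    return pd.DataFrame(rows)


def stopprob_vs_prespeed(trials: pd.DataFrame, n_bins: int = 6) -> dict:
    """Stop probability across equal-count bins of pre-flash tail speed,
    with an ordinary least-squares line, R^2 and the two-sided slope test."""
    df = trials.dropna(subset=["pre_speed"])
    if df["pre_speed"].nunique() < 2:
        logger.warning("degenerate pre-flash speeds; regression undefined")
        return {"bins": None, "slope": np.nan, "r2": np.nan, "p": np.nan,
                "degenerate": True}
    df = df.sort_values("pre_speed")
    chunks = np.array_split(np.arange(len(df)), n_bins)
    xs, ys = [], []
    for c in chunks:
        if len(c) == 0:
            continue
        sub = df.iloc[c]
        xs.append(float(sub["pre_speed"].mean()))
        ys.append(float(sub["stopped"].mean()))
    res = sps.linregress(xs, ys)
    return {
        "bins": pd.DataFrame({"pre_speed": xs, "stop_probability": ys}),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "degenerate": False,
    }


def per_trial_extrema(
    aligned: TrialAlignedSet,
    kind: str = "min",
    phase_labels=None,
) -> pd.DataFrame:
    """Extremum of the aligned quantity within each trial's flash window.

    ``kind='min'`` for tail-speed minima, ``'max'`` for body-length maxima.
    Optional per-trial phase labels (e.g. wave phase bin at flash onset)
    are attached for grouping.
    """
    if kind not in ("min", "max"):
        raise ValueError("kind must be 'min' or 'max'")
    rows = []
    for i in range(len(aligned)):
        dur = float(aligned.meta["flash_duration"].iloc[i])
        m = (aligned.time >= 0) & (aligned.time <= dur)
        seg = aligned.values[i, m]
        rows.append(
            {
                "trial": int(aligned.meta["trial"].iloc[i]),
                "value": float(seg.min() if kind == "min" else seg.max()),
                "phase": phase_labels[i] if phase_labels is not None else None,
            }
        )
    return pd.DataFrame(rows)
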