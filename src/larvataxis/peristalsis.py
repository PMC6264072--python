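"""Peristaltic wave-cycle, phase and segmental-wave analysis.

A forward peristaltic cycle is the window between a peak in tail speed (the
"visceral-piston" moment at which the posterior segments contract) and the
next peak in body length; a full cycle spans 360 degrees of phase.  Phase is
coarsely binned into an initial phase (posterior segments A7-A8, 0-90 deg),
a hinge phase (middle segments A4-A5, 135-225 deg) and a late phase
(anterior segments A1-A2, 270-360 deg).

Segmental activity (denticle-band displacement or per-segment dF/F) is
reduced to per-segment onset times; onsets advancing from posterior to
anterior within plausible inter-segment latencies constitute a wave.  The
response of an ongoing wave to an optogenetic stop command is classified
into six categories (see :class:`FlashOutcome`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "WaveCycle",
    "PhaseState",
    "SegmentTraceSet",
    "WaveEvent",
    "FlashOutcome",
    "OUTCOME_CATEGORIES",
    "detect_wave_cycles",
    "phase_at",
    "detect_segmental_waves",
    "classify_flash_outcome",
    "count_waves",
]

OUTCOME_CATEGORIES = (
    "COMPLETED_THEN_BLOCKED",
    "IMMEDIATE_TERMINATION",
    "TERMINATED_AT_HINGE",
    "NEW_WAVE_FROM_A4",
    "PULL_PUSH",
    "FAILURE_TO_STOP",
)

HINGE_SEGMENT = "A4"


@dataclass(frozen=True)
class WaveCycle:
    start: float  # s, tail-speed peak
    end: float    # s, next body-length peak

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError("cycle end must follow its start")


@dataclass(frozen=True)
class PhaseState:
    phase: float  # deg in [0, 360), NaN when outside any cycle
    bin: str      # INITIAL | HINGE | LATE | UNBINNED | OUTSIDE


def _phase_bin(phase: float) -> str:
    if 0.0 <= phase <= 90.0:
        return "INITIAL"
    if 135.0 <= phase <= 225.0:
        return "HINGE"
    if 270.0 <= phase < 360.0:
        return "LATE"
    return "UNBINNED"


@dataclass
class SegmentTraceSet:
    """Per-segment time series, ordered posterior to anterior.

    ``labels`` are segment names (``A8`` .. ``A1``; bilateral traces carry
    ``_L``/``_R`` suffixes and are merged by mean before onset detection).
    ``data`` is (n_segments, n_frames).
    """

    labels: list
    data: np.ndarray
    frame_rate: float
    modality: str = "contraction"  # contraction | fictive

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.labels):
            raise ValueError("one row per segment label required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("segment labels must be unique")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) / self.frame_rate

    def merged_bilateral(self) -> "SegmentTraceSet":
        """Average _L/_R pairs into one trace per segment."""
        base = []
        for lab in self.labels:
            root = lab.rsplit("_", 1)[0] if lab.endswith(("_L", "_R")) else lab
            if root not in base:
                base.append(root)
        if base == list(self.labels):
            return self
        rows = []
        for root in base:
            idx = [i for i, lab in enumerate(self.labels)
                   if lab == root or lab in (f"{root}_L", f"{root}_R")]
            rows.append(self.data[idx].mean(axis=0))
        return SegmentTraceSet(base, np.array(rows), self.frame_rate, self.modality)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data.T, columns=self.labels)
        df.insert(0, "t", self.t)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_rate: float | None = None, modality="contraction"):
        t = df["t"].to_numpy(float)
        fr = frame_rate or 1.0 / float(np.median(np.diff(t)))
        labels = [c for c in df.columns if c != "t"]
        return cls(labels, df[labels].to_numpy(float).T, fr, modality)


@dataclass
class WaveEvent:
    """One propagating wave: segment label -> onset time (s)."""

    onsets: dict
    start_segment: str
    end_segment: str
    complete: bool
    direction: str = "forward"

    @property
    def first_onset(self) -> float:
        return min(self.onsets.values())

    @property
    def last_onset(self) -> float:
        return max(self.onsets.values())


@dataclass
class FlashOutcome:
    category: str
    front_segment_at_onset: str | None
    flash_id: int = 0
    ambiguous: bool = False

    def __post_init__(self):
        if self.category not in OUTCOME_CATEGORIES:
            raise ValueError(f"unknown outcome category {self.category!r}")


# ----------------------------------------------------------------------
# wave cycles and phase
# ----------------------------------------------------------------------

def _estimate_period(x: np.ndarray, frame_rate: float) -> float:
    """Dominant period (s) from the autocorrelation's first off-zero peak."""
    x = np.asarray(x, float)
    x = x - np.nanmean(x)
    x = np.nan_to_num(x)
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
    if len(ac) < 4 or ac[0] <= 0:
        return 1.0
    peaks, _ = find_peaks(ac[1:])
    if len(peaks) == 0:
        return 1.0
    return (peaks[0] + 1) / frame_rate


def detect_wave_cycles(
    t: np.ndarray,
    tail_speed: np.ndarray,
    body_length: np.ndarray,
    run_mask: np.ndarray | None = None,
    prominence_frac: float = 0.2,
    min_distance_frac: float = 0.5,
) -> list:
    """Detect forward wave cycles (tail-speed peak -> next body-length peak).

    Non-run frames can be masked out; peaks falling in masked frames are
    dropped.  Peak prominence defaults to 20% of the series interquartile
    range, minimum peak distance to half the autocorrelation-estimated
    cycle period.
    """
    t = np.asarray(t, float)
    ts = np.asarray(tail_speed, float)
    bl = np.asarray(body_length, float)
    if run_mask is not None:
        run_mask = np.asarray(run_mask, bool)
        ts = np.where(run_mask, ts, np.nan)
        bl = np.where(run_mask, bl, np.nan)
    fr = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
    period = _estimate_period(np.nan_to_num(ts), fr)
    dist = max(1, int(round(min_distance_frac * period * fr)))

    def _peaks(x):
        q75, q25 = np.nanpercentile(x, [75, 25])
        prom = prominence_frac * (q75 - q25)
        if not prom > 0:
            return np.empty(0, int)
        idx, _ = find_peaks(np.nan_to_num(x, nan=-np.inf), prominence=prom, distance=dist)
        return idx[~np.isnan(x[idx])]

    ts_peaks = t[_peaks(ts)]
    bl_peaks = t[_peaks(bl)]
    cycles = []
    for i, start in enumerate(ts_peaks):
        nxt = ts_peaks[i + 1] if i + 1 < len(ts_peaks) else np.inf
        cand = bl_peaks[(bl_peaks > start) & (bl_peaks <= nxt)]
        if len(cand):
            cycles.append(WaveCycle(start=float(start), end=float(cand[0])))
    return cycles


def phase_at(t: float, cycles) -> PhaseState:
    """Phase (0-360 deg) of time ``t`` within its wave cycle."""
    for c in cycles:
        if c.start <= t < c.end:
            phase = 360.0 * (t - c.start) / (c.end - c.start)
            return PhaseState(phase=phase, bin=_phase_bin(phase))
        if t == c.end:
            # closing boundary maps to the end of the late phase
            return PhaseState(phase=360.0 - 1e-9, bin="LATE")
    return PhaseState(phase=float("nan"), bin="OUTSIDE")


# ----------------------------------------------------------------------
# segmental waves
# ----------------------------------------------------------------------

def _segment_onsets(
    x: np.ndarray,
    t: np.ndarray,
    threshold_frac: float = 0.5,
    min_prominence: float | None = None,
    smooth_window: int = 0,
) -> np.ndarray:
    """Onset times where the trace rises through ``threshold_frac`` of each
    event-local peak."""
    # robust per-frame noise, estimated before smoothing
    sigma = 1.4826 * np.median(np.abs(np.diff(x))) / math.sqrt(2.0)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        x = np.convolve(x, kernel, mode="same")
        sigma = sigma / math.sqrt(smooth_window)
    if min_prominence is not None:
        prom = min_prominence
    else:
        # the larger of: a fraction of the typical event amplitude (events
        # are sparse, so the 99th percentile of |x - median| tracks the
        # pulse height) and 5x the smoothed noise floor
        scale = np.percentile(np.abs(x - np.median(x)), 99)
        prom = max(0.35 * scale, 5.0 * sigma, 1e-12)
    fr = 1.0 / (t[1] - t[0]) if len(t) > 1 else 1.0
    peaks, props = find_peaks(x, prominence=prom, distance=max(1, int(round(0.25 * fr))))
    onsets = []
    for p in peaks:
        thr = threshold_frac * x[p]
        j = p
        while j > 0 and x[j - 1] >= thr:
            j -= 1
        if j == 0:
            onsets.append(t[0])
        else:
            x0, x1 = x[j - 1], x[j]
            frac = (thr - x0) / (x1 - x0) if x1 != x0 else 0.0
            onsets.append(float(t[j - 1] + frac * (t[j] - t[j - 1])))
    return np.asarray(sorted(set(onsets)))


def detect_segmental_waves(
    traces: SegmentTraceSet,
    threshold_frac: float = 0.5,
    min_prominence: float | None = None,
    lat_min: float | None = None,
    lat_max: float | None = None,
    smooth_window_s: float = 0.25,
) -> list:
    """Detect propagating posterior-to-anterior waves from segment traces.

    Per-segment onsets (threshold crossing at ``threshold_frac`` of the
    event-local peak) are chained into a wave when consecutive-segment
    latencies fall within ``[lat_min, lat_max]`` (defaults 0.02-2 s for
    contraction traces, 0.1-10 s for fictive traces).  Bilateral traces are
    merged by mean.  Returns :class:`WaveEvent` list sorted by first onset;
    single-segment chains are kept (they matter for pull-push detection).
    """
    if len(traces.labels) < 3 and not any(l.endswith(("_L", "_R")) for l in traces.labels):
        raise ValueError("need at least 3 segments")
    traces = traces.merged_bilateral()
    if lat_min is None:
        lat_min = 0.02 if traces.modality == "contraction" else 0.1
    if lat_max is None:
        lat_max = 2.0 if traces.modality == "contraction" else 10.0
    t = traces.t
    win = int(round(smooth_window_s * traces.frame_rate))
    labels = list(traces.labels)
    anterior_label = labels[-1]
    onset_lists = [
        _segment_onsets(traces.data[i], t, threshold_frac, min_prominence, win)
        for i in range(len(labels))
    ]
    # chain onsets: an onset at segment k extends a chain ending at k-1
    all_onsets = sorted(
        (float(o), k) for k, ons in enumerate(onset_lists) for o in ons
    )
    chains: list[list] = []
    open_chains: list[dict] = []
    for o, k in all_onsets:
        extended = False
        for ch in open_chains:
            if ch["seg"] == k - 1 and lat_min <= o - ch["t"] <= lat_max:
                ch["items"].append((k, o))
                ch["seg"] = k
                ch["t"] = o
                extended = True
                break
        if not extended:
            ch = {"seg": k, "t": o, "items": [(k, o)]}
            open_chains.append(ch)
            chains.append(ch["items"])
        # retire chains that can no longer be extended
        open_chains = [c for c in open_chains if o - c["t"] <= lat_max]
    waves = []
    for items in chains:
        onsets = {labels[k]: o for k, o in items}
        waves.append(
            WaveEvent(
                onsets=onsets,
                start_segment=labels[items[0][0]],
                end_segment=labels[items[-1][0]],
                complete=labels[items[-1][0]] == anterior_label,
            )
        )
    waves.sort(key=lambda w: w.first_onset)
    return waves


def _seg_number(label: str) -> int:
    return int("".join(ch for ch in label if ch.isdigit()))


def classify_flash_outcome(
    waves,
    flash_onset: float,
    flash_duration: float,
    hinge: str = HINGE_SEGMENT,
    hinge_tolerance: int = 0,
    flash_id: int = 0,
) -> FlashOutcome:
    """Classify the effect of a stop command on wave propagation.

    Precedence: FAILURE_TO_STOP > NEW_WAVE_FROM_A4 > PULL_PUSH >
    completion/termination of the ongoing wave.  "Posterior to the hinge"
    means a segment number greater than the hinge segment's (A5-A8 for
    hinge A4).
    """
    T, dur = flash_onset, flash_duration
    hinge_n = _seg_number(hinge)

    ongoing = [w for w in waves if w.first_onset < T and w.last_onset >= T - 2.0]
    if len(ongoing) > 1:
        logger.warning("flash %d: %d overlapping ongoing waves; using the most recent",
                       flash_id, len(ongoing))
    ongoing_wave = max(ongoing, key=lambda w: w.first_onset) if ongoing else None
    front = None
    if ongoing_wave is not None:
        pre = [(s, o) for s, o in ongoing_wave.onsets.items() if o < T]
        if pre:
            front = min(pre, key=lambda so: _seg_number(so[0]))[0]  # most anterior
        else:
            ongoing_wave, front = None, None

    new_waves = [w for w in waves if T <= w.first_onset < T + dur]
    # isolated single-segment onsets are treated as noise, not as waves,
    # when deciding between categories
    propagating = [w for w in new_waves if len(w.onsets) >= 2]
    ambiguous = len(ongoing) > 1

    # 1) a full, posterior-initiated wave starts during the flash
    for w in propagating:
        if _seg_number(w.start_segment) > hinge_n and w.complete:
            return FlashOutcome("FAILURE_TO_STOP", front, flash_id, ambiguous)
    # 2) a wave initiating at the hinge segment
    for w in propagating:
        if w.start_segment == hinge:
            return FlashOutcome("NEW_WAVE_FROM_A4", front, flash_id, ambiguous)
    # 3) repeated activity confined posterior to the hinge
    post_onsets = [
        o
        for w in propagating
        for s, o in w.onsets.items()
        if _seg_number(s) > hinge_n
    ]
    ant_onsets = [
        o
        for w in propagating
        for s, o in w.onsets.items()
        if _seg_number(s) <= hinge_n
    ]
    if len(post_onsets) >= 2 and not ant_onsets:
        return FlashOutcome("PULL_PUSH", front, flash_id, ambiguous)
    # 4) fate of the ongoing wave
    if ongoing_wave is not None:
        during = [(s, o) for s, o in ongoing_wave.onsets.items() if o >= T]
        if not during:
            return FlashOutcome("IMMEDIATE_TERMINATION", front, flash_id, ambiguous)
        last = ongoing_wave.end_segment
        if ongoing_wave.complete and not propagating:
            return FlashOutcome("COMPLETED_THEN_BLOCKED", front, flash_id, ambiguous)
        if abs(_seg_number(last) - hinge_n) <= hinge_tolerance:
            return FlashOutcome("TERMINATED_AT_HINGE", front, flash_id, ambiguous)
        return FlashOutcome("IMMEDIATE_TERMINATION", front, flash_id, ambiguous)
    # no ongoing wave, no new activity: locomotion was already suppressed
    return FlashOutcome("IMMEDIATE_TERMINATION", front, flash_id, ambiguous)


def count_waves(waves, flash_onset: float, window: float = 20.0) -> dict:
    """Complete waves in the 20-s windows before and through a flash.

    A complete wave is counted in the window containing its *first* onset.
    """
    n_before = sum(
        1 for w in waves if w.complete and flash_onset - window <= w.first_onset < flash_onset
    )
    n_during = sum(
        1 for w in waves if w.complete and flash_onset <= w.first_onset < flash_onset + window
    )
    return {"n_before": n_before, "n_during": n_during}
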