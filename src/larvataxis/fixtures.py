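"""Synthetic segmental-contraction, fictive-locomotion and ROI-fluorescence
traces with machine-readable ground truth.

``generate_segment_traces`` builds per-segment displacement (or dF/F)
pulses whose onsets advance from the most posterior segment to A1.  Stop
commands are modeled by three rule sets:

* ``none`` — undisturbed periodic waves;
* ``pdm`` — hinge truncation: a wave whose front is posterior to A4 at
  flash onset terminates at A4 (a configurable fraction terminates
  immediately), a wave already anterior of A4 completes, and no new waves
  initiate during the flash;
* ``sezdn1`` — additionally produces immediate posterior termination,
  waves initiating at A4, pull-push (repeated posterior-confined pulses)
  and outright failures to stop.

An explicit ``outcome_plan`` (one category per flash) overrides the rule
so classifier tests can cover every category deterministically.
"""

from __future__ import annotations

import numpy as np

from .peristalsis import OUTCOME_CATEGORIES, SegmentTraceSet
from .fluorescence import RoiSeries

__all__ = ["generate_segment_traces", "generate_roi_traces"]


def _add_pulse(row: np.ndarray, t: np.ndarray, onset: float, width: float, amp: float):
    """Raised-cosine pulse whose 50%-rise crossing is exactly at ``onset``."""
    lo, hi = onset - width / 4.0, onset + 3.0 * width / 4.0
    m = (t >= lo) & (t <= hi)
    row[m] += amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[m] - lo) / width))


def _wave_onsets(start: float, idx_from: int, idx_to: int, speed: float) -> dict:
    return {k: start + (k - idx_from) / speed for k in range(idx_from, idx_to + 1)}


def generate_segment_traces(
    n_segments: int = 8,
    duration: float | None = None,
    frame_rate: float = 20.0,
    wave_period: float = 4.0,
    wave_speed: float = 4.0,
    flashes=None,
    rule: str = "none",
    noise_sd: float = 0.0,
    amplitude: float = 1.0,
    pulse_width: float = 0.5,
    seed: int = 0,
    labels: list | None = None,
    modality: str = "contraction",
    outcome_plan: list | None = None,
    immediate_fraction: float = 0.3,
):
    """Build a :class:`SegmentTraceSet` plus ground truth.

    Returns ``(traces, truth)`` where ``truth`` holds the generated waves
    (segment -> onset, end segment, completeness) and, per flash, the
    categorical outcome and the wave-front segment at flash onset.
    """
    if not wave_speed > 0:
        raise ValueError("wave_speed must be positive")
    if rule not in ("none", "pdm", "sezdn1"):
        raise ValueError(f"unknown rule {rule!r}")
    rng = np.random.default_rng(seed)
    if labels is None:
        if modality == "fictive" and n_segments == 8:
            n_segments = 7
        labels = [f"A{n_segments - i}" for i in range(n_segments)]  # A8..A1 posterior->anterior
    n = len(labels)
    idx_hinge = labels.index("A4") if "A4" in labels else n - 4
    span = (n - 1) / wave_speed

    f_onsets = list(np.asarray(flashes.onsets, float)) if flashes is not None else []
    f_durs = list(np.asarray(flashes.durations, float)) if flashes is not None else []
    if duration is None:
        duration = (max(o + d for o, d in zip(f_onsets, f_durs)) + 2 * wave_period + span
                    if f_onsets else 5 * wave_period + span + 2.0)
    for o, d in zip(f_onsets, f_durs):
        if o < 0 or o + d > duration:
            raise ValueError("flash outside trace duration")

    categories = None
    if outcome_plan is not None:
        if len(outcome_plan) != len(f_onsets):
            raise ValueError("outcome_plan needs one category per flash")
        for c in outcome_plan:
            if c not in OUTCOME_CATEGORIES:
                raise ValueError(f"unknown outcome category {c!r}")
        categories = list(outcome_plan)
    elif rule == "sezdn1" and f_onsets:
        categories = list(rng.choice(OUTCOME_CATEGORIES, size=len(f_onsets)))

    waves: list[dict] = []      # each: {"onsets": {idx: t}, ...}
    outcomes: list[dict] = []

    def record(onsets_by_idx: dict):
        waves.append(
            {
                "onsets": {labels[k]: float(v) for k, v in sorted(onsets_by_idx.items())},
                "start_segment": labels[min(onsets_by_idx)],
                "end_segment": labels[max(onsets_by_idx)],
                "complete": max(onsets_by_idx) == n - 1,
            }
        )

    if categories is not None:
        # explicit per-flash construction, background waves in the gaps
        blocked = [(T - span - 1.0, T + d + 1.0) for T, d in zip(f_onsets, f_durs)]
        start = 1.0
        while start + span < duration:
            if not any(lo <= start <= hi or lo <= start + span <= hi for lo, hi in blocked):
                record(_wave_onsets(start, 0, n - 1, wave_speed))
            start += wave_period
        for fid, (T, d, cat) in enumerate(zip(f_onsets, f_durs, categories)):
            front_post = idx_hinge - 2 if idx_hinge >= 2 else 0  # e.g. A6
            if cat == "COMPLETED_THEN_BLOCKED":
                front = min(idx_hinge + 1, n - 2)  # anterior of the hinge, e.g. A3
                start = T - front / wave_speed - 0.05
                record(_wave_onsets(start, 0, n - 1, wave_speed))
                front_seg = labels[front]
            elif cat == "IMMEDIATE_TERMINATION":
                start = T - front_post / wave_speed - 0.05
                record(_wave_onsets(start, 0, front_post, wave_speed))
                front_seg = labels[front_post]
            elif cat == "TERMINATED_AT_HINGE":
                start = T - front_post / wave_speed - 0.05
                record(_wave_onsets(start, 0, idx_hinge, wave_speed))
                front_seg = labels[front_post]
            elif cat == "NEW_WAVE_FROM_A4":
                start = T - front_post / wave_speed - 0.05
                record(_wave_onsets(start, 0, front_post, wave_speed))
                record(_wave_onsets(T + 0.5, idx_hinge, n - 1, wave_speed))
                front_seg = labels[front_post]
            elif cat == "PULL_PUSH":
                start = T - front_post / wave_speed - 0.05
                record(_wave_onsets(start, 0, front_post, wave_speed))
                gap = min(1.5, max(0.5, (d - 1.0) / 3.0))
                for m in range(3):
                    p_start = T + 0.5 + m * gap
                    if p_start + (idx_hinge - 1) / wave_speed < T + d:
                        record(_wave_onsets(p_start, 0, idx_hinge - 1, wave_speed))
                front_seg = labels[front_post]
            else:  # FAILURE_TO_STOP
                start = T - front_post / wave_speed - 0.05
                record(_wave_onsets(start, 0, n - 1, wave_speed))
                record(_wave_onsets(T + 0.3, 0, n - 1, wave_speed))
                front_seg = labels[front_post]
            outcomes.append({"flash_onset": T, "category": cat, "front_segment": front_seg})
    else:
        # periodic waves, rule applied at each flash
        planned = []
        start = 1.0
        while start + span < duration or (not planned and start < duration):
            planned.append(start)
            start += wave_period
        for start in planned:
            onsets = _wave_onsets(start, 0, n - 1, wave_speed)
            drop = False
            for fid, (T, d) in enumerate(zip(f_onsets, f_durs)):
                if rule == "none":
                    continue
                if T <= start < T + d:
                    drop = True  # no initiation during the flash
                    break
                if start < T <= start + span:  # ongoing at flash onset
                    front = max(k for k, v in onsets.items() if v <= T)
                    if front < idx_hinge:
                        if rng.random() < immediate_fraction:
                            onsets = {k: v for k, v in onsets.items() if k <= front}
                            cat = "IMMEDIATE_TERMINATION"
                        else:
                            onsets = {k: v for k, v in onsets.items() if k <= idx_hinge}
                            cat = "TERMINATED_AT_HINGE"
                    else:
                        cat = "COMPLETED_THEN_BLOCKED"
                    outcomes.append(
                        {"flash_onset": T, "category": cat, "front_segment": labels[front]}
                    )
            if not drop:
                record(onsets)

    t = np.arange(int(round(duration * frame_rate))) / frame_rate
    data = np.zeros((n, len(t)))
    for w in waves:
        for lab, onset in w["onsets"].items():
            _add_pulse(data[labels.index(lab)], t, onset, pulse_width, amplitude)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, data.shape)

    traces = SegmentTraceSet(labels=list(labels), data=data, frame_rate=frame_rate,
                             modality=modality)
    truth = {"waves": waves, "outcomes": outcomes}
    return traces, truth


def _response_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Double-exponential response normalized to unit peak on the grid."""
    k = np.zeros_like(t)
    pos = t >= 0
    if tau_rise <= 0:
        k[pos] = np.exp(-t[pos] / tau_decay) if tau_decay > 0 else (t[pos] == 0).astype(float)
    else:
        k[pos] = (1.0 - np.exp(-t[pos] / tau_rise)) * np.exp(-t[pos] / tau_decay)
    peak = k.max()
    return k / peak if peak > 0 else k


def generate_roi_traces(
    f0: float = 100.0,
    response_amplitude: float = 1.0,
    response_onsets=(10.0,),
    tau_rise: float = 0.2,
    tau_decay: float = 1.5,
    noise_sd: float = 0.0,
    frame_rate: float = 10.0,
    duration: float | None = None,
    seed: int = 0,
):
    """Raw ROI fluorescence with known dF/F ground truth.

    The raw series is ``F0 * (1 + a * k(t))`` plus Gaussian noise, where
    ``k`` is a unit-peak double-exponential placed at each stimulus onset.
    Returns ``(RoiSeries, truth)``; ``truth['peak_dff']`` is the noiseless
    peak dF/F (= ``a`` for well-separated responses).
    """
    if not f0 > 0:
        raise ValueError("baseline F0 must be positive")
    rng = np.random.default_rng(seed)
    onsets = np.asarray(response_onsets, float)
    if duration is None:
        duration = float(onsets.max()) + 8.0 * max(tau_decay, 0.5)
    t = np.arange(int(round(duration * frame_rate))) / frame_rate
    resp = np.zeros_like(t)
    for o in onsets:
        resp += _response_kernel(t - o, tau_rise, tau_decay)
    dff_true = response_amplitude * resp
    raw = f0 * (1.0 + dff_true)
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, raw.shape)
    series = RoiSeries(raw=raw, frame_rate=frame_rate, roi_id="synthetic",
                       stimulus_onsets=list(onsets))
    truth = {
        "t": t,
        "dff_true": dff_true,
        "peak_dff": float(dff_true.max()),
        "peak_dff_per_epoch": [
            float(dff_true[(t >= o) & (t < (onsets[i + 1] if i + 1 < len(onsets) else np.inf))].max())
            for i, o in enumerate(onsets)
        ],
    }
    return series, truth
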