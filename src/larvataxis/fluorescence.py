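"""dF/F quantification of ROI fluorescence.

Two baseline conventions are supported: the motor-imaging convention where
F0 is the mean of the whole series (the dF/F trace is then optionally
smoothed with a third-order Savitzky-Golay filter of frame length 15), and
the stimulus-triggered convention where F0 is the mean of a 2-s window
preceding each stimulus onset and no filtering is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

logger = logging.getLogger(__name__)

__all__ = ["RoiSeries", "DffSeries", "roi_mean", "dff", "sg_filter", "peak_response"]


@dataclass
class RoiSeries:
    """Mean pixel intensity of one ROI per frame (arbitrary units)."""

    raw: np.ndarray
    frame_rate: float
    roi_id: str = "roi-0"
    stimulus_onsets: list = field(default_factory=list)

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if np.any(self.raw < 0):
            raise ValueError("fluorescence intensities must be non-negative")

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.raw)) / self.frame_rate


@dataclass
class DffSeries:
    dff: np.ndarray
    baseline: np.ndarray          # F0 per frame (constant in whole-series mode)
    baseline_mode: str            # whole_series_mean | prestimulus_window
    frame_rate: float
    stimulus_onsets: list = field(default_factory=list)
    filter_applied: str = "none"  # none | savitzky_golay(order,frame_length)

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.dff)) / self.frame_rate


def _rasterize(mask, shape):
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.shape != shape:
            raise ValueError("boolean mask must match frame shape")
        return mask
    if mask.ndim == 1 and len(mask) == 4:  # rectangle (r0, r1, c0, c1)
        r0, r1, c0, c1 = (int(v) for v in mask)
        out = np.zeros(shape, bool)
        out[r0:r1, c0:c1] = True
        return out
    if mask.ndim == 2 and mask.shape[1] == 2:  # polygon vertices (row, col)
        from matplotlib.path import Path

        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        pts = np.column_stack([rr.ravel() + 0.0, cc.ravel() + 0.0])
        return Path(mask).contains_points(pts).reshape(shape)
    raise ValueError("mask must be boolean array, rectangle 4-tuple or polygon vertices")


def roi_mean(frames, roi, frame_rate: float = 1.0, roi_id: str = "roi-0") -> RoiSeries:
    """Per-frame mean pixel intensity inside an ROI.

    ``frames`` is a (T, H, W) stack or a path to a multi-page TIFF; ``roi``
    a boolean mask, a rectangle ``(r0, r1, c0, c1)`` or polygon vertices in
    (row, col) coordinates.
    """
    if isinstance(frames, (str, bytes)) or hasattr(frames, "__fspath__"):
        import tifffile

        frames = tifffile.imread(frames)
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a (T, H, W) stack")
    mask = _rasterize(roi, frames.shape[1:])
    if not mask.any():
        raise ValueError("ROI mask is empty")
    series = frames[:, mask].mean(axis=1)
    return RoiSeries(raw=series, frame_rate=frame_rate, roi_id=roi_id)


def dff(
    series: RoiSeries,
    mode: str = "whole_series_mean",
    window: float = 2.0,
    onsets=None,
) -> DffSeries:
    """Relative fluorescence change (F_i - F0) / F0.

    ``whole_series_mean``: F0 is the mean of the entire raw series (the
    mean of the resulting dF/F is exactly zero).  ``prestimulus_window``:
    F0 is recomputed per stimulus epoch as the mean over ``[onset - window,
    onset)``; each epoch extends to the next epoch's baseline window.
    """
    raw = series.raw
    n = len(raw)
    fr = series.frame_rate
    if mode == "whole_series_mean":
        f0 = float(raw.mean())
        if f0 <= 0:
            raise ValueError("baseline F0 must be positive")
        baseline = np.full(n, f0)
        out = (raw - f0) / f0
    elif mode == "prestimulus_window":
        ons = list(onsets if onsets is not None else series.stimulus_onsets)
        if not ons:
            raise ValueError("prestimulus mode requires stimulus onsets")
        ons = sorted(float(o) for o in ons)
        baseline = np.empty(n)
        out = np.empty(n)
        w = max(1, int(round(window * fr)))
        bounds = [0] + [max(0, int(round((o - window) * fr))) for o in ons[1:]] + [n]
        for k, o in enumerate(ons):
            i_on = int(round(o * fr))
            i0 = max(0, i_on - w)
            if i0 == i_on:
                raise ValueError("no pre-stimulus frames available for baseline")
            f0 = float(raw[i0:i_on].mean())
            if f0 <= 0:
                raise ValueError("baseline F0 must be positive")
            lo, hi = bounds[k], bounds[k + 1]
            baseline[lo:hi] = f0
            out[lo:hi] = (raw[lo:hi] - f0) / f0
        ons_out = ons
        return DffSeries(dff=out, baseline=baseline, baseline_mode=mode, frame_rate=fr,
                         stimulus_onsets=ons_out)
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    return DffSeries(dff=out, baseline=baseline, baseline_mode=mode, frame_rate=fr,
                     stimulus_onsets=list(series.stimulus_onsets))


def sg_filter(x, order: int = 3, frame_length: int = 15) -> np.ndarray:
    """Savitzky-Golay smoothing with truncated-window edge handling.

    Interior points use the standard local least-squares polynomial of the
    stated order and window; at each edge the polynomial is fit to the
    available (truncated) window only, so no data are fabricated beyond the
    recording.  Polynomials up to ``order`` are reproduced exactly.
    """
    x = np.asarray(x, dtype=float)
    if frame_length % 2 == 0 or frame_length <= order:
        raise ValueError("frame_length must be odd and greater than the order")
    if len(x) <= frame_length:
        raise ValueError("series shorter than the filter window")
    half = frame_length // 2
    out = savgol_filter(x, frame_length, order, mode="interp")
    idx = np.arange(len(x))
    for i in range(half):
        # leading edge: fit on x[0 : i+half+1]
        sl = slice(0, i + half + 1)
        coef = np.polynomial.polynomial.polyfit(idx[sl], x[sl], order)
        out[i] = np.polynomial.polynomial.polyval(i, coef)
        # trailing edge
        j = len(x) - 1 - i
        sl = slice(j - half, len(x))
        coef = np.polynomial.polynomial.polyfit(idx[sl], x[sl], order)
        out[j] = np.polynomial.polynomial.polyval(j, coef)
    return out


def peak_response(dff_series: DffSeries, window: float, onsets=None) -> dict:
    """Per-epoch peak dF/F within ``[onset, onset + window]`` plus summary."""
    ons = list(onsets if onsets is not None else dff_series.stimulus_onsets)
    if not ons:
        raise ValueError("no stimulus onsets defined")
    fr = dff_series.frame_rate
    n = len(dff_series.dff)
    peaks = []
    clipped = 0
    for o in sorted(float(v) for v in ons):
        i0 = int(round(o * fr))
        i1 = int(round((o + window) * fr)) + 1
        if i1 > n:
            i1 = n
            clipped += 1
        if i0 >= n:
            raise ValueError("stimulus onset beyond the recording")
        peaks.append(float(dff_series.dff[i0:i1].max()))
    if clipped:
        logger.warning("%d response windows clipped at the end of the recording", clipped)
    arr = np.asarray(peaks)
    return {
        "peaks": arr,
        "n": len(arr),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "std": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "sem": float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0,
        "clipped": clipped,
    }
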