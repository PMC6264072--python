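"""Analytical point-source odor landscape.

The concentration field of an odor droplet suspended above the agar is
modeled as free diffusion from a point source,

    C(r, t) = gamma / (4 pi D r) * erfc(r / sqrt(4 D (t - t0)))

with ``gamma`` the source flux (arbitrary units, default 1), ``D`` the
diffusion constant in cm^2/min (default 0.025), ``r`` the 3-D Euclidean
distance to the source and ``t`` the time since release ``t0`` in minutes.
Multiple sources superpose linearly.  As ``t -> inf`` the field approaches
the steady state ``gamma / (4 pi D r)``.

Internal units are cm for space and minutes for time; helpers accept
seconds where noted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

logger = logging.getLogger(__name__)

__all__ = [
    "OdorSource",
    "OdorLandscape",
    "GridField",
    "four_corner_landscape",
]

_INV_SQRT_PI = 1.0 / math.sqrt(math.pi)


def _as_point3(point) -> np.ndarray:
    p = np.asarray(point, dtype=float)
    if p.shape == (2,):
        p = np.array([p[0], p[1], 0.0])
    if p.shape != (3,):
        raise ValueError(f"point must be a 2- or 3-vector, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError("point must be finite")
    return p


@dataclass(frozen=True)
class OdorSource:
    """A point odor source at ``position`` (cm) emitting flux ``flux`` (a.u./min)."""

    position: tuple
    flux: float = 1.0

    def __post_init__(self):
        pos = _as_point3(self.position)
        object.__setattr__(self, "position", tuple(pos))
        if not self.flux > 0:
            raise ValueError("flux must be positive")


@dataclass
class GridField:
    """Concentration sampled on a regular grid (cell centers)."""

    x: np.ndarray            # (nx,) cm
    y: np.ndarray            # (ny,) cm
    values: np.ndarray       # (ny, nx)
    singular: np.ndarray     # (ny, nx) bool, True where a cell center hits a source
    height: float            # evaluation plane, cm
    t: float                 # evaluation time, min

    def to_frame(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "concentration": self.values.ravel()}
        )


@dataclass
class OdorLandscape:
    """Superposition of point-source erfc diffusion fields.

    Parameters
    ----------
    sources
        One or more :class:`OdorSource`.
    diffusion_constant
        D in cm^2/min.
    release_time
        t0 in minutes; concentration is defined for t > t0 only.
    """

    sources: list = field(default_factory=list)
    diffusion_constant: float = 0.025
    release_time: float = 0.0

    def __post_init__(self):
        if not self.sources:
            raise ValueError("landscape needs at least one source")
        self.sources = [
            s if isinstance(s, OdorSource) else OdorSource(*s) for s in self.sources
        ]
        if not self.diffusion_constant > 0:
            raise ValueError("diffusion constant must be positive")
        # flat arrays for the fast scalar path used by the simulator
        self._pos = np.array([s.position for s in self.sources], dtype=float)
        self._flux = np.array([s.flux for s in self.sources], dtype=float)

    # ------------------------------------------------------------------
    def _tau(self, t: float) -> float:
        tau = t - self.release_time
        if tau <= 0:
            raise ValueError(f"t = {t} min is not after release time {self.release_time}")
        return tau

    def concentration(self, point, t: float) -> float:
        """Concentration at a point (cm) and time t (min)."""
        p = _as_point3(point)
        tau = self._tau(t)
        D = self.diffusion_constant
        denom = math.sqrt(4.0 * D * tau)
        total = 0.0
        for (sx, sy, sz), g in zip(self._pos, self._flux):
            r = math.sqrt((p[0] - sx) ** 2 + (p[1] - sy) ** 2 + (p[2] - sz) ** 2)
            if r == 0.0:
                raise ValueError("evaluation point coincides with a source (singular)")
            total += g / (4.0 * math.pi * D * r) * math.erfc(r / denom)
        return total

    def spatial_gradient(self, point, t: float) -> np.ndarray:
        """Analytic gradient of the field, concentration units per cm.

        For a single source the gradient points from the evaluation point
        toward the source (the field increases toward the source).
        """
        p = _as_point3(point)
        tau = self._tau(t)
        D = self.diffusion_constant
        denom = math.sqrt(4.0 * D * tau)
        grad = np.zeros(3)
        for (sx, sy, sz), g in zip(self._pos, self._flux):
            d = p - np.array([sx, sy, sz])
            r = math.sqrt(d @ d)
            if r == 0.0:
                raise ValueError("evaluation point coincides with a source (singular)")
            u = r / denom
            # d/dr [ erfc(u)/r ] = -erfc(u)/r^2 - 2 exp(-u^2) / (sqrt(pi) r denom)
            dCdr = (
                g
                / (4.0 * math.pi * D)
                * (-math.erfc(u) / r**2 - 2.0 * _INV_SQRT_PI * math.exp(-u * u) / (r * denom))
            )
            grad += dCdr * d / r
        return grad

    def concentration_grid(
        self,
        extent,
        resolution: float,
        t: float,
        height: float = 0.0,
    ) -> GridField:
        """Sample the field on a regular grid of cell centers.

        ``extent`` is ``(xmin, xmax, ymin, ymax)`` in cm; ``resolution`` the
        cell edge in cm.  Cells whose center coincides with a source are
        flagged in ``singular`` and set to NaN rather than +inf.
        """
        if not resolution > 0:
            raise ValueError("resolution must be positive")
        xmin, xmax, ymin, ymax = extent
        nx = max(1, int(round((xmax - xmin) / resolution)))
        ny = max(1, int(round((ymax - ymin) / resolution)))
        x = xmin + (np.arange(nx) + 0.5) * resolution
        y = ymin + (np.arange(ny) + 0.5) * resolution
        tau = self._tau(t)
        D = self.diffusion_constant
        denom = math.sqrt(4.0 * D * tau)
        xx, yy = np.meshgrid(x, y)
        values = np.zeros_like(xx)
        singular = np.zeros_like(xx, dtype=bool)
        for (sx, sy, sz), g in zip(self._pos, self._flux):
            r = np.sqrt((xx - sx) ** 2 + (yy - sy) ** 2 + (height - sz) ** 2)
            sing = r == 0.0
            singular |= sing
            r = np.where(sing, np.nan, r)
            values += g / (4.0 * math.pi * D * r) * erfc(r / denom)
        if singular.any():
            logger.warning("%d grid cells coincide with a source; set to NaN", singular.sum())
        return GridField(x=x, y=y, values=values, singular=singular, height=height, t=t)

    def concentration_along_path(
        self,
        trajectory,
        body_point: str = "centroid",
        plane_height: float = 0.0,
        smoothing_window: float = 1.0,
        static_time: float | None = None,
        time_offset: float = 0.0,
        derivative: str = "central",
    ):
        """Concentration and its time derivative along a trajectory.

        Parameters
        ----------
        trajectory
            A :class:`~larvataxis.trajectory.Trajectory` (positions in cm,
            times in seconds).
        body_point
            Which skeleton point samples the field: head, centroid or tail.
        plane_height
            z of the behavioral plane, cm.
        smoothing_window
            Moving-average window (s) applied to C before differencing;
            0 disables smoothing.
        static_time
            If given, the field is frozen at this time (minutes): the
            derivative is then purely motion-induced.  Otherwise the field
            is evaluated at ``time_offset + t/60`` minutes per frame.
        time_offset
            Gradient age (min) at trajectory time 0 when not static.
        derivative
            ``central``: central differences of the moving-average-smoothed
            C series.  ``lagged``: backward difference over the smoothing
            window (lightly pre-smoothed, 0.25 s), mimicking a sensory
            integrator that compares the present concentration with that
            experienced one window earlier.

        Returns
        -------
        (C, dC_dt) : two arrays, trajectory length; dC/dT in units per second.
        """
        pts = getattr(trajectory, body_point)
        t = trajectory.t
        D = self.diffusion_constant
        n = len(t)
        c = np.zeros(n)
        for (sx, sy, sz), g in zip(self._pos, self._flux):
            r = np.sqrt(
                (pts[:, 0] - sx) ** 2 + (pts[:, 1] - sy) ** 2 + (plane_height - sz) ** 2
            )
            if np.any(r == 0.0):
                raise ValueError("trajectory passes exactly through a source (singular)")
            if static_time is not None:
                tau = self._tau(static_time)
                c += g / (4.0 * math.pi * D * r) * erfc(r / np.sqrt(4.0 * D * tau))
            else:
                tau = time_offset + t / 60.0 - self.release_time
                if np.any(tau <= 0):
                    raise ValueError("trajectory starts at or before odor release")
                c += g / (4.0 * math.pi * D * r) * erfc(r / np.sqrt(4.0 * D * tau))
        def smooth(x, win_s):
            w = max(1, int(round(win_s * trajectory.frame_rate)))
            if w <= 1:
                return x
            kernel = np.ones(w) / w
            pad = np.r_[np.full(w // 2, x[0]), x, np.full(w - 1 - w // 2, x[-1])]
            return np.convolve(pad, kernel, mode="valid")

        if derivative == "central":
            dcdt = np.gradient(smooth(c, smoothing_window or 0.0), t)
        elif derivative == "lagged":
            c_s = smooth(c, 0.25)
            lag = max(1, int(round((smoothing_window or 1.0) * trajectory.frame_rate)))
            dcdt = np.empty_like(c_s)
            dcdt[lag:] = (c_s[lag:] - c_s[:-lag]) * trajectory.frame_rate / lag
            dcdt[:lag] = dcdt[lag] if len(c_s) > lag else 0.0
        else:
            raise ValueError(f"unknown derivative mode {derivative!r}")
        return c, dcdt


def four_corner_landscape(
    half_side: float = 4.0,
    flux: float = 1.0,
    D: float = 0.025,
    source_height: float = 0.5,
) -> OdorLandscape:
    """Four identical sources at the corners of a square (the multi-source assay)."""
    corners = [
        (-half_side, -half_side, source_height),
        (half_side, -half_side, source_height),
        (half_side, half_side, source_height),
        (-half_side, half_side, source_height),
    ]
    return OdorLandscape(sources=[OdorSource(c, flux) for c in corners], diffusion_constant=D)
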