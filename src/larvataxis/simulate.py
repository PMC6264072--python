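"""Agent-based larva simulator.

Implements the sensorimotor algorithm of larval chemotaxis as a per-frame
state machine: peristaltic runs whose termination is an inhomogeneous
Poisson process with hazard set by the sign of the experienced concentration
change (turning suppressed while ascending the gradient, promoted while
descending), stop/head-cast/turn maneuvers with gradient-biased direction
acceptance, and optogenetically evoked stop commands for the
channelrhodopsin ("chrimson") genotype.

Every simulation returns the trajectory plus a complete ground truth
(per-frame state, event list, per-flash response, peristaltic cycle starts)
so that downstream detectors can be validated exactly.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "RUN",
    "STOP",
    "CAST",
    "STATE_NAMES",
    "SimulationConfig",
    "GroundTruth",
    "simulate_larva",
    "simulate_cohort",
]

RUN, STOP, CAST = 0, 1, 2
STATE_NAMES = {RUN: "RUN", STOP: "STOP", CAST: "CAST"}


@dataclass
class SimulationConfig:
    """Parameters of the simulated larva.

    Rates are per minute, durations in seconds, lengths in mm, angles in
    degrees.  ``genotype`` is one of ``wildtype`` (gradient-modulated
    hazards), ``pdm_silenced`` (down-gradient hazard forced equal to the
    up-gradient one, abolishing the asymmetry) or ``chrimson``
    (flash-responsive: each light flash evokes a stop command with
    probability ``p_stop``).
    """

    seed: int = 0
    frame_rate: float = 20.0
    duration: float = 300.0
    body_length: float = 4.0            # L0, mm
    length_amplitude: float = 0.6       # peristaltic body-length modulation, mm
    run_speed: float = 0.8              # v0, mean tail speed during runs, mm/s
    peristaltic_period: float = 1.0     # s
    turn_hazard_up: float = 2.0         # lambda_up, events/min while dC/dT > 0
    turn_hazard_down: float = 8.0       # lambda_down, events/min while dC/dT < 0
    baseline_hazard: float = 4.0        # lambda_0, events/min without odor
    stop_duration_mean: float = 2.0     # s, quiescent part of a stop
    casts_per_stop_mean: float = 2.0
    cast_amplitude: float = 60.0        # deg
    cast_speed: float = 120.0           # deg/s for spontaneous casts
    turn_angle_sd: float = 50.0         # deg
    turn_angle_min: float = 35.0
    turn_angle_max: float = 150.0
    gradient_bias: float = 0.7          # P(turn toward the gradient)
    heading_noise: float = 5.0          # deg / sqrt(s) during runs
    position_noise: float = 0.01        # mm, per-frame sensor noise on coordinates
    genotype: str = "wildtype"
    # flash response (chrimson genotype)
    p_stop: float = 0.95
    stop_latency_mean: float = 0.4      # s
    adaptation_time: float = 3.0        # tau_adapt, s
    cast_vigor_up: float = 100.0        # deg/s when pre-flash dC/dT > 0
    cast_vigor_down: float = 200.0      # deg/s when pre-flash dC/dT < 0
    flash_cast_delay_ref: float = 3.0   # s mean casting delay at vigor 100 deg/s
    # odor-field sampling
    gradient_age: float = 200.0         # min; field evaluated quasi-statically
    plane_height: float = 0.0           # cm

    def __post_init__(self):
        if self.duration < 10:
            raise ValueError("duration must be at least 10 s")
        for name in (
            "frame_rate", "body_length", "run_speed", "peristaltic_period",
            "turn_hazard_up", "turn_hazard_down", "baseline_hazard",
            "stop_duration_mean", "cast_amplitude", "cast_speed",
            "turn_angle_sd", "stop_latency_mean", "adaptation_time",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gradient_bias", "p_stop"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.genotype not in ("wildtype", "pdm_silenced", "chrimson"):
            raise ValueError(f"unknown genotype {self.genotype!r}")


@dataclass
class GroundTruth:
    """Machine-readable truth accompanying a simulated trajectory."""

    states: np.ndarray                      # (N,) int8: RUN/STOP/CAST
    hazard_class: np.ndarray                # (N,) int8: +1 up, -1 down, 0 none
    events: list = field(default_factory=list)
    flash_responses: list = field(default_factory=list)
    flash_commands: list = field(default_factory=list)
    cycle_starts: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def turns(self) -> list:
        return [e for e in self.events if e["type"] == "turn"]

    @property
    def stops(self) -> list:
        return [e for e in self.events if e["type"] == "stop"]


def _unit(angle_rad: float) -> np.ndarray:
    return np.array([math.cos(angle_rad), math.sin(angle_rad)])


def _flash_responses_from_states(t, states, flashes) -> list:
    """Per-flash response derived from the true state sequence.

    A flash counts as answered by a stop when a non-RUN interval *begins*
    inside the flash window; latency is measured to that interval's start
    and duration is the full interval length (it may outlast the flash).
    """
    out = []
    nonrun = states != RUN
    starts = np.flatnonzero(nonrun & ~np.r_[False, nonrun[:-1]])
    ends = np.flatnonzero(nonrun & ~np.r_[nonrun[1:], False])
    dt = t[1] - t[0]
    for onset, dur in zip(flashes.onsets, flashes.durations):
        i_on = min(len(t) - 1, max(0, int(round(onset / dt))))
        resp = {
            "flash_onset": float(onset),
            "stopped": False,
            "latency": None,
            "duration": None,
            "running_at_onset": bool(states[i_on] == RUN),
        }
        for s, e in zip(starts, ends):
            if onset <= t[s] < onset + dur:
                resp.update(
                    stopped=True,
                    latency=float(t[s] - onset),
                    duration=float(t[e] - t[s] + (t[1] - t[0])),
                )
                break
        out.append(resp)
    return out


def simulate_larva(
    config: SimulationConfig,
    landscape=None,
    flashes=None,
    start=(0.0, 0.0),
    start_heading: float | None = None,
    rng: np.random.Generator | None = None,
):
    """Simulate one larva; returns ``(Trajectory, GroundTruth)``.

    ``start`` is the initial centroid (cm); ``start_heading`` in radians
    (drawn uniformly when None).
    """
    cfg = config
    if cfg.genotype == "chrimson" and flashes is None:
        warnings.warn("chrimson genotype simulated without a flash schedule")
    rng = rng or np.random.default_rng(cfg.seed)

    dt = 1.0 / cfg.frame_rate
    n = int(round(cfg.duration * cfg.frame_rate))
    t = np.arange(n) * dt
    P = cfg.peristaltic_period
    L0, A = cfg.body_length, cfg.length_amplitude
    bl_peak = 340.0 / 360.0  # body length peaks just before the next tail-speed peak

    # effective hazards (per second)
    lam_up = cfg.turn_hazard_up / 60.0
    lam_down = cfg.turn_hazard_down / 60.0
    if cfg.genotype == "pdm_silenced":
        lam_down = lam_up
    lam0 = cfg.baseline_hazard / 60.0

    t_eval = cfg.gradient_age  # quasi-static field age, min
    zplane = cfg.plane_height

    def conc(xy) -> float:
        return landscape.concentration((xy[0], xy[1], zplane), t_eval)

    heading = float(rng.uniform(0, 2 * math.pi)) if start_heading is None else float(start_heading)
    L = L0
    centroid = np.array(start, dtype=float)
    tail = centroid - (L / 20.0) * _unit(heading)
    head_angle = 0.0

    head_arr = np.zeros((n, 2))
    cen_arr = np.zeros((n, 2))
    tail_arr = np.zeros((n, 2))
    states = np.zeros(n, dtype=np.int8)
    hazard_class = np.zeros(n, dtype=np.int8)
    events: list = []
    cycle_starts: list = []

    # The sensed concentration change is the difference over one peristaltic
    # period: the centroid sways back and forth within each cycle (body
    # length oscillates), so a per-frame difference would flip sign inside
    # every cycle regardless of the direction of travel.
    from collections import deque

    period_frames = max(1, int(round(P * cfg.frame_rate)))
    c_buf: deque = deque()
    if landscape is not None:
        c_buf.append(conc(centroid))
    dc = 0.0
    run_dc_sum = 0.0
    run_start = 0.0

    mode = RUN
    phase = 0.0
    cycle_starts.append(0.0)
    ha_noise = 0.0

    # stop/cast bookkeeping (times in seconds)
    stop_onset = 0.0
    cast_begin = math.inf
    resume_at = math.inf
    cast_speed = cfg.cast_speed
    cast_amp = cfg.cast_amplitude
    turn_angle = 0.0
    in_flash_stop = False
    speed_ramp_until = -1.0

    # flash schedule bookkeeping
    flash_commands: list = []
    f_onsets = np.asarray(flashes.onsets, float) if flashes is not None else np.empty(0)
    f_durs = np.asarray(flashes.durations, float) if flashes is not None else np.empty(0)
    next_flash = 0
    forced_stop_at = math.inf
    flash_end = -math.inf

    def choose_turn():
        """Signed turn angle (deg): side biased toward the gradient."""
        for _ in range(1000):
            mag = rng.normal(cfg.cast_amplitude, cfg.turn_angle_sd)
            if cfg.turn_angle_min <= mag <= cfg.turn_angle_max:
                break
        else:  # pragma: no cover - pathological parameters
            mag = cfg.cast_amplitude
        if landscape is not None:
            amp = math.radians(cast_amp)
            half = L / 20.0
            c_plus = conc(centroid + half * _unit(heading + amp))
            c_minus = conc(centroid + half * _unit(heading - amp))
            toward = 1.0 if c_plus > c_minus else -1.0
            side = toward if rng.random() < cfg.gradient_bias else -toward
        else:
            side = 1.0 if rng.random() < 0.5 else -1.0
        return side * mag

    def begin_stop(now: float, flash_evoked: bool):
        nonlocal mode, stop_onset, cast_begin, resume_at, cast_speed, turn_angle, in_flash_stop
        mode = STOP
        stop_onset = now
        in_flash_stop = flash_evoked
        if flash_evoked:
            vigor = cfg.cast_vigor_down if dc < 0 else cfg.cast_vigor_up
            cast_speed = vigor
            delay = rng.exponential(cfg.flash_cast_delay_ref * 100.0 / vigor)
            cast_begin = now + delay
            resume_at = min(flash_end, now + cfg.adaptation_time + abs(rng.normal(0.0, 0.3)))
            resume_at = max(resume_at, now + 2 * dt)
        else:
            cast_speed = cfg.cast_speed
            quiet = rng.gamma(2.0, cfg.stop_duration_mean / 2.0)
            n_casts = 1 + rng.poisson(max(cfg.casts_per_stop_mean - 1.0, 0.0))
            sweep = 2.0 * cast_amp / cast_speed
            cast_begin = now + quiet
            resume_at = now + quiet + n_casts * sweep
        turn_angle = choose_turn()

    def finish_stop(now: float):
        nonlocal mode, heading, phase, run_dc_sum, run_start, head_angle, speed_ramp_until
        heading += math.radians(turn_angle)
        toward = None
        if landscape is not None:
            g = landscape.spatial_gradient((centroid[0], centroid[1], zplane), t_eval)
            d = g[0] * math.cos(heading) + g[1] * math.sin(heading)
            toward = bool(d > 0)
        events.append(
            {
                "type": "stop",
                "onset": stop_onset,
                "offset": now,
                "flash_evoked": in_flash_stop,
            }
        )
        events.append(
            {
                "type": "turn",
                "t": now,
                "sign": int(math.copysign(1, turn_angle)),
                "angle": float(turn_angle),
                "toward_gradient": toward,
                "pre_class": int(np.sign(run_dc_sum)) if landscape is not None else 0,
                "position": (float(centroid[0]), float(centroid[1])),
                "post_heading": float(heading),
            }
        )
        mode = RUN
        phase = 0.0
        cycle_starts.append(now)
        head_angle = 0.0
        run_dc_sum = 0.0
        run_start = now
        c_buf.clear()
        speed_ramp_until = now + (1.0 if in_flash_stop else 0.0)

    for i in range(n):
        now = t[i]

        # ---- flash triggering (chrimson only)
        if cfg.genotype == "chrimson" and next_flash < len(f_onsets):
            if now >= f_onsets[next_flash]:
                flash_end = f_onsets[next_flash] + f_durs[next_flash]
                commanded = rng.random() < cfg.p_stop
                latency = None
                if commanded:
                    # jittered command latency, clipped to +/- 2 sd
                    sd = cfg.stop_latency_mean / 8.0
                    latency = float(np.clip(rng.normal(cfg.stop_latency_mean, sd),
                                            max(dt, cfg.stop_latency_mean - 2 * sd),
                                            cfg.stop_latency_mean + 2 * sd))
                    forced_stop_at = f_onsets[next_flash] + latency
                flash_commands.append({"flash_onset": float(f_onsets[next_flash]),
                                       "commanded": bool(commanded),
                                       "latency": latency})
                next_flash += 1
        if now >= forced_stop_at:
            if mode == RUN:
                begin_stop(now, flash_evoked=True)
            forced_stop_at = math.inf

        # ---- advance the current mode
        if mode == RUN:
            phase += dt / P
            if phase >= 1.0:
                phase -= 1.0
                cycle_starts.append(now)
            speed = cfg.run_speed * (1.0 + math.cos(2 * math.pi * phase))
            if now < speed_ramp_until:
                speed *= max(0.2, 1.0 - (speed_ramp_until - now))
            heading += math.radians(cfg.heading_noise) * math.sqrt(dt) * rng.standard_normal()
            tail = tail + _unit(heading) * (speed * dt / 10.0)
            L = L0 + 0.5 * A * (1.0 + math.cos(2 * math.pi * (phase - bl_peak)))
            ha_noise = 0.9 * ha_noise + rng.normal(0.0, 1.0)
            head_angle = ha_noise
        else:
            # stopped or casting: tail anchored, body relaxes toward rest length
            L += (L0 - L) * (1.0 - math.exp(-dt / 0.3))
            if mode == STOP and now >= cast_begin:
                mode = CAST
            if mode == CAST:
                tau = now - cast_begin
                sweep = 2.0 * cast_amp / cast_speed
                frac = (tau % sweep) / sweep
                side = math.copysign(1.0, turn_angle)
                head_angle = side * cast_amp * (1.0 - abs(1.0 - 2.0 * frac))
            else:
                head_angle *= 0.8
            if now >= resume_at:
                finish_stop(now)

        centroid = tail + (L / 20.0) * _unit(heading)
        head = centroid + (L / 20.0) * _unit(heading + math.radians(head_angle))

        frame_mode = mode

        # ---- experienced concentration change and hazard
        if landscape is not None and mode == RUN:
            c_now = conc(centroid)
            c_buf.append(c_now)
            while len(c_buf) > period_frames + 1:
                c_buf.popleft()
            dc = c_now - c_buf[0]
        if mode == RUN:
            if landscape is None:
                lam, hclass = lam0, 0
            elif dc > 0:
                lam, hclass = lam_up, 1
            elif dc < 0:
                lam, hclass = lam_down, -1
            else:
                lam, hclass = lam0, 0
            run_dc_sum += dc
            hazard_class[i] = hclass
            if rng.random() < 1.0 - math.exp(-lam * dt):
                begin_stop(now + dt, flash_evoked=False)

        states[i] = frame_mode
        head_arr[i] = head
        cen_arr[i] = centroid
        tail_arr[i] = tail

    # close an unfinished stop so events stay well-formed
    if mode != RUN:
        events.append({"type": "stop", "onset": stop_onset, "offset": float(t[-1] + dt), "flash_evoked": in_flash_stop})

    if cfg.position_noise > 0:
        sd_cm = cfg.position_noise / 10.0
        head_arr = head_arr + rng.normal(0.0, sd_cm, head_arr.shape)
        cen_arr = cen_arr + rng.normal(0.0, sd_cm, cen_arr.shape)
        tail_arr = tail_arr + rng.normal(0.0, sd_cm, tail_arr.shape)

    traj = Trajectory(
        t=t,
        head=head_arr,
        centroid=cen_arr,
        tail=tail_arr,
        frame_rate=cfg.frame_rate,
        id=f"larva-{cfg.seed}",
        meta={"genotype": cfg.genotype, "seed": cfg.seed},
    )
    truth = GroundTruth(
        states=states,
        hazard_class=hazard_class,
        events=sorted(events, key=lambda e: e.get("onset", e.get("t", 0.0))),
        cycle_starts=np.asarray(cycle_starts),
    )
    if flashes is not None:
        truth.flash_responses = _flash_responses_from_states(t, states, flashes)
        truth.flash_commands = flash_commands
    return traj, truth


def simulate_cohort(
    config: SimulationConfig,
    n: int,
    landscape=None,
    flashes=None,
    start=(0.0, 0.0),
):
    """Simulate ``n`` independent larvae with per-larva seeds derived from
    ``config.seed``; same master seed gives a byte-identical cohort."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(n)
    out = []
    for i, child in enumerate(children):
        seed_i = int(child.generate_state(1)[0] % (2**31))
        cfg_i = replace(config, seed=seed_i)
        traj, truth = simulate_larva(cfg_i, landscape=landscape, flashes=flashes, start=start)
        traj.id = f"larva-{i:03d}"
        out.append((traj, truth))
    return out
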