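import logging

import numpy as np
import pytest

import larvataxis as lt

logging.getLogger("larvataxis").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def single_source():
    return lt.OdorLandscape([lt.OdorSource((2.5, 0.0, 0.5), 1.0)])


@pytest.fixture(scope="session")
def four_sources():
    return lt.four_corner_landscape()


@pytest.fixture(scope="session")
def sim_gradient_cohort(single_source):
    """20 wildtype larvae, 5 min each, in the single-source gradient."""
    cfg = lt.SimulationConfig(seed=42, duration=300.0)
    return lt.simulate_cohort(cfg, 20, landscape=single_source)


@pytest.fixture(scope="session")
def analyzed_cohort(single_source, sim_gradient_cohort):
    out = []
    for traj, truth in sim_gradient_cohort:
        kin = lt.derive_kinematics(traj)
        ann = lt.segment_behavior(kin)
        _, dcdt = single_source.concentration_along_path(
            traj, "centroid", static_time=200.0, derivative="lagged")
        lt.classify_run_gradient(ann, dcdt)
        out.append((traj, truth, kin, ann, dcdt))
    return out


def straight_trajectory(speed_mm_s=1.0, duration=20.0, frame_rate=20.0,
                        body_mm=4.0, heading_deg=0.0, start=(0.0, 0.0)):
    """Rigid 3-point body translating at constant speed along a heading."""
    n = int(duration * frame_rate)
    t = np.arange(n) / frame_rate
    h = np.radians(heading_deg)
    u = np.array([np.cos(h), np.sin(h)])
    cen = np.asarray(start, float) + (speed_mm_s / 10.0) * t[:, None] * u
    half = body_mm / 20.0
    return lt.Trajectory(t=t, head=cen + half * u, centroid=cen, tail=cen - half * u,
                         frame_rate=frame_rate)
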