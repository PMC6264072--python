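"""Kinematics derivation, run/stop/cast/turn segmentation and chemotaxis
metrics."""

import numpy as np
import pytest

import larvataxis as lt
from larvataxis.segmentation import SegmentationParams, estimate_turn_hazards
from larvataxis.simulate import RUN, STOP, CAST
from conftest import straight_trajectory

FR = 20.0


def staged_trajectory(stages, body_mm=4.0, speed=1.0):
    """Hand-built run/stop/cast sequence: stages are ('run', dur_s, heading_deg)
    or ('stop', dur_s, cast_amp_deg).  During a stop the body pivots
    gradually toward the next run's heading, as it would while casting."""
    half = body_mm / 20.0
    dt = 1.0 / FR
    tail = np.array([0.0, 0.0])
    rows = []
    heading = 0.0
    tme = 0.0
    for si, stage in enumerate(stages):
        if stage[0] == "run":
            _, dur, heading_deg = stage
            heading = np.radians(heading_deg)
            u = np.array([np.cos(heading), np.sin(heading)])
            for _ in range(int(dur * FR)):
                tail = tail + u * speed * dt / 10.0
                cen = tail + half * u
                rows.append((tme, *(cen + half * u), *cen, *tail))
                tme += dt
        else:
            _, dur, amp = stage
            next_heading = heading
            for nxt in stages[si + 1:]:
                if nxt[0] == "run":
                    next_heading = np.radians(nxt[2])
                    break
            delta = (next_heading - heading + np.pi) % (2 * np.pi) - np.pi
            n = int(dur * FR)
            for i in range(n):
                h = heading + delta * (i + 1) / n
                ang = np.radians(amp) * np.sin(2 * np.pi * i / n) if amp else 0.0
                u = np.array([np.cos(h), np.sin(h)])
                cen = tail + half * u
                v = np.array([np.cos(h + ang), np.sin(h + ang)])
                rows.append((tme, *(cen + half * v), *cen, *tail))
                tme += dt
    arr = np.asarray(rows)
    return lt.Trajectory(t=arr[:, 0], head=arr[:, 1:3], centroid=arr[:, 3:5],
                         tail=arr[:, 5:7], frame_rate=FR)


class TestKinematics:
    def test_rigid_translation_speeds(self):
        traj = straight_trajectory(speed_mm_s=1.0, duration=20.0)
        kin = lt.derive_kinematics(traj)
        interior = slice(10, -10)
        np.testing.assert_allclose(kin.tail_speed[interior], 1.0, atol=1e-9)
        np.testing.assert_allclose(kin.head_speed[interior], 1.0, atol=1e-9)
        np.testing.assert_allclose(kin.head_angle_speed[interior], 0.0, atol=1e-9)
        np.testing.assert_allclose(kin.body_length, 4.0, atol=1e-9)

    def test_pure_head_rotation(self):
        n = int(10 * FR)
        t = np.arange(n) / FR
        cen = np.zeros((n, 2))
        tail = np.tile([-0.2, 0.0], (n, 1))
        ang = np.radians(30.0 * t)  # 30 deg/s about the centroid
        head = 0.2 * np.column_stack([np.cos(ang), np.sin(ang)])
        traj = lt.Trajectory(t=t, head=head, centroid=cen, tail=tail, frame_rate=FR)
        kin = lt.derive_kinematics(traj, smoothing_window=0.0)
        interior = slice(5, -5)
        np.testing.assert_allclose(kin.tail_speed[interior], 0.0, atol=1e-9)
        np.testing.assert_allclose(kin.head_angle_speed[interior], 30.0, atol=1e-6)

    def test_series_lengths_and_angle_range(self, sim_gradient_cohort):
        traj, _ = sim_gradient_cohort[0]
        kin = lt.derive_kinematics(traj)
        for arr in (kin.tail_speed, kin.head_speed, kin.body_length,
                    kin.heading, kin.head_angle, kin.head_angle_speed):
            assert len(arr) == len(traj)
        assert np.all(kin.head_angle > -180.0) and np.all(kin.head_angle <= 180.0)

    def test_too_short_trajectory_rejected(self):
        traj = straight_trajectory(duration=0.2)
        with pytest.raises(ValueError):
            lt.derive_kinematics(traj, smoothing_window=1.0)

    def test_tail_speed_peaks_match_cycle_starts(self):
        cfg = lt.SimulationConfig(seed=8, duration=60.0, position_noise=0.0)
        traj, truth = lt.simulate_larva(cfg)
        kin = lt.derive_kinematics(traj, smoothing_window=0.05)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(kin.tail_speed, prominence=0.3, distance=10)
        peak_t = kin.t[peaks]
        matched = sum(1 for s in truth.cycle_starts
                      if len(peak_t) and np.min(np.abs(peak_t - s)) <= 1.0 / FR + 1e-9)
        assert matched / len(truth.cycle_starts) >= 0.9


class TestSegmentation:
    def test_constant_speed_run_is_single_run(self):
        traj = straight_trajectory(speed_mm_s=1.0, duration=30.0)
        ann = lt.segment_behavior(lt.derive_kinematics(traj))
        assert np.all(ann.states == RUN)
        assert len(ann.turns) == 0 and len(ann.stops) == 0
        assert len(ann.runs) == 1

    def test_time_reversed_run_gives_same_partition(self):
        traj = straight_trajectory(speed_mm_s=1.0, duration=30.0)
        rev = lt.Trajectory(t=traj.t, head=traj.tail[::-1], centroid=traj.centroid[::-1],
                            tail=traj.head[::-1], frame_rate=traj.frame_rate)
        ann = lt.segment_behavior(lt.derive_kinematics(rev))
        assert np.all(ann.states == RUN) and len(ann.runs) == 1

    def test_all_zero_speeds_yield_single_stop_no_turns(self):
        traj = straight_trajectory(speed_mm_s=0.0, duration=20.0)
        ann = lt.segment_behavior(lt.derive_kinematics(traj))
        assert len(ann.turns) == 0
        assert np.all(ann.states == STOP)

    def test_staged_run_stop_cast_turn_recovered(self):
        traj = staged_trajectory([
            ("run", 10.0, 0.0),
            ("stop", 1.5, 0.0),
            ("stop", 2.0, 60.0),   # casting phase
            ("run", 10.0, 70.0),
            ("stop", 2.5, 0.0),
            ("run", 10.0, 20.0),
        ])
        ann = lt.segment_behavior(lt.derive_kinematics(traj))
        assert len(ann.stops) == 2
        assert ann.stops[0]["onset"] == pytest.approx(10.0, abs=0.5)
        assert ann.stops[0]["offset"] == pytest.approx(13.5, abs=0.5)
        turns = ann.turns
        assert len(turns) == 2
        assert turns[0]["t"] == pytest.approx(13.5, abs=0.5)
        assert turns[0]["sign"] == 1 and turns[0]["net_change"] == pytest.approx(70, abs=5)
        assert turns[1]["sign"] == -1 and turns[1]["net_change"] == pytest.approx(-50, abs=5)
        # cast frames present inside the first stop
        i0 = int(11.5 * FR)
        i1 = int(13.4 * FR)
        assert (ann.states[i0:i1] == CAST).any()

    def test_threshold_monotonicity_in_stop_count(self, analyzed_cohort):
        _, _, kin, _, _ = analyzed_cohort[0]
        counts = []
        for theta in (0.15, 0.25, 0.4, 0.6):
            ann = lt.segment_behavior(kin, SegmentationParams(theta_stop=theta))
            counts.append(int((ann.states != RUN).sum()))
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_simulated_turns_recovered_with_correct_sign(self):
        cfg = lt.SimulationConfig(seed=31, duration=300.0, position_noise=0.0)
        traj, truth = lt.simulate_larva(cfg)
        ann = lt.segment_behavior(lt.derive_kinematics(traj))
        det = [(e["t"], e["sign"]) for e in ann.turns]
        matched = 0
        for ev in truth.turns:
            hits = [s for td, s in det if abs(td - ev["t"]) <= 0.5]
            if hits:
                matched += 1
                assert hits[0] == ev["sign"]
        assert matched / max(1, len(truth.turns)) >= 0.9

    def test_turn_rate_arithmetic(self):
        traj = staged_trajectory([
            ("run", 20.0, 0.0), ("stop", 2.0, 30.0),
            ("run", 20.0, 80.0), ("stop", 2.0, 30.0),
            ("run", 20.0, 160.0), ("stop", 2.0, 30.0),
            ("run", 20.0, -120.0),
        ])
        kin = lt.derive_kinematics(traj)
        ann = lt.segment_behavior(kin)
        tr = lt.turn_rate(ann, kin)
        assert tr["n_turns"] == 3
        total_min = len(traj) / FR / 60.0
        assert tr["turns_per_min"] * total_min == pytest.approx(3.0)
        # 80 s of running at 1 mm/s -> 8 cm of run path
        assert tr["turns_per_cm"] == pytest.approx(3 / 8.0, rel=0.05)


class TestGradientMetrics:
    def test_straight_runs_classified_up_and_down(self):
        land = lt.OdorLandscape([lt.OdorSource((50, 0, 0), 1.0)])
        toward = straight_trajectory(speed_mm_s=1.0, duration=30.0, heading_deg=0.0)
        away = straight_trajectory(speed_mm_s=1.0, duration=30.0, heading_deg=180.0)
        for traj, expect in ((toward, "UP"), (away, "DOWN")):
            kin = lt.derive_kinematics(traj)
            ann = lt.segment_behavior(kin)
            _, dcdt = land.concentration_along_path(traj, "centroid", static_time=1e9)
            lt.classify_run_gradient(ann, dcdt)
            assert ann.runs[0]["gradient_class"] == expect

    def test_run_labels_match_simulated_hazard_regime(self, analyzed_cohort):
        ok = tot = 0
        for _, truth, _, ann, _ in analyzed_cohort[:10]:
            for run in ann.runs:
                seg = truth.hazard_class[run["i0"]:run["i1"]]
                m = seg != 0
                if m.sum() < 5:
                    continue
                maj = 1 if (seg == 1).sum() >= (seg == -1).sum() else -1
                lab = {"UP": 1, "DOWN": -1, "NONE": 0}[run["gradient_class"]]
                tot += int(m.sum())
                ok += int(m.sum()) * (lab == maj)
        assert ok / tot >= 0.95

    def test_hazard_recovery_on_cohort(self, analyzed_cohort):
        ku = kd = 0
        tu = td = 0.0
        for _, _, _, ann, dcdt in analyzed_cohort:
            h = estimate_turn_hazards(ann, dcdt)
            ku += h["events_up"]
            kd += h["events_down"]
            tu += h["time_up_min"]
            td += h["time_down_min"]
        lam_up, lam_down = ku / tu, kd / td
        assert lam_up == pytest.approx(2.0, rel=0.3)
        assert lam_down == pytest.approx(8.0, rel=0.3)

    def test_all_turns_at_source_count_as_toward(self):
        land = lt.OdorLandscape([lt.OdorSource((0, 0, 0), 1.0)])
        from larvataxis.segmentation import BehaviorAnnotation

        events = []
        rng = np.random.default_rng(0)
        for _ in range(20):
            pos = rng.uniform(-3, 3, 2)
            heading = np.arctan2(-pos[1], -pos[0])  # straight at the source
            events.append({"type": "turn", "t": 0.0, "sign": 1, "net_change": 45.0,
                           "gradient_class": "NONE", "toward_gradient": None,
                           "position": tuple(pos), "post_heading": float(heading)})
        ann = BehaviorAnnotation(t=np.arange(10) / FR, states=np.zeros(10, np.int8),
                                 runs=[], events=events,
                                 params=SegmentationParams(), frame_rate=FR)
        res = lt.fraction_turns_toward_gradient(ann, land, t_eval=100.0)
        assert res["proportion"] == 1.0

    def test_uniform_random_headings_give_half(self):
        land = lt.OdorLandscape([lt.OdorSource((0, 0, 0), 1.0)])
        from larvataxis.segmentation import BehaviorAnnotation

        rng = np.random.default_rng(1)
        events = [{"type": "turn", "t": 0.0, "sign": 1, "net_change": 45.0,
                   "gradient_class": "NONE", "toward_gradient": None,
                   "position": tuple(rng.uniform(-3, 3, 2)),
                   "post_heading": float(rng.uniform(0, 2 * np.pi))}
                  for _ in range(2000)]
        ann = BehaviorAnnotation(t=np.arange(10) / FR, states=np.zeros(10, np.int8),
                                 runs=[], events=events,
                                 params=SegmentationParams(), frame_rate=FR)
        res = lt.fraction_turns_toward_gradient(ann, land, t_eval=100.0)
        assert abs(res["proportion"] - 0.5) < 3 * 0.5 / np.sqrt(2000)

    def test_measured_toward_fraction_matches_ground_truth(self, single_source,
                                                           analyzed_cohort):
        k = n = kt = nt = 0
        for _, truth, _, ann, _ in analyzed_cohort:
            res = lt.fraction_turns_toward_gradient(ann, single_source, t_eval=200.0)
            k += res["k"]
            n += res["n"]
            for ev in truth.turns:
                if ev["toward_gradient"] is not None:
                    nt += 1
                    kt += int(ev["toward_gradient"])
        p_true = kt / nt
        assert abs(k / n - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n)


class TestDistance:
    def test_fixed_larva_constant_distance(self):
        traj = straight_trajectory(speed_mm_s=0.0, duration=20.0, start=(2.0, 0.0))
        res = lt.distance_to_nearest_source([traj], [(0.0, 0.0, 0.0)],
                                            snapshot_time=10.0)
        np.testing.assert_allclose(res["per_larva"][0], 2.0, atol=1e-6)
        np.testing.assert_allclose(res["sem"], 0.0, atol=1e-12)
        assert res["snapshot"][0] == pytest.approx(2.0, abs=1e-6)

    def test_equidistant_two_sources(self):
        traj = straight_trajectory(speed_mm_s=1.0, duration=10.0, heading_deg=90.0,
                                   start=(0.0, 0.0))
        res = lt.distance_to_nearest_source([traj], [(-1.0, 0.0), (1.0, 0.0)])
        d0 = res["per_larva"][0][0]
        assert d0 == pytest.approx(1.0, abs=1e-6)
        # moving off the midline (along +y) increases the distance to both
        assert np.all(np.diff(res["per_larva"][0]) >= 0)

    def test_empty_source_list_rejected(self):
        traj = straight_trajectory(duration=12.0)
        with pytest.raises(ValueError):
            lt.distance_to_nearest_source([traj], [])
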