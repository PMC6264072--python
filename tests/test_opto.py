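"""Flash-triggered alignment, stop detection and trial statistics."""

import numpy as np
import pandas as pd
import pytest

import larvataxis as lt
from larvataxis.opto import concat_aligned
from larvataxis.segmentation import SegmentationParams


def make_annotation(tail_speed, head_angle=None, fr=20.0):
    """Segment a synthetic kinematic series (direct threshold path)."""
    n = len(tail_speed)
    kin = lt.KinematicSeries(
        t=np.arange(n) / fr,
        tail_speed=np.asarray(tail_speed, float),
        head_speed=np.zeros(n),
        body_length=np.full(n, 4.0),
        heading=np.zeros(n),
        head_angle=np.zeros(n) if head_angle is None else np.asarray(head_angle, float),
        head_angle_speed=np.zeros(n),
        frame_rate=fr,
        centroid=np.zeros((n, 2)),
    )
    return lt.segment_behavior(kin, SegmentationParams(theta_stop=0.25))


class TestSchedule:
    def test_standard_protocol(self):
        sched = lt.FlashSchedule.periodic(n=8, duration=6.0, gap=30.0)
        assert len(sched) == 8
        np.testing.assert_allclose(np.diff(sched.onsets), 36.0)
        assert sched.intensity == 18.0

    def test_validation(self):
        with pytest.raises(ValueError):
            lt.FlashSchedule(onsets=[10.0, 5.0])
        with pytest.raises(ValueError):
            lt.FlashSchedule(onsets=[0.0, 4.0], durations=[6.0, 6.0])


class TestAlignment:
    def test_constant_series_rows_constant(self):
        t = np.arange(4000) / 20.0
        sched = lt.FlashSchedule.periodic(n=4, first_onset=20.0)
        aligned = lt.align_to_flashes(t, np.full_like(t, 2.0), sched, window=(5, 10))
        assert len(aligned) == 4
        np.testing.assert_allclose(aligned.values, 2.0)

    def test_all_complete_flashes_kept_partials_dropped(self):
        t = np.arange(3000) / 20.0  # 150 s
        sched = lt.FlashSchedule.periodic(n=8, first_onset=20.0)
        aligned = lt.align_to_flashes(t, np.zeros_like(t), sched, window=(5, 10))
        # onsets at 20..272 s: only those with onset+10 <= 150 survive
        assert len(aligned) == 4

    def test_averaging_single_trial_set_returns_the_trial(self):
        rng = np.random.default_rng(0)
        t = np.arange(1200) / 20.0
        x = rng.random(len(t))
        sched = lt.FlashSchedule(onsets=[30.0], durations=[6.0])
        aligned = lt.align_to_flashes(t, x, sched, window=(5, 10))
        avg = lt.triggered_average(aligned)["all"]
        np.testing.assert_allclose(avg["mean"], aligned.values[0])
        np.testing.assert_allclose(avg["sem"], 0.0)

    def test_two_rows_pointwise_mean(self):
        time = np.arange(11) / 10.0 - 0.5
        a, b = np.arange(11.0), np.arange(11.0) * 3
        aligned = lt.TrialAlignedSet(time=time, values=np.vstack([a, b]),
                                     meta=pd.DataFrame({"trial": [0, 1]}),
                                     window=(0.5, 0.5))
        avg = lt.triggered_average(aligned)["all"]
        np.testing.assert_allclose(avg["mean"], (a + b) / 2)

    def test_grouped_average_by_metadata(self):
        time = np.arange(5) / 10.0
        vals = np.vstack([np.zeros(5), np.ones(5), np.ones(5) * 3])
        meta = pd.DataFrame({"trial": [0, 1, 2], "gradient_class": ["UP", "DOWN", "DOWN"]})
        avg = lt.triggered_average(
            lt.TrialAlignedSet(time=time, values=vals, meta=meta, window=(0, 0.4)),
            by="gradient_class")
        np.testing.assert_allclose(avg["DOWN"]["mean"], 2.0)
        assert avg["UP"]["n"] == 1


class TestFlashStops:
    def test_constructed_step_stop(self):
        fr = 20.0
        speed = np.full(2400, 1.0)
        onset = 60.0
        i0 = int((onset + 0.5) * fr)
        speed[i0:i0 + int(3 * fr)] = 0.0
        ann = make_annotation(speed, fr=fr)
        sched = lt.FlashSchedule(onsets=[onset], durations=[6.0])
        trials = lt.detect_flash_stops(ann, sched)
        row = trials.iloc[0]
        assert row["stopped"]
        assert row["latency"] == pytest.approx(0.5, abs=0.1)
        assert row["duration"] == pytest.approx(3.0, abs=0.1)
        assert row["running_at_onset"]

    def test_speed_never_below_threshold_means_no_stop(self):
        speed = np.full(2400, 1.0)
        ann = make_annotation(speed)
        sched = lt.FlashSchedule(onsets=[60.0], durations=[6.0])
        trials = lt.detect_flash_stops(ann, sched)
        assert not trials.iloc[0]["stopped"]
        assert np.isnan(trials.iloc[0]["latency"])

    def test_truncated_trial_excluded(self):
        ann = make_annotation(np.full(400, 1.0))  # 20 s
        sched = lt.FlashSchedule(onsets=[16.0], durations=[6.0])
        trials = lt.detect_flash_stops(ann, sched)
        assert len(trials) == 0

    def test_simulator_agreement(self, single_source):
        sched = lt.FlashSchedule.periodic(n=8)
        cfg = lt.SimulationConfig(seed=5, duration=320.0, genotype="chrimson")
        agree = tot = 0
        lat_err = []
        for traj, truth in lt.simulate_cohort(cfg, 12, landscape=single_source,
                                              flashes=sched):
            ann = lt.segment_behavior(lt.derive_kinematics(traj))
            trials = lt.detect_flash_stops(ann, sched)
            for row, resp in zip(trials.itertuples(), truth.flash_responses):
                tot += 1
                agree += row.stopped == resp["stopped"]
                if row.stopped and resp["stopped"]:
                    lat_err.append(abs(row.latency - resp["latency"]))
        assert agree / tot >= 0.95
        assert np.median(lat_err) <= 0.25


class TestStopProbability:
    def test_boundary_cases(self):
        sp0 = lt.stop_probability([False] * 10)
        assert sp0["proportion"] == 0.0 and sp0["lower"] == 0.0
        sp1 = lt.stop_probability([True] * 10)
        assert sp1["proportion"] == 1.0 and sp1["upper"] == 1.0

    def test_interval_matches_cdf_inversion(self):
        from test_stats import clopper_pearson_by_cdf_inversion

        sp = lt.stop_probability([True] * 7 + [False] * 3)
        lo, hi = clopper_pearson_by_cdf_inversion(7, 10)
        assert sp["lower"] == pytest.approx(lo, abs=1e-9)
        assert sp["upper"] == pytest.approx(hi, abs=1e-9)

    def test_coverage_of_clopper_pearson(self):
        rng = np.random.default_rng(13)
        n, p = 20, 0.3
        ks = rng.binomial(n, p, size=10_000)
        covered = 0
        cis = {k: lt.clopper_pearson(k, n) for k in range(n + 1)}
        for k in ks:
            ci = cis[int(k)]
            covered += ci.lower <= p <= ci.upper
        assert covered / len(ks) >= 0.94

    def test_estimated_probability_monotone_in_p_stop(self):
        sched = lt.FlashSchedule.periodic(n=8)
        props = []
        for p_stop in (0.2, 0.6, 0.95):
            cfg = lt.SimulationConfig(seed=9, duration=320.0, genotype="chrimson",
                                      p_stop=p_stop, baseline_hazard=1.0)
            stopped = []
            for traj, truth in lt.simulate_cohort(cfg, 8, flashes=sched):
                ann = lt.segment_behavior(lt.derive_kinematics(traj))
                trials = lt.detect_flash_stops(ann, sched)
                stopped += list(trials[trials["running_at_onset"]]["stopped"])
            props.append(np.mean(stopped))
        assert props[0] < props[1] < props[2]


class TestCastingFraction:
    def test_no_casts_zero_full_cast_one(self):
        speed = np.full(1200, 1.0)
        onset = 20.0
        ann = make_annotation(speed)
        sched = lt.FlashSchedule(onsets=[onset], durations=[6.0])
        assert lt.casting_fraction(ann, sched).iloc[0]["fraction"] == 0.0
        # now a stop filled with large head angles -> all CAST
        fr = 20.0
        speed2 = np.full(1200, 1.0)
        i0, i1 = int(onset * fr), int((onset + 6.0) * fr)
        speed2[i0:i1] = 0.0
        angle = np.zeros(1200)
        angle[i0:i1] = 60.0
        ann2 = make_annotation(speed2, head_angle=angle)
        assert lt.casting_fraction(ann2, sched).iloc[0]["fraction"] == pytest.approx(1.0)

    def test_down_gradient_trials_cast_more(self, single_source):
        sched = lt.FlashSchedule.periodic(n=8)
        cfg = lt.SimulationConfig(seed=7, duration=320.0, genotype="chrimson")
        frac = {"UP": [], "DOWN": []}
        for traj, truth in lt.simulate_cohort(cfg, 20, landscape=single_source,
                                              flashes=sched):
            kin = lt.derive_kinematics(traj)
            ann = lt.segment_behavior(kin)
            _, dcdt = single_source.concentration_along_path(
                traj, "centroid", static_time=200.0, derivative="lagged")
            lt.classify_run_gradient(ann, dcdt)

            def cls_at(onset):
                for r in ann.runs:
                    if r["onset"] <= onset < r["offset"]:
                        return r["gradient_class"]
                return "NONE"

            for row in lt.casting_fraction(ann, sched).itertuples():
                c = cls_at(row.flash_onset)
                if c in frac:
                    frac[c].append(row.fraction)
        assert np.mean(frac["DOWN"]) > np.mean(frac["UP"])


class TestRegressionAndExtrema:
    def test_flat_stop_probability_gives_zero_slope(self):
        rng = np.random.default_rng(2)
        trials = pd.DataFrame({
            "pre_speed": rng.uniform(0.2, 1.4, 120),
            "stopped": ([True] * 60 + [False] * 60),
        })
        res = lt.stopprob_vs_prespeed(trials, n_bins=6)
        assert abs(res["slope"]) < 0.3
        assert res["r2"] < 0.5

    def test_perfectly_linear_bins_r2_one(self):
        pre = np.repeat(np.arange(1, 7, dtype=float), 10)
        stopped = np.concatenate([
            [True] * k + [False] * (10 - k) for k in range(1, 7)
        ])
        res = lt.stopprob_vs_prespeed(pd.DataFrame({"pre_speed": pre, "stopped": stopped}))
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(0.1)

    def test_degenerate_speeds_flagged(self):
        trials = pd.DataFrame({"pre_speed": np.ones(20), "stopped": [True] * 20})
        assert lt.stopprob_vs_prespeed(trials)["degenerate"]

    def test_extrema_monotone_and_constant_rows(self):
        time = np.linspace(-2, 8, 101)
        dec = np.linspace(10, 0, 101)
        const = np.full(101, 3.0)
        meta = pd.DataFrame({"trial": [0, 1], "flash_duration": [6.0, 6.0]})
        aligned = lt.TrialAlignedSet(time=time, values=np.vstack([dec, const]),
                                     meta=meta, window=(2, 8))
        res = lt.per_trial_extrema(aligned, kind="min")
        in_flash = dec[(time >= 0) & (time <= 6.0)]
        assert res["value"].iloc[0] == pytest.approx(in_flash.min())
        assert res["value"].iloc[1] == 3.0
        res_max = lt.per_trial_extrema(aligned, kind="max")
        assert res_max["value"].iloc[1] == 3.0

    def test_pooled_simulator_minima_bimodal(self):
        sched = lt.FlashSchedule.periodic(n=6)
        cfg = lt.SimulationConfig(seed=3, duration=260.0, genotype="chrimson",
                                  p_stop=0.5, baseline_hazard=0.5)
        sets = []
        for traj, truth in lt.simulate_cohort(cfg, 6, flashes=sched):
            kin = lt.derive_kinematics(traj)
            # cycle-averaged speed: the raw tail speed dips near zero within
            # every peristaltic cycle, so extrema use a 1-s moving average
            smooth = np.convolve(kin.tail_speed, np.ones(20) / 20, mode="same")
            sets.append(lt.align_to_flashes(kin.t, smooth, sched,
                                            window=(2.0, 8.0)))
        pooled = concat_aligned(sets)
        res = lt.per_trial_extrema(pooled, kind="min")
        vals = res["value"].to_numpy()
        assert (vals < 0.25).any() and (vals > 0.5).any()
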