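"""Perturbation statistics: pre/post contrasts, latencies, effect sizes."""

import numpy as np
import pytest

from gapcross import (
    StimEpoch,
    SynthConfig,
    apply_stim_effect,
    compute_joint_angles,
    generate_trial,
    hedges_g,
    hedges_j,
    movement_latency,
    oneway_anova_tukey,
    paired_t,
    prepost_angles,
    timepoint_contrast,
    welch_t,
)
from gapcross.kinematics import JointAngleSeries


def _angle_series(values):
    return JointAngleSeries(joint="hip", triplet=("shoulder", "hip", "knee"),
                            angle_deg=np.asarray(values, float))


class TestPrePost:
    def test_constant_angle_equal_means(self):
        t = np.arange(-200.0, 200.0, 2.0)
        series = _angle_series(np.full(t.size, 95.0))
        epoch = StimEpoch(onset_ms=0.0, duration_ms=50.0)
        pre, post = prepost_angles(series, t, epoch, pre_ms=50, post_ms=50)
        assert pre == post == pytest.approx(95.0)

    def test_step_change_at_epoch_end(self):
        t = np.arange(-200.0, 200.0, 2.0)
        vals = np.where(t < 50.0, 120.0, 60.0)
        epoch = StimEpoch(onset_ms=0.0, duration_ms=50.0)
        pre, post = prepost_angles(_angle_series(vals), t, epoch,
                                   pre_ms=50, post_ms=50)
        assert pre == pytest.approx(120.0)
        assert post == pytest.approx(60.0)

    def test_flex_drive_post_below_pre_all_joints(self):
        cfg = SynthConfig().noiseless()
        trial, _ = generate_trial(cfg, "A0", 15.0, seed=0)
        epoch = StimEpoch(onset_ms=-100.0, duration_ms=50.0)
        out, _ = apply_stim_effect(trial, [], epoch, "flex_drive",
                                   latency_ms=5.0)
        for s in compute_joint_angles(out):
            pre, post = prepost_angles(s, out.relative_time_ms, epoch,
                                       pre_ms=40, post_ms=20)
            assert post < pre  # flexion decreases the joint angle

    def test_overlapping_windows_rejected(self):
        t = np.arange(-200.0, 200.0, 2.0)
        epoch = StimEpoch(onset_ms=0.0, duration_ms=-1.0) if False else StimEpoch(0.0, 50.0)
        with pytest.raises(ValueError):
            prepost_angles(_angle_series(np.zeros(t.size)), t,
                           StimEpoch(onset_ms=0.0, duration_ms=10.0),
                           pre_ms=-20, post_ms=50)


class TestPairedT:
    def test_no_change_t_zero_p_one(self):
        res = paired_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert res.t == 0.0 and res.p == 1.0

    def test_differences_one_two_three(self):
        res = paired_t(np.zeros(3), np.array([1.0, 2.0, 3.0]))
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert res.df == 2

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(0)
        pre = rng.normal(size=8)
        post = pre + rng.normal(size=8)
        r1 = paired_t(pre, post)
        r2 = paired_t(post, pre)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)


class TestWelch:
    def test_identical_samples_t_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert welch_t(x, x.copy()).t == 0.0

    def test_equal_variance_equal_n_matches_pooled_t(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 1, 10)
        ours = welch_t(x, y)
        pooled = stats.ttest_ind(x, y, equal_var=True)
        # algebraic identity when n1 == n2
        assert ours.t == pytest.approx(float(pooled.statistic), abs=1e-12)

    def test_hand_computed_example(self):
        res = welch_t(np.array([0.0, 1.0]), np.array([2.0, 3.0]))
        assert res.t == pytest.approx(-2 * np.sqrt(2), abs=1e-12)
        assert res.df == pytest.approx(2.0, abs=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 6), rng.normal(1, 2, 6)
        r1, r2 = welch_t(x, y), welch_t(x + 100.0, y + 100.0)
        assert r1.t == pytest.approx(r2.t)
        assert r1.g == pytest.approx(r2.g)

    def test_type_one_error_calibrated(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (2000, 6))
        y = rng.normal(0, 1, (2000, 6))
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
        rate = float((res.pvalue < 0.05).mean())
        assert 0.03 <= rate <= 0.07


class TestHedgesG:
    def test_equal_means_zero(self):
        assert hedges_g(np.array([1.0, 2, 3]), np.array([3.0, 2, 1])) == 0.0

    def test_correction_factor_for_six_vs_six(self):
        # n1 = n2 = 6: df = 10, J = 1 - 3/(4*10 - 1) = 1 - 3/39
        assert hedges_j(10) == pytest.approx(0.923077, abs=1e-6)

    def test_unit_pooled_sd_example(self):
        # x, y with mean difference 1 and pooled SD exactly 1 (n = 3 + 3):
        # g = J(4) * 1 = 1 - 3/15 = 0.8
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 2.0])
        assert hedges_g(x, y) == pytest.approx(0.8, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(2, 1, 8), rng.normal(0, 1, 8)
        assert hedges_g(3 * x, 3 * y) == pytest.approx(hedges_g(x, y))

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        x, y = rng.normal(1, 1, 9), rng.normal(0, 2, 7)
        assert hedges_g(x, y) == pytest.approx(
            float(pg.compute_effsize(x, y, eftype="hedges")), abs=1e-10
        )

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            hedges_g(np.ones(3), np.ones(3))


class TestMovementLatency:
    def test_injected_latency_recovered_within_one_frame(self):
        cfg = SynthConfig().noiseless()
        trial, _ = generate_trial(cfg, "A0", 15.0, seed=0)
        epoch = StimEpoch(onset_ms=-100.0, duration_ms=50.0)
        out, _ = apply_stim_effect(trial, [], epoch, "flex_drive",
                                   latency_ms=10.0)
        hip = next(a for a in compute_joint_angles(out) if a.joint == "hip")
        lat = movement_latency(hip.angle_deg, out.relative_time_ms, epoch,
                               baseline_ms=50.0)
        frame_ms = 1000.0 / trial.frame_rate
        assert lat.onset_latency_ms == pytest.approx(10.0, abs=frame_ms + 1e-9)

    def test_constant_series_flagged(self):
        t = np.arange(-200.0, 200.0, 2.0)
        lat = movement_latency(np.full(t.size, 90.0), t,
                               StimEpoch(onset_ms=0.0, duration_ms=50.0))
        assert lat.flagged and lat.onset_latency_ms is None

    def test_max_latency_at_least_onset(self):
        rng = np.random.default_rng(0)
        t = np.arange(-200.0, 200.0, 2.0)
        sig = np.where(t >= 20.0, 50.0 * np.sin((t - 20) / 40.0), 0.0)
        sig = sig + rng.normal(0, 0.1, t.size)
        lat = movement_latency(sig, t, StimEpoch(onset_ms=0.0, duration_ms=50.0))
        assert lat.onset_latency_ms is not None
        assert lat.max_latency_ms >= lat.onset_latency_ms


class TestTimepointContrast:
    def test_identical_conditions_all_p_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 10))
        df = timepoint_contrast(a, a.copy(), np.arange(10) * 2.0)
        assert np.allclose(df["t"], 0.0)
        assert np.allclose(df["p"], 1.0)

    def test_bh_step_up_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.03, 0.04])
        adj = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)

    def test_stim_effect_localized_in_epoch(self):
        cfg = SynthConfig()
        epoch = StimEpoch(onset_ms=20.0, duration_ms=50.0, phase_label="flight")
        hits = 0
        for seed in range(20):
            ctrl_rows, stim_rows = [], []
            for animal in range(6):
                trial, _ = generate_trial(cfg, f"A{animal}", 15.0,
                                          seed=1000 * seed + animal)
                hip_c = next(a for a in compute_joint_angles(trial)
                             if a.joint == "hip")
                stim, _ = apply_stim_effect(trial, [], epoch, "flex_drive",
                                            latency_ms=10.0)
                hip_s = next(a for a in compute_joint_angles(stim)
                             if a.joint == "hip")
                ctrl_rows.append(hip_c.angle_deg)
                stim_rows.append(hip_s.angle_deg)
            ctrl = np.stack(ctrl_rows)
            stim_arr = np.stack(stim_rows)
            times = trial.relative_time_ms
            df = timepoint_contrast(ctrl, stim_arr, times)
            t_min = df.loc[df["p_adj"].idxmin(), "time_ms"]
            if epoch.onset_ms <= t_min <= epoch.offset_ms + 30.0:
                hits += 1
        assert hits >= 18

    def test_unknown_correction_rejected(self):
        with pytest.raises(ValueError):
            timepoint_contrast(np.zeros((3, 2)), np.zeros((3, 2)),
                               np.zeros(2), correction="bonferroni")


class TestAnova:
    def test_identical_groups_f_zero(self):
        g = {"a": np.array([1.0, 2, 3]), "b": np.array([1.0, 2, 3])}
        assert oneway_anova_tukey(g)["F"] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        res = oneway_anova_tukey(
            {"g1": np.array([1.0, 2.0, 3.0]), "g2": np.array([4.0, 5.0, 6.0])}
        )
        assert res["F"] == pytest.approx(13.5, abs=1e-9)
        assert (res["df1"], res["df2"]) == (1, 4)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        g = {k: rng.normal(i, 1, 6) for i, k in enumerate("abc")}
        f1 = oneway_anova_tukey(g)["F"]
        f2 = oneway_anova_tukey({k: v + 42.0 for k, v in g.items()})["F"]
        assert f1 == pytest.approx(f2)

    def test_flight_durations_separate_across_distances(self, default_config):
        from gapcross import compute_acceleration, phase_durations, segment_phases

        groups = {}
        for d in (10.0, 15.0, 20.0):
            durs = []
            for seed in range(8):
                trial, _ = generate_trial(default_config, "A0", d, seed=seed)
                seg = segment_phases(
                    compute_acceleration(trial, "hindpaw"), trial.frame_rate
                )
                durs.append(phase_durations(seg, trial.frame_rate)["flight"])
            groups[str(d)] = np.array(durs)
        res = oneway_anova_tukey(groups)
        assert res["p"] < 0.001
        assert all(p < 0.05 for p in res["tukey"].values())

    def test_tukey_matches_r_reference(self):
        # oracle frozen from R: TukeyHSD(aov(y ~ g)) on the fixture below
        g = {
            "a": np.array([1.0, 2.0, 3.0, 4.0]),
            "b": np.array([3.0, 4.0, 5.0, 6.0]),
            "c": np.array([7.0, 8.0, 9.0, 10.0]),
        }
        res = oneway_anova_tukey(g)
        assert res["tukey"][("a", "b")] == pytest.approx(0.1263089, abs=1e-4)
        assert res["tukey"][("a", "c")] == pytest.approx(0.0002699, abs=2e-5)
        assert res["tukey"][("b", "c")] == pytest.approx(0.0045122, abs=1e-4)
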