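"""Generator tests: kinematics, spiking, raw synthesis, determinism, I/O."""

import dataclasses

import numpy as np
import pytest

from spindec.synthetic import (
    GroundTruth,
    RawRecording,
    SimConfig,
    config_from_yaml,
    simulate_kinematics,
    simulate_session,
    simulate_units,
    spike_template,
    synthesize_raw,
)


def quiet_config(**kw) -> SimConfig:
    """Config with every additive component off except what the test enables."""
    base = dict(
        seed=0, duration_s=10.0, n_channels=4, n_units=0, noise_rms_uv=0.0,
        pink_rms_uv=0.0, mains_amp_uv=0.0, lfp_locked_amp_uv=0.0,
        artifact_rate_hz=0.0, moving_fraction=1.0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestKinematics:
    def test_stationary_only_has_no_toe_excursion(self):
        kin = simulate_kinematics(SimConfig(seed=1, duration_s=5.0, moving_fraction=0.0))
        assert (kin.state == "stationary").all()
        assert kin.x["toe"].std() < 1.0  # tracking jitter only (0.3 px)

    def test_toe_oscillates_at_step_frequency(self):
        cfg = SimConfig(seed=2, duration_s=10.0, step_freq_hz=3.5, moving_fraction=1.0)
        kin = simulate_kinematics(cfg)
        x = kin.x["toe"] - kin.x["toe"].mean()
        freqs = np.fft.rfftfreq(len(x), d=1.0 / cfg.fs_video)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
        assert abs(peak - 3.5) <= freqs[1]  # within the DFT resolution

    def test_toe_has_largest_excursion(self):
        kin = simulate_kinematics(SimConfig(seed=3, duration_s=8.0, moving_fraction=1.0))
        spans = {j: kin.x[j].max() - kin.x[j].min() for j in kin.x}
        assert max(spans, key=spans.get) == "toe"

    def test_swing_stance_partition_moving_frames(self):
        kin = simulate_kinematics(SimConfig(seed=4, duration_s=10.0))
        moving = kin.state == "moving"
        assert set(np.unique(kin.phase_label[moving])) <= {"swing", "stance"}
        # phase increases modulo 2*pi inside moving bouts
        phi = kin.phase[moving]
        d = np.mod(np.diff(phi), 2 * np.pi)
        assert (d[d > 1e-12] < np.pi).all()

    def test_frame_spacing_matches_video_rate(self):
        kin = simulate_kinematics(SimConfig(seed=4, duration_s=5.0))
        assert np.allclose(np.diff(kin.frame_times_s), 1.0 / 60.0)

    def test_too_short_session_rejected(self):
        with pytest.raises(ValueError, match="3 full step cycles"):
            simulate_kinematics(SimConfig(seed=0, duration_s=0.5, step_freq_hz=3.5))

    def test_deterministic_under_seed(self):
        a = simulate_kinematics(SimConfig(seed=9, duration_s=6.0))
        b = simulate_kinematics(SimConfig(seed=9, duration_s=6.0))
        for j in a.x:
            np.testing.assert_array_equal(a.x[j], b.x[j])
        np.testing.assert_array_equal(a.phase, b.phase)


class TestUnits:
    def test_flat_tuning_gives_constant_mean_rate(self):
        # kappa=0 removes phase tuning: the rate is the peak rate throughout
        cfg = quiet_config(
            n_units=20, tuning_concentration=0.0, base_rate_hz=20.0,
            peak_rate_hz=20.0, refractory_ms=0.1, duration_s=20.0,
        )
        kin = simulate_kinematics(cfg)
        gt = simulate_units(cfg, kin)
        counts = np.array([len(st) for st in gt.spike_times])
        expected = 20.0 * cfg.duration_s
        se = np.sqrt(expected)
        # each unit within 3 SE of the Poisson expectation (tiny refractory loss)
        assert (np.abs(counts - expected) <= 3 * se + 0.002 * expected).all()

    def test_degenerate_footprint_is_single_site(self):
        cfg = quiet_config(n_units=10, footprint_lambda_um=1e-9)
        kin = simulate_kinematics(cfg)
        gt = simulate_units(cfg, kin)
        assert ((gt.amplitudes_uv > 1e-6).sum(axis=1) == 1).all()

    def test_refractory_period_respected(self):
        cfg = quiet_config(n_units=15, refractory_ms=2.0, peak_rate_hz=120.0)
        kin = simulate_kinematics(cfg)
        gt = simulate_units(cfg, kin)
        for st in gt.spike_times:
            if len(st) > 1:
                assert np.diff(st).min() >= 0.002 - 1e-12

    def test_amplitude_decays_with_distance(self):
        cfg = quiet_config(n_units=8)
        gt = simulate_units(cfg, simulate_kinematics(cfg))
        pos = cfg.channel_positions_um()
        for u in range(8):
            d = np.abs(pos - pos[gt.home_channel[u]])
            order = np.argsort(d)
            assert (np.diff(gt.amplitudes_uv[u][order]) <= 1e-12).all()

    def test_peak_below_base_rejected(self):
        cfg = quiet_config(base_rate_hz=10.0, peak_rate_hz=5.0)
        with pytest.raises(ValueError, match="peak_rate"):
            cfg.validate()


class TestRawSynthesis:
    def test_noise_only_rms(self):
        cfg = quiet_config(noise_rms_uv=8.0)
        rec = synthesize_raw(simulate_units(cfg, simulate_kinematics(cfg)),
                             simulate_kinematics(cfg), cfg)
        rms = np.sqrt((rec.to_uv() ** 2).mean(axis=1))
        assert np.allclose(rms, 8.0, rtol=0.02)

    def test_spike_times_sit_at_local_minima(self):
        cfg = quiet_config(n_units=1, base_rate_hz=5.0, peak_rate_hz=5.0,
                           refractory_ms=2.0)
        kin = simulate_kinematics(cfg)
        gt = simulate_units(cfg, kin)
        rec = synthesize_raw(gt, kin, cfg)
        x = rec.to_uv()[gt.home_channel[0]]
        half = int(0.3e-3 * cfg.fs_raw)
        for t in gt.spike_times[0]:
            i = int(round(t * cfg.fs_raw))
            if i - half < 0 or i + half >= len(x):
                continue
            j = i - half + np.argmin(x[i - half : i + half + 1])
            assert abs(j - i) / cfg.fs_raw <= 0.1e-3

    def test_artifact_windows_have_high_variance(self):
        cfg = quiet_config(noise_rms_uv=5.0, artifact_rate_hz=0.5,
                           artifact_amp_uv=100.0)
        kin = simulate_kinematics(cfg)
        gt = simulate_units(cfg, kin)
        rec = synthesize_raw(gt, kin, cfg)
        x = rec.to_uv()
        assert gt.artifact_intervals, "expected at least one artifact"
        for s, e in gt.artifact_intervals:
            seg = x[:, int(s * cfg.fs_raw) : int(e * cfg.fs_raw)]
            assert seg.std(axis=1).min() > 25.0

    def test_component_variances_add(self):
        # uncorrelated components: total variance ~ sum of single-component variances
        parts = ["noise_rms_uv", "pink_rms_uv", "mains_amp_uv", "lfp_locked_amp_uv"]
        full = quiet_config(noise_rms_uv=6.0, pink_rms_uv=4.0, mains_amp_uv=5.0,
                            lfp_locked_amp_uv=20.0)
        def variance(cfg):
            rec = synthesize_raw(simulate_units(cfg, simulate_kinematics(cfg)),
                                 simulate_kinematics(cfg), cfg)
            return rec.to_uv().var(axis=1)
        total = variance(full)
        component_sum = np.zeros_like(total)
        for p in parts:
            cfg = quiet_config(**{p: getattr(full, p)})
            component_sum += variance(cfg)
        assert np.allclose(total, component_sum, rtol=0.05)

    def test_template_is_biphasic_with_dominant_trough(self):
        w = spike_template(20000.0)
        assert w.min() == -1.0
        assert 0.0 < w.max() < 0.6
        assert np.argmin(w) == len(w) // 2

    def test_int16_headroom_under_default_config(self):
        rec, _, _ = simulate_session(SimConfig(seed=3, duration_s=5.0))
        assert np.abs(rec.samples).max() < 2**15 - 1

    def test_session_deterministic_under_seed(self):
        r1, k1, g1 = simulate_session(SimConfig(seed=21, duration_s=4.0, n_channels=8, n_units=6))
        r2, k2, g2 = simulate_session(SimConfig(seed=21, duration_s=4.0, n_channels=8, n_units=6))
        np.testing.assert_array_equal(r1.samples, r2.samples)
        for a, b in zip(g1.spike_times, g2.spike_times):
            np.testing.assert_array_equal(a, b)


class TestIO:
    def test_raw_recording_round_trip(self, tmp_path):
        rec, _, _ = simulate_session(SimConfig(seed=2, duration_s=4.0, n_channels=6, n_units=4))
        rec.write(tmp_path / "rec")
        back = RawRecording.read(tmp_path / "rec")
        np.testing.assert_array_equal(rec.samples, back.samples)
        assert back.fs == rec.fs
        np.testing.assert_array_equal(back.channel_positions_um, rec.channel_positions_um)

    def test_kinematics_csv_round_trip(self, tmp_path):
        import pandas as pd

        kin = simulate_kinematics(SimConfig(seed=2, duration_s=4.0))
        kin.write_csv(tmp_path / "kin.csv")
        df = pd.read_csv(tmp_path / "kin.csv")
        assert list(df.columns[:2]) == ["frame", "time_s"]
        np.testing.assert_allclose(df["toe_x"].to_numpy(), kin.x["toe"])
        assert set(df["state"]) <= {"moving", "stationary"}

    def test_ground_truth_json_round_trip(self, tmp_path):
        cfg = quiet_config(n_units=3, noise_rms_uv=2.0)
        kin = simulate_kinematics(cfg)
        gt = simulate_units(cfg, kin)
        synthesize_raw(gt, kin, cfg)
        gt.to_json(tmp_path / "gt.json")
        back = GroundTruth.from_json(tmp_path / "gt.json")
        for a, b in zip(gt.spike_times, back.spike_times):
            np.testing.assert_allclose(a, b)
        np.testing.assert_allclose(gt.amplitudes_uv, back.amplitudes_uv)

    def test_yaml_config_rejects_unknown_keys(self, tmp_path):
        p = tmp_path / "sim.yaml"
        p.write_text("seed: 3\nduration_s: 5.0\nnot_a_field: 1\n")
        with pytest.raises(ValueError, match="unknown"):
            config_from_yaml(p)

    def test_yaml_config_round_trip(self, tmp_path):
        p = tmp_path / "sim.yaml"
        p.write_text("seed: 3\nduration_s: 5.0\nn_channels: 8\n")
        cfg = config_from_yaml(p)
        assert cfg == dataclasses.replace(SimConfig(), seed=3, duration_s=5.0, n_channels=8)
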