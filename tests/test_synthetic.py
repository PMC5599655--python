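"""The cohort generator: determinism, spectral fidelity, planted effects."""

import numpy as np
import pytest

from calmflow.spectral import (DEFAULT_BANDS, band_amplitudes, rereference,
                               segment_session, session_band_table)
from calmflow.synthetic import (DEFAULT_CARRIERS, OutlierSpec,
                                SimulationConfig, generate_cohort,
                                generate_eeg_recording, generate_environment,
                                generate_task_log, generate_thermogram)


class TestDeterminism:
    def test_recordings_bit_identical_for_same_seed(self, small_config):
        a = generate_eeg_recording(2, "RS", small_config)
        b = generate_eeg_recording(2, "RS", small_config)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.session_spans == b.session_spans

    def test_streams_differ_across_participants_and_conditions(
            self, small_config):
        a = generate_eeg_recording(1, "AC", small_config)
        b = generate_eeg_recording(2, "AC", small_config)
        c = generate_eeg_recording(1, "RS", small_config)
        assert not np.array_equal(a.samples[:, :1000], b.samples[:, :1000])
        assert not np.array_equal(a.samples[:, :1000], c.samples[:, :1000])

    def test_adding_participants_leaves_existing_data_unchanged(
            self, small_config):
        a = generate_eeg_recording(1, "AC", small_config)
        bigger = SimulationConfig(**{**vars(small_config),
                                     "n_participants": 6})
        b = generate_eeg_recording(1, "AC", bigger)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_thermograms_identical_for_same_seed(self, small_config):
        f1, m1 = generate_thermogram(1, "AC", "first", small_config)
        f2, m2 = generate_thermogram(1, "AC", "first", small_config)
        np.testing.assert_array_equal(f1.temperatures, f2.temperatures)
        np.testing.assert_array_equal(m1, m2)


class TestEEGSignalModel:
    def test_null_config_gives_all_zero_channels(self):
        cfg = SimulationConfig(
            n_participants=1, session_length=4.0, session_jitter=0.0,
            band_effect={b: (0.0, 0.0) for b in DEFAULT_CARRIERS},
            noise_sigma_uV=0.0, participant_amp_sigma=0.0,
            session_amp_sigma_uV=0.0, seed=0)
        rec = generate_eeg_recording(1, "AC", cfg)
        np.testing.assert_array_equal(rec.samples, 0.0)

    def test_planted_gamma_carrier_recovered_by_dft(self, clean_tone_config):
        cfg = clean_tone_config
        for cond, expected in (("RS", 0.8), ("AC", 1.1)):
            rec = generate_eeg_recording(1, cond, cfg)
            block = segment_session(rec, 1, 1)[0][0]  # Fz, whole session
            n = len(block)
            spec = np.abs(np.fft.rfft(block)) * 2.0 / n
            k40 = int(round(40.0 * n / cfg.sampling_rate))
            assert spec[k40] == pytest.approx(expected, rel=1e-6)

    def test_ac_rs_amplitude_gap_equals_configured_offset(
            self, clean_tone_config):
        ac = generate_eeg_recording(3, "AC", clean_tone_config)
        rs = generate_eeg_recording(3, "RS", clean_tone_config)
        for s in range(1, clean_tone_config.n_sessions + 1):
            for band, (rs_mean, offset) in \
                    clean_tone_config.band_effect.items():
                gap = (ac.meta["true_amplitudes"][(s, band)]
                       - rs.meta["true_amplitudes"][(s, band)])
                assert gap == pytest.approx(offset, abs=1e-12)

    def test_spectral_energy_only_at_carriers_when_noise_off(
            self, clean_tone_config):
        rec = generate_eeg_recording(1, "AC", clean_tone_config)
        block = segment_session(rec, 1, 1)[0][0]
        n = len(block)
        spec = np.abs(np.fft.rfft(block)) * 2.0 / n
        carrier_bins = {int(round(f * n / clean_tone_config.sampling_rate))
                        for f in DEFAULT_CARRIERS.values()}
        others = np.delete(spec, sorted(carrier_bins | {0}))
        assert others.max() < 1e-8

    def test_reference_channels_are_attenuated_common_noise(self):
        cfg = SimulationConfig(n_participants=1, session_length=4.0,
                               session_jitter=0.0,
                               band_effect={"gamma": (0.0, 0.0)},
                               carrier_freqs={"gamma": 40.0},
                               participant_amp_sigma=0.0,
                               session_amp_sigma_uV=0.0, seed=2)
        rec = generate_eeg_recording(1, "AC", cfg)
        a1, a2 = rec.channel("A1"), rec.channel("A2")
        np.testing.assert_array_equal(a1, a2)
        # scalp channels equal the common noise here; A1 = 0.2 x that
        np.testing.assert_allclose(a1, 0.2 * rec.channel("Fz"), rtol=1e-12)

    def test_rereferencing_preserves_planted_band_amplitudes(
            self, clean_tone_config):
        cfg = SimulationConfig(**{**vars(clean_tone_config),
                                  "noise_sigma_uV": 1.0})
        rec = generate_eeg_recording(1, "AC", cfg)
        before = band_amplitudes(segment_session(rec, 1, 1)[0][0],
                                 cfg.sampling_rate)
        after_rec = rereference(rec)
        after = band_amplitudes(segment_session(after_rec, 1, 1)[0][0],
                                cfg.sampling_rate)
        assert not np.array_equal(rec.channel("Fz"), after_rec.channel("Fz"))
        # carriers live only on scalp channels, so band means shift only
        # through the attenuated noise, not through the planted tones
        for band, (rs_mean, offset) in cfg.band_effect.items():
            if rs_mean + offset > 0:
                assert after[band] == pytest.approx(before[band], rel=0.25)

    def test_guided_first_session_has_exact_length(self, small_config):
        rec = generate_eeg_recording(1, "AC", small_config)
        s1 = rec.session_spans[0]
        assert s1[2] - s1[1] == pytest.approx(
            small_config.session_length, abs=1e-9)


class TestEnvironment:
    @pytest.mark.parametrize("season,cond,med", [
        ("cooling", "AC", 1.1), ("cooling", "RS", 0.0033),
        ("heating", "AC", 0.61), ("heating", "RS", 0.071),
    ])
    def test_velocity_median_approaches_target(self, season, cond, med):
        cfg = SimulationConfig(n_participants=1, season=season,
                               env_n_samples=20000, seed=1)
        env = generate_environment(cond, cfg)
        got = np.median(env["velocity"])
        assert got == pytest.approx(med, rel=0.15)
        assert (env["velocity"] >= 0).all()

    def test_temperature_median_and_iqr(self):
        cfg = SimulationConfig(n_participants=1, season="cooling",
                               env_n_samples=20000, seed=1)
        env = generate_environment("AC", cfg)
        assert np.median(env["temperature"]) == pytest.approx(25.0, abs=0.1)
        q75, q25 = np.percentile(env["temperature"], [75, 25])
        assert q75 - q25 == pytest.approx(1.6, rel=0.1)

    def test_zero_variance_targets_give_constant_series(self):
        cfg = SimulationConfig(
            n_participants=1,
            env_targets={"AC": {"temperature": (25.0, 0.0),
                                "velocity": (1.0, 0.0)},
                         "RS": {"temperature": (24.0, 0.0)}},
            seed=0)
        env = generate_environment("AC", cfg)
        assert (env["temperature"] == 25.0).all()
        assert (env["velocity"] == 1.0).all()

    def test_missing_targets_error(self):
        cfg = SimulationConfig(n_participants=1, seed=0)
        cfg.env_targets = {"AC": {"temperature": (25.0, 1.0)}}
        with pytest.raises(ValueError, match="RS"):
            cfg.validate()


class TestTaskLog:
    def test_guided_session_ttl_exactly_sixty(self, small_config):
        log = generate_task_log(1, "AC", small_config)
        assert log.ttl(1) == 60.0
        np.testing.assert_array_equal(log.presses[1],
                                      [10, 20, 30, 40, 50, 60])

    def test_noise_free_null_effect_gives_sixty_everywhere(self):
        cfg = SimulationConfig(n_participants=1, ttl_effect=0.0,
                               ttl_interval_sigma=0.0, seed=0)
        log = generate_task_log(1, "RS", cfg)
        for s in log.sessions:
            assert log.ttl(s) == pytest.approx(60.0)

    def test_rs_minus_ac_ttl_difference_recovers_configured_effect(self):
        diffs = []
        for pid in range(1, 121):
            cfg = SimulationConfig(n_participants=121, ttl_effect=6.0,
                                   seed=9)
            rs = generate_task_log(pid, "RS", cfg)
            ac = generate_task_log(pid, "AC", cfg)
            for s in range(2, cfg.n_sessions + 1):
                diffs.append(rs.ttl(s) - ac.ttl(s))
        assert np.mean(diffs) == pytest.approx(6.0, abs=0.5)

    def test_expected_ttl_strictly_increases_with_effect(self):
        means = []
        for effect in (0.0, 3.0, 6.0, 12.0):
            cfg = SimulationConfig(n_participants=30, ttl_effect=effect,
                                   ttl_interval_sigma=0.5, seed=4)
            ttls = [generate_task_log(p, "RS", cfg).ttl(s)
                    for p in range(1, 31) for s in (2, 3, 4, 5)]
            means.append(np.mean(ttls))
        assert means == sorted(means)
        assert all(b > a for a, b in zip(means, means[1:]))


class TestThermograms:
    def test_noise_free_frame_has_exactly_two_values(self):
        cfg = SimulationConfig(n_participants=1, thermo_noise_sigma=0.0,
                               thermo_participant_sigma=0.0, seed=0)
        frame, mask = generate_thermogram(1, "AC", "first", cfg)
        assert set(np.unique(frame.temperatures)) == {25.0, 33.0}
        assert frame.temperatures[mask].min() == 33.0

    def test_planted_cooling_drop_visible_in_skin_pixels(self, small_config):
        first, m1 = generate_thermogram(1, "AC", "first", small_config)
        last, m2 = generate_thermogram(1, "AC", "last", small_config)
        drop = last.temperatures[m2].mean() - first.temperatures[m1].mean()
        assert drop < 0  # AC cooling lowers skin temperature by design

    def test_equal_skin_and_background_warns(self):
        cfg = SimulationConfig(n_participants=1, seed=0)
        cfg.thermo_skin[("AC", "first")] = cfg.thermo_background
        with pytest.warns(UserWarning, match="unidentifiable"):
            generate_thermogram(1, "AC", "first", cfg)


class TestCohortAssembly:
    def test_every_participant_in_both_conditions(self, small_config):
        cohort = generate_cohort(small_config)
        for pid in small_config.participants:
            assert (pid, "AC") in cohort.recordings
            assert (pid, "RS") in cohort.recordings
            assert (pid, "AC") in cohort.task_logs

    def test_outlier_plan_perturbs_only_named_participant(self):
        plan = [OutlierSpec(participant=3, kind="delta_amplitude",
                            value=10.0)]
        cfg = SimulationConfig(n_participants=3, session_length=10.0,
                               outlier_plan=plan, seed=6)
        clean = SimulationConfig(n_participants=3, session_length=10.0,
                                 seed=6)
        pert = generate_eeg_recording(3, "AC", cfg)
        base = generate_eeg_recording(2, "AC", cfg)
        base_clean = generate_eeg_recording(2, "AC", clean)
        assert pert.meta["true_amplitudes"][(1, "delta")] > 6.0
        np.testing.assert_array_equal(base.samples, base_clean.samples)

    def test_unknown_participant_in_plan_errors(self):
        with pytest.raises(ValueError, match="unknown participant"):
            SimulationConfig(n_participants=2, outlier_plan=[
                OutlierSpec(participant=9, kind="ttl_shift", value=50.0)])

    def test_truth_records_plan_and_amplitudes(self, small_config):
        cohort = generate_cohort(small_config)
        assert cohort.truth["band_effect"]["gamma"] == (0.8, 0.3)
        assert "1:AC" in cohort.truth["true_amplitudes"]

    def test_ttl_table_differentials(self, small_config):
        tab = generate_cohort(small_config).ttl_table()
        s1 = tab[tab["session"] == 1]
        assert (s1["ttl_differential_s"] == 0.0).all()
        assert len(tab) == 3 * 2 * small_config.n_sessions
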