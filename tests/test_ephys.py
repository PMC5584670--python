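"""Seal-test signal chain, impedance simulator, seal/break-in logic."""
import numpy as np
import pytest
from scipy import signal as sps

from patchrig import ephys


class TestWaveform:
    def test_construction(self):
        cfg = ephys.SealTestConfig()
        v = ephys.seal_test_waveform(cfg, 1.0)
        assert v.size == 20000
        assert set(np.unique(v)) == {0.0, 10.0}
        # 10 cycles: 10 rising transitions
        rises = np.sum(np.diff(v) > 0)
        assert rises in (9, 10)

    def test_peak_to_peak_10mv(self):
        cfg = ephys.SealTestConfig()
        v = ephys.seal_test_waveform(cfg, 0.5)
        assert v.max() - v.min() == pytest.approx(10.0)

    def test_holding_offset(self):
        cfg = ephys.SealTestConfig(holding_potential=-70.0)
        v = ephys.seal_test_waveform(cfg, 0.2)
        assert set(np.unique(v)) == {-70.0, -60.0}

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError):
            ephys.seal_test_waveform(ephys.SealTestConfig(), 0.05)


class TestBessel:
    def test_dc_gain_unity(self):
        cfg = ephys.SealTestConfig()
        out = ephys.bessel_lowpass(np.full(4000, 3.7), cfg)
        assert out[-1] == pytest.approx(3.7, rel=1e-6)

    def test_zeros_to_zeros(self):
        out = ephys.bessel_lowpass(np.zeros(1000), ephys.SealTestConfig())
        assert not out.any()

    def test_tone_attenuation_matches_analytic(self):
        cfg = ephys.SealTestConfig(filter_cutoff=2000.0)
        f_tone = 6000.0
        t = np.arange(20000) / cfg.sample_rate
        x = np.sin(2 * np.pi * f_tone * t)
        y = ephys.bessel_lowpass(x, cfg)
        sos = sps.bessel(cfg.filter_order, cfg.filter_cutoff, btype="low",
                         fs=cfg.sample_rate, output="sos")
        _, h = sps.sosfreqz(sos, worN=[f_tone], fs=cfg.sample_rate)
        expected = abs(h[0])
        measured = y[5000:].std() * np.sqrt(2)
        assert measured == pytest.approx(expected, rel=0.05)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            ephys.SealTestConfig(filter_cutoff=10000.0, sample_rate=20000.0)


class TestResistance:
    def _square_current(self, ipp_na, cfg, duration=0.5):
        v = ephys.seal_test_waveform(cfg, duration)
        return (v - v.min()) / (v.max() - v.min()) * ipp_na

    def test_5_megaohm_at_2na(self):
        cfg = ephys.SealTestConfig()
        est = ephys.estimate_resistance(10.0, self._square_current(2.0, cfg),
                                        cfg)
        assert est.megaohms == pytest.approx(5.0, abs=1e-12)

    def test_1_gigaohm_at_10pa(self):
        cfg = ephys.SealTestConfig()
        est = ephys.estimate_resistance(10.0, self._square_current(0.01, cfg),
                                        cfg)
        assert est.megaohms == pytest.approx(1000.0, rel=1e-12)

    def test_closed_loop_bath_within_0p1_percent(self):
        cfg = ephys.SealTestConfig()
        model = ephys.ImpedanceModel(r_bath=6.0)
        v = ephys.seal_test_waveform(cfg, 0.5)
        i, _ = ephys.impedance_response(model, v, 0.0, 1 / cfg.sample_rate)
        est = ephys.estimate_resistance(cfg.amplitude,
                                        ephys.bessel_lowpass(i, cfg), cfg)
        assert abs(est.megaohms - 6.0) / 6.0 < 1e-3

    def test_noise_floor_sentinel(self):
        cfg = ephys.SealTestConfig()
        est = ephys.estimate_resistance(10.0,
                                        self._square_current(1e-6, cfg), cfg)
        assert est.unmeasurable

    def test_per_cycle_list_length(self):
        cfg = ephys.SealTestConfig()
        est = ephys.estimate_resistance(10.0, self._square_current(2.0, cfg,
                                                                   1.0), cfg)
        assert len(est.per_cycle) == 10


class TestImpedanceModel:
    def test_bath_constant(self):
        m = ephys.ImpedanceModel(r_bath=6.0)
        for _ in range(10):
            m.evolve(0.5, 0.0)
        assert m.resistance == 6.0

    def test_contact_rises_by_factor(self):
        m = ephys.ImpedanceModel(r_bath=6.0, contact_factor=1.5,
                                 stage="contact")
        for _ in range(100):
            m.evolve(0.1, 0.0)
        assert m.resistance == pytest.approx(9.0, rel=0.01)

    def test_suction_and_hyperpolarization_accelerate_seal(self):
        def first_crossing(holding, pressure):
            m = ephys.ImpedanceModel(stage="sealing", resistance=9.0,
                                     holding_mv=holding)
            t = 0.0
            while m.resistance < 1000.0 and t < 300.0:
                m.evolve(0.1, pressure)
                t += 0.1
            return t

        assert first_crossing(-70.0, -2.0) < first_crossing(0.0, 0.0)

    def test_seal_efficacy_across_rates(self):
        """Hyperpolarization+suction wins for every seeded seal rate."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            rate = float(0.35 * rng.lognormal(0, 0.5))

            def t_cross(holding, pressure):
                m = ephys.ImpedanceModel(stage="sealing", resistance=9.0,
                                         holding_mv=holding, seal_rate=rate)
                t = 0.0
                while m.resistance < 1000.0 and t < 600.0:
                    m.evolve(0.1, pressure)
                    t += 0.1
                return t

            assert t_cross(-70.0, -2.0) < t_cross(0.0, 0.0)

    def test_sealing_monotone_nondecreasing(self):
        m = ephys.ImpedanceModel(stage="sealing", resistance=9.0,
                                 holding_mv=-70.0)
        prev = m.resistance
        for _ in range(200):
            r = m.evolve(0.1, -2.0)
            assert r >= prev - 1e-9
            prev = r

    def test_wholecell_access_resistance(self):
        m = ephys.ImpedanceModel(stage="wholecell")
        m.evolve(0.1, 0.0)
        assert m.resistance <= 2 * m.r_access_wholecell


class TestEngagement:
    def test_flat_false(self):
        assert not ephys.detect_engagement([6.0] * 30)

    def test_sustained_rise_true(self):
        r = [6.0] * 20 + [7.8] * 5
        assert ephys.detect_engagement(r)

    def test_single_spike_false(self):
        r = [6.0] * 20 + [9.0] + [6.0] * 2
        assert not ephys.detect_engagement(r)


class TestAdaptiveSuction:
    @pytest.mark.parametrize("r_now,rising,expect_deepen", [
        (50.0, False, True),    # low and stalled -> suction
        (200.0, False, False),  # above 15% of threshold -> hold
        (50.0, True, False),    # rising fast enough -> hold
        (200.0, True, False),
    ])
    def test_truth_table(self, r_now, rising, expect_deepen):
        policy = ephys.SuctionPolicy(seal_threshold=1000.0, s_th=5.0,
                                     t_seal=2.0)
        ts = np.arange(0.0, 4.1, 0.5)
        if rising:
            rs = np.linspace(r_now - 40.0, r_now, ts.size)  # 20 MOhm over 2 s
        else:
            rs = np.full(ts.size, r_now)
        action, sp = ephys.adaptive_suction_step(policy, rs, ts, 0.0)
        assert (action == "deepen") == expect_deepen
        if expect_deepen:
            assert sp == policy.suction_step

    def test_suction_bounded_by_vacuum(self):
        policy = ephys.SuctionPolicy(max_suction=-3.0)
        ts = np.arange(0.0, 4.1, 0.5)
        rs = np.full(ts.size, 10.0)
        sp = -2.5
        action, sp = ephys.adaptive_suction_step(policy, rs, ts, sp)
        assert sp == -3.0


class TestSealAndBreakin:
    def test_seal_threshold(self):
        policy = ephys.SuctionPolicy(seal_threshold=1000.0)
        assert ephys.detect_seal(1200.0, policy)
        assert not ephys.detect_seal(900.0, policy)

    def test_breakin_drop(self):
        r = [1500.0] * 5 + [16.0]
        assert ephys.detect_breakin(r)
        assert not ephys.detect_breakin([1500.0] * 6)

    def test_pulses_until_rupture(self):
        # cumulative doses 1.2, 2.7, 4.575 kPa*s -> threshold 4.0 ruptures at 3
        m = ephys.ImpedanceModel(stage="sealed", resistance=1500.0,
                                 rupture_threshold=4.0)
        applied = []
        ok, n = ephys.breakin_pulses(lambda a, d: applied.append((a, d)), m)
        assert ok and n == 3
        assert len(applied) == 3
        assert m.stage == "wholecell"

    def test_rupture_on_first_pulse(self):
        m = ephys.ImpedanceModel(stage="sealed", resistance=1500.0,
                                 rupture_threshold=1.0)
        ok, n = ephys.breakin_pulses(lambda a, d: None, m)
        assert ok and n == 1

    def test_budget_exhausted(self):
        m = ephys.ImpedanceModel(stage="sealed", resistance=1500.0,
                                 rupture_threshold=1e9)
        ok, n = ephys.breakin_pulses(lambda a, d: None, m)
        assert not ok and n == 10


class TestCheckPipette:
    def test_clean(self):
        assert ephys.check_pipette(6.0, 6.0) == "ok"

    def test_clogged(self):
        assert ephys.check_pipette(12.0, 6.0) == "clogged"

    def test_boundary_inclusive(self):
        assert ephys.check_pipette(9.0, 6.0, clog_factor=1.5) == "clogged"
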