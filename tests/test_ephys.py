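"""Leak subtraction, Boltzmann fits, half-height idealization and P_O."""

import numpy as np
import pytest

from radmem import synth
from radmem.ephys import (
    IdealizedTrace,
    IVCurve,
    SingleChannelSweep,
    UnitaryIV,
    boltzmann_iv,
    cd_subtract,
    count_channels,
    ensemble_po,
    fit_iv_boltzmann,
    fit_po_boltzmann,
    fractional_shortening,
    idealize_half_height,
    junction_correct,
    p3_leak_subtract,
    po_at,
    ramp_fold_change,
)


class TestLeakSubtraction:
    def test_pure_ohmic_leak_cancels(self):
        dv = np.linspace(0, 100, 50)  # voltage excursion from holding
        main = 0.8 * dv
        subs = np.tile(0.8 * dv / 3.0, (3, 1))
        assert np.allclose(p3_leak_subtract(main, subs), 0.0, atol=1e-12)

    def test_affine_leak_annihilated_channel_recovered(self):
        dv = np.linspace(0, 120, 60)
        chan = boltzmann_iv(dv - 80.0, 8.0, -15.0, 6.0, 60.0)
        leak = 0.5 * dv + 0.0
        main = chan + leak
        subs = np.tile(leak / 3.0, (3, 1))
        assert np.allclose(p3_leak_subtract(main, subs), chan, atol=1e-9)

    def test_zero_subpulses_identity(self):
        main = np.arange(10.0)
        assert np.array_equal(p3_leak_subtract(main, np.zeros((3, 10))),
                              main)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            p3_leak_subtract(np.arange(5.0), np.zeros((3, 4)))


class TestCdSubtract:
    def test_identical_curves_zero(self):
        iv = IVCurve(np.arange(-60.0, 61.0, 10.0), np.ones(13))
        out = cd_subtract(iv, iv)
        assert np.allclose(out.currents, 0.0)

    def test_zero_background_identity(self):
        v = np.arange(-60.0, 61.0, 10.0)
        iv = IVCurve(v, np.sin(v / 30.0), capacitance=12.0)
        out = cd_subtract(iv, IVCurve(v, np.zeros_like(v)))
        assert np.array_equal(out.currents, iv.currents)
        assert out.capacitance == 12.0

    def test_synthetic_decomposition_recovered(self):
        total, bg, truth = synth.gen_iv(1, noise_sd=0.0)
        chan = cd_subtract(total, bg)
        expected = boltzmann_iv(total.voltages, truth["g_max"],
                                truth["v50"], truth["k_slope"],
                                truth["v_rev"])
        assert np.allclose(chan.currents, expected, atol=1e-12)

    def test_grid_mismatch(self):
        iv1 = IVCurve(np.arange(-60.0, 61.0, 10.0), np.zeros(13))
        iv2 = IVCurve(np.arange(-50.0, 71.0, 10.0), np.zeros(13))
        with pytest.raises(ValueError):
            cd_subtract(iv1, iv2)


class TestBoltzmannIvFit:
    def test_noiseless_exact_recovery(self):
        v = np.arange(-60.0, 61.0, 5.0)
        iv = IVCurve(v, boltzmann_iv(v, 10.0, -15.0, 6.0, 60.0))
        fit = fit_iv_boltzmann(iv)
        assert fit.g_max == pytest.approx(10.0, abs=1e-6)
        assert fit.v50 == pytest.approx(-15.0, abs=1e-6)
        assert fit.k_slope == pytest.approx(6.0, abs=1e-6)
        assert fit.v_rev == pytest.approx(60.0, abs=1e-6)

    def test_half_activation_at_v50(self):
        # the sigmoidal factor is exactly 1/2 at V = v50
        assert boltzmann_iv(-15.0, 1.0, -15.0, 6.0, 60.0) == \
            pytest.approx(0.5 * (-15.0 - 60.0))

    def test_voltage_translation_equivariance(self):
        v = np.arange(-60.0, 61.0, 5.0)
        i = boltzmann_iv(v, 10.0, -15.0, 6.0, 60.0)
        f0 = fit_iv_boltzmann(IVCurve(v, i))
        f1 = fit_iv_boltzmann(IVCurve(v + 7.0, i), v_rev_init=67.0)
        assert f1.v50 == pytest.approx(f0.v50 + 7.0, abs=1e-5)
        assert f1.v_rev == pytest.approx(f0.v_rev + 7.0, abs=1e-5)

    def test_junction_correction_shifts_v50(self):
        v = np.arange(-60.0, 61.0, 5.0)
        i = boltzmann_iv(v, 10.0, -15.0, 6.0, 60.0)
        vj = junction_correct(v, -10.0)
        fit = fit_iv_boltzmann(IVCurve(vj, i), v_rev_init=50.0)
        assert fit.v50 == pytest.approx(-25.0, abs=1e-5)

    def test_too_few_points(self):
        v = np.arange(-30.0, 1.0, 10.0)
        with pytest.raises(ValueError):
            fit_iv_boltzmann(IVCurve(v, np.zeros_like(v)))


class TestJunctionCorrect:
    def test_zero_offset_identity(self):
        v = np.arange(5.0)
        assert np.array_equal(junction_correct(v, 0.0), v)

    def test_double_application(self):
        v = np.arange(5.0)
        assert np.allclose(junction_correct(junction_correct(v)), v - 20.0)


class TestRampFoldChange:
    @staticmethod
    def _family(g_max, n=12, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        v = np.arange(-60.0, 41.0, 2.0)
        out = []
        for _ in range(n):
            i = boltzmann_iv(v, g_max, -15.0, 6.0, 60.0) + \
                rng.normal(0, noise, v.shape)
            out.append(IVCurve(v, i, capacitance=15.0))
        return out

    def test_identical_conditions_unity(self):
        fam = self._family(10.0)
        volts, fold = ramp_fold_change(fam, fam, v_rev=60.0)
        assert np.allclose(fold, 1.0, atol=1e-12)

    def test_gmax_doubling_gives_fold_two(self):
        volts, fold = ramp_fold_change(self._family(10.0),
                                       self._family(20.0), v_rev=60.0,
                                       normalize_capacitance=True)
        assert np.allclose(fold, 2.0, atol=1e-9)

    def test_reversal_neighborhood_masked(self):
        v = np.arange(40.0, 81.0, 2.0)
        fam = [IVCurve(v, v - 60.0) for _ in range(10)]
        volts, _ = ramp_fold_change(fam, fam, v_rev=60.0)
        assert np.all(np.abs(volts - 60.0) >= 10.0)

    def test_too_few_traces(self):
        fam = self._family(10.0, n=5)
        with pytest.raises(ValueError):
            ramp_fold_change(fam, fam, v_rev=60.0)


UNIT = UnitaryIV(gamma=0.05, v_rev_sc=60.0)


def hold_sweep(current, v=30.0, khz=10.0):
    n = len(current)
    return SingleChannelSweep(time_ms=np.arange(n) / khz,
                              current_pA=np.asarray(current, float),
                              voltage_mV=np.full(n, v),
                              sampling_rate_khz=khz)


class TestIdealization:
    def test_square_opening_exact_duration(self):
        i_open = UNIT(30.0)  # -1.5 pA
        cur = np.zeros(1000)
        cur[200:500] = i_open
        ideal = idealize_half_height(hold_sweep(cur), UNIT, 1)
        assert ideal.state.sum() == 300
        assert np.all(ideal.state[200:500] == 1)

    def test_flat_trace_all_closed(self):
        ideal = idealize_half_height(hold_sweep(np.zeros(500)), UNIT, 1)
        assert ideal.state.sum() == 0

    def test_half_amplitude_threshold(self):
        i_open = UNIT(30.0)
        cur = np.concatenate([np.zeros(20),
                              [0.49 * i_open, 0.51 * i_open, i_open]])
        ideal = idealize_half_height(hold_sweep(cur), UNIT, 1)
        assert ideal.state[-3:].tolist() == [0, 1, 1]

    def test_stacked_openings_clipped_to_channel_count(self):
        i_open = UNIT(30.0)
        cur = np.array([0.0, i_open, 2 * i_open, 3 * i_open, 5 * i_open])
        ideal = idealize_half_height(hold_sweep(cur), UNIT, 3)
        assert ideal.state.tolist() == [0, 1, 2, 3, 3]

    def test_low_amplitude_samples_flagged_invalid(self):
        n = 100
        v = np.linspace(55.0, 65.0, n)  # spans the single-channel reversal
        sw = SingleChannelSweep(time_ms=np.arange(n) / 10.0,
                                current_pA=np.zeros(n), voltage_mV=v,
                                sampling_rate_khz=10.0)
        ideal = idealize_half_height(sw, UNIT, 1, min_amp_pA=0.2)
        assert not ideal.valid.all()
        assert not ideal.valid[np.argmin(np.abs(v - 60.0))]

    def test_markov_stationary_open_fraction(self):
        """Time-average of idealized states matches k_open/(k_open+k_close)."""
        sweeps, _, truth = synth.gen_channel_sweeps(
            5, n_sweeps=60, hold_mV=30.0, k_open0=12.5, v_e_mV=np.inf,
            k_close=50.0, noise_sd_frac=0.15)
        fracs = [idealize_half_height(sw, UNIT, 1).state.mean()
                 for sw in sweeps]
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.2) < 3 * se + 1e-9


class TestEnsemblePo:
    @staticmethod
    def _trace(states, v=30.0, n_channels=1):
        states = np.asarray(states, int)
        return IdealizedTrace(state=states,
                              valid=np.ones(len(states), bool),
                              voltage_mV=np.full(len(states), v),
                              n_channels=n_channels, baseline_pA=0.0)

    def test_all_closed_po_zero(self):
        tr = [self._trace(np.zeros(100)) for _ in range(5)]
        curve = ensemble_po(tr, 1)
        assert np.all(curve.po == 0.0)

    def test_duplicated_sweeps_normalize_by_channel_count(self):
        single = self._trace([0, 1, 1, 0, 1])
        stacked = self._trace([0, 2, 2, 0, 2], n_channels=2)
        po1 = ensemble_po([single, single], 1).po
        po2 = ensemble_po([stacked, stacked], 2).po
        assert np.allclose(po1, po2)

    def test_sweep_order_and_batch_pooling_invariance(self):
        rng = np.random.default_rng(2)
        traces = [self._trace(rng.integers(0, 2, 50)) for _ in range(8)]
        po_a = ensemble_po(traces, 1).po
        po_b = ensemble_po(traces[::-1], 1).po
        assert np.allclose(po_a, po_b)

    def test_voltage_dependent_gating_matches_generator(self):
        """Detected P_O(V) along a ramp tracks the simulated gating states."""
        from scipy.stats import spearmanr

        sweeps, states, truth = synth.gen_channel_sweeps(
            6, n_sweeps=80, k_open0=50.0, v_e_mV=20.0, k_close=200.0,
            noise_sd_frac=0.15)
        ideal = [idealize_half_height(sw, UNIT, 1) for sw in sweeps]
        curve = ensemble_po(ideal, 1, v_bin=5.0)
        keep = (curve.voltages >= -60.0) & (curve.voltages <= 40.0)
        # detector accuracy: binned detected P_O vs the true state occupancy
        v_grid = sweeps[0].voltage_mV
        bins = np.round(v_grid / 5.0).astype(int)
        all_states = np.array(states)
        for v, po in zip(curve.voltages[keep], curve.po[keep]):
            true_po = all_states[:, bins == int(round(v / 5.0))].mean()
            assert abs(po - true_po) < 0.03
        # physiology: P_O increases monotonically with ramp voltage
        rho, _ = spearmanr(curve.voltages[keep], curve.po[keep])
        assert rho > 0.95

    def test_po_at_reads_the_right_bin(self):
        tr = [self._trace([1, 1, 0, 0]), self._trace([1, 1, 1, 1])]
        curve = ensemble_po(tr, 1)
        assert po_at(curve, 30.0) == pytest.approx(0.75)


class TestCountChannels:
    @staticmethod
    def _trace(states):
        states = np.asarray(states, int)
        return IdealizedTrace(state=states,
                              valid=np.ones(len(states), bool),
                              voltage_mV=np.full(len(states), 30.0),
                              n_channels=5, baseline_pA=0.0)

    def test_single_channel_patch(self):
        tr = [self._trace([0, 1, 0, 1]) for _ in range(50)]
        assert count_channels(tr) == 1

    def test_three_channels_at_high_po(self):
        """At P_O=0.8/channel, 60 sweeps, triple stacking is near-certain."""
        rng = np.random.default_rng(8)
        tr = [self._trace(rng.binomial(3, 0.8, 200)) for _ in range(60)]
        assert count_channels(tr) == 3

    def test_no_openings_flagged(self):
        tr = [self._trace(np.zeros(10)) for _ in range(50)]
        with pytest.raises(ValueError, match="no openings"):
            count_channels(tr)

    def test_too_few_sweeps(self):
        tr = [self._trace([0, 1])] * 10
        with pytest.raises(ValueError):
            count_channels(tr)


class TestPoBoltzmannFit:
    def test_noiseless_exact(self):
        from radmem.ephys import PoCurve, boltzmann_po
        v = np.arange(-60.0, 41.0, 5.0)
        po = boltzmann_po(v, 0.6, -10.0, 7.0)
        curve = PoCurve(voltages=v, po=po, n_sweeps=100, n_channels=1)
        po_max, v50, k = fit_po_boltzmann(curve)
        assert po_max == pytest.approx(0.6, abs=1e-6)
        assert v50 == pytest.approx(-10.0, abs=1e-5)
        assert k == pytest.approx(7.0, abs=1e-5)


class TestFractionalShortening:
    def test_constant_length_zero_percent(self):
        t = np.linspace(0, 10, 1000)
        fs, warn = fractional_shortening(t, np.full_like(t, 1.8),
                                         np.arange(0.5, 9.0, 1.0))
        assert fs == 0.0

    def test_sawtooth_ten_percent_exact(self):
        t = np.linspace(0, 9.995, 2000)
        ln = np.full_like(t, 1.80)
        stims = np.arange(0.5, 8.6, 1.0)  # 9 beats
        for t0 in stims:
            dip = (t >= t0) & (t < t0 + 0.3)
            ln[dip] = 1.62  # flat-bottom contraction to L_min
        fs, warn = fractional_shortening(t, ln, stims)
        assert fs == pytest.approx(10.0, abs=1e-9)
        assert not warn

    def test_heterogeneous_beats_mean_matches_hand_average(self):
        t = np.linspace(0, 8.0, 1600)
        ln = np.full_like(t, 2.0)
        mins = [1.9, 1.8, 1.7, 1.6, 1.9, 1.8, 1.7, 1.6]
        stims = np.arange(0.25, 7.5, 1.0)
        for t0, lm in zip(stims, mins):
            ln[(t >= t0) & (t < t0 + 0.3)] = lm
        fs, warn = fractional_shortening(t, ln, stims)
        expected = 100 * np.mean([(2.0 - m) / 2.0 for m in mins])
        assert fs == pytest.approx(expected, abs=1e-9)

    def test_fewer_than_eight_contractions_warns(self):
        t = np.linspace(0, 3.0, 600)
        ln = np.full_like(t, 1.8)
        stims = [0.5, 1.5, 2.5]
        for t0 in stims:
            ln[(t >= t0) & (t < t0 + 0.2)] = 1.6
        fs, warn = fractional_shortening(t, ln, stims)
        assert warn

    def test_generator_round_trip(self):
        t, ln, stims, truth = synth.gen_shortening(3, noise_um=0.0)
        fs, warn = fractional_shortening(t, ln, stims)
        assert fs == pytest.approx(100 * truth["fs_frac"], abs=1e-6)
        assert not warn
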