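"""Anti-aliasing sideband demodulation and jitter correction."""

import numpy as np
import pytest
import scipy.stats

import elastoct as et
from elastoct.noise import jitter_phase_error

from conftest import demod_mirror


class TestSidebandPlan:
    @pytest.mark.parametrize(
        "fm, n, folded, apparent",
        [
            (688.8e3, 31, 19.2e3, -2.4e3),
            (10e3, 0, 10e3, 10e3),
            (679.6e3, 31, 10.0e3, -11.6e3),
            (53.2e3, 2, 10e3, 10e3),
        ],
    )
    def test_parity_rule(self, sweep, fm, n, folded, apparent):
        plan = et.plan_sidebands(fm, sweep)
        assert plan.n == n
        assert plan.f_folded == pytest.approx(folded, abs=1.0)
        assert plan.f_apparent == pytest.approx(apparent, abs=1.0)

    def test_sideband_pixel_offset(self, sweep):
        plan = et.plan_sidebands(679.6e3, sweep)
        assert plan.z_m_pixels == pytest.approx(12.89, abs=0.01)
        assert plan.z_m == pytest.approx(2 * np.pi * 679.6e3 / (2 * sweep.k1))

    def test_out_of_range_sideband_rejected(self, sweep):
        with pytest.raises(ValueError, match="depth range"):
            et.plan_sidebands(sweep.delta_f * sweep.n_depth * 1.5 + 1234.0, sweep)

    def test_folds_to_dc_rejected(self, sweep):
        with pytest.raises(ValueError, match="DC"):
            et.plan_sidebands(sweep.f_A, sweep)


class TestTomogram:
    def test_mirror_appears_at_107th_pixel(self, mirror_cube):
        tom = et.aline_transform(mirror_cube)
        assert np.abs(tom.carrier_dc[0]).argmax() == 107

    def test_all_zero_cube_gives_zero_tomogram(self, sweep):
        cube = et.MScanCube(
            data=np.zeros((1, 8, sweep.n_samples)),
            x=np.zeros(1),
            stimulus_phase=np.zeros((1, 8)),
            sweep=sweep,
            f_m=10e3,
        )
        tom = et.aline_transform(cube)
        assert np.all(tom.F == 0)

    def test_unknown_window_rejected(self, mirror_cube):
        with pytest.raises(ValueError, match="window"):
            et.aline_transform(mirror_cube, window="blackman-exotic")


class TestDemodulate:
    def test_mirror_amplitude_and_phase(self, sweep):
        # sideband/carrier ratio 0.1 at 1307 nm corresponds to 20.8 nm
        delta = 0.1 / sweep.k0
        assert delta == pytest.approx(20.8e-9, abs=0.05e-9)
        vm = demod_mirror(sweep, 688.8e3, delta, phi=0.3)
        assert abs(vm.k0_delta[0, 107]) == pytest.approx(0.1, rel=0.01)
        assert vm.delta[0, 107] == pytest.approx(delta, rel=0.01)
        assert np.angle(vm.k0_delta[0, 107]) == pytest.approx(0.3, abs=0.01)

    def test_three_scatterer_roundtrip(self, sweep):
        scene, vib = et.three_scatterer_scene(sweep, deltas=(20e-9, 0.0, 10e-9))
        prot = et.ScanProtocol(n_alines=108, n_positions=1)
        cube = et.simulate_mscan(scene, sweep, vib, prot, snr_db=None, seed=2)
        plan = et.plan_sidebands(vib.f_m, sweep)
        vm = et.demodulate(et.aline_transform(cube), plan)
        zm = plan.z_m_pixels
        d1 = vm.delta[0, 106:109].max()
        d2 = vm.delta[0, int(round(107 - zm))]  # read at the scatterer pixel
        d3 = vm.delta[0, int(round(107 - 2 * zm)) - 1 : int(round(107 - 2 * zm)) + 2].max()
        assert d1 == pytest.approx(20e-9, rel=0.02)
        assert d3 == pytest.approx(10e-9, rel=0.02)
        assert d2 < 0.02 * 20e-9  # static scatterer recovered as silent

    def test_null_vibration_stays_at_noise_floor(self, sweep):
        vm = demod_mirror(sweep, 679.6e3, 0.0, snr_db=40.0, seed=7)
        floor = 1.0 / np.sqrt(108 * 1e4)
        assert abs(vm.k0_delta[0, 107]) < 3 * floor

    def test_linearity_in_amplitude(self, sweep):
        # delta-hat proportional to delta within 1% for k0 delta <= 0.05
        deltas = np.array([2e-9, 5e-9, 10e-9])
        est = np.array(
            [demod_mirror(sweep, 688.8e3, d).delta[0, 107] for d in deltas]
        )
        gains = est / deltas
        assert np.ptp(gains) / gains.mean() < 0.01

    def test_left_right_lobes_agree(self, sweep):
        vl = demod_mirror(sweep, 688.8e3, 15e-9, lobe="left")
        vr = demod_mirror(sweep, 688.8e3, 15e-9, lobe="right")
        assert vl.delta[0, 107] == pytest.approx(vr.delta[0, 107], rel=1e-3)

    def test_aliasing_consistency_across_folds(self, sweep):
        # same vibration amplitude recovered whether or not f_m is aliased
        ests = [
            demod_mirror(sweep, 10e3 + k * sweep.f_A, 20e-9).delta[0, 107]
            for k in (0, 1, 2)
        ]
        assert np.ptp(ests) / np.mean(ests) < 1e-6

    def test_dc_cancellation_integer_cycles(self, sweep):
        # sum over m of the sideband rotation vanishes when N f_m / f_A is integer
        plan = et.plan_sidebands(688.8e3, sweep)
        m = np.arange(1, 109)
        s = np.abs(np.sum(np.exp(2j * np.pi * plan.f_apparent / sweep.f_A * m)))
        assert s < 1e-10 * 108

    def test_non_integer_cycles_rejected_without_window(self, sweep):
        scene = et.mirror_scene(sweep, depth_px=107)
        vib = et.VibrationField(f_m=688.8e3, delta=10e-9)
        prot = et.ScanProtocol(n_alines=100, n_positions=1)  # 100*688.8/43.2 not int
        cube = et.simulate_mscan(scene, sweep, vib, prot, snr_db=None, seed=1)
        tom = et.aline_transform(cube)
        plan = et.plan_sidebands(688.8e3, sweep)
        with pytest.raises(ValueError, match="integer"):
            et.demodulate(tom, plan)
        vm = et.demodulate(tom, plan, time_window="hann")
        assert vm.delta[0, 107] == pytest.approx(10e-9, rel=0.05)

    def test_masked_pixels_not_nan(self, sweep):
        vm = demod_mirror(sweep, 688.8e3, 10e-9, snr_db=30.0, seed=5)
        assert np.all(np.isfinite(vm.k0_delta))
        assert not vm.mask.all() and vm.mask[0, 107]


class TestConventionalOracle:
    def test_mirror_50nm_recovered(self, sweep):
        scene = et.mirror_scene(sweep, depth_px=107)
        vib = et.VibrationField(f_m=10e3, delta=50e-9)
        prot = et.ScanProtocol(n_alines=108, n_positions=1)
        cube = et.simulate_mscan(scene, sweep, vib, prot, snr_db=None, seed=3)
        vm = et.conventional_phase_demod(et.aline_transform(cube), 10e3)
        assert vm.delta[0, 107] == pytest.approx(50e-9, rel=0.005)

    def test_agrees_with_sideband_demodulator(self, sweep):
        # oracle equivalence in the non-aliased regime, identical cube
        scene = et.mirror_scene(sweep, depth_px=107)
        vib = et.VibrationField(f_m=10e3, delta=10e-9)
        prot = et.ScanProtocol(n_alines=108, n_positions=1)
        cube = et.simulate_mscan(scene, sweep, vib, prot, snr_db=None, seed=4)
        tom = et.aline_transform(cube)
        d_side = et.demodulate(tom, et.plan_sidebands(10e3, sweep)).delta[0, 107]
        d_conv = et.conventional_phase_demod(tom, 10e3).delta[0, 107]
        assert d_side == pytest.approx(d_conv, rel=0.01)

    def test_refuses_aliased_frequencies(self, mirror_cube):
        tom = et.aline_transform(mirror_cube)
        with pytest.raises(ValueError, match="0.5"):
            et.conventional_phase_demod(tom, 30e3)

    def test_zero_vibration_floor(self, sweep):
        scene = et.mirror_scene(sweep, depth_px=107)
        vib = et.VibrationField(f_m=10e3, delta=0.0)
        prot = et.ScanProtocol(n_alines=108, n_positions=1)
        cube = et.simulate_mscan(scene, sweep, vib, prot, snr_db=40.0, seed=5)
        vm = et.conventional_phase_demod(et.aline_transform(cube), 10e3)
        assert vm.delta[0, 107] < 3 / np.sqrt(108 * 1e4) / sweep.k0


def _phases(sweep, fm, n_total, batch, seed0, correct, delta=20e-9):
    out = []
    prot = et.ScanProtocol(n_alines=108, n_positions=batch)
    plan = et.plan_sidebands(fm, sweep)
    vib = et.VibrationField(f_m=fm, delta=delta)
    cum = []
    for i in range(n_total // batch):
        scene = et.mirror_scene(sweep, depth_px=107, n_positions=batch)
        cube = et.simulate_mscan(scene, sweep, vib, prot, snr_db=40.0, seed=seed0 + i)
        tom = et.aline_transform(cube)
        vm = (
            et.jitter_correct(tom, plan)
            if correct
            else et.demodulate(tom, plan)
        )
        out.append(np.angle(vm.k0_delta[:, 107]))
        # mean stimulus-phase deviation tracks the cumulative jitter per M-scan
        m = np.arange(1, 109)
        nominal = np.angle(np.exp(2j * np.pi * fm / sweep.f_A * m))
        dev = np.angle(np.exp(1j * (cube.stimulus_phase - nominal[None, :])))
        cum.append(dev.mean(axis=1))
    return np.concatenate(out), np.concatenate(cum)


class TestJitterCorrection:
    def test_zero_jitter_correction_is_identity(self, sweep):
        scene = et.mirror_scene(sweep, depth_px=107)
        vib = et.VibrationField(f_m=679.6e3, delta=20e-9)
        prot = et.ScanProtocol(n_alines=108, n_positions=1)
        cube = et.simulate_mscan(scene, sweep, vib, prot, snr_db=None, seed=6)
        tom = et.aline_transform(cube)
        plan = et.plan_sidebands(679.6e3, sweep)
        a = et.demodulate(tom, plan).k0_delta[0, 107]
        b = et.jitter_correct(tom, plan).k0_delta[0, 107]
        assert a == pytest.approx(b, rel=1e-9)

    def test_missing_stimulus_warns_and_passes_through(self, sweep):
        scene = et.mirror_scene(sweep, depth_px=107)
        vib = et.VibrationField(f_m=679.6e3, delta=20e-9)
        prot = et.ScanProtocol(n_alines=108, n_positions=1)
        cube = et.simulate_mscan(scene, sweep, vib, prot, snr_db=None, seed=6)
        cube.stimulus_phase = None
        tom = et.aline_transform(cube)
        plan = et.plan_sidebands(679.6e3, sweep)
        with pytest.warns(UserWarning, match="stimulus"):
            vm = et.jitter_correct(tom, plan)
        assert not vm.jitter_corrected

    def test_phase_noise_statistics(self, sweep_jitter):
        # uncorrected phase SD ~ sigma_L; corrected ~ SNR-limited floor
        fm = 679.6e3
        ph_un, _ = _phases(sweep_jitter, fm, 200, 50, 100, correct=False)
        ph_co, cum = _phases(sweep_jitter, fm, 200, 50, 100, correct=True)
        sig_l = jitter_phase_error(108, fm, sweep_jitter.sigma_T)
        k0d = sweep_jitter.k0 * 20e-9
        floor = 1 / np.sqrt(2 * 108 * 1e4) / k0d
        sd_un = scipy.stats.circstd(ph_un)
        sd_co = scipy.stats.circstd(ph_co)
        assert sd_un == pytest.approx(sig_l, rel=0.20)
        assert sd_co <= 1.3 * floor
        # corrected phase error decorrelated from the cumulative jitter
        err = np.angle(np.exp(1j * (ph_co - np.mean(ph_co))))
        r = np.corrcoef(err, cum)[0, 1]
        assert abs(r) < 0.15
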