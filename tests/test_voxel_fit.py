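"""VARPRO projection and multi-start voxel fitting."""

import numpy as np
import pytest

import wfsep as w
from wfsep.voxel_fit import FittingError, varpro_residual


def _signal(pw, pf, r2, df, acq, spectrum):
    tes = acq.echo_times_s
    cn = w.fat_modulation(tes, spectrum)
    return np.exp((-r2 + 2j * np.pi * df) * tes) * (pw + pf * cn)


class TestVarproResidual:
    def test_zero_residual_at_truth(self, acq6, spectrum):
        sig = _signal(0.7 + 0.2j, 0.3 + 0.1j, 80.0, 35.0, acq6, spectrum)
        res, pw, pf = varpro_residual(35.0, 80.0, sig, acq6, spectrum)
        assert res < 1e-12
        assert pw == pytest.approx(0.7 + 0.2j, abs=1e-10)
        assert pf == pytest.approx(0.3 + 0.1j, abs=1e-10)

    def test_zero_signal_gives_zero_amplitudes(self, acq6, spectrum):
        res, pw, pf = varpro_residual(10.0, 20.0, np.zeros(6, complex), acq6, spectrum)
        assert res == 0.0 and pw == 0.0 and pf == 0.0

    def test_matches_dense_lstsq_oracle(self, acq6, spectrum):
        """Closed-form normal equations vs numpy lstsq over a 1 Hz grid."""
        rng = np.random.default_rng(0)
        sig = _signal(0.6, 0.4, 60.0, 120.0, acq6, spectrum) + 0.01 * (
            rng.normal(size=6) + 1j * rng.normal(size=6)
        )
        tes = acq6.echo_times_s
        cn = w.fat_modulation(tes, spectrum)
        for df in np.arange(-200.0, 201.0, 20.0):
            res, _, _ = varpro_residual(df, 60.0, sig, acq6, spectrum)
            phi = np.exp((-60.0 + 2j * np.pi * df) * tes)
            a = np.stack([phi, phi * cn], axis=1)
            amps, *_ = np.linalg.lstsq(a, sig, rcond=None)
            oracle = np.linalg.norm(sig - a @ amps)
            assert res == pytest.approx(oracle, abs=1e-10)

    def test_degenerate_design_flagged(self, acq6):
        # a "fat" species indistinguishable from water makes the design rank-1
        sp = w.FatSpectrum((0.0,), (1.0,))
        with pytest.raises(FittingError):
            varpro_residual(0.0, 0.0, np.ones(6, complex), acq6, sp)

    def test_too_few_echoes_rejected(self, spectrum):
        acq = w.AcquisitionParams.from_ms(1.29, 2.1, 2)
        with pytest.raises(w.ValidationError):
            varpro_residual(0.0, 0.0, np.ones(2, complex), acq, spectrum)


class TestFitVoxel:
    def test_noiseless_recovery_within_tolerance(self, acq6, spectrum):
        truth = dict(pw=0.55 + 0.3j, pf=0.35 + 0.19j, r2=95.0, df=40.0)
        sig = _signal(truth["pw"], truth["pf"], truth["r2"], truth["df"], acq6, spectrum)
        fit = w.fit_voxel(sig, acq6, spectrum, w.FitConfig())
        assert fit.fieldmap_hz == pytest.approx(truth["df"], rel=1e-6, abs=1e-4)
        assert fit.r2star_per_s == pytest.approx(truth["r2"], rel=1e-6)
        assert abs(fit.pw - truth["pw"]) < 1e-6
        assert abs(fit.pf - truth["pf"]) < 1e-6

    def test_pure_water_voxel_pdff_zero(self, acq6, spectrum):
        sig = _signal(1.0, 0.0, 50.0, -30.0, acq6, spectrum)
        fit = w.fit_voxel(sig, acq6, spectrum, w.FitConfig())
        pdff = abs(fit.pf) / (abs(fit.pw) + abs(fit.pf))
        assert pdff < 1e-8

    def test_zero_signal_returns_null_fit(self, acq6, spectrum):
        fit = w.fit_voxel(np.zeros(6, complex), acq6, spectrum)
        assert fit.pw == 0 and fit.pf == 0 and fit.residual == 0

    def test_swap_ambiguity_landscape_is_bimodal(self, acq6):
        """Single-peak fat at df=0 has a near-zero residual near df = f_fat."""
        f_fat = -217.0
        sp = w.FatSpectrum((f_fat,), (1.0,))
        sig = _signal(0.3, 0.7, 40.0, 0.0, acq6, sp)
        grid = np.arange(-400.0, 401.0, 1.0)
        # residual minimised over an R2* grid, as the fitter's search does
        res = np.array(
            [
                min(varpro_residual(d, r2, sig, acq6, sp)[0] for r2 in np.linspace(0, 200, 21))
                for d in grid
            ]
        )
        # global minimum at the truth
        assert res[np.flatnonzero(grid == 0.0)[0]] < 1e-8
        # a pronounced second basin (the swap solution) sits near df ~ f_fat,
        # far below the typical residual level of the landscape
        swap_region = res[(grid > f_fat - 30) & (grid < f_fat + 30)]
        assert swap_region.min() < 0.5 * np.median(res)
        # multi-start selection still lands on the true composition
        fit = w.fit_voxel(sig, acq6, sp, w.FitConfig())
        pdff = abs(fit.pf) / (abs(fit.pw) + abs(fit.pf))
        assert pdff == pytest.approx(0.7, abs=1e-6)

    def test_residual_no_worse_than_truth(self, acq6, spectrum):
        rng = np.random.default_rng(8)
        for _ in range(5):
            pw = rng.uniform(0.2, 1) * np.exp(1j * rng.uniform(-np.pi, np.pi))
            pf = rng.uniform(0, 0.8) * np.exp(1j * rng.uniform(-np.pi, np.pi))
            r2 = rng.uniform(0, 180)
            df = rng.uniform(-350, 350)
            sig = _signal(pw, pf, r2, df, acq6, spectrum)
            fit = w.fit_voxel(sig, acq6, spectrum, w.FitConfig())
            truth_res, _, _ = varpro_residual(df, r2, sig, acq6, spectrum)
            # sqrt of the projected residual bottoms out at sqrt(eps_f64)
            floor = 1e-7 * np.linalg.norm(sig)
            assert fit.residual <= truth_res + floor


class TestFitImage:
    def test_empty_mask_returns_zero_maps(self, acq6, spectrum):
        echoes = w.EchoSeries(
            data=np.ones((6, 4, 4), complex),
            echo_times_s=tuple(acq6.echo_times_s),
            acquisition=acq6,
        )
        maps, qc = w.fit_image(echoes, spectrum, mask=np.zeros((4, 4), bool))
        assert qc["n_voxels"] == 0
        assert np.all(maps.water == 0) and np.all(maps.fat == 0)

    def test_mask_shape_mismatch_rejected(self, acq6, spectrum):
        echoes = w.EchoSeries(
            data=np.ones((6, 4, 4), complex),
            echo_times_s=tuple(acq6.echo_times_s),
            acquisition=acq6,
        )
        with pytest.raises(w.ValidationError):
            w.fit_image(echoes, spectrum, mask=np.zeros((5, 5), bool))

    def test_noisy_roi_bias_is_small(self, acq6, spectrum):
        """PDFF bias in a uniform region stays under one percentage point."""
        shape = (8, 8)
        maps = w.ParameterMaps(
            water=np.full(shape, 0.75 + 0j),
            fat=np.full(shape, 0.25 + 0j),
            r2star_per_s=np.full(shape, 60.0),
            fieldmap_hz=np.full(shape, 25.0),
            mask=np.ones(shape, bool),
        )
        biases = []
        for seed in range(10):
            echoes = w.simulate_signal(maps, acq6, spectrum)
            noisy = w.add_noise(echoes, 50.0, seed=seed)
            fitted, _ = w.fit_image(noisy, spectrum, w.FitConfig(), mask=maps.mask)
            est = w.compute_pdff(fitted)
            biases.append(est.values[est.mask].mean() - 0.25)
        assert abs(np.mean(biases)) < 0.01


def test_rmse_decreases_with_snr(acq6, spectrum):
    """Estimator consistency: PDFF RMSE improves monotonically with SNR."""
    maps = w.generate_phantom(
        w.PhantomConfig(image_size=16, n_regions=2, seed=4, noise_snr=None)
    )
    truth = w.compute_pdff(maps)
    echoes = w.simulate_signal(maps, acq6, spectrum)
    rmses = []
    for snr in (10.0, 25.0, 50.0, 100.0):
        errs = []
        for seed in (0, 1):
            noisy = w.add_noise(echoes, snr, seed=seed)
            fitted, _ = w.fit_image(noisy, spectrum, w.FitConfig(), mask=maps.mask)
            est = w.compute_pdff(fitted)
            errs.append(np.sqrt(np.mean((est.values - truth.values)[maps.mask] ** 2)))
        rmses.append(np.mean(errs))
    assert all(a > b for a, b in zip(rmses, rmses[1:]))
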