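"""Saturation-recovery and empirical banding estimation and correction."""

import numpy as np
import pytest

import hcpasl_lite as h
from hcpasl_lite import debanding, subtraction
from hcpasl_lite.debanding import (
    empirical_correct,
    fit_empirical_banding,
    fit_satrecov,
    sat_time,
    satrecov_correct,
    satrecov_factor,
    satrecov_signal,
)


class TestSatrecovSignal:
    def test_no_recovery_at_zero(self):
        assert satrecov_signal(100.0, 1.3, 0.0) == 0.0

    def test_full_recovery_at_long_times(self):
        assert satrecov_signal(100.0, 1.3, 1e6) == pytest.approx(100.0)

    def test_one_time_constant(self):
        # 100 * (1 - e^-1)
        assert satrecov_signal(100.0, 1.3, 1.3) == pytest.approx(63.212, abs=1e-3)

    def test_nonpositive_t1_rejected(self):
        with pytest.raises(ValueError):
            satrecov_signal(100.0, 0.0, 1.0)

    def test_sat_time_delegates_to_protocol(self, protocol):
        assert sat_time(protocol, 2.2, 9) == pytest.approx(4.231)


class TestFitSatrecov:
    def test_noiseless_uniform_t1_recovered(self, protocol):
        t = h.make_phantom((16, 16, 60), protocol, seed=1, noise_sd=0.0, t1_tissue=1.3)
        s, _, _ = h.simulate_dataset(t, protocol)
        mask = t.brain_mask()
        model = fit_satrecov(s, mask=mask)
        good = mask & model.fit_mask
        assert np.all(np.abs(model.t1t_map[good] - 1.3) < 1e-3)

    def test_voxelwise_t1_map_recovered(self, noiseless_chain):
        t, model, mask = (
            noiseless_chain["truth"],
            noiseless_chain["model"],
            noiseless_chain["mask"],
        )
        good = mask & model.fit_mask
        assert np.all(np.abs(model.t1t_map[good] - t.t1_tissue[good]) < 1e-3)

    def test_constant_input_flagged_invalid(self, protocol):
        t = h.make_phantom((12, 12, 60), protocol, seed=0, noise_sd=0.0)
        s, _, _ = h.simulate_dataset(t, protocol, apply_satrecov=False)
        # fully relaxed static signal: make the series time-constant
        s = s.with_data(np.repeat(s.data[..., :1], s.data.shape[3], axis=3))
        with pytest.raises(ValueError):
            # every fit degenerate -> all-invalid is an error
            fit_satrecov(s, mask=t.brain_mask())

    def test_empty_mask_rejected(self, noiseless_chain):
        with pytest.raises(ValueError):
            fit_satrecov(
                noiseless_chain["series"], mask=np.zeros((24, 24, 60), dtype=bool)
            )

    def test_noisy_t1_error_small(self, protocol):
        """1% of M0 noise: median |T1 error| below 5% (seeded Monte Carlo)."""
        t = h.make_phantom((16, 16, 60), protocol, seed=13, noise_sd=1.0, t1_tissue=1.3)
        s, _, _ = h.simulate_dataset(t, protocol)
        mask = t.brain_mask() & (t.pv_gm + t.pv_wm > 0.9)
        model = fit_satrecov(s, mask=mask)
        good = mask & model.fit_mask
        rel_err = np.abs(model.t1t_map[good] - 1.3) / 1.3
        assert np.median(rel_err) < 0.05


class TestSatrecovCorrect:
    def test_first_excitation_factor_is_one(self, noiseless_chain, protocol):
        t1 = noiseless_chain["model"].t1_filled()
        for s0 in (0.0, 10.0, 50.0):
            fac = satrecov_factor(t1, protocol, 0.2, s0)
            np.testing.assert_allclose(fac, 1.0)

    def test_factor_in_unit_interval_for_later_slices(self, noiseless_chain, protocol):
        t1 = noiseless_chain["model"].t1_filled()
        for s0 in (1.0, 5.0, 9.0, 19.0):
            fac = satrecov_factor(t1, protocol, 0.2, s0)
            assert np.all(fac > 0) and np.all(fac <= 1)

    def test_corrected_profile_flat_within_bands(self, protocol):
        t = h.make_phantom(
            (24, 24, 60), protocol, seed=1, noise_sd=0.0, empirical_gradient=0.0,
            bias_amplitude=0.0,
        )
        s, _, _ = h.simulate_dataset(t, protocol)
        mask = t.brain_mask()
        model = fit_satrecov(s, mask=mask)
        corrected = satrecov_correct(s, model)
        ctrl = corrected.data[..., corrected.control_indices()[0]]
        prof = np.array([ctrl[:, :, z][mask[:, :, z]].mean() for z in range(60)])
        for b in range(6):
            band = prof[b * 10 : (b + 1) * 10]
            assert (band.max() - band.min()) / band.mean() < 0.005

    def test_double_correction_guarded(self, noiseless_chain):
        with pytest.raises(ValueError):
            satrecov_correct(noiseless_chain["corrected"], noiseless_chain["model"])

    def test_correction_magnitude_decreases_with_pld(self, noiseless_chain, protocol):
        """The satrecov correction shrinks with PLD; the empirical one does not."""
        t1 = noiseless_chain["model"].t1_filled()
        mask = noiseless_chain["mask"]
        mags = []
        for pld in protocol.plds:
            fac = satrecov_factor(
                t1, protocol, pld, np.arange(60.0)[None, None, :]
            )
            mags.append(np.abs(fac[mask] - 1).max())
        assert all(a > b for a, b in zip(mags, mags[1:]))

    def test_subtraction_unaffected_by_correction(self, protocol):
        """Correcting label and control and rescaling the difference gives
        the same dM as subtracting the uncorrected series."""
        t = h.make_phantom(
            (16, 16, 60), protocol, seed=2, noise_sd=0.0, empirical_gradient=0.0,
            bias_amplitude=0.0,
        )
        s, _, _ = h.simulate_dataset(t, protocol)
        mask = t.brain_mask()
        dm_raw = subtraction.subtract_glm(s, mask=mask)
        model = fit_satrecov(s, mask=mask)
        dm_corr = subtraction.subtract_glm(
            satrecov_correct(s, model), banding_model=model, mask=mask
        )
        np.testing.assert_allclose(
            dm_corr.dm[:, mask], dm_raw.dm[:, mask], atol=1e-8
        )


class TestEmpiricalBanding:
    def test_round_trip_four_subjects(self, protocol):
        imgs, gms, wms = [], [], []
        for seed in range(4):
            t = h.make_phantom(
                (24, 24, 60), protocol, seed=seed, noise_sd=0.0,
                empirical_gradient=0.02, bias_amplitude=0.0,
            )
            _, calib, _ = h.simulate_dataset(t, protocol)
            imgs.append(calib[..., 0])
            gms.append(t.pv_gm)
            wms.append(t.pv_wm)
        g = fit_empirical_banding(imgs, gms, wms, protocol.band_size)
        assert g == pytest.approx(0.02, abs=1e-4)

    def test_flat_images_give_zero(self, protocol):
        t = h.make_phantom(
            (16, 16, 60), protocol, seed=0, noise_sd=0.0,
            empirical_gradient=0.0, bias_amplitude=0.0,
        )
        _, calib, _ = h.simulate_dataset(t, protocol)
        g = fit_empirical_banding([calib[..., 0]], t.pv_gm, t.pv_wm, 10)
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_two_cohorts_pool_to_mean(self, protocol):
        """Equal-sized groups with gradients 0.015 and 0.025 pool to 0.020."""
        imgs, gms, wms = [], [], []
        for seed, g_true in [(0, 0.015), (1, 0.015), (2, 0.025), (3, 0.025)]:
            t = h.make_phantom(
                (16, 16, 60), protocol, seed=seed, noise_sd=0.0,
                empirical_gradient=g_true, bias_amplitude=0.0,
            )
            _, calib, _ = h.simulate_dataset(t, protocol)
            imgs.append(calib[..., 0])
            gms.append(t.pv_gm)
            wms.append(t.pv_wm)
        g = fit_empirical_banding(imgs, gms, wms, protocol.band_size)
        assert g == pytest.approx(0.020, abs=1e-4)

    def test_per_band_estimate_matches_scalar(self, protocol):
        t = h.make_phantom(
            (16, 16, 60), protocol, seed=0, noise_sd=0.0,
            empirical_gradient=0.02, bias_amplitude=0.0,
        )
        _, calib, _ = h.simulate_dataset(t, protocol)
        per_band = fit_empirical_banding(
            [calib[..., 0]], t.pv_gm, t.pv_wm, 10, per_band=True
        )
        assert per_band.shape == (6,)
        np.testing.assert_allclose(per_band, 0.02, atol=1e-10)
        # per-band correction with equal slopes reproduces the scalar one
        a = empirical_correct(calib[..., 0], per_band, 10)
        b = empirical_correct(calib[..., 0], 0.02, 10)
        np.testing.assert_allclose(a, b)

    def test_all_bands_skipped_is_error(self, protocol):
        img = np.ones((8, 8, 60))
        empty = np.zeros((8, 8, 60))
        with pytest.raises(ValueError):
            fit_empirical_banding([img], empty, empty, 10)


class TestEmpiricalCorrect:
    def test_zero_gradient_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(6, 6, 60))
        np.testing.assert_array_equal(empirical_correct(img, 0.0, 10), img)

    def test_round_trip_flattens_slices(self, protocol):
        t = h.make_phantom(
            (24, 24, 60), protocol, seed=1, noise_sd=0.0,
            empirical_gradient=0.02, bias_amplitude=0.0,
        )
        s, _, _ = h.simulate_dataset(t, protocol, apply_satrecov=False)
        corr = empirical_correct(s.data[..., 0], 0.02, 10)
        gm = t.gm_mask(0.999)
        prof = np.array([corr[:, :, z][gm[:, :, z]].mean() for z in range(60)])
        assert (prof.max() - prof.min()) / prof.mean() < 1e-3

    def test_band_mean_preserved_to_first_order(self):
        """Dividing by factors that average to 1 changes the band mean only
        at second order in g (≈ g^2 * var(p) ≈ 0.33% for g = 0.02)."""
        img = np.ones((4, 4, 60))
        corr = empirical_correct(img, 0.02, 10)
        for b in range(6):
            band_mean = corr[:, :, b * 10 : (b + 1) * 10].mean()
            assert abs(band_mean - 1.0) < 0.0035

    def test_oversized_gradient_rejected(self):
        with pytest.raises(ValueError):
            empirical_correct(np.ones((4, 4, 60)), 0.5, 10)

    def test_double_correction_guarded(self, noiseless_chain):
        with pytest.raises(ValueError):
            empirical_correct(noiseless_chain["corrected"], 0.02)
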