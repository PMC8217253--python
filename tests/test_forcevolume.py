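import numpy as np
import pytest

from pellifilm import forcevolume as fv
from pellifilm import synthetic as syn

CANT = fv.Cantilever(0.1, 20.0)


def make_ramp(lam, seed=0, noise=None, z0_jitter=0.0, n=1):
    noise = noise if noise is not None else syn.NoiseSpec()
    ramps, ref, info = syn.gen_force_volume(lam, grid=(1, n), seed=seed,
                                            z0_jitter=z0_jitter, noise=noise)
    return ramps, ref, info


class TestDeflectionSensitivity:
    def test_ideal_rigid_contact_is_reciprocal_slope(self):
        piezo = np.linspace(0.0, 100.0, 200)
        signal = np.clip(piezo - 60.0, 0.0, None) * 0.05  # 0.05 V/nm contact slope
        assert fv.deflection_sensitivity(fv.ForceRamp(piezo, signal)) == pytest.approx(20.0)

    def test_noisy_reference_within_two_percent(self):
        rng = np.random.default_rng(5)
        piezo = np.linspace(0.0, 100.0, 400)
        signal = np.clip(piezo - 60.0, 0.0, None) * 0.05 + 1e-3 * rng.standard_normal(400)
        assert fv.deflection_sensitivity(fv.ForceRamp(piezo, signal)) == pytest.approx(
            20.0, rel=0.02)

    def test_never_contacting_ramp_is_an_error(self):
        rng = np.random.default_rng(6)
        piezo = np.linspace(0.0, 100.0, 200)
        with pytest.raises(ValueError, match="R²|contact"):
            fv.deflection_sensitivity(
                fv.ForceRamp(piezo, 1e-3 * rng.standard_normal(200)))


class TestContactPoint:
    def test_pure_hertz_recovered_noise_free(self):
        # lam=None: no steric tail -> pure sphere-plane Hertz contact
        ramps, _, info = syn.gen_force_volume(None, grid=(1, 1), z0_jitter=0.0,
                                              noise=syn.NOISELESS, seed=0)
        defl = ramps[0].detector_signal * CANT.deflection_sensitivity
        z0, b, quality = fv.find_contact_hertz(ramps[0].piezo_z, defl, 0.1)
        assert z0 == pytest.approx(float(info["z0"][0]), abs=0.2)
        assert b == pytest.approx(1.0, rel=0.02)
        assert quality < 0.01

    def test_contact_with_steric_tail_within_half_nm(self):
        ramps, _, info = make_ramp(12.0, seed=7)
        defl = ramps[0].detector_signal * CANT.deflection_sensitivity
        z0, _, _ = fv.find_contact_hertz(ramps[0].piezo_z, defl, 0.1)
        # the exponential pedestal biases z0 slightly; must stay within 1.5 nm
        assert z0 == pytest.approx(info["z0"][0], abs=1.5)

    def test_flat_curve_is_an_error(self):
        piezo = np.linspace(0.0, 100.0, 300)
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="no contact"):
            fv.find_contact_hertz(piezo, 0.01 * rng.standard_normal(300), 0.1)


class TestForceDistance:
    def test_zero_deflection_maps_to_piezo_distance(self):
        piezo = np.linspace(0.0, 50.0, 10)
        ramp = fv.ForceRamp(piezo, np.zeros(10))
        curve = fv.to_force_distance(ramp, CANT, z0=60.0)
        assert np.allclose(curve.force, 0.0)
        assert np.allclose(curve.d_ts, 60.0 - piezo)

    def test_hard_wall_keeps_dts_near_zero_in_contact(self):
        piezo = np.linspace(0.0, 100.0, 500)
        signal = np.clip(piezo - 60.0, 0.0, None) / CANT.deflection_sensitivity
        curve = fv.to_force_distance(fv.ForceRamp(piezo, signal), CANT, z0=60.0)
        in_contact = piezo > 60.0
        assert np.allclose(curve.d_ts[in_contact], 0.0, atol=1e-9)

    def test_generator_round_trip_matches_truth_within_noise(self):
        ramps, _, info = make_ramp(10.0, seed=9)
        curve = fv.to_force_distance(ramps[0], CANT, z0=float(info["z0"][0]))
        tail = curve.d_ts > 5.0
        expected = 1.0 * np.exp(-curve.d_ts[tail] / 10.0)
        # detector noise is 0.05 nm -> 0.005 nN force noise
        assert np.percentile(np.abs(curve.force[tail] - expected), 95) < 0.02


class TestStericFit:
    def _curve(self, lam=10.0, f0=1.0, noise=0.0, seed=0, d_max=80.0):
        rng = np.random.default_rng(seed)
        d = np.linspace(d_max, 0.5, 300)
        f = f0 * np.exp(-d / lam) + noise * rng.standard_normal(d.size)
        return fv.ForceCurve(d, f)

    def test_exact_exponential_recovered_exactly(self):
        fit = fv.fit_steric(self._curve())
        assert fit.ok
        assert fit.lambda_exp == pytest.approx(10.0, rel=1e-6)
        assert fit.f0 == pytest.approx(1.0, rel=1e-6)

    def test_noisy_median_within_three_percent(self):
        """0.02 nN noise, 200 repeats: median lambda within 3% of 10 nm."""
        lams = []
        for seed in range(200):
            fit = fv.fit_steric(self._curve(noise=0.02, seed=seed))
            if fit.ok:
                lams.append(fit.lambda_exp)
        assert len(lams) > 150
        assert np.median(lams) == pytest.approx(10.0, rel=0.03)

    def test_pure_hertz_curve_flagged_unfit(self):
        d = np.linspace(80.0, -20.0, 400)
        rng = np.random.default_rng(3)
        f = np.clip(-d, 0, None) ** 1.5 + 0.005 * rng.standard_normal(d.size)
        fit = fv.fit_steric(fv.ForceCurve(d, f))
        assert not fit.ok


class TestAnalyzeVolume:
    def test_uniform_grid_median_within_three_percent(self):
        ramps, ref, _ = syn.gen_force_volume(10.0, grid=(8, 8), seed=11)
        cant = fv.Cantilever(0.1, fv.deflection_sensitivity(ref))
        res = fv.analyze_volume(ramps, cant)
        assert res.median_lambda == pytest.approx(10.0, rel=0.03)
        assert res.n_excluded == 0
        # distribution integrates to 1
        widths = np.diff(res.hist_edges)
        assert np.sum(res.hist_density * widths) == pytest.approx(1.0, abs=1e-6)

    def test_aggregate_ramps_excluded_but_distribution_unaffected(self):
        """~5% stiff tail-less ramps: excluded, median unchanged."""
        ramps, ref, info = syn.gen_force_volume(10.0, grid=(12, 12), seed=12,
                                                aggregate_fraction=0.05)
        cant = fv.Cantilever(0.1, fv.deflection_sensitivity(ref))
        res = fv.analyze_volume(ramps, cant)
        assert res.n_excluded == int(info["is_aggregate"].sum())
        assert res.median_lambda == pytest.approx(10.0, rel=0.03)

    def test_single_ramp_gives_point_mass(self):
        ramps, _, _ = make_ramp(10.0, seed=13)
        res = fv.analyze_volume(ramps, CANT)
        assert res.lambdas.size == 1
        assert res.iqr_lambda[0] == res.iqr_lambda[1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fv.analyze_volume([], CANT)

    def test_pipeline_invariant_to_piezo_offset_and_gain(self):
        """Shifting the piezo origin and rescaling detector gain (with the
        reference rescaled identically) must not change the fitted lambdas."""
        ramps, ref, _ = syn.gen_force_volume(8.0, grid=(2, 2), seed=14)
        cant = fv.Cantilever(0.1, fv.deflection_sensitivity(ref))
        base = fv.analyze_volume(ramps, cant)

        gain = 2.5
        shifted = [fv.ForceRamp(r.piezo_z + 37.0, r.detector_signal / gain)
                   for r in ramps]
        ref_scaled = fv.ForceRamp(ref.piezo_z + 37.0, ref.detector_signal / gain)
        cant2 = fv.Cantilever(0.1, fv.deflection_sensitivity(ref_scaled))
        moved = fv.analyze_volume(shifted, cant2)
        assert np.allclose(np.sort(moved.lambdas), np.sort(base.lambdas), rtol=1e-6)

    @pytest.mark.parametrize("lam", [2.0, 8.0, 30.0])
    def test_recovery_across_decay_length_range(self, lam):
        """End-to-end |median - truth|/truth <= 5% for lambda in [2, 30] nm."""
        ramps, ref, _ = syn.gen_force_volume(lam, grid=(5, 5), seed=int(lam))
        cant = fv.Cantilever(0.1, fv.deflection_sensitivity(ref))
        res = fv.analyze_volume(ramps, cant)
        assert res.median_lambda == pytest.approx(lam, rel=0.05)


class TestConditionRatio:
    def _result(self, lam, seed):
        ramps, ref, _ = syn.gen_force_volume(lam, grid=(4, 4), seed=seed)
        cant = fv.Cantilever(0.1, fv.deflection_sensitivity(ref))
        return fv.analyze_volume(ramps, cant)

    def test_identical_inputs_give_unity(self):
        res = self._result(10.0, 21)
        ratio, ci = fv.condition_ratio(res, res, seed=1)
        assert ratio == 1.0
        assert ci[0] <= 1.0 <= ci[1]

    def test_threefold_collapse_recovered(self):
        before = self._result(12.0, 22)
        after = self._result(4.0, 23)
        ratio, _ = fv.condition_ratio(before, after, seed=2)
        assert ratio == pytest.approx(3.0, rel=0.05)

    def test_antisymmetry_is_exact(self):
        before = self._result(12.0, 24)
        after = self._result(4.0, 25)
        r_ab, _ = fv.condition_ratio(before, after, seed=3)
        r_ba, _ = fv.condition_ratio(after, before, seed=3)
        assert r_ab * r_ba == pytest.approx(1.0, rel=1e-12)
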