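import numpy as np
import pytest

from pellifilm import materials as mat
from pellifilm import reflectometry as refl
from pellifilm import synthetic as syn

from conftest import parratt_reflectivity


def fresnel(q, sld_front, sld_back):
    k0 = np.asarray(q) / 2.0
    k1 = np.sqrt((k0**2 - 4 * np.pi * (sld_back - sld_front) * 1e-6).astype(complex))
    return np.abs((k0 - k1) / (k0 + k1)) ** 2


class TestReflectivity:
    def test_single_interface_matches_fresnel(self, q_grid):
        stack = [refl.Slab(0, refl.SI_SLD), refl.Slab(0, 6.36, 0.0, 1.0)]
        r = refl.reflectivity(stack, q_grid)
        expected = np.minimum(fresnel(q_grid, refl.SI_SLD, 6.36), 1.0)
        assert np.allclose(r, expected, rtol=1e-10)

    def test_no_contrast_gives_no_reflection(self, q_grid):
        stack = [refl.Slab(0, refl.SI_SLD), refl.Slab(0, refl.SI_SLD, 0.0, 1.0)]
        assert np.all(refl.reflectivity(stack, q_grid) < 1e-12)

    def test_total_reflection_plateau_below_critical_edge(self):
        qc = refl.critical_edge(refl.SI_SLD, 6.36)
        assert qc == pytest.approx(0.01468, abs=2e-4)
        q = np.linspace(0.006, qc * 0.98, 50)
        stack = [refl.Slab(0, refl.SI_SLD), refl.Slab(0, 6.36, 0.0, 1.0)]
        assert np.allclose(refl.reflectivity(stack, q), 1.0, atol=1e-12)

    def test_critical_edge_degenerate_cases(self):
        assert refl.critical_edge(2.07, 2.07) == 0.0
        assert refl.critical_edge(2.07, -0.56) == 0.0  # solvent below substrate

    def test_abeles_equals_parratt_on_random_stacks(self, q_grid):
        rng = np.random.default_rng(42)
        for _ in range(10):
            stack = [refl.Slab(0, 2.07)]
            for _ in range(5):
                stack.append(refl.Slab(rng.uniform(10, 300), rng.uniform(-0.5, 6.4),
                                       rng.uniform(0, 8)))
            stack.append(refl.Slab(0, rng.uniform(-0.56, 6.36), rng.uniform(0, 15), 1.0))
            r_abeles = refl.reflectivity(stack, q_grid)
            r_parratt = parratt_reflectivity(stack, q_grid)
            assert np.allclose(r_abeles, r_parratt, rtol=1e-8, atol=1e-15)

    def test_roughness_damps_reflectivity_above_edge(self, q_grid):
        sharp = [refl.Slab(0, refl.SI_SLD), refl.Slab(0, 6.36, 0.0, 1.0)]
        rough = [refl.Slab(0, refl.SI_SLD), refl.Slab(0, 6.36, 8.0, 1.0)]
        qc = refl.critical_edge(refl.SI_SLD, 6.36)
        above = q_grid > 1.5 * qc
        assert np.all(refl.reflectivity(rough, q_grid)[above]
                      < refl.reflectivity(sharp, q_grid)[above])

    def test_invariant_under_slab_subdivision(self, q_grid):
        base = [refl.Slab(0, 2.07), refl.Slab(120, 3.0, 4.0),
                refl.Slab(0, 6.36, 6.0, 1.0)]
        split = [refl.Slab(0, 2.07), refl.Slab(50, 3.0, 4.0),
                 refl.Slab(70, 3.0, 0.0), refl.Slab(0, 6.36, 6.0, 1.0)]
        assert np.allclose(refl.reflectivity(base, q_grid),
                           refl.reflectivity(split, q_grid), rtol=1e-10)

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError):
            refl.Slab(-5.0, 2.0)


class TestSmearing:
    def test_zero_resolution_is_identity(self, q_grid):
        stack = [refl.Slab(0, 2.07), refl.Slab(300, 4.0, 3.0), refl.Slab(0, 6.36, 3.0, 1.0)]
        r = refl.reflectivity(stack, q_grid)
        assert np.array_equal(refl.smear(q_grid, r, 0.0), r)
        assert np.allclose(refl.smeared_reflectivity(stack, q_grid, 0.0), r)

    def test_constant_curve_unchanged(self, q_grid):
        r = np.full(q_grid.size, 0.37)
        assert np.allclose(refl.smear(q_grid, r, 0.04), r, rtol=1e-12)

    def test_kiessig_fringes_damped_at_every_extremum(self):
        """4% smearing must reduce the fringe amplitude of a 300 Å slab."""
        q = np.linspace(0.02, 0.18, 1600)
        stack = [refl.Slab(0, 2.07), refl.Slab(300, 4.0, 0.0), refl.Slab(0, 6.36, 0.0, 1.0)]
        r = refl.reflectivity(stack, q)
        rs = refl.smeared_reflectivity(stack, q, 0.04)
        logr, logrs = np.log(r), np.log(rs)
        # local extrema of the unsmeared curve, away from the grid edges
        d2 = np.diff(np.sign(np.diff(logr)))
        maxima = np.flatnonzero(d2 < 0) + 1
        minima = np.flatnonzero(d2 > 0) + 1
        maxima = maxima[(maxima > 10) & (maxima < q.size - 10)]
        minima = minima[(minima > 10) & (minima < q.size - 10)]
        assert maxima.size >= 3 and minima.size >= 3
        assert np.all(logrs[maxima] < logr[maxima])
        assert np.all(logrs[minima] > logr[minima])

    def test_smearing_matches_numerical_convolution(self):
        """Quadrature smearing agrees with a dense brute-force convolution."""
        q = np.linspace(0.03, 0.1, 60)
        stack = [refl.Slab(0, 2.07), refl.Slab(300, 4.0, 0.0), refl.Slab(0, 6.36, 0.0, 1.0)]
        rs = refl.smeared_reflectivity(stack, q, 0.04)
        sigma = 0.04 * q / 2.3548
        brute = np.empty_like(q)
        for i, (qi, si) in enumerate(zip(q, sigma)):
            grid = np.linspace(qi - 5 * si, qi + 5 * si, 1001)
            w = np.exp(-0.5 * ((grid - qi) / si) ** 2)
            brute[i] = np.sum(w * refl.reflectivity(stack, grid)) / w.sum()
        assert np.allclose(rs, brute, rtol=2e-3)


class TestPellicleModel:
    def test_layer_sld_limits(self):
        solvated = refl.PellicleLayer(50.0, 1.0)
        assert refl.layer_sld(solvated, 6.36, 2.0, 0.36) == pytest.approx(6.36)
        dry = refl.PellicleLayer(50.0, 0.0)
        assert refl.layer_sld(dry, 6.36, 2.0, 0.36) == pytest.approx(2.0)

    def test_layer_sld_hand_arithmetic(self):
        # hydration 0.955, dry split 92% salivary (SLD 2.0) / 8% CAPB (0.36), dPBS
        layer = refl.PellicleLayer(117.0, 0.955, surfactant_fraction=0.08)
        expected = 0.955 * 6.36 + 0.045 * (0.92 * 2.0 + 0.08 * 0.36)
        assert refl.layer_sld(layer, 6.36, 2.0, 0.36) == pytest.approx(expected)
        assert expected == pytest.approx(6.1579, abs=1e-4)

    def test_fraction_sum_invariant_enforced(self):
        with pytest.raises(ValueError, match="must equal 1"):
            refl.PellicleLayer(50.0, 0.5, surfactant_fraction=0.1, salivary_fraction=0.5)

    def test_stack_structure_is_contrast_invariant(self, pellicle_model, contrasts):
        stacks = [refl.stack_from_model(pellicle_model, c) for c in contrasts]
        for s in stacks[1:]:
            assert [sl.thickness for sl in s] == [sl.thickness for sl in stacks[0]]
            assert [sl.roughness for sl in s] == [sl.roughness for sl in stacks[0]]
        assert not np.allclose([sl.sld for sl in stacks[0]],
                               [sl.sld for sl in stacks[1]])

    def test_slab_slds_monotone_toward_dpbs(self, contrasts):
        """Pre-treatment pellicle in dPBS: SLD rises from inner layer to solvent."""
        model = refl.PellicleTwoLayerModel(
            inner=refl.PellicleLayer(46.0, 0.620, roughness=5.0),
            outer=refl.PellicleLayer(286.0, 0.971, roughness=10.0),
        )
        slds = [s.sld for s in refl.stack_from_model(model, contrasts[2])[2:]]
        assert np.all(np.diff(slds) > 0)

    def test_zero_thickness_oxide_dropped(self, pellicle_model, contrasts):
        m = pellicle_model.copy()
        m.oxide.thickness = 0.0
        assert len(refl.stack_from_model(m, contrasts[2])) == 4


class TestCorefine:
    def test_truth_is_a_zero_residual_fixed_point(self, pellicle_model, contrasts, q_grid):
        meas = syn.gen_nr(pellicle_model, contrasts, q_grid, noise=syn.NOISELESS, seed=0)
        res = refl._residuals(pellicle_model, meas)
        assert np.max(np.abs(res)) < 1e-9

    def test_recovery_within_tight_bounds(self, pellicle_model, contrasts, q_grid):
        """Noise-free data, bounds bracketing the truth: parameters recovered."""
        meas = syn.gen_nr(pellicle_model, [contrasts[2]], q_grid,
                          noise=syn.NOISELESS, seed=0)
        bounds = {
            "inner.thickness": (40.0, 55.0),
            "outer.thickness": (280.0, 380.0),
            "outer.hydration": (0.95, 0.99),
        }
        start = pellicle_model.copy()
        start.inner.thickness, start.outer.thickness = 50.0, 300.0
        fit = refl.corefine(meas, start, bounds, seed=5, maxiter=40, popsize=10)
        assert fit.converged
        assert fit.model.inner.thickness == pytest.approx(46.0, rel=0.01)
        assert fit.model.outer.thickness == pytest.approx(325.0, rel=0.01)
        assert fit.model.outer.hydration == pytest.approx(0.975, abs=0.005)
        assert fit.chi2 < 1e-6

    def test_requires_measurements_and_parameters(self, pellicle_model):
        with pytest.raises(ValueError):
            refl.corefine([], pellicle_model, {"outer.thickness": (100, 400)}, seed=0)


class TestPosterior:
    def _one_param_fit(self, pellicle_model, contrasts, q_grid, dr_scale=1.0):
        stack_meas = syn.gen_nr(pellicle_model, [contrasts[2]], q_grid,
                                noise=syn.NOISELESS, seed=0)
        for m in stack_meas:
            m.dr = np.full_like(m.dr, 0.02 * np.median(m.reflectivity) * dr_scale)
        fit = refl.FitResult(model=pellicle_model.copy(), chi2=0.0,
                             n_points=q_grid.size, converged=True,
                             param_names=["outer.thickness"],
                             bounds={"outer.thickness": (250.0, 400.0)})
        return fit, stack_meas

    def test_credible_width_matches_gaussian_curvature(self, pellicle_model,
                                                       contrasts, q_grid):
        """For a single free parameter the 1-sigma credible half-width must
        agree with the analytic Gaussian width from the local curvature."""
        fit, meas = self._one_param_fit(pellicle_model, contrasts, q_grid)
        intervals = refl.posterior_sample(fit, meas, seed=7, n_walkers=24, n_steps=1000)
        med, half = intervals["outer.thickness"]
        # analytic: sigma = 1/sqrt(J^T J) with J = d(residual)/d(thickness)
        eps = 0.05
        m_plus, m_minus = pellicle_model.copy(), pellicle_model.copy()
        m_plus.outer.thickness += eps
        m_minus.outer.thickness -= eps
        jac = (refl._residuals(m_plus, meas) - refl._residuals(m_minus, meas)) / (2 * eps)
        sigma_analytic = 1.0 / np.sqrt(jac @ jac)
        assert med == pytest.approx(325.0, abs=3 * sigma_analytic)
        assert half == pytest.approx(sigma_analytic, rel=0.10)

    def test_intervals_shrink_with_noise(self, pellicle_model, contrasts, q_grid):
        fit_tight, meas_tight = self._one_param_fit(pellicle_model, contrasts, q_grid, 1.0)
        fit_loose, meas_loose = self._one_param_fit(pellicle_model, contrasts, q_grid, 5.0)
        w_tight = refl.posterior_sample(fit_tight, meas_tight, seed=3, n_walkers=16,
                                        n_steps=300)["outer.thickness"][1]
        w_loose = refl.posterior_sample(fit_loose, meas_loose, seed=3, n_walkers=16,
                                        n_steps=300)["outer.thickness"][1]
        assert w_loose > 3.0 * w_tight

    def test_requires_converged_fit(self, pellicle_model):
        fit = refl.FitResult(model=pellicle_model, chi2=1.0, n_points=10, converged=False)
        with pytest.raises(ValueError, match="converged"):
            refl.posterior_sample(fit, [], seed=0)
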