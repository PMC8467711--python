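import numpy as np
import pytest

from ctirecon import models
from ctirecon.models import (LiteratureConstants, S_S_PER_MM3_TO_INTERNAL,
                             estimate_ce, fem_scale_factor, lem_scale_factor,
                             reconstruct_cti, reconstruct_fem, reconstruct_lem,
                             reconstruct_vcm, reconstruct_vfm,
                             sigma_iso_from_labels, solve_vfm_fractions,
                             vfm_forward_eigs)
from ctirecon.synthetic_data import simulate_sigma_h
from ctirecon.tensor_core import (Quantity, TensorField, anisotropy_ratio,
                                  eig_decompose, isotropic_field, mean_scalar)
from conftest import random_spd


def small_field(mats, quantity=Quantity.DIFFUSION):
    return TensorField.from_matrices(np.asarray(mats), quantity)


class TestConstants:
    def test_defaults(self):
        c = LiteratureConstants()
        assert (c.sigma_wm, c.sigma_gm, c.sigma_csf) == (0.14, 0.27, 1.79)
        assert c.eta_empirical == 0.844
        assert c.beta == 0.41
        assert (c.q, c.N, c.kBT) == (1.6e-19, 2.0e25, 4.1e-21)

    def test_validation(self):
        with pytest.raises(ValueError):
            LiteratureConstants(sigma_wm=-1)
        with pytest.raises(ValueError):
            LiteratureConstants(beta=1.5)


class TestLem:
    def test_scale_factor_equal_diffusivities(self):
        # dWM = dGM = d  ->  eta = (sWM + sGM) / (2 d)
        d = 0.8e-3
        eta = lem_scale_factor([d, d], [0.14, 0.27])
        assert eta == pytest.approx((0.14 + 0.27) / (2 * d), rel=1e-12)

    def test_scale_factor_arithmetic(self):
        dwm, dgm = 0.7e-3, 0.9e-3
        expected = (dwm * 0.14 + dgm * 0.27) / (dwm ** 2 + dgm ** 2)
        assert lem_scale_factor([dwm, dgm], [0.14, 0.27]) == \
            pytest.approx(expected, rel=1e-14)

    def test_empty_mask_raises(self, brain_dti):
        empty = np.zeros(brain_dti.grid_shape, dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            reconstruct_lem(brain_dti, {"WM": empty, "GM": empty}, "matched")

    def test_zero_d_gives_zero_c(self):
        D = small_field([np.zeros((3, 3))])
        C, _ = reconstruct_lem(D, mode="empirical")
        np.testing.assert_array_equal(C.values, 0.0)
        assert C.quantity is Quantity.CONDUCTIVITY

    def test_empirical_eta_value(self):
        D = small_field([np.eye(3) * 1e-3])
        _, eta = reconstruct_lem(D, mode="empirical")
        assert eta.eta == pytest.approx(0.844 * S_S_PER_MM3_TO_INTERNAL)
        assert eta.eta / S_S_PER_MM3_TO_INTERNAL == 0.844  # S*s/mm^3

    def test_anisotropy_preserved(self, rng):
        mats = np.array([random_spd(rng) for _ in range(20)])
        D = small_field(mats)
        C, _ = reconstruct_lem(D, mode="empirical")
        np.testing.assert_allclose(anisotropy_ratio(C), anisotropy_ratio(D),
                                   rtol=1e-12)

    def test_matched_mode_requires_masks(self, brain_dti):
        with pytest.raises(ValueError, match="masks"):
            reconstruct_lem(brain_dti, None, "matched")


class TestFem:
    def test_si_value(self):
        # 0.76 * (1.6e-19)^2 * 2e25 / 4.1e-21
        expected = 0.76 * (1.6e-19) ** 2 * 2e25 / 4.1e-21
        assert fem_scale_factor(units="si") == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(9.49e7, rel=1e-3)

    def test_linearity_in_N(self):
        full = fem_scale_factor(LiteratureConstants())
        half = fem_scale_factor(LiteratureConstants(N=1e25))
        assert half == pytest.approx(full / 2, rel=1e-14)

    def test_global_and_data_independent(self, phantom1_fit):
        _, eta = reconstruct_fem(phantom1_fit.Df)
        assert eta.scope == "global"
        assert np.isscalar(eta.eta) or np.ndim(eta.eta) == 0

    def test_zero_df_zero_c(self):
        Df = small_field([np.zeros((3, 3))])
        C, _ = reconstruct_fem(Df)
        np.testing.assert_array_equal(C.values, 0.0)

    def test_blind_to_concentration(self, phantom1, phantom1_fit):
        # EL1 and EL2 differ only in ion concentration -> identical FEM output
        C, _ = reconstruct_fem(phantom1_fit.Df)
        lab = {name: lid for lid, name in phantom1.label_names.items()}
        c1 = C.values[phantom1.labels == lab["EL1"]]
        c2 = C.values[phantom1.labels == lab["EL2"]]
        np.testing.assert_array_equal(np.unique(np.round(c1, 15), axis=0),
                                      np.unique(np.round(c2, 15), axis=0))


class TestVcm:
    def test_mean_scalar_equals_sigma_iso(self, rng):
        mats = np.array([random_spd(rng) for _ in range(20)])
        D = small_field(mats)
        C, _ = reconstruct_vcm(D, np.full(D.grid_shape, 1.79))
        np.testing.assert_allclose(mean_scalar(C), 1.79, rtol=1e-12)

    def test_isotropic_d(self):
        D = small_field([np.eye(3) * 2e-3])
        C, _ = reconstruct_vcm(D, np.array([0.5]))
        np.testing.assert_allclose(C.as_matrices()[0], 0.5 * np.eye(3),
                                   rtol=1e-13)

    def test_anisotropy_preserved(self, rng):
        mats = np.array([random_spd(rng) for _ in range(20)])
        D = small_field(mats)
        C, _ = reconstruct_vcm(D, np.full(D.grid_shape, 0.3))
        np.testing.assert_allclose(anisotropy_ratio(C), anisotropy_ratio(D),
                                   rtol=1e-12)

    def test_zero_trace_masked_with_warning(self):
        D = small_field([np.zeros((3, 3)), np.eye(3) * 1e-3])
        with pytest.warns(RuntimeWarning, match="zero trace"):
            C, _ = reconstruct_vcm(D, np.full((2,), 1.0))
        assert not C.mask[0] and C.mask[1]

    def test_label_map_helper(self):
        labels = np.array([0, 1, 2, 3])
        out = sigma_iso_from_labels(labels, {1: 0.14, 2: 0.27, 3: 1.79})
        assert np.isnan(out[0])
        np.testing.assert_allclose(out[1:], [0.14, 0.27, 1.79])


class TestVfmFractions:
    def test_isotropic_voxel(self):
        c = LiteratureConstants()
        frac, ill = solve_vfm_fractions([c.vfm_d_iso] * 3)
        np.testing.assert_allclose(frac, [0, 0, 0, 1], atol=1e-10)
        assert not ill

    def test_pure_bundle_voxel(self):
        c = LiteratureConstants()
        frac, ill = solve_vfm_fractions([c.vfm_d_lW, c.vfm_d_tW, c.vfm_d_tW])
        np.testing.assert_allclose(frac, [1, 0, 0, 0], atol=1e-10)

    def test_random_simplex_round_trip(self, rng):
        raw = rng.dirichlet(np.ones(4), size=100)
        eigs = vfm_forward_eigs(raw[:, :3])
        back, ill = solve_vfm_fractions(eigs)
        np.testing.assert_allclose(back, raw, atol=1e-8)
        assert not ill.any()

    def test_bad_shape(self):
        with pytest.raises(ValueError, match="3 eigenvalues"):
            solve_vfm_fractions(np.ones((4, 2)))


class TestVfmReconstruction:
    def test_isotropic_voxel_sigma_iso(self):
        c = LiteratureConstants()
        D = small_field([np.eye(3) * c.vfm_d_iso])
        masks = {"WM": np.array([True])}
        C, frac, _ = reconstruct_vfm(D, masks, c)
        np.testing.assert_allclose(C.as_matrices()[0],
                                   c.vfm_sigma_iso * np.eye(3), atol=1e-9)

    def test_pure_bundle_eigenvalues(self):
        c = LiteratureConstants()
        D = small_field([np.diag([c.vfm_d_lW, c.vfm_d_tW, c.vfm_d_tW])])
        C, frac, _ = reconstruct_vfm(D, {"WM": np.array([True])}, c)
        lam = eig_decompose(C).eigenvalues[0]
        np.testing.assert_allclose(
            lam, [c.vfm_sigma_lW, c.vfm_sigma_tW, c.vfm_sigma_tW], atol=1e-8)

    def test_anisotropy_reduced_on_unequal_transversals(self, brain,
                                                        brain_dti):
        truth, masks = brain
        C, _, _ = reconstruct_vfm(brain_dti, masks)
        wm = masks["WM"]
        lam_d = eig_decompose(brain_dti).eigenvalues
        unequal = wm & (np.abs(lam_d[..., 1] - lam_d[..., 2]) > 1e-6)
        ar_c = anisotropy_ratio(C)[unequal]
        ar_d = anisotropy_ratio(brain_dti)[unequal]
        assert np.all(ar_c < ar_d)

    def test_gm_csf_isotropic_literature(self, brain, brain_dti):
        truth, masks = brain
        c = LiteratureConstants()
        C, _, _ = reconstruct_vfm(brain_dti, masks, c)
        sl = mean_scalar(C)
        np.testing.assert_allclose(sl[masks["GM"]], c.sigma_gm, rtol=1e-10)
        np.testing.assert_allclose(sl[masks["CSF"]], c.sigma_csf, rtol=1e-10)

    def test_missing_masks(self, brain_dti):
        with pytest.raises(ValueError, match="WM"):
            reconstruct_vfm(brain_dti, {})


class TestEstimateCe:
    def test_alpha_one(self):
        assert estimate_ce(1.2, 1.0, 2e-3, 0.4e-3, 0.41) == \
            pytest.approx(1.2 / 2e-3, rel=1e-13)

    def test_direct_arithmetic(self):
        # sigma_H=1.0, alpha=0.5, dew=2e-3, diw=0.5e-3, beta=0.41
        expected = 1.0 / (0.5 * 2e-3 + 0.5 * 0.5e-3 * 0.41)
        assert estimate_ce(1.0, 0.5, 2e-3, 0.5e-3, 0.41) == \
            pytest.approx(expected, rel=1e-13)

    def test_zero_denominator_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="denominator"):
            out = estimate_ce(np.array([1.0]), np.array([0.5]),
                              np.array([0.0]), np.array([0.0]), 0.41)
        assert np.isnan(out[0])

    def test_bad_beta(self):
        with pytest.raises(ValueError, match="beta"):
            estimate_ce(1.0, 1.0, 2e-3, 0.4e-3, 0.0)


class TestCti:
    def test_electrolyte_limit(self):
        # alpha=1, De = dew * I  ->  C = sigma_H * I
        from ctirecon.multib_fit import BiexpFitField
        grid = (1, 1, 1)
        dew = 2e-3
        Df = isotropic_field(np.full(grid, dew), Quantity.DIFFUSION)
        ones = np.ones(grid)
        fit = BiexpFitField(ones[..., None], 0 * ones[..., None],
                            dew * ones[..., None], 0 * ones[..., None],
                            Df, Df, ones, dew * ones, 0 * ones, 0 * ones,
                            np.ones(grid, dtype=bool))
        C, eta = reconstruct_cti(np.full(grid, 0.9), fit, 0.41)
        np.testing.assert_allclose(C.as_matrices()[0, 0, 0],
                                   0.9 * np.eye(3), rtol=1e-12)

    def test_full_round_trip_per_voxel(self, phantom1, phantom1_fit):
        # forward and inverse models are algebraic inverses
        sigma_h = simulate_sigma_h(phantom1)
        C, _ = reconstruct_cti(sigma_h, phantom1_fit, phantom1.beta)
        m = phantom1.mask & C.mask
        rel = np.abs(C.values[m] - phantom1.C_true.values[m]) \
            / np.abs(mean_scalar(phantom1.C_true)[m])[:, None]
        assert rel.max() < 1e-3      # < 0.1 % per voxel

    def test_sensitive_to_sigma_h(self, phantom1, phantom1_fit):
        # unlike LEM/FEM, equal De but different sigma_H -> different C
        sigma_h = simulate_sigma_h(phantom1)
        C1, _ = reconstruct_cti(sigma_h, phantom1_fit, phantom1.beta)
        C2, _ = reconstruct_cti(2 * sigma_h, phantom1_fit, phantom1.beta)
        m = phantom1.mask
        np.testing.assert_allclose(C2.values[m], 2 * C1.values[m], rtol=1e-12)

    def test_grid_mismatch(self, phantom1_fit):
        with pytest.raises(ValueError, match="grid"):
            reconstruct_cti(np.ones((2, 2, 2)), phantom1_fit, 0.41)

    def test_anisotropy_preserved(self, brain, brain_fit):
        truth, masks = brain
        sigma_h = simulate_sigma_h(truth)
        C, _ = reconstruct_cti(sigma_h, brain_fit, truth.beta)
        wm = masks["WM"] & C.mask
        np.testing.assert_allclose(anisotropy_ratio(C)[wm],
                                   anisotropy_ratio(brain_fit.Df)[wm],
                                   rtol=1e-10)
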