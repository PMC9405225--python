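"""Turbulence post-processing operators against algebraic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from vwbr import synthetic_data as sd
from vwbr import turbulence_post as tp

finite_tensors = hnp.arrays(
    float, (3, 3), elements=st.floats(-100.0, 100.0, allow_nan=False)
)


def _rotation_gradient(omega):
    g = np.zeros((3, 3))
    g[0, 1], g[1, 0] = -omega, omega
    return g


class TestStrainRate:
    @given(finite_tensors)
    @settings(deadline=None, max_examples=50)
    def test_matches_symmetric_part(self, g):
        assert tp.strain_rate(g) == pytest.approx((g + g.T) / 2)

    def test_solid_rotation_has_zero_strain(self):
        assert tp.strain_rate(_rotation_gradient(10.0)) == pytest.approx(
            np.zeros((3, 3))
        )

    def test_pure_shear_components(self):
        g = np.zeros((3, 3))
        g[0, 1] = 8.0
        S = tp.strain_rate(g)
        assert S[0, 1] == S[1, 0] == pytest.approx(4.0)
        assert np.count_nonzero(S) == 2

    @given(finite_tensors, st.floats(-50.0, 50.0))
    @settings(deadline=None, max_examples=50)
    def test_frame_objectivity(self, g, omega):
        """Adding a rigid rotation leaves the strain tensor unchanged."""
        assert tp.strain_rate(g + _rotation_gradient(omega)) == pytest.approx(
            tp.strain_rate(g), abs=1e-9
        )


class TestWaleNut:
    def test_zero_gradient_gives_zero(self):
        assert tp.wale_nut(np.zeros((3, 3)), 1e-3) == 0.0

    @pytest.mark.parametrize("i,j", [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0),
                                     (2, 1)])
    def test_pure_shear_null_in_every_orientation(self, i, j):
        # single off-diagonal gradient: g^2 nilpotent, Sd = 0 exactly
        g = np.zeros((3, 3))
        g[i, j] = 7.3
        assert tp.wale_nut(g, 1e-3) == 0.0

    def test_solid_rotation_closed_form(self):
        omega, Cw, delta = 10.0, 0.325, 1e-3
        expected = (Cw * delta) ** 2 * (2.0 / 3.0) ** 0.25 * omega
        got = tp.wale_nut(_rotation_gradient(omega), delta, Cw)
        assert got == pytest.approx(expected, rel=1e-10)
        assert got == pytest.approx(9.54e-7, rel=1e-3)

    def test_vectorised_matches_scalar(self, rng):
        g = rng.normal(size=(10, 3, 3))
        batch = tp.wale_nut(g, 1e-3)
        singles = [tp.wale_nut(g[i], 1e-3) for i in range(10)]
        assert batch == pytest.approx(singles, rel=1e-12)

    @given(finite_tensors)
    @settings(deadline=None, max_examples=50)
    def test_non_negative(self, g):
        assert tp.wale_nut(g, 1e-3) >= 0.0


class TestEpsTotal:
    def test_sgs_term_hand_arithmetic(self):
        field = sd.gen_flow(sd.FlowSpec(kind="pure_shear", amplitude=0.0))[0]
        field = tp.GradientField(
            position=field.position[:1],
            cell_volume=np.array([1e-9]),  # Delta = 1e-3 m
            gradU=np.zeros((1, 3, 3)),
            nu=1e-6,
            k_sgs=np.array([1e-4]),
        )
        eps, eps_res, eps_sgs = tp.eps_total(field)
        assert eps_sgs[0] == pytest.approx(1.034 * (1e-4) ** 1.5 / 1e-3,
                                           rel=1e-12)
        assert eps_sgs[0] == pytest.approx(1.034e-3, rel=1e-12)
        assert eps_res[0] == 0.0
        assert eps[0] == pytest.approx(eps_res[0] + eps_sgs[0], rel=1e-15)

    def test_missing_k_sgs_is_input_error(self):
        field, _ = sd.gen_flow(sd.FlowSpec(kind="pure_shear"))
        with pytest.raises(ValueError):
            tp.eps_total(field, include_sgs=True)

    def test_taylor_green_volume_mean_oracle(self):
        spec = sd.FlowSpec(kind="taylor_green", grid_n=64)
        field, truth = sd.gen_flow(spec)
        _, eps_res, _ = tp.eps_total(field, include_sgs=False)
        mean = np.average(eps_res, weights=field.cell_volume)
        assert mean == pytest.approx(truth["mean_eps_res"], rel=0.01)

    def test_taylor_green_second_order_convergence(self):
        errs = []
        for n in (16, 32):
            field, truth = sd.gen_flow(sd.FlowSpec(kind="taylor_green",
                                                   grid_n=n))
            _, eps_res, _ = tp.eps_total(field, include_sgs=False)
            mean = np.average(eps_res, weights=field.cell_volume)
            errs.append(abs(mean - truth["mean_eps_res"]) /
                        truth["mean_eps_res"])
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)

    def test_analytic_gradients_are_exact(self):
        field, truth = sd.gen_flow(
            sd.FlowSpec(kind="taylor_green", grid_n=16, gradients="analytic")
        )
        _, eps_res, _ = tp.eps_total(field, include_sgs=False)
        mean = np.average(eps_res, weights=field.cell_volume)
        assert mean == pytest.approx(truth["mean_eps_res"], rel=1e-12)

    def test_rigid_rotation_added_leaves_eps_res_unchanged(self, rng):
        field, _ = sd.gen_flow(sd.FlowSpec(kind="random_smooth", seed=8))
        _, eps0, _ = tp.eps_total(field, include_sgs=False)
        rotated = tp.GradientField(
            position=field.position,
            cell_volume=field.cell_volume,
            gradU=field.gradU + _rotation_gradient(25.0),
            nu=field.nu,
        )
        _, eps1, _ = tp.eps_total(rotated, include_sgs=False)
        assert eps1 == pytest.approx(eps0, rel=1e-8, abs=1e-18)


class TestKolmogorov:
    def test_hand_value(self):
        assert tp.kolmogorov(9.78e-7, 1e-3) == pytest.approx(1.75e-4,
                                                             rel=2e-3)

    def test_quarter_power_scaling(self):
        eta = tp.kolmogorov(1e-6, 1e-3)
        assert tp.kolmogorov(1e-6, 16e-3) == pytest.approx(eta / 2, rel=1e-12)

    def test_zero_dissipation_maps_to_infinity(self):
        eta = tp.kolmogorov(1e-6, np.array([0.0, 1e-3]))
        assert np.isinf(eta[0]) and np.isfinite(eta[1])

    def test_culture_range_dissipation_gives_culture_scale_eddies(self):
        # dissipation levels typical of gentle suspension culture map to
        # Kolmogorov lengths in the 150-400 um band used as aggregate bounds
        eps = np.logspace(np.log10(4e-5), np.log10(4e-4), 20)
        eta = tp.kolmogorov(9.78e-7, eps)
        assert np.all((eta > 150e-6) & (eta < 400e-6))


class TestShearStress:
    def test_zero_strain_zero_stress(self):
        assert tp.shear_stress(_rotation_gradient(5.0), 1e-3) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_pure_shear_hand_value(self):
        g = np.zeros((3, 3))
        g[0, 1] = 10.0
        # S:S = gamma^2/2; tau = mu*sqrt(2*S:S) = mu*gamma
        assert tp.shear_stress(g, 1e-3) == pytest.approx(0.01, rel=1e-12)

    def test_linear_in_total_viscosity(self, rng):
        g = rng.normal(size=(3, 3))
        assert tp.shear_stress(g, 2e-3, 2e-3) == pytest.approx(
            2 * tp.shear_stress(g, 1e-3, 1e-3), rel=1e-12
        )

    def test_literal_form_is_the_plain_product(self):
        g = np.zeros((3, 3))
        g[0, 1] = 10.0
        assert tp.shear_stress(g, 1e-3, literal=True) == pytest.approx(
            1e-3 * 50.0, rel=1e-12
        )


class TestTurbDiffusivity:
    def test_default_turbulent_schmidt(self):
        assert tp.turb_diffusivity(1.34e-6) == pytest.approx(1.0e-6,
                                                             rel=1e-12)
        assert tp.turb_diffusivity(0.0) == 0.0
        assert tp.turb_diffusivity(9.54e-7) == pytest.approx(7.12e-7,
                                                             rel=1e-3)


class TestKeRatio:
    def test_threshold_arithmetic(self):
        # resolved 8e-4, SGS 2e-4 -> exactly the 0.8 mesh-quality threshold
        u = np.zeros((1, 4, 3))
        u[0, :, 0] = np.sqrt(8e-4) * np.array([1.0, -1.0, 1.0, -1.0])
        u[0, :, 1] = np.sqrt(8e-4) * np.array([1.0, -1.0, -1.0, 1.0])
        # k_res = 0.5*(8e-4 + 8e-4) = 8e-4
        fluct = tp.FluctuationSeries(u_prime=u, k_sgs=np.array([2e-4]))
        ratio, flagged = tp.ke_ratio(fluct)
        assert ratio[0] == pytest.approx(0.8, rel=1e-12)
        assert not flagged[0]

    def test_no_sgs_energy_gives_unity(self, rng):
        u = rng.normal(size=(3, 50, 3))
        u -= u.mean(axis=1, keepdims=True)
        fluct = tp.FluctuationSeries(u_prime=u, k_sgs=np.zeros(3))
        ratio, flagged = tp.ke_ratio(fluct)
        assert ratio == pytest.approx(np.ones(3), rel=1e-12)
        assert not flagged.any()

    def test_isotropic_fluctuations_variance_identity(self):
        rng = np.random.default_rng(77)
        sigma = 0.02
        u = rng.normal(0.0, sigma, size=(1, 200_000, 3))
        u -= u.mean(axis=1, keepdims=True)
        k_res = 0.5 * (u**2).mean(axis=1).sum()
        assert k_res == pytest.approx(1.5 * sigma**2, rel=0.02)

    def test_zero_energy_flagged_undefined(self):
        fluct = tp.FluctuationSeries(
            u_prime=np.zeros((1, 5, 3)), k_sgs=np.zeros(1)
        )
        ratio, flagged = tp.ke_ratio(fluct)
        assert np.isnan(ratio[0]) and flagged[0]

    @given(st.floats(1e-8, 1e-1), st.floats(0.0, 1e-1))
    @settings(deadline=None, max_examples=50)
    def test_ratio_bounded_and_monotone_in_sgs(self, k_res2, k_sgs):
        u = np.zeros((1, 2, 3))
        u[0, :, 0] = np.sqrt(k_res2) * np.array([1.0, -1.0])
        fluct = tp.FluctuationSeries(u_prime=u, k_sgs=np.array([k_sgs]))
        ratio, _ = tp.ke_ratio(fluct)
        assert 0.0 <= ratio[0] <= 1.0
        more_sgs = tp.FluctuationSeries(
            u_prime=u, k_sgs=np.array([k_sgs + 1e-3])
        )
        assert tp.ke_ratio(more_sgs)[0][0] < ratio[0]


class TestSurfaceKl:
    def test_single_face_hand_arithmetic(self):
        surface = tp.SurfaceFluxField(
            area=np.array([1.0]), dCdy=np.array([1e5]),
            D_ABt=np.array([0.0]), C_sat=0.25, C_bulk_mean=0.05,
        )
        kl = tp.surface_kl(surface, D_AB=2.1e-9)
        assert kl == pytest.approx(2.1e-4 / 0.2, rel=1e-12)

    def test_zero_gradient_zero_kl(self):
        surface = tp.SurfaceFluxField(
            area=np.ones(4), dCdy=np.zeros(4), D_ABt=np.zeros(4),
            C_sat=0.25, C_bulk_mean=0.0,
        )
        assert tp.surface_kl(surface, 2.1e-9) == 0.0

    def test_film_profile_round_trip_exact(self):
        kl_true = 2.68e-5
        surface = sd.gen_surface_profile(
            kl_true, C_sat=0.27, C_bulk=0.05, D_AB=2.1e-9
        )
        assert tp.surface_kl(surface, 2.1e-9) == pytest.approx(kl_true,
                                                               rel=1e-12)

    def test_zero_mean_face_perturbations_cancel(self):
        kl_true = 2.68e-5
        surface = sd.gen_surface_profile(
            kl_true, C_sat=0.27, C_bulk=0.05, D_AB=2.1e-9,
            face_variation=0.2, seed=6,
        )
        assert tp.surface_kl(surface, 2.1e-9) == pytest.approx(kl_true,
                                                               rel=1e-12)

    def test_saturated_run_is_error(self):
        surface = tp.SurfaceFluxField(
            area=np.ones(2), dCdy=np.full(2, 1e4), D_ABt=np.zeros(2),
            C_sat=0.25, C_bulk_mean=0.25 - 1e-12,
        )
        with pytest.raises(ValueError):
            tp.surface_kl(surface, 2.1e-9)


class TestSummaries:
    def _diag(self, eps, vol):
        n = eps.size
        zeros = np.zeros(n)
        return tp.TurbulenceDiagnostics(
            S_dd=zeros, nu_t=zeros, eps_res=eps, eps_sgs=zeros, eps=eps,
            eta=tp.kolmogorov(1e-6, eps), tau=zeros, D_ABt=zeros,
            cell_volume=vol,
        )

    def test_uniform_field_single_occupied_bin(self):
        diag = self._diag(np.full(100, 2e-4), np.full(100, 1e-9))
        out = tp.summarize_distributions(diag)
        assert np.count_nonzero(out["eps"]["histogram"]) == 1

    def test_equal_weights_match_unweighted_histogram(self, rng):
        eps = rng.uniform(1e-5, 1e-3, 500)
        diag = self._diag(eps, np.full(500, 3e-9))
        out = tp.summarize_distributions(diag, bins=20)
        unweighted, _ = np.histogram(eps, bins=out["eps"]["bin_edges"])
        assert out["eps"]["histogram"] == pytest.approx(
            unweighted * 3e-9, rel=1e-9
        )

    def test_two_valued_field_volume_split(self):
        eps = np.array([1e-4, 4e-4])
        diag = self._diag(eps, np.array([1.0, 3.0]))
        out = tp.summarize_distributions(diag, bins=2,
                                         quantiles=(0.05, 0.5, 0.95))
        hist = out["eps"]["histogram"]
        assert hist[0] / hist.sum() == pytest.approx(0.25)
        q = out["eps"]["quantiles"]
        assert q[0] == pytest.approx(1e-4)  # low quantile hits light value
        assert q[2] == pytest.approx(4e-4)  # high quantile hits heavy value

    def test_edr_exceedance_fraction(self):
        eps = np.array([1e-4, 1e-3, 2e-3, 1e-5])
        diag = self._diag(eps, np.array([1.0, 1.0, 2.0, 4.0]))
        out = tp.summarize_distributions(diag)
        assert out["volume_fraction_edr_above_limit"] == pytest.approx(3 / 8)


class TestDiagnoseField:
    def test_full_chain_consistency_on_taylor_green(self):
        field, _ = sd.gen_flow(sd.FlowSpec(kind="taylor_green", grid_n=16))
        diag = tp.diagnose_field(field)
        assert np.all(diag.eps == diag.eps_res + diag.eps_sgs)
        assert np.all(diag.nu_t >= 0)
        assert np.all(diag.D_ABt == pytest.approx(diag.nu_t / 1.34))
        finite = np.isfinite(diag.eta)
        assert np.all(diag.eta[finite] > 0)
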