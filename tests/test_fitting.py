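import numpy as np
import pytest

from nmrihm.fitting import (
    DEFAULT_BOUNDS,
    FitConfig,
    FitResult,
    difference_target_value,
    estimate_concentrations,
    pack_parameters,
    residual_vector,
    run_fit,
    unpack_parameters,
)
from nmrihm.mixture import MixtureModel, RegionSet, mixture_spectrum
from nmrihm.synthetic import simulate_mixture

from conftest import doublet, simple_component, singlet


@pytest.fixture
def small_model(grid500_small):
    a = simple_component("a", [singlet(7.0, label="s")], nuclei=1)
    b = simple_component(
        "b", [doublet(3.0, 10.0, label="d"), singlet(4.2, label="s2")],
        nuclei=3, amplitude=3,
    )
    return MixtureModel([a, b], np.array([1.0, 0.5]), grid500_small)


class TestFitConfig:
    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            FitConfig(mode="warp")

    def test_custom_mode_requires_sequence(self):
        with pytest.raises(ValueError, match="custom"):
            FitConfig(mode="custom")

    def test_unknown_optimizer_rejected(self):
        with pytest.raises(ValueError, match="gradient_descent"):
            FitConfig(mode="custom", custom_sequence=("gradient_descent",))

    def test_mode_to_sequence_mapping(self):
        assert FitConfig(mode="fast").sequence == ("levenberg_marquardt",)
        assert FitConfig(mode="tight").sequence == (
            "simplex", "levenberg_marquardt",
        )
        seq = ("simplex", "levenberg_marquardt", "levenberg_marquardt")
        assert FitConfig(mode="custom", custom_sequence=seq).sequence == seq

    def test_partial_bounds_merge_with_defaults(self):
        cfg = FitConfig(bounds={"center_window_ppm": 0.01})
        assert cfg.bounds["center_window_ppm"] == 0.01
        assert cfg.bounds["conc_max_factor"] == DEFAULT_BOUNDS["conc_max_factor"]


class TestParameterPacking:
    def test_round_trip_is_identity(self, small_model):
        params = pack_parameters(small_model, FitConfig())
        back = unpack_parameters(params, small_model)
        np.testing.assert_array_equal(back.concentrations, small_model.concentrations)
        for c0, c1 in zip(small_model.components, back.components):
            assert c0 == c1

    def test_parameter_count(self, small_model):
        # M concentrations + one center per multiplet + 4 per feature
        params = pack_parameters(small_model, FitConfig())
        n_mult = sum(len(c.multiplets) for c in small_model.components)
        n_feat = sum(c.n_peaks for c in small_model.components)
        assert len(params) == 2 + n_mult + 4 * n_feat

    def test_default_vary_flags(self, small_model):
        params = pack_parameters(small_model, FitConfig())
        for nm, p in params.items():
            if nm.startswith(("fo_", "fa_")):
                assert not p.vary, f"{nm} should be frozen by default"
            else:
                assert p.vary, f"{nm} should be free by default"

    def test_bounds_follow_config(self, small_model):
        cfg = FitConfig(bounds={"center_window_ppm": 0.015, "conc_max_factor": 3.0})
        params = pack_parameters(small_model, cfg)
        assert params["c_0"].min == 0.0
        assert params["c_0"].max == pytest.approx(3.0 * 1.0)
        m0 = small_model.components[0].multiplets[0].center_ppm
        assert params["mc_0"].min == pytest.approx(m0 - 0.015)
        assert params["mc_0"].max == pytest.approx(m0 + 0.015)
        assert params["fb_0"].min == 0.0 and params["fb_0"].max == 1.0

    def test_modified_values_propagate(self, small_model):
        params = pack_parameters(small_model, FitConfig())
        params["c_1"].value = 0.75
        params["mc_0"].value = small_model.components[0].multiplets[0].center_ppm + 0.01
        back = unpack_parameters(params, small_model)
        assert back.concentrations[1] == 0.75
        assert back.components[0].multiplets[0].center_ppm == pytest.approx(
            small_model.components[0].multiplets[0].center_ppm + 0.01
        )


class TestResidual:
    def test_residual_matches_direct_subtraction(self, small_model):
        exp = mixture_spectrum(small_model)
        other = small_model.copy()
        other.concentrations = np.array([0.8, 0.6])
        regions = RegionSet([(7.5, 6.5), (4.8, 2.4)])
        r = residual_vector(other, exp, regions)
        idx = regions.mask(small_model.grid)
        direct = exp.intensities[idx] - mixture_spectrum(other).intensities[idx]
        np.testing.assert_allclose(r, direct, rtol=1e-10, atol=1e-12)

    def test_self_residual_is_zero(self, small_model):
        exp = mixture_spectrum(small_model)
        assert difference_target_value(small_model, exp) == pytest.approx(
            0.0, abs=1e-18
        )

    def test_target_is_quadratic_in_scale(self, small_model):
        exp = mixture_spectrum(small_model)
        zero = small_model.copy()
        zero.concentrations = np.array([0.0, 0.0])
        t1 = difference_target_value(zero, exp)
        exp2 = type(exp)(exp.grid, 3.0 * exp.intensities)
        t3 = difference_target_value(zero, exp2)
        assert t3 == pytest.approx(9.0 * t1, rel=1e-10)

    def test_grid_mismatch_rejected(self, small_model, grid500):
        exp = mixture_spectrum(small_model)
        other = MixtureModel(small_model.components, small_model.concentrations,
                             grid500)
        with pytest.raises(ValueError, match="grid"):
            residual_vector(other, exp)


class TestConcentrationEstimate:
    def test_exact_on_aligned_noiseless_data(self, small_model):
        truth = small_model.copy()
        truth.concentrations = np.array([1.3, 0.4])
        exp = mixture_spectrum(truth)
        est = estimate_concentrations(small_model, exp)
        np.testing.assert_allclose(est, [1.3, 0.4], rtol=1e-8)

    def test_nonnegative_even_for_absent_component(self, small_model):
        truth = small_model.copy()
        truth.concentrations = np.array([1.0, 0.0])
        exp = mixture_spectrum(truth)
        est = estimate_concentrations(small_model, exp)
        assert np.all(est >= 0)
        assert est[1] == pytest.approx(0.0, abs=1e-6)

    def test_broadening_tolerates_misalignment(self, grid500_small):
        # a 0.02 ppm shift makes the sharp linear solve collapse;
        # broadening by more than the shift keeps it quantitative
        lib = [simple_component("a", [singlet(7.0)]),
               simple_component("b", [singlet(3.0)])]
        truth_c = np.array([1.0, 0.7])
        exp, truth = simulate_mixture(lib, truth_c, drift_ppm=0.02, seed=4,
                                      grid=grid500_small)
        guess = MixtureModel(lib, np.ones(2), grid500_small)
        sharp = estimate_concentrations(guess, exp)
        broad = estimate_concentrations(guess, exp, broaden_hz=25.0)
        err_sharp = np.abs(sharp - truth_c).max()
        err_broad = np.abs(broad - truth_c).max()
        assert err_broad < 0.25 * err_sharp
        assert np.all(broad > 0.5 * truth_c)


class TestRunFit:
    def test_noiseless_guess_at_truth_is_a_fixed_point(self, small_model):
        exp = mixture_spectrum(small_model)
        res = run_fit(small_model, exp, config=FitConfig(mode="fast"))
        scale = float(np.dot(exp.intensities, exp.intensities))
        assert res.target_final <= 1e-10 * scale
        np.testing.assert_allclose(
            res.model.concentrations, small_model.concentrations, rtol=1e-4
        )

    def test_concentrations_recovered_from_perturbed_guess(self, grid500_small):
        lib = [
            simple_component("a", [singlet(7.0, label="s")], nuclei=1),
            simple_component("b", [doublet(3.0, 10.0, label="d")], nuclei=2,
                             amplitude=2),
        ]
        truth_c = np.array([1.0, 0.6])
        exp, truth = simulate_mixture(lib, truth_c, seed=8, grid=grid500_small)
        sigma = exp.intensities.max() / 500.0
        rng = np.random.default_rng(12)
        noisy = type(exp)(exp.grid, exp.intensities + rng.normal(0, sigma,
                                                                 exp.grid.n_points))
        guess = MixtureModel(lib, np.array([0.5, 1.5]), grid500_small)
        res = run_fit(guess, noisy, config=FitConfig(mode="fast"))
        np.testing.assert_allclose(res.model.concentrations, truth_c, rtol=0.01)

    def test_stage_targets_never_increase(self, small_model):
        exp = mixture_spectrum(small_model)
        off = small_model.copy()
        off.concentrations = np.array([0.7, 0.8])
        res = run_fit(off, exp, config=FitConfig(mode="tight"))
        last = res.target_initial
        for entry in res.stage_log:
            assert entry["target_final"] <= last * (1 + 1e-12)
            last = entry["target_final"]
        assert res.target_final <= res.target_initial

    def test_tight_mode_never_worse_than_fast(self, grid500_small):
        # displaced centers + noise: a well-posed floor so the two modes
        # are compared on a rugged problem, not on numerical dust
        lib = [
            simple_component("a", [singlet(7.0, label="s")], nuclei=1),
            simple_component("b", [doublet(3.0, 10.0, label="d")], nuclei=2,
                             amplitude=2),
        ]
        exp, _ = simulate_mixture(lib, np.array([1.0, 0.6]), seed=2,
                                  grid=grid500_small)
        sigma = exp.intensities.max() / 1000.0
        rng = np.random.default_rng(21)
        noisy = type(exp)(exp.grid, exp.intensities + rng.normal(
            0, sigma, exp.grid.n_points))
        displaced = [
            type(c)(name=c.name,
                    multiplets=tuple(m.shifted(0.025) for m in c.multiplets),
                    total_amplitude=c.total_amplitude, nuclei=c.nuclei)
            for c in lib
        ]
        guess = MixtureModel(displaced, np.array([0.5, 1.2]), grid500_small)
        fast = run_fit(guess, noisy, config=FitConfig(mode="fast"))
        tight = run_fit(guess, noisy, config=FitConfig(mode="tight"))
        assert tight.target_final <= fast.target_final * 1.001

    def test_residual_is_unpolarized_after_fit(self, small_model):
        exp = mixture_spectrum(small_model)
        off = small_model.copy()
        off.concentrations = np.array([0.9, 0.55])
        res = run_fit(off, exp, config=FitConfig(mode="fast"))
        assert abs(res.residual.mean()) <= 1e-6 * np.abs(exp.intensities).max()

    def test_all_zero_mask_rejected(self, small_model):
        exp = type(mixture_spectrum(small_model))(
            small_model.grid, np.zeros(small_model.grid.n_points)
        )
        with pytest.raises(ValueError, match="zero"):
            run_fit(small_model, exp)

    def test_worsening_result_is_rejected_by_contract(self, small_model):
        with pytest.raises(ValueError, match="exceeds"):
            FitResult(
                model=small_model, target_initial=1.0, target_final=2.0,
                residual=np.zeros(3), parameters={}, bound_hits={},
                stage_log=[], regions=RegionSet.full_axis(small_model.grid),
            )
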