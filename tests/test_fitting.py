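"""Tests for profiled NLS fitting, model comparison and the bootstrap."""

import numpy as np
import pandas as pd
import pytest

from ninflux import (
    AssayDesign,
    ComparisonError,
    ConfigurationError,
    DegenerateDataError,
    FitFailureError,
    InfluxDataset,
    InsufficientDataError,
    KineticParams,
    NoiseModel,
    bootstrap_ci,
    brute_force_fit,
    compare_models,
    default_t_candidates,
    fit_single_mm,
    fit_two_stage,
    reference,
    simulate_influx,
    sse_at,
)

AMMONIUM = reference.AMMONIUM_PARAMS
NITRATE = reference.NITRATE_PARAMS


def mono_dataset(noise: NoiseModel) -> InfluxDataset:
    """Pure single-phase data: threshold beyond the whole grid."""
    p = KineticParams(V1=2.02, Km1=0.31, V2=0.0, Km2=1.0, T=11.0)
    return simulate_influx(p, AssayDesign(n_source="nitrate"), noise)


class TestFitSingleMM:
    def test_noise_free_round_trip(self):
        ds = mono_dataset(NoiseModel(kind="none", seed=0))
        fit = fit_single_mm(ds)
        assert fit.converged
        assert fit.params.V == pytest.approx(2.02, rel=1e-6)
        assert fit.params.Km == pytest.approx(0.31, rel=1e-6)

    def test_saturated_data_pins_km_at_zero(self):
        df = pd.DataFrame({
            "n_source": "x",
            "S_mM": np.repeat([1.0, 2.0, 5.0, 10.0], 2),
            "replicate": list(range(1, 3)) * 4,
            "v_umol_per_gDW_h": 2.0,
        })
        fit = fit_single_mm(InfluxDataset(data=df))
        assert fit.params.Km < 1e-4
        assert fit.params.V == pytest.approx(2.0, rel=1e-3)

    def test_mono_fit_worse_than_two_stage_on_biphasic_data(self, nitrate_clean):
        mono = fit_single_mm(nitrate_clean)
        two = fit_two_stage(nitrate_clean)
        assert mono.sse > two.sse
        assert mono.sse > 1.0  # the biphasic shape is far from any mono curve

    def test_all_zero_rates_degenerate(self):
        df = pd.DataFrame({"n_source": "x", "S_mM": [1.0, 2.0, 5.0],
                           "replicate": [1, 1, 1],
                           "v_umol_per_gDW_h": [0.0, 0.0, 0.0]})
        with pytest.raises(DegenerateDataError):
            fit_single_mm(InfluxDataset(data=df))

    def test_too_few_concentrations(self):
        df = pd.DataFrame({"n_source": "x", "S_mM": [1.0, 2.0],
                           "replicate": [1, 1],
                           "v_umol_per_gDW_h": [0.5, 0.8]})
        with pytest.raises(InsufficientDataError):
            fit_single_mm(InfluxDataset(data=df))


class TestFitTwoStage:
    @pytest.mark.parametrize("params", [AMMONIUM, NITRATE],
                             ids=["ammonium", "nitrate"])
    def test_noise_free_round_trip_recovers_printed_constants(self, params):
        ds = simulate_influx(params, AssayDesign(),
                             NoiseModel(kind="none", seed=0))
        fit = fit_two_stage(ds)
        assert fit.converged
        est = fit.params
        for name in ("V1", "Km1", "V2", "Km2"):
            assert getattr(est, name) == pytest.approx(
                getattr(params, name), rel=1e-3), name
        assert est.T == params.T  # candidate grid contains the truth exactly

    def test_degenerate_second_phase_matches_mono_sse(self):
        # the two-stage family contains every mono curve exactly, so on
        # single-phase data its SSE cannot exceed the mono fit's
        ds = mono_dataset(NoiseModel(kind="none", seed=0))
        mono, two = fit_single_mm(ds), fit_two_stage(ds)
        assert two.sse == pytest.approx(mono.sse, abs=1e-12)

    def test_optimizer_dominates_generating_parameters(self, nitrate_noisy):
        fit = fit_two_stage(nitrate_noisy)
        assert fit.sse <= sse_at(nitrate_noisy, NITRATE) * (1 + 1e-9)

    def test_nesting_two_stage_never_worse_than_mono(self):
        ds = mono_dataset(NoiseModel(cv_or_sigma=0.05, seed=5))
        mono = fit_single_mm(ds)
        cands = list(default_t_candidates(ds.S)) + [float(ds.S.max()) + 1.0]
        two = fit_two_stage(ds, t_candidates=cands)
        assert two.sse <= mono.sse * (1 + 1e-9)

    def test_ridge_ratio_recovered_despite_km2_above_grid(self):
        # ammonium LATS: Km2 = 81.3 mM >> max(S); V2 and Km2 are poorly
        # identified individually but their ratio (the initial LATS slope)
        # is tight
        true_ratio = AMMONIUM.V2 / AMMONIUM.Km2
        for seed in (0, 1, 2):
            ds = simulate_influx(AMMONIUM, AssayDesign(),
                                 NoiseModel(cv_or_sigma=0.02, seed=seed))
            fit = fit_two_stage(ds)
            ratio = fit.params.V2 / fit.params.Km2
            assert ratio == pytest.approx(true_ratio, rel=0.05)

    def test_t_profile_reported_and_minimal_at_estimate(self, nitrate_clean):
        fit = fit_two_stage(nitrate_clean)
        sses = {p["T"]: p["sse"] for p in fit.t_profile}
        assert fit.sse <= min(sses.values()) + 1e-9
        assert fit.params.T in sses

    def test_no_admissible_candidate_split(self, nitrate_clean):
        with pytest.raises(InsufficientDataError):
            fit_two_stage(nitrate_clean, t_candidates=[0.011])

    def test_too_few_concentrations(self):
        df = pd.DataFrame({"n_source": "x", "S_mM": [0.1, 0.2, 1.0, 2.0],
                           "replicate": 1,
                           "v_umol_per_gDW_h": [0.5, 0.8, 1.2, 1.5]})
        with pytest.raises(InsufficientDataError):
            fit_two_stage(InfluxDataset(data=df))


class TestBruteForceOracle:
    def grids_around(self, p, rel=0.2, n=5):
        return {k: np.linspace(v * (1 - rel), v * (1 + rel), n)
                for k, v in p.to_dict().items()}

    def test_grid_containing_truth_finds_it_exactly(self, nitrate_clean):
        bf = brute_force_fit(nitrate_clean, self.grids_around(NITRATE))
        assert bf.sse == pytest.approx(0.0, abs=1e-20)
        assert bf.params.to_dict() == pytest.approx(NITRATE.to_dict())

    def test_grid_excluding_truth_has_positive_sse(self, nitrate_clean):
        grids = self.grids_around(NITRATE)
        grids["V1"] = np.array([1.0, 1.5])  # truth 2.02 excluded
        bf = brute_force_fit(nitrate_clean, grids)
        assert bf.sse > 0

    def test_profiled_fit_matches_oracle_argmin(self, nitrate_clean):
        # noise-free: both the grid oracle and the continuous optimizer land
        # exactly on the generating parameters
        fit = fit_two_stage(nitrate_clean)
        grids = self.grids_around(NITRATE, rel=0.3, n=7)
        bf = brute_force_fit(nitrate_clean, grids)
        for name, grid in grids.items():
            est = getattr(fit.params, name)
            nearest = grid[np.argmin(np.abs(grid - est))]
            assert getattr(bf.params, name) == pytest.approx(nearest)

    def test_profiled_fit_dominates_oracle_on_noisy_data(self, nitrate_noisy):
        # the continuous optimizer must be at least as good as any grid point
        fit = fit_two_stage(nitrate_noisy)
        bf = brute_force_fit(nitrate_noisy, self.grids_around(NITRATE, rel=0.3, n=7))
        assert fit.sse <= bf.sse + 1e-9

    def test_oversize_grid_refused(self, nitrate_clean):
        grids = {k: np.linspace(1, 2, 26) for k in
                 ("V1", "Km1", "V2", "Km2", "T")}
        with pytest.raises(ConfigurationError, match="1e7|cap"):
            brute_force_fit(nitrate_clean, grids)  # 26^5 > 1e7


class TestCompareModels:
    def test_biphasic_data_selects_two_stage(self, nitrate_noisy):
        cmp_ = compare_models(fit_single_mm(nitrate_noisy),
                              fit_two_stage(nitrate_noisy))
        assert cmp_.selected == "two_stage"
        assert cmp_.delta == cmp_.aicc_two - cmp_.aicc_mono

    def test_mono_data_selects_mono_in_majority_of_seeds(self):
        wins = 0
        seeds = range(11)
        for seed in seeds:
            ds = mono_dataset(NoiseModel(cv_or_sigma=0.05, seed=seed))
            cmp_ = compare_models(fit_single_mm(ds), fit_two_stage(ds))
            wins += cmp_.selected == "mono"
        assert wins > len(seeds) / 2

    def test_small_sample_aicc_undefined(self):
        df = pd.DataFrame({"n_source": "x",
                           "S_mM": [0.05, 0.1, 0.5, 1.0, 2.0, 5.0],
                           "replicate": 1,
                           "v_umol_per_gDW_h": [0.3, 0.5, 1.0, 1.2, 1.5, 1.7]})
        ds = InfluxDataset(data=df)
        mono, two = fit_single_mm(ds), fit_two_stage(ds)
        with pytest.raises(ComparisonError):  # n = 6 = k + 1 for k = 5
            compare_models(mono, two)

    def test_mismatched_datasets_rejected(self, nitrate_clean, nitrate_noisy):
        with pytest.raises(ComparisonError):
            compare_models(fit_single_mm(nitrate_clean),
                           fit_two_stage(nitrate_noisy))


class TestBootstrap:
    def test_deterministic_under_seed(self, nitrate_noisy):
        fit = fit_two_stage(nitrate_noisy)
        a = bootstrap_ci(nitrate_noisy, fit, n_boot=100, seed=9)
        b = bootstrap_ci(nitrate_noisy, fit, n_boot=100, seed=9)
        assert a.ci == b.ci

    def test_noise_free_data_gives_zero_width(self, nitrate_clean):
        fit = fit_two_stage(nitrate_clean)
        out = bootstrap_ci(nitrate_clean, fit, n_boot=100, seed=0)
        for lo, hi in out.ci.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-9)
        assert not out.ci_warning

    def test_interval_covers_truth_here(self, nitrate_noisy):
        fit = fit_two_stage(nitrate_noisy)
        out = bootstrap_ci(nitrate_noisy, fit, n_boot=200, seed=1)
        lo, hi = out.ci["V1"]
        assert lo < NITRATE.V1 < hi
        assert lo < fit.params.V1 < hi

    def test_mono_model_bootstrap(self):
        ds = mono_dataset(NoiseModel(cv_or_sigma=0.05, seed=2))
        fit = fit_single_mm(ds)
        out = bootstrap_ci(ds, fit, n_boot=100, seed=3)
        assert set(out.ci) == {"V", "Km"}

    def test_too_few_resamples_rejected(self, nitrate_noisy):
        fit = fit_two_stage(nitrate_noisy)
        with pytest.raises(ConfigurationError):
            bootstrap_ci(nitrate_noisy, fit, n_boot=50, seed=0)
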