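"""Kinetic fitting: goodness of fit, derived constants, recovery, ranking."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from affinikit import reference as ref
from affinikit.exceptions import (
    InvalidParameterError,
    MissingMolecularWeightError,
    UnderDeterminedError,
)
from affinikit.kinetics import (
    chi_square,
    compare_models,
    derive_equilibrium_constants,
    fit_kinetics,
    lag1_autocorrelation,
)
from affinikit.models import BivalentAnalyteParams, OneToOneParams
from affinikit.synth import GeneratorConfig, gen_sensorgrams


class TestChiSquare:
    def test_perfect_fit_is_zero(self):
        x = np.array([5.0, 10.0, 200.0])
        assert chi_square(x, x) == 0.0

    def test_hand_arithmetic(self):
        # (4-2)^2/2 + (9-10)^2/10 = 2.1
        assert chi_square([4, 9], [2, 10]) == pytest.approx(2.1)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(7)
        obs = rng.uniform(0, 500, 100)
        exp = rng.uniform(0, 500, 100)
        brute = sum((o - e) ** 2 / max(e, 1.0) for o, e in zip(obs, exp))
        assert chi_square(obs, exp) == pytest.approx(brute, rel=1e-12)

    def test_denominator_floor_guards_small_expected(self):
        # expected near zero would explode without the 1 RU floor
        assert chi_square([1.0], [1e-9]) == pytest.approx(1.0, rel=1e-6)

    def test_empty_input_raises(self):
        with pytest.raises(UnderDeterminedError):
            chi_square([], [])


class TestDerivedConstants:
    @pytest.mark.parametrize(
        "k_on1,k_off1,k_on2_molar,k_off2,kd1_3sf,kd2_3sf",
        [
            # published local and global bivalent fits
            (7.24e4, 0.439, 156.6, 4.30e-3, 6.06e-6, 2.75e-5),
            (5.22e4, 0.380, 96.9, 4.10e-3, 7.28e-6, 4.23e-5),
        ])
    def test_reproduces_published_constants_to_3sf(
            self, k_on1, k_off1, k_on2_molar, k_off2, kd1_3sf, kd2_3sf):
        mw = ref.ANALYTE_MW_DA
        params = BivalentAnalyteParams(
            k_on1=k_on1, k_off1=k_off1,
            k_on2_ru=k_on2_molar / (100.0 * mw), k_off2=k_off2,
            R_max=1000.0, analyte_mw=mw)
        kc = derive_equilibrium_constants(params)
        assert kc.K_D1 == pytest.approx(kd1_3sf, rel=5e-3)
        assert kc.K_D2 == pytest.approx(kd2_3sf, rel=5e-3)
        assert kc.k_on2_molar == pytest.approx(k_on2_molar, rel=1e-12)

    def test_unit_rates_give_unit_kd(self):
        params = BivalentAnalyteParams(k_on1=1.0, k_off1=1.0,
                                       k_on2_ru=1e-6, k_off2=1e-3,
                                       R_max=100.0, analyte_mw=1e5)
        assert derive_equilibrium_constants(params).K_D1 == 1.0

    def test_missing_molecular_weight_raises(self):
        params = BivalentAnalyteParams(k_on1=1e4, k_off1=0.1, k_on2_ru=1e-6,
                                       k_off2=1e-3, R_max=100.0)
        with pytest.raises(MissingMolecularWeightError):
            derive_equilibrium_constants(params)

    def test_one_to_one_params_give_kd_only(self):
        kc = derive_equilibrium_constants(
            OneToOneParams(k_on=1e5, k_off=0.5, R_max=100.0))
        assert kc.K_D1 == pytest.approx(5e-6)
        assert kc.K_D2 is None


class TestGlobalFitRecovery:
    def test_noise_free_recovery_within_one_percent(
            self, noise_free_global_fit, global_params):
        f = noise_free_global_fit.params
        t = global_params
        for name in ("k_on1", "k_off1", "k_on2_ru", "k_off2", "R_max"):
            assert getattr(f, name) == pytest.approx(
                getattr(t, name), rel=0.01), name

    def test_kd1_identity_holds_exactly(self, noise_free_global_fit):
        r = noise_free_global_fit
        assert r.derived.K_D1 * r.params.k_on1 == pytest.approx(
            r.params.k_off1, rel=1e-15)

    def test_per_cycle_ri_and_shared_rmax(self, noise_free_global_fit,
                                          kinetic_concs):
        assert len(noise_free_global_fit.ri_per_cycle) == kinetic_concs.size

    def test_fit_is_deterministic(self, global_params, protocol):
        concs = ref.KINETIC_CONCENTRATIONS_M[-3:]
        sgs = gen_sensorgrams(global_params, concs, protocol,
                              GeneratorConfig(seed=4, noise_sd_ru=2.0))
        r1 = fit_kinetics(sgs, model="bivalent", scope="global",
                          mw=global_params.analyte_mw)
        r2 = fit_kinetics(sgs, model="bivalent", scope="global",
                          mw=global_params.analyte_mw)
        assert r1.params == r2.params
        assert r1.ri_per_cycle == r2.ri_per_cycle
        assert r1.chi_square_paper == r2.chi_square_paper


class TestOneToOneFit:
    def test_round_trip_recovery(self, one_to_one_sensorgrams,
                                 one_to_one_params):
        r = fit_kinetics(one_to_one_sensorgrams, model="one_to_one",
                         scope="global")
        assert r.params.k_on == pytest.approx(one_to_one_params.k_on,
                                              rel=0.01)
        assert r.params.k_off == pytest.approx(one_to_one_params.k_off,
                                               rel=0.01)

    def test_bivalent_fit_of_one_to_one_data_collapses_second_site(
            self, one_to_one_sensorgrams):
        r = fit_kinetics(one_to_one_sensorgrams, model="bivalent",
                         scope="global", mw=ref.ANALYTE_MW_DA)
        # second-site pathway contributes nothing: either its on-rate has
        # collapsed toward the lower bound or its equilibrium occupancy at
        # full capacity is negligible
        occupancy = r.params.k_on2_ru * r.params.R_max / r.params.k_off2
        assert r.params.k_on2_ru < 1e-9 or occupancy < 0.05


class TestLocalFit:
    def test_local_fit_structure_and_recovery(self, local_params, protocol):
        sgs = gen_sensorgrams(local_params, [7.1e-6], protocol,
                              GeneratorConfig(seed=2, noise_sd_ru=0.0))
        r = fit_kinetics(sgs[0], model="bivalent", scope="local",
                         mw=local_params.analyte_mw)
        assert r.scope == "local"
        assert len(r.ri_per_cycle) == 1
        assert r.concentration_range.tolist() == [7.1e-6]
        assert r.params.k_on1 == pytest.approx(local_params.k_on1, rel=0.01)
        assert r.params.k_off1 == pytest.approx(local_params.k_off1, rel=0.01)

    def test_local_rejects_multiple_cycles(self, noise_free_sensorgrams):
        with pytest.raises(InvalidParameterError):
            fit_kinetics(noise_free_sensorgrams, model="bivalent",
                         scope="local")

    def test_local_and_global_kd1_agree(self, noise_free_global_fit,
                                        global_params, protocol):
        sgs = gen_sensorgrams(global_params, [7.1e-6], protocol,
                              GeneratorConfig(seed=3, noise_sd_ru=2.0))
        local = fit_kinetics(sgs[0], model="bivalent", scope="local",
                             mw=global_params.analyte_mw)
        ratio = local.derived.K_D1 / noise_free_global_fit.derived.K_D1
        assert 0.75 < ratio < 1.25


@pytest.fixture(scope="module")
def bivalent_data_fits(global_params, protocol):
    sgs = gen_sensorgrams(global_params,
                          ref.KINETIC_CONCENTRATIONS_M[-4:], protocol,
                          GeneratorConfig(seed=6, noise_sd_ru=2.0))
    biv = fit_kinetics(sgs, model="bivalent", scope="global",
                       mw=global_params.analyte_mw)
    one = fit_kinetics(sgs, model="one_to_one", scope="global")
    return biv, one


class TestModelComparison:
    def test_bivalent_data_ranks_bivalent_first(self, bivalent_data_fits):
        biv, one = bivalent_data_fits
        cmp = compare_models([one, biv])
        assert cmp.entries[0]["model"] == "bivalent"
        assert cmp.best_model == "bivalent"
        assert "bivalent" not in cmp.overparameterized

    def test_identical_fits_reported_as_tie(self, bivalent_data_fits):
        biv, _ = bivalent_data_fits
        cmp = compare_models([biv, biv])
        assert cmp.tie
        assert cmp.best_model is None

    def test_one_to_one_data_flags_overparameterized_bivalent(
            self, one_to_one_sensorgrams):
        one = fit_kinetics(one_to_one_sensorgrams, model="one_to_one",
                           scope="global")
        biv = fit_kinetics(one_to_one_sensorgrams, model="bivalent",
                           scope="global", mw=ref.ANALYTE_MW_DA)
        cmp = compare_models([one, biv])
        chis = {e["model"]: e["chi_square"] for e in cmp.entries}
        if chis["bivalent"] <= chis["one_to_one"]:
            assert "bivalent" in cmp.overparameterized

    def test_mismatched_data_rejected(self, bivalent_data_fits,
                                      noise_free_global_fit):
        biv, _ = bivalent_data_fits
        with pytest.raises(InvalidParameterError):
            compare_models([biv, noise_free_global_fit])


class TestResidualStatistics:
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=50))
    def test_lag1_autocorrelation_bounded(self, values):
        r = lag1_autocorrelation(np.array(values))
        assert -1.000001 <= r <= 1.000001

    def test_white_noise_has_low_autocorrelation(self):
        rng = np.random.default_rng(0)
        assert abs(lag1_autocorrelation(rng.normal(size=5000))) < 0.05

    def test_smooth_trace_has_high_autocorrelation(self):
        t = np.linspace(0, 1, 200)
        assert lag1_autocorrelation(np.sin(2 * np.pi * t)) > 0.9
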