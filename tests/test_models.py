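"""Forward-model correctness: closed forms, ODE scheme, invariants."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from affinikit.exceptions import InvalidParameterError
from affinikit.models import (
    PHASE_ASSOCIATION,
    PHASE_BASELINE,
    PHASE_DISSOCIATION,
    BivalentAnalyteParams,
    InjectionProtocol,
    OneToOneParams,
    Sensorgram,
    closed_form_one_to_one,
    equilibrium_response_bivalent,
    simulate_bivalent,
)


def _params_with(params, **overrides):
    fields = dict(k_on1=params.k_on1, k_off1=params.k_off1,
                  k_on2_ru=params.k_on2_ru, k_off2=params.k_off2,
                  R_max=params.R_max, RI=params.RI,
                  analyte_mw=params.analyte_mw)
    fields.update(overrides)
    return BivalentAnalyteParams(**fields)


class TestClosedFormOneToOne:
    def test_zero_concentration_gives_ri_only(self):
        p = OneToOneParams(k_on=1e5, k_off=0.5, R_max=1000, RI=7.0)
        proto = InjectionProtocol(analyte_concentration=0.0)
        sg = closed_form_one_to_one(p, proto)
        assoc = sg.mask(PHASE_ASSOCIATION)
        assert np.allclose(sg.responses[assoc], 7.0)
        assert np.allclose(sg.responses[~assoc], 0.0)

    def test_irreversible_limit_plateaus_at_rmax_plus_ri(self):
        p = OneToOneParams(k_on=1e6, k_off=1e-9, R_max=800, RI=3.0)
        proto = InjectionProtocol(analyte_concentration=1e-4,
                                  association_duration=5000,
                                  dissociation_duration=10,
                                  sampling_interval=5.0)
        sg = closed_form_one_to_one(p, proto)
        plateau = sg.responses[sg.mask(PHASE_ASSOCIATION)][-1]
        assert plateau == pytest.approx(800 + 3.0, rel=1e-6)

    def test_association_value_matches_ode_integration(self):
        # K_D = 5e-6 M equals C, so R_eq = R_max/2 = 500 RU; at t = 30 s
        # the exponential term is negligible and R ~ 500.
        p = OneToOneParams(k_on=1e5, k_off=0.5, R_max=1000, RI=0.0)
        C = 5e-6
        proto = InjectionProtocol(analyte_concentration=C,
                                  association_duration=30)
        sg = closed_form_one_to_one(p, proto)
        r30 = sg.responses[np.argmin(np.abs(sg.times - 30.0))]
        k_obs = p.k_on * C + p.k_off
        expected = 500.0 * (1 - np.exp(-k_obs * 30))
        assert r30 == pytest.approx(expected, rel=1e-12)
        # independent oracle: numerical integration of dR/dt
        sol = solve_ivp(lambda t, r: p.k_on * C * (p.R_max - r) - p.k_off * r,
                        (0, 30), [0.0], rtol=1e-10, atol=1e-10)
        assert r30 == pytest.approx(sol.y[0, -1], rel=1e-6)

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(InvalidParameterError):
            OneToOneParams(k_on=-1.0, k_off=0.5, R_max=100)
        with pytest.raises(InvalidParameterError):
            OneToOneParams(k_on=1e5, k_off=0.0, R_max=100)


class TestBivalentSimulator:
    def test_reduces_to_one_to_one_when_second_site_off(self, global_params):
        p2 = _params_with(global_params, k_on2_ru=0.0, k_off2=1e-9)
        p1 = OneToOneParams(k_on=p2.k_on1, k_off=p2.k_off1, R_max=p2.R_max,
                            RI=p2.RI)
        proto = InjectionProtocol(analyte_concentration=7.1e-6)
        biv = simulate_bivalent(p2, proto)
        one = closed_form_one_to_one(p1, proto)
        assert np.max(np.abs(biv.responses - one.responses)) \
            < 1e-6 * p2.R_max

    def test_conservation_bounds(self, global_params):
        rng = np.random.default_rng(11)
        for _ in range(5):
            p = _params_with(
                global_params,
                k_on1=global_params.k_on1 * rng.uniform(0.2, 5),
                k_off1=global_params.k_off1 * rng.uniform(0.2, 5),
                k_on2_ru=global_params.k_on2_ru * rng.uniform(0.2, 5),
                k_off2=global_params.k_off2 * rng.uniform(0.2, 5), RI=0.0)
            proto = InjectionProtocol(
                analyte_concentration=rng.uniform(0.1e-6, 50e-6))
            sg = simulate_bivalent(p, proto)
            assert np.all(sg.responses >= -1e-6)
            assert np.all(sg.responses <= p.R_max * (1 + 1e-9))

    def test_response_monotone_in_concentration(self, global_params):
        concs = np.array([0.5e-6, 1e-6, 2e-6, 4e-6, 8e-6])
        traces = []
        for c in concs:
            proto = InjectionProtocol(analyte_concentration=c)
            sg = simulate_bivalent(_params_with(global_params, RI=0.0), proto)
            traces.append(sg.responses[sg.mask(PHASE_ASSOCIATION)])
        traces = np.array(traces)
        # at every association time point, response non-decreasing in C
        assert np.all(np.diff(traces, axis=0) >= -1e-6)

    def test_fast_dissociation_at_reference_local_parameters(
            self, local_params):
        # Dissociation dominated by the fast first-site off-rate: most of
        # the bound signal is lost within seconds of injection stop.
        proto = InjectionProtocol(analyte_concentration=7.1e-6)
        sg = simulate_bivalent(local_params, proto)
        assoc_end = sg.responses[sg.mask(PHASE_ASSOCIATION)][-1] \
            - local_params.RI
        dissoc = sg.mask(PHASE_DISSOCIATION)
        r10s = sg.responses[dissoc][np.argmin(
            np.abs(sg.times[dissoc] - 40.0))]
        assert r10s < 0.5 * assoc_end

    def test_dissociation_lengthens_with_ligand_density(self, global_params):
        fractions = []
        for r_max in (244.0, 525.0, 1000.0):
            p = _params_with(global_params, R_max=r_max, RI=0.0)
            proto = InjectionProtocol(analyte_concentration=7.1e-6)
            sg = simulate_bivalent(p, proto)
            dissoc = sg.mask(PHASE_DISSOCIATION)
            r0 = sg.responses[sg.mask(PHASE_ASSOCIATION)][-1]
            idx = np.argmin(np.abs(sg.times[dissoc] - 90.0))  # 60 s in
            fractions.append(sg.responses[dissoc][idx] / r0)
        assert np.all(np.diff(fractions) >= 0)


class TestEquilibriumResponse:
    def test_zero_concentration(self, global_params):
        assert equilibrium_response_bivalent(global_params, 0.0) == 0.0

    def test_reduces_to_langmuir_isotherm(self, global_params):
        p = _params_with(global_params, k_on2_ru=0.0)
        C = 3e-6
        kd = p.k_off1 / p.k_on1
        assert equilibrium_response_bivalent(p, C) == pytest.approx(
            p.R_max * C / (C + kd), rel=1e-12)

    @pytest.mark.parametrize("conc", [0.5e-6, 7.1e-6, 57e-6])
    def test_matches_long_time_ode_plateau(self, global_params, conc):
        proto = InjectionProtocol(analyte_concentration=conc,
                                  association_duration=20000,
                                  dissociation_duration=10,
                                  sampling_interval=10.0)
        sg = simulate_bivalent(_params_with(global_params, RI=0.0), proto)
        plateau = sg.responses[sg.mask(PHASE_ASSOCIATION)][-1]
        eq = equilibrium_response_bivalent(global_params, conc)
        assert abs(plateau - eq) < 0.1  # RU


class TestSensorgramValidation:
    def test_rejects_non_monotone_times(self):
        with pytest.raises(InvalidParameterError):
            Sensorgram(times=[0, 1, 1], responses=[0, 0, 0],
                       phases=[PHASE_BASELINE] * 3, concentration=1e-6)

    def test_rejects_unknown_phase(self):
        with pytest.raises(InvalidParameterError):
            Sensorgram(times=[0, 1], responses=[0, 0],
                       phases=["assoc", "dissoc"], concentration=1e-6)

    def test_protocol_invariants(self):
        with pytest.raises(InvalidParameterError):
            InjectionProtocol(analyte_concentration=-1e-6)
        with pytest.raises(InvalidParameterError):
            InjectionProtocol(analyte_concentration=1e-6,
                              sampling_interval=60.0,
                              association_duration=30.0)
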