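"""Forward models for SPR sensorgrams: 1:1 Langmuir and bivalent analyte.

Surface plasmon resonance (SPR) reports the mass of analyte bound to a
ligand-coated surface in response units (RU) over an injection cycle:
a baseline in running buffer, an association phase while analyte at
concentration ``C`` flows over the surface, and a dissociation phase after
the injection stops (``C = 0``).

Two binding schemes are modelled:

* **1:1 Langmuir** — analyte ``A`` binds immobilized ligand ``B`` with rates
  ``k_on`` (M^-1 s^-1) and ``k_off`` (s^-1).  The association response has
  the closed form ``R(t) = R_eq (1 - exp(-(k_on C + k_off) t))`` with
  ``R_eq = R_max k_on C / (k_on C + k_off)``, and dissociation decays
  exponentially at ``k_off``.

* **Bivalent analyte** — a dimeric analyte first binds one ligand
  (``k_on1``/``k_off1``) forming ``AB``, which can then engage a second
  ligand (``k_on2``/``k_off2``) forming ``AB2``.  The second step is a
  surface reaction, so its forward rate is expressed per RU of free ligand
  (``k_on2_ru``, RU^-1 s^-1) and converted to molar units only for
  reporting.  Both bound species carry one analyte and therefore one unit
  of mass response; the scheme integrated here is

  dAB/dt  = k_on1 C B - k_off1 AB - k_on2 AB B + k_off2 AB2
  dAB2/dt = k_on2 AB B - k_off2 AB2

  with free ligand ``B = R_max - AB - AB2`` by default (an ``AB2`` complex
  occupying two ligand equivalents, ``B = R_max - AB - 2 AB2``, is available
  via ``stoichiometry="double"``).

A bulk refractive-index jump ``RI`` (RU) adds a rectangular offset while
analyte is flowing and vanishes when the injection stops.  Time zero is the
injection start; baseline samples carry negative times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import IntegrationError, InvalidParameterError, NoRootError

__all__ = [
    "InjectionProtocol",
    "OneToOneParams",
    "BivalentAnalyteParams",
    "Sensorgram",
    "closed_form_one_to_one",
    "simulate_bivalent",
    "equilibrium_response_bivalent",
    "PHASE_BASELINE",
    "PHASE_ASSOCIATION",
    "PHASE_DISSOCIATION",
]

PHASE_BASELINE = "baseline"
PHASE_ASSOCIATION = "association"
PHASE_DISSOCIATION = "dissociation"

#: Integration tolerances shared by simulator and fitter.
ODE_RTOL = 1e-8
ODE_ATOL = 1e-6  # RU

Stoichiometry = Literal["single", "double"]


@dataclass(frozen=True)
class InjectionProtocol:
    """One injection cycle's timing and analyte concentration.

    Parameters
    ----------
    analyte_concentration : float
        Injected analyte concentration in molar (M).
    association_duration : float
        Length of the injection (s).
    dissociation_duration : float
        Buffer-flow time recorded after the injection stops (s).
    sampling_interval : float
        Spacing of the recorded time grid (s).
    association_start : float
        Clock time at which the injection begins (s); the output time axis
        is zeroed here, so baseline samples carry negative times.
    baseline_duration : float
        Length of baseline recorded before the injection (s).
    """

    analyte_concentration: float
    association_duration: float = 30.0
    dissociation_duration: float = 300.0
    sampling_interval: float = 1.0
    association_start: float = 0.0
    baseline_duration: float = 10.0

    def __post_init__(self):
        if self.analyte_concentration < 0:
            raise InvalidParameterError("analyte_concentration must be >= 0")
        for name in ("association_duration", "dissociation_duration",
                     "sampling_interval"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.baseline_duration < 0:
            raise InvalidParameterError("baseline_duration must be >= 0")
        if self.sampling_interval > self.association_duration:
            raise InvalidParameterError(
                "sampling_interval must not exceed association_duration")

    def time_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Sample times (s, zeroed at injection start) and phase labels."""
        dt = self.sampling_interval
        n_base = int(round(self.baseline_duration / dt))
        t_base = -self.baseline_duration + dt * np.arange(n_base)
        t_assoc = np.arange(0.0, self.association_duration + 0.5 * dt, dt)
        t_dissoc = self.association_duration + np.arange(
            dt, self.dissociation_duration + 0.5 * dt, dt)
        times = np.concatenate([t_base, t_assoc, t_dissoc])
        phases = np.concatenate([
            np.full(t_base.size, PHASE_BASELINE),
            np.full(t_assoc.size, PHASE_ASSOCIATION),
            np.full(t_dissoc.size, PHASE_DISSOCIATION),
        ])
        return times, phases


@dataclass(frozen=True)
class OneToOneParams:
    """1:1 Langmuir model parameters.

    ``k_on`` in M^-1 s^-1, ``k_off`` in s^-1, ``R_max`` (maximum analyte
    binding capacity) and ``RI`` (bulk refractive-index offset) in RU.
    """

    k_on: float
    k_off: float
    R_max: float
    RI: float = 0.0

    def __post_init__(self):
        if self.k_on <= 0 or self.k_off <= 0:
            raise InvalidParameterError("rate constants must be > 0")
        if self.R_max <= 0:
            raise InvalidParameterError("R_max must be > 0")
        if self.RI < 0:
            raise InvalidParameterError("RI must be >= 0")

    @property
    def K_D(self) -> float:
        """Equilibrium dissociation constant k_off/k_on (M)."""
        return self.k_off / self.k_on


@dataclass(frozen=True)
class BivalentAnalyteParams:
    """Bivalent-analyte model parameters.

    ``k_on1`` (M^-1 s^-1) / ``k_off1`` (s^-1) govern the first, solution-
    phase binding event; ``k_on2_ru`` (RU^-1 s^-1) / ``k_off2`` (s^-1) the
    second, surface-phase event.  ``k_on2_ru`` is stored natively in
    instrument units and converted for reporting as
    ``k_on2 (M^-1 s^-1) = k_on2_ru * 100 * analyte_mw``.

    ``analyte_mw`` (Da) is required whenever molar-unit constants are
    derived; there is no default.
    """

    k_on1: float
    k_off1: float
    k_on2_ru: float
    k_off2: float
    R_max: float
    RI: float = 0.0
    analyte_mw: float | None = None

    def __post_init__(self):
        for name in ("k_on1", "k_off1", "k_off2"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.k_on2_ru < 0:
            raise InvalidParameterError("k_on2_ru must be >= 0")
        if self.R_max <= 0:
            raise InvalidParameterError("R_max must be > 0")
        if self.RI < 0:
            raise InvalidParameterError("RI must be >= 0")
        if self.analyte_mw is not None and self.analyte_mw <= 0:
            raise InvalidParameterError("analyte_mw must be > 0")


@dataclass
class Sensorgram:
    """One injection cycle's response-vs-time trace.

    ``times`` are strictly increasing seconds (0 = injection start),
    ``responses`` in RU, ``phases`` per-sample labels among
    baseline/association/dissociation.  ``ligand_density`` is the
    immobilized ligand level in RU (``None`` when unknown).  ``metadata``
    may carry generator ground truth.
    """

    times: np.ndarray
    responses: np.ndarray
    phases: np.ndarray
    concentration: float
    ligand_density: float | None = None
    cycle_id: str = "cycle-1"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        self.phases = np.asarray(self.phases, dtype=object)
        if not (self.times.size == self.responses.size == self.phases.size):
            raise InvalidParameterError(
                "times, responses and phases must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        bad = set(self.phases) - {PHASE_BASELINE, PHASE_ASSOCIATION,
                                  PHASE_DISSOCIATION}
        if bad:
            raise InvalidParameterError(f"unknown phase labels: {sorted(bad)}")
        if self.ligand_density is not None and self.ligand_density < 0:
            raise InvalidParameterError("ligand_density must be >= 0")

    def mask(self, phase: str) -> np.ndarray:
        return self.phases == phase

    def with_responses(self, responses: np.ndarray) -> "Sensorgram":
        new = replace(self, responses=np.asarray(responses, dtype=float))
        return new


def closed_form_one_to_one(params: OneToOneParams,
                           protocol: InjectionProtocol) -> Sensorgram:
    """Analytic 1:1 Langmuir sensorgram for one injection cycle.

    Association follows ``R(t) = RI + R_eq (1 - exp(-(k_on C + k_off) t))``;
    dissociation decays exponentially from the end-of-association bound
    response with the bulk RI removed; baseline is zero.
    """
    C = protocol.analyte_concentration
    times, phases = protocol.time_grid()
    bound = _one_to_one_bound(params, C, times, protocol.association_duration)
    responses = bound + np.where(phases == PHASE_ASSOCIATION, params.RI, 0.0)
    return Sensorgram(times, responses, phases, concentration=C,
                      cycle_id="1to1-sim")


def _one_to_one_bound(params: OneToOneParams, C: float, times: np.ndarray,
                      t_stop: float) -> np.ndarray:
    """Bound response (no RI) of the 1:1 model on an arbitrary grid."""
    k_obs = params.k_on * C + params.k_off
    R_eq = params.R_max * params.k_on * C / k_obs
    bound = np.zeros_like(times, dtype=float)
    assoc = (times >= 0) & (times <= t_stop)
    dissoc = times > t_stop
    bound[assoc] = R_eq * (1.0 - np.exp(-k_obs * times[assoc]))
    r_end = R_eq * (1.0 - np.exp(-k_obs * t_stop))
    bound[dissoc] = r_end * np.exp(-params.k_off * (times[dissoc] - t_stop))
    return bound


def _bivalent_rhs(y: np.ndarray, C: np.ndarray, k_on1: float, k_off1: float,
                  k_on2: float, k_off2: float, R_max: float,
                  double_site: bool) -> np.ndarray:
    """Vectorized RHS for the two-state surface scheme.

    ``y`` is shaped (2*n,): first n entries AB, last n entries AB2, one per
    cycle; ``C`` is the per-cycle analyte concentration (0 in dissociation).
    """
    n = y.size // 2
    ab, ab2 = y[:n], y[n:]
    occupancy = ab + (2.0 * ab2 if double_site else ab2)
    b_free = R_max - occupancy
    second_on = k_on2 * ab * b_free
    d_ab = k_on1 * C * b_free - k_off1 * ab - second_on + k_off2 * ab2
    d_ab2 = second_on - k_off2 * ab2
    return np.concatenate([d_ab, d_ab2])


def integrate_bivalent_cycles(
    params: BivalentAnalyteParams,
    concentrations: np.ndarray,
    t_assoc: np.ndarray,
    t_dissoc: np.ndarray,
    association_duration: float,
    stoichiometry: Stoichiometry = "single",
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the bivalent scheme for several cycles simultaneously.

    All cycles share the rate parameters and surface capacity; only the
    analyte concentration differs, so they form one block-diagonal ODE
    solved in a single pass (much cheaper inside a fit loop than one solver
    call per cycle).

    Returns ``(bound_assoc, bound_dissoc)`` with shapes
    ``(n_cycles, len(t_assoc))`` and ``(n_cycles, len(t_dissoc))``; bound
    response is ``AB + AB2`` in RU, without any RI offset.

    ``t_assoc`` times are relative to injection start (>= 0);
    ``t_dissoc`` times are absolute (> association_duration).
    """
    concs = np.asarray(concentrations, dtype=float)
    n = concs.size
    double = stoichiometry == "double"
    args_assoc = (concs, params.k_on1, params.k_off1, params.k_on2_ru,
                  params.k_off2, params.R_max, double)
    y0 = np.zeros(2 * n)

    def rhs_assoc(t, y):
        return _bivalent_rhs(y, *args_assoc)

    zero_c = np.zeros(n)

    def rhs_dissoc(t, y):
        return _bivalent_rhs(y, zero_c, *args_assoc[1:])

    t_a = np.asarray(t_assoc, dtype=float)
    need_end = t_a.size == 0 or t_a[-1] < association_duration
    t_eval_a = np.append(t_a, association_duration) if need_end else t_a
    sol_a = solve_ivp(rhs_assoc, (0.0, association_duration), y0,
                      t_eval=t_eval_a, method="LSODA",
                      rtol=ODE_RTOL, atol=ODE_ATOL)
    if not sol_a.success:
        raise IntegrationError(f"association integration failed: {sol_a.message}")
    ya = sol_a.y[:, : t_a.size] if need_end else sol_a.y
    bound_assoc = ya[:n, :] + ya[n:, :]

    t_d = np.asarray(t_dissoc, dtype=float)
    if t_d.size:
        y_end = sol_a.y[:, -1]
        sol_d = solve_ivp(rhs_dissoc,
                          (association_duration, t_d[-1]),
                          y_end, t_eval=t_d, method="LSODA",
                          rtol=ODE_RTOL, atol=ODE_ATOL)
        if not sol_d.success:
            raise IntegrationError(
                f"dissociation integration failed: {sol_d.message}")
        bound_dissoc = sol_d.y[:n, :] + sol_d.y[n:, :]
    else:
        bound_dissoc = np.zeros((n, 0))
    return bound_assoc, bound_dissoc


def simulate_bivalent(params: BivalentAnalyteParams,
                      protocol: InjectionProtocol,
                      stoichiometry: Stoichiometry = "single") -> Sensorgram:
    """Numerically integrate one bivalent-analyte injection cycle.

    The reported response is ``AB + AB2 + RI`` during association and
    ``AB + AB2`` elsewhere.
    """
    times, phases = protocol.time_grid()
    assoc = phases == PHASE_ASSOCIATION
    dissoc = phases == PHASE_DISSOCIATION
    bound = np.zeros_like(times)
    ba, bd = integrate_bivalent_cycles(
        params, np.array([protocol.analyte_concentration]),
        times[assoc], times[dissoc], protocol.association_duration,
        stoichiometry)
    bound[assoc] = ba[0]
    bound[dissoc] = bd[0]
    responses = bound + np.where(assoc, params.RI, 0.0)
    return Sensorgram(times, responses, phases,
                      concentration=protocol.analyte_concentration,
                      ligand_density=params.R_max, cycle_id="bivalent-sim")


def equilibrium_response_bivalent(params: BivalentAnalyteParams,
                                  concentration: float,
                                  stoichiometry: Stoichiometry = "single"
                                  ) -> float:
    """Steady-state bound response (RU) of the bivalent scheme at fixed C.

    At steady state the second step equilibrates (``AB2 = (k_on2/k_off2)
    AB B``) and detailed balance of the first step gives ``AB = (k_on1 C /
    k_off1) B``; substituting into the ligand-conservation relation yields a
    quadratic in free ligand ``B`` whose unique root in ``[0, R_max]`` is
    taken.  Returns ``AB + AB2`` (the RI bulk offset is excluded).
    """
    if concentration < 0:
        raise InvalidParameterError("concentration must be >= 0")
    if concentration == 0:
        return 0.0
    a = params.k_on1 * concentration / params.k_off1
    b = params.k_on2_ru / params.k_off2
    mult = 2.0 if stoichiometry == "double" else 1.0
    # B + a B + mult * a b B^2 = R_max
    q = mult * a * b
    if q == 0:
        b_free = params.R_max / (1.0 + a)
    else:
        disc = (1.0 + a) ** 2 + 4.0 * q * params.R_max
        if disc < 0:
            raise NoRootError("no admissible steady-state root")
        b_free = (-(1.0 + a) + np.sqrt(disc)) / (2.0 * q)
    if not (0.0 <= b_free <= params.R_max * (1 + 1e-12)):
        raise NoRootError("steady-state root outside [0, R_max]")
    ab = a * b_free
    ab2 = a * b * b_free ** 2
    return float(ab + ab2)
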