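"""Nonlinear least-squares kinetic fitting of SPR sensorgrams.

Implements the simultaneous k_on/k_off fitting of association and
dissociation phases for the 1:1 Langmuir and bivalent-analyte models, at
two scopes:

* **local** — one sensorgram at a single analyte concentration, with its
  own full parameter vector;
* **global** — several cycles over a concentration series on one ligand
  surface, sharing the rate constants and ``R_max`` while each cycle keeps
  its own bulk refractive-index offset ``RI``.

Positivity of rate constants is enforced by optimizing their logarithms
with a trust-region-reflective solver; per-cycle ``RI`` enters the response
linearly and is solved in closed form inside the residual (variable
projection), which keeps the nonlinear search low-dimensional.  Five seeded
starts guard against local minima; repeated fits with identical inputs and
settings are bit-identical.

Goodness of fit is reported both as the instrument-style statistic
``chi2 = sum((observed - expected)^2 / expected)`` (with a 1 RU floor on
the denominator, which the published formula leaves unguarded near zero
response) and as the plain sum of squared residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .exceptions import (
    FitConvergenceError,
    InvalidParameterError,
    MissingMolecularWeightError,
    UnderDeterminedError,
)
from .models import (
    PHASE_ASSOCIATION,
    PHASE_DISSOCIATION,
    BivalentAnalyteParams,
    OneToOneParams,
    Sensorgram,
    _one_to_one_bound,
    integrate_bivalent_cycles,
)

__all__ = [
    "KineticConstants",
    "FitResult",
    "ModelComparison",
    "SensorgramKineticFitter",
    "fit_kinetics",
    "chi_square",
    "derive_equilibrium_constants",
    "compare_models",
    "lag1_autocorrelation",
]

#: RU to M conversion factor in k_on2_molar = k_on2_ru * 100 * MW.
RU_TO_MOLAR_FACTOR = 100.0

#: Floor (RU) applied to the denominator of the instrument-style chi-square.
CHI_SQUARE_FLOOR_RU = 1.0

_MIN_PHASE_SAMPLES = 5

# Log-space box bounds per parameter (natural units).
_BOUNDS = {
    "k_on1": (1.0, 1e9),
    "k_off1": (1e-6, 1e3),
    "k_on2_ru": (1e-12, 1.0),
    "k_off2": (1e-6, 1e3),
    "R_max": (1.0, 1e6),
}


@dataclass(frozen=True)
class KineticConstants:
    """Equilibrium constants derived from fitted rate constants.

    ``K_D1 = k_off1 / k_on1`` (monovalent component, M); for bivalent fits
    ``k_on2_molar = k_on2_ru * 100 * analyte_mw`` and ``K_D2 = k_off2 /
    k_on2_molar`` (bivalent component, M).
    """

    K_D1: float
    K_D2: float | None = None
    k_on2_molar: float | None = None

    def __post_init__(self):
        if self.K_D1 <= 0:
            raise InvalidParameterError("K_D1 must be > 0")
        if (self.K_D2 is None) != (self.k_on2_molar is None):
            raise InvalidParameterError(
                "K_D2 and k_on2_molar must be set together")
        if self.K_D2 is not None and (self.K_D2 <= 0 or self.k_on2_molar <= 0):
            raise InvalidParameterError("bivalent constants must be > 0")


@dataclass
class FitResult:
    """Outcome of one kinetic fit (local or global)."""

    model: str                      # "one_to_one" | "bivalent"
    scope: str                      # "local" | "global"
    params: BivalentAnalyteParams | OneToOneParams
    ri_per_cycle: list[float]
    chi_square_paper: float
    ssr: float
    residuals: list[np.ndarray]
    derived: KineticConstants | None
    converged: bool
    concentration_range: np.ndarray
    cycle_ids: list[str] = field(default_factory=list)
    n_starts_used: int = 0
    cost_per_start: list[float] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        shared = 5 if self.model == "bivalent" else 3
        return shared + len(self.ri_per_cycle)

    @property
    def n_samples(self) -> int:
        return int(sum(r.size for r in self.residuals))


def chi_square(observed: np.ndarray, expected: np.ndarray,
               floor: float = CHI_SQUARE_FLOOR_RU) -> float:
    """Instrument-style goodness of fit ``sum((obs-exp)^2 / exp)``.

    The denominator is floored at ``floor`` RU because expected responses
    approach zero at baseline and late dissociation, where the raw formula
    diverges.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    exp = np.asarray(expected, dtype=float).ravel()
    if obs.size == 0:
        raise UnderDeterminedError("chi_square of empty input")
    if obs.size != exp.size:
        raise InvalidParameterError("observed and expected lengths differ")
    denom = np.maximum(exp, floor)
    return float(np.sum((obs - exp) ** 2 / denom))


def derive_equilibrium_constants(
        params: BivalentAnalyteParams | OneToOneParams) -> KineticConstants:
    """Equilibrium dissociation constants from rate constants.

    For the bivalent model the second-site on-rate is converted from
    instrument units via ``k_on2 (M^-1 s^-1) = k_on2 (RU^-1 s^-1) * 100 *
    analyte MW``; the molecular weight must be set on the parameters.
    """
    if isinstance(params, OneToOneParams):
        return KineticConstants(K_D1=params.k_off / params.k_on)
    if params.analyte_mw is None:
        raise MissingMolecularWeightError(
            "analyte_mw is required to convert k_on2 to molar units")
    k_on2_molar = params.k_on2_ru * RU_TO_MOLAR_FACTOR * params.analyte_mw
    if k_on2_molar <= 0:
        raise InvalidParameterError("k_on2 must be > 0 to derive K_D2")
    return KineticConstants(K_D1=params.k_off1 / params.k_on1,
                            K_D2=params.k_off2 / k_on2_molar,
                            k_on2_molar=k_on2_molar)


def lag1_autocorrelation(residuals: np.ndarray) -> float:
    """Lag-1 autocorrelation of a residual trace (0 for white residuals)."""
    r = np.asarray(residuals, dtype=float).ravel()
    if r.size < 3:
        return 0.0
    r = r - r.mean()
    denom = float(np.dot(r, r))
    if denom == 0:
        return 0.0
    return float(np.dot(r[:-1], r[1:]) / denom)


class _CycleData:
    """Fitted-window views of one sensorgram (baseline excluded)."""

    __slots__ = ("t_assoc", "t_dissoc", "obs_assoc", "obs_dissoc",
                 "concentration", "t_stop", "cycle_id")

    def __init__(self, sg: Sensorgram):
        a = sg.mask(PHASE_ASSOCIATION)
        d = sg.mask(PHASE_DISSOCIATION)
        if a.sum() < _MIN_PHASE_SAMPLES or d.sum() < _MIN_PHASE_SAMPLES:
            raise UnderDeterminedError(
                f"cycle {sg.cycle_id!r}: association and dissociation phases "
                f"each need >= {_MIN_PHASE_SAMPLES} samples")
        self.t_assoc = sg.times[a]
        self.t_dissoc = sg.times[d]
        self.obs_assoc = sg.responses[a]
        self.obs_dissoc = sg.responses[d]
        self.concentration = float(sg.concentration)
        self.t_stop = float(self.t_assoc[-1])
        self.cycle_id = sg.cycle_id


class SensorgramKineticFitter(BaseEstimator):
    """Simultaneous k_on/k_off least-squares fitter for sensorgrams.

    Parameters
    ----------
    model : {"bivalent", "one_to_one"}
        Binding scheme to fit.
    scope : {"global", "local"}
        Global fits share rates and R_max across cycles (one RI per cycle);
        local fits require exactly one sensorgram.
    analyte_mw : float or None
        Analyte molecular weight (Da); required to report molar-unit
        second-site constants from a bivalent fit.
    stoichiometry : {"single", "double"}
        Ligand equivalents occupied by the doubly bound complex.
    n_starts : int
        Seeded multi-start count for the nonlinear search.
    start_seed : int
        Seed for the multi-start jitter (deterministic).
    initial_guess : dict or None
        Overrides for starting values (keys among k_on1, k_off1, k_on2_ru,
        k_off2, R_max, or k_on/k_off for the 1:1 model).
    ftol : float
        Convergence tolerance on the cost.

    Attributes
    ----------
    result_ : FitResult
        Full fit outcome.
    params_ : BivalentAnalyteParams or OneToOneParams
        Fitted parameters (RI = first cycle's value; per-cycle values in
        ``result_.ri_per_cycle``).
    kinetic_constants_ : KineticConstants or None
        Derived equilibrium constants (None when MW is needed but unset).
    chi_square_, ssr_ : float
        Goodness-of-fit statistics.
    """

    def __init__(self, model: str = "bivalent", scope: str = "global",
                 analyte_mw: float | None = None,
                 stoichiometry: str = "single", n_starts: int = 5,
                 start_seed: int = 0,
                 initial_guess: dict | None = None, ftol: float = 1e-10):
        self.model = model
        self.scope = scope
        self.analyte_mw = analyte_mw
        self.stoichiometry = stoichiometry
        self.n_starts = n_starts
        self.start_seed = start_seed
        self.initial_guess = initial_guess
        self.ftol = ftol

    # -- residual machinery -------------------------------------------------

    def _model_bound(self, theta: np.ndarray, cycles: list[_CycleData]
                     ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Bound-response traces (assoc, dissoc) per cycle for log-params."""
        p = np.exp(theta)
        if self.model == "one_to_one":
            params = OneToOneParams(k_on=p[0], k_off=p[1], R_max=p[2])
            out = []
            for c in cycles:
                ba = _one_to_one_bound(params, c.concentration, c.t_assoc,
                                       c.t_stop)
                bd = _one_to_one_bound(params, c.concentration, c.t_dissoc,
                                       c.t_stop)
                out.append((ba, bd))
            return out
        params = BivalentAnalyteParams(
            k_on1=p[0], k_off1=p[1], k_on2_ru=max(p[2], 1e-300),
            k_off2=p[3], R_max=p[4])
        # Cycles from one run share the sampling grid; integrate them as one
        # block-diagonal system.  Mixed grids fall back to per-cycle solves.
        g0 = cycles[0]
        shared = all(
            c.t_assoc.size == g0.t_assoc.size
            and c.t_dissoc.size == g0.t_dissoc.size
            and np.array_equal(c.t_assoc, g0.t_assoc)
            and np.array_equal(c.t_dissoc, g0.t_dissoc)
            for c in cycles[1:])
        if shared:
            concs = np.array([c.concentration for c in cycles])
            ba, bd = integrate_bivalent_cycles(
                params, concs, g0.t_assoc, g0.t_dissoc, g0.t_stop,
                self.stoichiometry)
            return [(ba[i], bd[i]) for i in range(len(cycles))]
        out = []
        for c in cycles:
            ba, bd = integrate_bivalent_cycles(
                params, np.array([c.concentration]), c.t_assoc, c.t_dissoc,
                c.t_stop, self.stoichiometry)
            out.append((ba[0], bd[0]))
        return out

    @staticmethod
    def _project_ri(cycles: list[_CycleData],
                    bound: list[tuple[np.ndarray, np.ndarray]]
                    ) -> np.ndarray:
        """Closed-form per-cycle RI (nonnegative) given bound traces."""
        ri = np.empty(len(cycles))
        for i, (c, (ba, _)) in enumerate(zip(cycles, bound)):
            ri[i] = max(0.0, float(np.mean(c.obs_assoc - ba)))
        return ri

    def _residual(self, theta: np.ndarray, cycles: list[_CycleData]
                  ) -> np.ndarray:
        bound = self._model_bound(theta, cycles)
        ri = self._project_ri(cycles, bound)
        res = [np.concatenate([c.obs_assoc - (ba + ri[i]),
                               c.obs_dissoc - bd])
               for i, (c, (ba, bd)) in enumerate(zip(cycles, bound))]
        return np.concatenate(res)

    # -- starting points ----------------------------------------------------

    def _theta0(self, cycles: list[_CycleData]) -> np.ndarray:
        max_obs = max(float(np.max(c.obs_assoc)) for c in cycles)
        guess = {"k_on1": 1e4, "k_off1": 0.1, "k_on2_ru": 1e-4,
                 "k_off2": 1e-3, "R_max": 1.2 * max(max_obs, 1.0)}
        user = dict(self.initial_guess or {})
        # accept 1:1 aliases
        if "k_on" in user:
            user["k_on1"] = user.pop("k_on")
        if "k_off" in user:
            user["k_off1"] = user.pop("k_off")
        guess.update({k: v for k, v in user.items() if k in guess})
        if self.model == "one_to_one":
            keys = ["k_on1", "k_off1", "R_max"]
        else:
            keys = ["k_on1", "k_off1", "k_on2_ru", "k_off2", "R_max"]
        return np.log([guess[k] for k in keys])

    def _log_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if self.model == "one_to_one":
            keys = ["k_on1", "k_off1", "R_max"]
        else:
            keys = ["k_on1", "k_off1", "k_on2_ru", "k_off2", "R_max"]
        lo = np.log([_BOUNDS[k][0] for k in keys])
        hi = np.log([_BOUNDS[k][1] for k in keys])
        return lo, hi

    # -- public API ---------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the configured model to a collection of sensorgrams.

        ``X`` is a single :class:`~affinikit.models.Sensorgram` or a
        sequence of them (exactly one for local scope).
        """
        if self.model not in ("bivalent", "one_to_one"):
            raise InvalidParameterError(f"unknown model {self.model!r}")
        if self.scope not in ("global", "local"):
            raise InvalidParameterError(f"unknown scope {self.scope!r}")
        sensorgrams = [X] if isinstance(X, Sensorgram) else list(X)
        if not sensorgrams:
            raise UnderDeterminedError("no sensorgrams supplied")
        if self.scope == "local" and len(sensorgrams) != 1:
            raise InvalidParameterError(
                "local scope fits exactly one sensorgram")
        cycles = [_CycleData(sg) for sg in sensorgrams]

        theta0 = self._theta0(cycles)
        lo, hi = self._log_bounds()
        theta0 = np.clip(theta0, lo, hi)
        rng = np.random.default_rng(self.start_seed)
        starts = [theta0]
        for _ in range(max(0, self.n_starts - 1)):
            jitter = rng.uniform(-1.0, 1.0, theta0.size) * np.log(10.0) * 0.5
            starts.append(np.clip(theta0 + jitter, lo, hi))

        best = None
        costs = []
        for s in starts:
            try:
                sol = least_squares(
                    self._residual, s, bounds=(lo, hi), args=(cycles,),
                    method="trf", ftol=self.ftol, xtol=1e-12, gtol=1e-12)
            except Exception:  # integration failure at a pathological start
                costs.append(np.inf)
                continue
            costs.append(float(sol.cost))
            if sol.status > 0 and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitConvergenceError(
                "kinetic fit did not converge from any start",
                diagnostics={"costs": costs, "n_starts": len(starts)})

        self.result_ = self._build_result(best, cycles, costs)
        self.params_ = self.result_.params
        self.kinetic_constants_ = self.result_.derived
        self.chi_square_ = self.result_.chi_square_paper
        self.ssr_ = self.result_.ssr
        return self

    def _build_result(self, sol, cycles: list[_CycleData],
                      costs: list[float]) -> FitResult:
        bound = self._model_bound(sol.x, cycles)
        ri = self._project_ri(cycles, bound)
        p = np.exp(sol.x)
        residuals, expected_all, observed_all = [], [], []
        for i, (c, (ba, bd)) in enumerate(zip(cycles, bound)):
            exp_c = np.concatenate([ba + ri[i], bd])
            obs_c = np.concatenate([c.obs_assoc, c.obs_dissoc])
            residuals.append(obs_c - exp_c)
            expected_all.append(exp_c)
            observed_all.append(obs_c)
        obs = np.concatenate(observed_all)
        exp = np.concatenate(expected_all)
        if self.model == "one_to_one":
            params = OneToOneParams(k_on=p[0], k_off=p[1], R_max=p[2],
                                    RI=float(ri[0]))
        else:
            params = BivalentAnalyteParams(
                k_on1=p[0], k_off1=p[1], k_on2_ru=max(p[2], 1e-300),
                k_off2=p[3], R_max=p[4], RI=float(ri[0]),
                analyte_mw=self.analyte_mw)
        try:
            derived = derive_equilibrium_constants(params)
        except (MissingMolecularWeightError, InvalidParameterError):
            derived = None
        return FitResult(
            model=self.model, scope=self.scope, params=params,
            ri_per_cycle=[float(r) for r in ri],
            chi_square_paper=chi_square(obs, exp),
            ssr=float(np.sum((obs - exp) ** 2)),
            residuals=residuals, derived=derived,
            converged=True,
            concentration_range=np.array([c.concentration for c in cycles]),
            cycle_ids=[c.cycle_id for c in cycles],
            n_starts_used=len(costs), cost_per_start=costs)

    def predict(self, X):
        """Fitted model response traces for the given sensorgrams.

        Returns one array per sensorgram covering its association and
        dissociation samples (baseline excluded), using the fitted shared
        parameters and freshly projected per-cycle RI.
        """
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "result_")
        sensorgrams = [X] if isinstance(X, Sensorgram) else list(X)
        cycles = [_CycleData(sg) for sg in sensorgrams]
        p = self.params_
        if self.model == "one_to_one":
            theta = np.log([p.k_on, p.k_off, p.R_max])
        else:
            theta = np.log([p.k_on1, p.k_off1, max(p.k_on2_ru, 1e-300),
                            p.k_off2, p.R_max])
        bound = self._model_bound(theta, cycles)
        ri = self._project_ri(cycles, bound)
        return [np.concatenate([ba + ri[i], bd])
                for i, (ba, bd) in enumerate(bound)]


def fit_kinetics(sensorgrams, model: str = "bivalent", scope: str = "global",
                 initial_guess: dict | None = None,
                 mw: float | None = None, **kwargs) -> FitResult:
    """Functional wrapper over :class:`SensorgramKineticFitter`."""
    fitter = SensorgramKineticFitter(model=model, scope=scope,
                                     analyte_mw=mw,
                                     initial_guess=initial_guess, **kwargs)
    fitter.fit(sensorgrams)
    return fitter.result_


@dataclass
class ModelComparison:
    """Ranked goodness-of-fit comparison of kinetic fits on shared data."""

    entries: list[dict]
    best_model: str | None
    tie: bool
    overparameterized: list[str]


def compare_models(fits: Sequence[FitResult],
                   improvement_threshold: float = 0.01) -> ModelComparison:
    """Rank fits of the same data by the instrument-style chi-square.

    SSR and mean lag-1 residual autocorrelation are reported alongside; no
    formal test statistic is computed — selection is a ranking, with the
    more heavily parameterized model flagged when its chi-square improves
    on a simpler model's by less than ``improvement_threshold`` (relative).
    """
    fits = list(fits)
    if len(fits) < 2:
        raise UnderDeterminedError("compare_models needs >= 2 fits")
    n0 = fits[0].n_samples
    if any(f.n_samples != n0 for f in fits):
        raise InvalidParameterError(
            "fits cover different samples; comparison undefined")
    entries = []
    for f in fits:
        entries.append({
            "model": f.model,
            "scope": f.scope,
            "chi_square": f.chi_square_paper,
            "ssr": f.ssr,
            "lag1_autocorrelation": float(np.mean(
                [lag1_autocorrelation(r) for r in f.residuals])),
            "n_parameters": f.n_parameters,
        })
    order = sorted(range(len(entries)),
                   key=lambda i: (entries[i]["chi_square"],
                                  entries[i]["n_parameters"]))
    entries = [entries[i] for i in order]
    for rank, e in enumerate(entries, start=1):
        e["rank"] = rank
    best, runner = entries[0], entries[1]
    tie = best["chi_square"] == runner["chi_square"]
    overparameterized = []
    # A complex model that barely beats a simpler one is not preferred.
    for e in entries:
        simpler = [o for o in entries if o["n_parameters"] < e["n_parameters"]]
        if not simpler:
            continue
        ref = min(simpler, key=lambda o: o["chi_square"])
        if ref["chi_square"] > 0:
            rel_gain = (ref["chi_square"] - e["chi_square"]) / ref["chi_square"]
            if 0 <= rel_gain < improvement_threshold:
                overparameterized.append(e["model"])
    best_model = None if tie else best["model"]
    return ModelComparison(entries=entries, best_model=best_model, tie=tie,
                           overparameterized=overparameterized)
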