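"""Steady-state (equilibrium) affinity analysis of low-density sensorgrams.

At low immobilized-ligand density a fast-kinetics interaction reaches a
concentration-dependent plateau within the injection; plotting the plateau
response (baseline-subtracted, read a fixed time into the injection)
against analyte concentration and fitting the one-site specific binding
isotherm

    R(C) = B_max * C / (K_D + C)

yields the monovalent equilibrium dissociation constant without kinetic
assumptions.  The module also compares apparent dissociation across
ligand-density series: under a bivalent scheme higher surface density
allows more second-site engagement and lengthens the apparent off-rate,
whereas 1:1 kinetics are density-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import (
    FitConvergenceError,
    InvalidParameterError,
    PhaseMissingError,
    UnderDeterminedError,
)
from .models import (
    PHASE_ASSOCIATION,
    PHASE_BASELINE,
    PHASE_DISSOCIATION,
    Sensorgram,
)

__all__ = [
    "EquilibriumPoint",
    "IsothermFit",
    "DensityGroupSummary",
    "DensityReport",
    "OneSiteBindingRegressor",
    "extract_plateau",
    "fit_one_site",
    "analyze_density_series",
    "one_site_response",
]

DEFAULT_READOUT_TIME_S = 30.0
DEFAULT_BASELINE_WINDOW_S = 10.0
_MIN_BASELINE_SAMPLES = 3
_MIN_CONCENTRATIONS = 4


@dataclass(frozen=True)
class EquilibriumPoint:
    """Baseline-subtracted steady-state response at one concentration."""

    concentration: float    # M
    response: float         # RU

    def __post_init__(self):
        if self.concentration < 0:
            raise InvalidParameterError("concentration must be >= 0")
        if not np.isfinite(self.response):
            raise InvalidParameterError("response must be finite")


@dataclass(frozen=True)
class IsothermFit:
    """One-site specific binding fit result."""

    K_D: float              # M
    B_max: float            # RU
    ssr: float              # RU^2
    converged: bool
    kd_constrained: bool = True

    def __post_init__(self):
        if self.K_D <= 0 or self.B_max <= 0:
            raise InvalidParameterError("K_D and B_max must be > 0")


def one_site_response(c, K_D, B_max):
    """One-site specific binding isotherm ``B_max c / (K_D + c)``."""
    c = np.asarray(c, float)
    return B_max * c / (K_D + c)


def extract_plateau(sensorgram: Sensorgram,
                    readout_time: float = DEFAULT_READOUT_TIME_S,
                    baseline_window: float = DEFAULT_BASELINE_WINDOW_S,
                    warn_slope_ru_per_s: float | None = None
                    ) -> EquilibriumPoint:
    """Steady-state response: nearest sample to ``readout_time`` minus the
    mean baseline over the final ``baseline_window`` seconds before
    injection.

    With ``warn_slope_ru_per_s`` set, a plateau check compares the response
    slope over the last 5 s of association against the threshold and
    annotates nothing — it only emits a RuntimeWarning — because at low
    density the readout is treated as steady state by design.
    """
    assoc = sensorgram.mask(PHASE_ASSOCIATION)
    if not np.any(assoc):
        raise PhaseMissingError("sensorgram has no association samples")
    t_assoc = sensorgram.times[assoc]
    if not (t_assoc[0] <= readout_time <= t_assoc[-1]):
        raise InvalidParameterError(
            f"readout_time {readout_time} s outside association phase "
            f"[{t_assoc[0]}, {t_assoc[-1]}] s")
    base = sensorgram.mask(PHASE_BASELINE)
    base &= sensorgram.times >= -baseline_window
    if base.sum() < _MIN_BASELINE_SAMPLES:
        raise UnderDeterminedError(
            f"baseline window must cover >= {_MIN_BASELINE_SAMPLES} samples")
    baseline = float(np.mean(sensorgram.responses[base]))
    idx = np.argmin(np.abs(t_assoc - readout_time))
    value = float(sensorgram.responses[assoc][idx])
    if warn_slope_ru_per_s is not None:
        import warnings
        tail = assoc & (sensorgram.times >= t_assoc[-1] - 5.0)
        if tail.sum() >= 2:
            slope = np.polyfit(sensorgram.times[tail],
                               sensorgram.responses[tail], 1)[0]
            if abs(slope) > warn_slope_ru_per_s:
                warnings.warn(
                    f"association slope {slope:.3g} RU/s exceeds "
                    f"{warn_slope_ru_per_s} RU/s; plateau may not be steady "
                    "state", RuntimeWarning, stacklevel=2)
    return EquilibriumPoint(concentration=float(sensorgram.concentration),
                            response=value - baseline)


class OneSiteBindingRegressor(RegressorMixin, BaseEstimator):
    """One-site specific binding isotherm fit (sklearn estimator).

    ``fit(X, y)`` takes analyte concentrations (M) and plateau responses
    (RU).  Fitted attributes: ``K_D_`` (M), ``B_max_`` (RU), ``ssr_``,
    ``kd_constrained_`` (False when the data cannot pin the K_D down, e.g.
    all concentrations saturating).
    """

    def __init__(self, max_nfev: int = 10_000):
        self.max_nfev = max_nfev

    def fit(self, X, y):
        X = check_array(X, ensure_2d=False, dtype=float)
        c = X.ravel()
        y = np.asarray(y, dtype=float).ravel()
        if c.size != y.size:
            raise InvalidParameterError("X and y lengths differ")
        if np.unique(c).size < _MIN_CONCENTRATIONS:
            raise UnderDeterminedError(
                f"need >= {_MIN_CONCENTRATIONS} distinct concentrations")
        b0 = max(float(np.max(y)), 1e-9)
        k0 = float(np.median(c[c > 0])) if np.any(c > 0) else 1e-6

        def model(cc, log_kd, b_max):
            return one_site_response(cc, np.exp(log_kd), b_max)

        try:
            popt, pcov = curve_fit(model, c, y, p0=[np.log(k0), b0],
                                   maxfev=self.max_nfev)
        except RuntimeError as exc:
            raise FitConvergenceError(f"isotherm fit failed: {exc}") from exc
        self.K_D_ = float(np.exp(popt[0]))
        self.B_max_ = float(popt[1])
        resid = y - model(c, *popt)
        self.ssr_ = float(np.dot(resid, resid))
        # K_D below the sampled range, or with huge relative uncertainty,
        # means the design only saw the saturated arm of the isotherm.
        with np.errstate(invalid="ignore"):
            kd_rel_err = float(np.sqrt(np.abs(pcov[0, 0])))
        self.kd_constrained_ = bool(
            self.K_D_ >= 0.5 * np.min(c[c > 0]) and kd_rel_err < 1.0)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "K_D_")
        X = check_array(X, ensure_2d=False, dtype=float)
        return one_site_response(X.ravel(), self.K_D_, self.B_max_)

    @property
    def result_(self) -> IsothermFit:
        check_is_fitted(self, "K_D_")
        return IsothermFit(K_D=self.K_D_, B_max=self.B_max_, ssr=self.ssr_,
                           converged=True,
                           kd_constrained=self.kd_constrained_)


def fit_one_site(points) -> IsothermFit:
    """Fit the one-site isotherm to a collection of equilibrium points."""
    pts = list(points)
    c = np.array([p.concentration for p in pts])
    r = np.array([p.response for p in pts])
    reg = OneSiteBindingRegressor()
    reg.fit(c.reshape(-1, 1), r)
    return reg.result_


@dataclass(frozen=True)
class DensityGroupSummary:
    ligand_density: float
    half_time_s: float                 # inf if never halves in the window
    fraction_remaining: dict           # offset (s) -> fraction of R0


@dataclass(frozen=True)
class DensityReport:
    groups: tuple                       # ordered by ligand density
    half_time_increases: bool
    density_effect: bool


def _dissociation_half_time(sg: Sensorgram,
                            offsets=(10.0, 30.0, 60.0)) -> tuple[float, dict]:
    dissoc = sg.mask(PHASE_DISSOCIATION)
    if not np.any(dissoc):
        raise PhaseMissingError(f"cycle {sg.cycle_id!r}: no dissociation phase")
    assoc = sg.mask(PHASE_ASSOCIATION)
    r0 = float(sg.responses[assoc][-1]) if np.any(assoc) else \
        float(sg.responses[dissoc][0])
    t = sg.times[dissoc]
    r = sg.responses[dissoc]
    t0 = float(sg.times[assoc][-1]) if np.any(assoc) else float(t[0])
    rel_t = t - t0
    if r0 <= 0:
        return np.inf, {o: np.nan for o in offsets}
    frac = r / r0
    below = np.nonzero(frac <= 0.5)[0]
    if below.size == 0:
        half = np.inf
    else:
        i = below[0]
        if i == 0:
            half = float(rel_t[0])
        else:  # linear interpolation across the half-crossing
            f1, f2 = frac[i - 1], frac[i]
            w = (f1 - 0.5) / (f1 - f2)
            half = float(rel_t[i - 1] + w * (rel_t[i] - rel_t[i - 1]))
    remaining = {}
    for o in offsets:
        j = np.argmin(np.abs(rel_t - o))
        remaining[float(o)] = float(frac[j])
    return half, remaining


def analyze_density_series(series, half_time_tolerance_s: float = 1.0,
                           offsets=(10.0, 30.0, 60.0)) -> DensityReport:
    """Apparent dissociation half-times across a ligand-density series.

    ``series`` maps ligand density (RU) to a sensorgram recorded at a
    common analyte concentration (a dict, or an iterable of sensorgrams
    carrying ``ligand_density``).  Densities are ordered ascending and the
    report flags whether the half-time increases with density beyond
    ``half_time_tolerance_s`` (the bivalent signature; 1:1 kinetics give a
    flat profile).
    """
    if isinstance(series, dict):
        items = [(float(d), sg) for d, sg in series.items()]
    else:
        items = []
        for sg in series:
            if sg.ligand_density is None:
                raise InvalidParameterError(
                    f"cycle {sg.cycle_id!r} has no ligand_density")
            items.append((float(sg.ligand_density), sg))
    if len(items) < 2:
        raise UnderDeterminedError("need >= 2 density groups")
    concs = {round(sg.concentration, 12) for _, sg in items}
    if len(concs) > 1:
        raise InvalidParameterError(
            "density comparison requires a common analyte concentration")
    items.sort(key=lambda kv: kv[0])
    groups = []
    for density, sg in items:
        half, remaining = _dissociation_half_time(sg, offsets)
        groups.append(DensityGroupSummary(
            ligand_density=density, half_time_s=half,
            fraction_remaining=remaining))
    halves = [g.half_time_s for g in groups]
    diffs = np.diff(halves)
    increases = bool(np.all(diffs >= -half_time_tolerance_s))
    effect = bool(increases and np.any(diffs > half_time_tolerance_s))
    return DensityReport(groups=tuple(groups),
                         half_time_increases=increases,
                         density_effect=effect)
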