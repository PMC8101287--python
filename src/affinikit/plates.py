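"""Bead-proximity (AlphaScreen-style) plate analysis and 4PL inhibition fits.

Cross-titration plates titrate one binding partner on donor beads against a
dilution series of the other on acceptor beads.  Binding shows as a
concentration-dependent rise in counts over buffer-alone background; at
high protein concentration the signal can fall again as free protein
saturates the beads (the "hook" effect), so the monotone-trend statistic is
evaluated only up to the observed peak.

Blockade experiments titrate an inhibitor against fixed binder
concentrations and are summarized by a four-parameter logistic (4PL) fit

    S(c) = bottom + (top - bottom) / (1 + (c / IC50)^h)

with the Hill slope ``h`` fitted rather than fixed at 1.  Counts are
arbitrary amplified units and are treated as continuous with Gaussian
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import (
    DegenerateSeriesError,
    FitConvergenceError,
    InvalidParameterError,
    NoBackgroundError,
    NoTransitionError,
)

__all__ = [
    "CrossTitrationPlate",
    "InhibitionSeries",
    "HookReport",
    "TitrationRowSummary",
    "TitrationReport",
    "InhibitionFit",
    "FourParamLogisticRegressor",
    "four_param_logistic",
    "subtract_background",
    "summarize_cross_titration",
    "detect_hook",
    "fit_inhibition",
]

#: Default binding-call thresholds (package-defined; upstream work makes
#: only qualitative detected / not-detected calls).
FOLD_THRESHOLD = 3.0
TREND_THRESHOLD = 0.8
HOOK_DROP_FRACTION = 0.20


@dataclass
class CrossTitrationPlate:
    """Donor-conc x acceptor-conc matrix of assay counts.

    ``signal`` has one row per acceptor concentration and one column per
    donor concentration; ``background_wells`` are buffer-alone counts.
    """

    donor_concs: np.ndarray
    acceptor_concs: np.ndarray
    signal: np.ndarray
    background_wells: np.ndarray
    background_corrected: bool = False
    background_mean: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.donor_concs = np.asarray(self.donor_concs, float)
        self.acceptor_concs = np.asarray(self.acceptor_concs, float)
        self.signal = np.asarray(self.signal, float)
        self.background_wells = np.asarray(self.background_wells, float)
        if self.signal.shape != (self.acceptor_concs.size,
                                 self.donor_concs.size):
            raise InvalidParameterError(
                "signal shape must be (n_acceptor, n_donor)")
        for name, c in (("donor_concs", self.donor_concs),
                        ("acceptor_concs", self.acceptor_concs)):
            if np.any(c < 0):
                raise InvalidParameterError(f"{name} must be >= 0")
            if c.size > 1 and not (np.all(np.diff(c) > 0)
                                   or np.all(np.diff(c) < 0)):
                raise InvalidParameterError(f"{name} must be strictly monotone")


@dataclass
class InhibitionSeries:
    """Inhibitor dilution series with its controls."""

    inhibitor_concs: np.ndarray
    signal: np.ndarray
    no_inhibitor_signal: float | None = None
    background_signal: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.inhibitor_concs = np.asarray(self.inhibitor_concs, float)
        self.signal = np.asarray(self.signal, float)
        if self.inhibitor_concs.size != self.signal.size:
            raise InvalidParameterError("series lengths differ")
        if np.any(self.inhibitor_concs < 0):
            raise InvalidParameterError("concentrations must be >= 0")


@dataclass(frozen=True)
class HookReport:
    hooked: bool
    peak_concentration: float | None
    peak_index: int | None
    drop_fraction: float


@dataclass(frozen=True)
class TitrationRowSummary:
    acceptor_concentration: float
    fold_over_background: np.ndarray
    trend_statistic: float
    hook: HookReport
    positive: bool


@dataclass(frozen=True)
class TitrationReport:
    rows: tuple
    background_mean: float
    fold_threshold: float
    trend_threshold: float

    @property
    def any_positive(self) -> bool:
        return any(r.positive for r in self.rows)


def subtract_background(plate: CrossTitrationPlate) -> CrossTitrationPlate:
    """Subtract mean buffer-alone counts, flooring corrected counts at 0.

    Idempotent: a plate already marked corrected is returned unchanged.
    """
    if plate.background_corrected:
        return plate
    if plate.background_wells.size == 0:
        raise NoBackgroundError("plate has no background wells")
    mean_bg = float(np.mean(plate.background_wells))
    corrected = np.clip(plate.signal - mean_bg, 0.0, None)
    return replace(plate, signal=corrected, background_corrected=True,
                   background_mean=mean_bg)


def detect_hook(concentrations, signals,
                drop_fraction: float = HOOK_DROP_FRACTION) -> HookReport:
    """Flag a bead-saturation hook in a concentration-ordered series.

    A hook is called when the signal beyond the maximum falls by at least
    ``drop_fraction`` of that maximum.  Series with fewer than 4 points
    return no-hook.
    """
    c = np.asarray(concentrations, float)
    s = np.asarray(signals, float)
    if c.size != s.size:
        raise InvalidParameterError("series lengths differ")
    if c.size < 4:
        return HookReport(False, None, None, 0.0)
    order = np.argsort(c)
    c, s = c[order], s[order]
    peak = int(np.argmax(s))
    if peak == c.size - 1 or s[peak] <= 0:
        return HookReport(False, None, None, 0.0)
    drop = float((s[peak] - np.min(s[peak:])) / s[peak])
    if drop >= drop_fraction:
        return HookReport(True, float(c[peak]), peak, drop)
    return HookReport(False, None, None, drop)


def summarize_cross_titration(
        plate: CrossTitrationPlate,
        fold_threshold: float = FOLD_THRESHOLD,
        trend_threshold: float = TREND_THRESHOLD) -> TitrationReport:
    """Per-acceptor-row binding calls on a background-corrected plate.

    For each acceptor concentration the report gives fold-over-background
    at each donor concentration, a Spearman rank correlation of signal vs
    donor concentration over the pre-hook region, any hook, and a binding
    call (positive when peak fold >= ``fold_threshold`` and trend >=
    ``trend_threshold``).
    """
    plate = subtract_background(plate)
    if plate.donor_concs.size < 3:
        raise DegenerateSeriesError("need >= 3 donor concentrations")
    bg = plate.background_mean if plate.background_mean else 1.0
    order = np.argsort(plate.donor_concs)
    donor = plate.donor_concs[order]
    rows = []
    for i, acc in enumerate(plate.acceptor_concs):
        corrected = plate.signal[i, order]
        fold = (corrected + bg) / bg
        hook = detect_hook(donor, corrected)
        end = hook.peak_index + 1 if hook.hooked else donor.size
        if end >= 3 and np.ptp(corrected[:end]) > 0:
            trend = float(spearmanr(donor[:end], corrected[:end]).statistic)
        else:
            trend = 0.0
        positive = (float(np.max(fold)) >= fold_threshold
                    and trend >= trend_threshold)
        rows.append(TitrationRowSummary(
            acceptor_concentration=float(acc), fold_over_background=fold,
            trend_statistic=trend, hook=hook, positive=positive))
    return TitrationReport(rows=tuple(rows), background_mean=float(bg),
                           fold_threshold=fold_threshold,
                           trend_threshold=trend_threshold)


def four_param_logistic(c, ic50, hill, top, bottom):
    """Descending 4PL curve ``bottom + (top-bottom)/(1 + (c/ic50)^hill)``."""
    c = np.asarray(c, float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


@dataclass(frozen=True)
class InhibitionFit:
    ic50: float
    hill: float
    top: float
    bottom: float
    ssr: float
    converged: bool


class FourParamLogisticRegressor(RegressorMixin, BaseEstimator):
    """Four-parameter logistic dose-response fit (sklearn estimator).

    ``fit(X, y)`` takes inhibitor concentrations (shape ``(n, 1)`` or
    ``(n,)``) and signals; the IC50 is optimized on a log scale.  Fitted
    attributes: ``ic50_``, ``hill_``, ``top_``, ``bottom_``, ``ssr_``.
    """

    def __init__(self, min_transition_ratio: float = 2.0,
                 max_nfev: int = 10_000):
        self.min_transition_ratio = min_transition_ratio
        self.max_nfev = max_nfev

    def fit(self, X, y):
        X = check_array(X, ensure_2d=False, dtype=float)
        c = X.ravel()
        y = np.asarray(y, dtype=float).ravel()
        if c.size != y.size:
            raise InvalidParameterError("X and y lengths differ")
        if c.size < 5:
            raise DegenerateSeriesError(
                "need >= 5 inhibitor concentrations spanning the transition")
        lo, hi = float(np.min(y)), float(np.max(y))
        if lo <= 0:
            lo_ref = hi / 1e6 if hi > 0 else 1.0
        else:
            lo_ref = lo
        if hi / lo_ref < self.min_transition_ratio:
            raise NoTransitionError(
                f"max/min signal ratio {hi / lo_ref:.2f} < "
                f"{self.min_transition_ratio}; no transition to fit")
        pos = c[c > 0]
        log_ic50_0 = float(np.mean(np.log(pos))) if pos.size else 0.0

        def model(cc, log_ic50, hill, top, bottom):
            return four_param_logistic(cc, np.exp(log_ic50), hill, top,
                                       bottom)

        p0 = [log_ic50_0, 1.0, hi, lo]
        try:
            popt, _ = curve_fit(
                model, c, y, p0=p0, maxfev=self.max_nfev,
                bounds=([log_ic50_0 - 25, 0.05, -np.inf, -np.inf],
                        [log_ic50_0 + 25, 20.0, np.inf, np.inf]))
        except RuntimeError as exc:
            raise FitConvergenceError(f"4PL fit failed: {exc}") from exc
        self.ic50_ = float(np.exp(popt[0]))
        self.hill_ = float(popt[1])
        self.top_ = float(popt[2])
        self.bottom_ = float(popt[3])
        resid = y - model(c, *popt)
        self.ssr_ = float(np.dot(resid, resid))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "ic50_")
        X = check_array(X, ensure_2d=False, dtype=float)
        return four_param_logistic(X.ravel(), self.ic50_, self.hill_,
                                   self.top_, self.bottom_)

    @property
    def result_(self) -> InhibitionFit:
        check_is_fitted(self, "ic50_")
        return InhibitionFit(ic50=self.ic50_, hill=self.hill_, top=self.top_,
                             bottom=self.bottom_, ssr=self.ssr_,
                             converged=True)


def fit_inhibition(series: InhibitionSeries, **kwargs) -> InhibitionFit:
    """Fit the 4PL blockade curve to an inhibition series; returns IC50 etc.

    The no-inhibitor control, when present, is included as a zero-
    concentration point anchoring the top plateau.
    """
    c = series.inhibitor_concs
    y = series.signal
    if series.no_inhibitor_signal is not None and not np.any(c == 0):
        c = np.concatenate([[0.0], c])
        y = np.concatenate([[series.no_inhibitor_signal], y])
    reg = FourParamLogisticRegressor(**kwargs)
    reg.fit(c.reshape(-1, 1), y)
    return reg.result_
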