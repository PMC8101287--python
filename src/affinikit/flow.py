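"""Multimer-staining flow-cytometry quantification.

Events arrive as plain intensity tables (one fluorescence value and a
viability flag per event); compensation, transformation and upstream gating
are assumed done.  The module provides the geometric mean fluorescence
intensity (gMFI) of live events, fluorescence-minus-one (FMO) background
subtraction, percent-positive gating against a reference sample's upper
quantile, and blockade normalization
``100 * (condition - FMO) / (control - FMO)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .exceptions import DataError, InvalidParameterError

__all__ = [
    "EventTable",
    "SubtractedGMFI",
    "geometric_mfi",
    "fmo_subtract",
    "percent_positive",
    "normalize_blockade",
]

#: Default positivity gate: 99.9th percentile of the reference sample.
DEFAULT_POSITIVITY_QUANTILE = 0.999


@dataclass
class EventTable:
    """Per-event fluorescence intensities with viability flags."""

    intensities: np.ndarray
    live_flags: np.ndarray | None = None
    sample_label: str = "stain"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not np.all(np.isfinite(self.intensities)):
            raise InvalidParameterError("intensities must be finite")
        if self.live_flags is None:
            self.live_flags = np.ones(self.intensities.size, dtype=bool)
        else:
            self.live_flags = np.asarray(self.live_flags, dtype=bool)
        if self.live_flags.size != self.intensities.size:
            raise InvalidParameterError(
                "live_flags and intensities lengths differ")

    @property
    def live_intensities(self) -> np.ndarray:
        return self.intensities[self.live_flags]


def geometric_mfi(events: EventTable) -> float:
    """Geometric mean fluorescence intensity over live events.

    ``exp(mean(log I))``; raises if no live events or any live intensity is
    nonpositive (log-transform guard).
    """
    live = events.live_intensities
    if live.size == 0:
        raise DataError("no live events")
    if np.any(live <= 0):
        raise DataError("nonpositive intensity among live events")
    return float(np.exp(np.mean(np.log(live))))


class SubtractedGMFI(NamedTuple):
    value: float
    floored: bool


def fmo_subtract(stain_gmfi: float, fmo_gmfi: float) -> SubtractedGMFI:
    """Background-subtracted gMFI ``stain - FMO``, floored at zero.

    The ``floored`` flag records when the raw difference was negative.
    """
    if not (np.isfinite(stain_gmfi) and np.isfinite(fmo_gmfi)):
        raise InvalidParameterError("gMFI values must be finite")
    diff = stain_gmfi - fmo_gmfi
    if diff < 0:
        return SubtractedGMFI(0.0, True)
    return SubtractedGMFI(float(diff), False)


def percent_positive(stain: EventTable, reference: EventTable,
                     quantile: float = DEFAULT_POSITIVITY_QUANTILE) -> float:
    """Percentage of live stain events above the reference's quantile gate.

    The gate is the ``quantile`` (default 99.9th percentile) of the live
    reference intensities, so a stain identical in distribution to the
    reference reads ~``100 * (1 - quantile)`` percent.
    """
    if not 0.0 < quantile < 1.0:
        raise InvalidParameterError("quantile must be in (0, 1)")
    ref = reference.live_intensities
    if ref.size == 0:
        raise DataError("empty reference sample")
    stain_live = stain.live_intensities
    if stain_live.size == 0:
        raise DataError("no live stain events")
    threshold = float(np.quantile(ref, quantile))
    return float(100.0 * np.mean(stain_live > threshold))


def normalize_blockade(condition_gmfi: float, control_gmfi: float,
                       fmo_gmfi: float) -> float:
    """Percent binding relative to the control blockade condition.

    ``100 * (condition - FMO) / (control - FMO)``, floored at 0; the
    control must exceed the FMO background.
    """
    if control_gmfi <= fmo_gmfi:
        raise DataError("degenerate control: control gMFI <= FMO gMFI")
    pct = 100.0 * (condition_gmfi - fmo_gmfi) / (control_gmfi - fmo_gmfi)
    return float(max(0.0, pct))
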