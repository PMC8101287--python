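"""Published reference parameter sets for the LAG-3:Fc / pHLA-DR1 system.

These constants reproduce the published bivalent-analyte kinetic fits of a
dimeric LAG-3:Fc fusion protein binding immobilized peptide–HLA-DR1, and the
companion steady-state, blockade and multimer-staining readouts.  They serve
as the ground-truth conditions for the synthetic-data generators and the
package's worked examples.

The second-site on-rate is published in molar units; it is converted back to
native instrument units (RU^-1 s^-1) through
``k_on2_ru = k_on2_molar / (100 * analyte_mw)``.  The analyte molecular
weight is not published; :data:`ANALYTE_MW_DA` is the package's nominal value
for a glycosylated dimeric four-Ig-domain:Fc fusion.
"""

from __future__ import annotations

import numpy as np

from .models import BivalentAnalyteParams, InjectionProtocol

__all__ = [
    "ANALYTE_MW_DA",
    "GLOBAL_FIT_PARAMS",
    "LOCAL_FIT_PARAMS",
    "GLOBAL_RI_RANGE_RU",
    "KINETIC_CONCENTRATIONS_M",
    "STEADY_STATE_CONCENTRATIONS_M",
    "STEADY_STATE_KD_M",
    "STEADY_STATE_BMAX_RU",
    "BLOCKADE_IC50_NM",
    "MULTIMER_POSITIVE_FRACTION",
    "LIGAND_DENSITIES_RU",
    "DEFAULT_PROTOCOL",
    "twofold_series",
]

#: Nominal molecular weight (Da) of the dimeric receptor:Fc fusion analyte.
ANALYTE_MW_DA = 200_000.0


def _ru_rate(k_on2_molar: float, mw: float = ANALYTE_MW_DA) -> float:
    return k_on2_molar / (100.0 * mw)


#: Global (multi-concentration) bivalent-analyte fit parameters.
GLOBAL_FIT_PARAMS = BivalentAnalyteParams(
    k_on1=5.22e4, k_off1=0.380,
    k_on2_ru=_ru_rate(96.9), k_off2=4.10e-3,
    R_max=962.0, RI=10.0, analyte_mw=ANALYTE_MW_DA)

#: Local (single-concentration, 7.1 uM) bivalent-analyte fit parameters.
LOCAL_FIT_PARAMS = BivalentAnalyteParams(
    k_on1=7.24e4, k_off1=0.439,
    k_on2_ru=_ru_rate(156.6), k_off2=4.30e-3,
    R_max=1190.0, RI=6.6, analyte_mw=ANALYTE_MW_DA)

#: Per-cycle bulk refractive-index range (RU) reported for the global fit.
GLOBAL_RI_RANGE_RU = (4.6, 16.9)


def twofold_series(top: float, n: int) -> np.ndarray:
    """Twofold serial dilution from ``top`` down, length ``n``, ascending."""
    return top / 2.0 ** np.arange(n)[::-1]


#: Twofold analyte series 0.11–7.1 uM used for kinetic fitting (molar).
KINETIC_CONCENTRATIONS_M = twofold_series(7.1e-6, 7)

#: Twofold analyte series 0.11–57 uM used for steady-state analysis (molar).
STEADY_STATE_CONCENTRATIONS_M = twofold_series(57e-6, 10)

#: Monovalent affinity from low-density steady-state analysis (M).
STEADY_STATE_KD_M = 13.1e-6

#: Maximal response used for synthetic isotherm designs (RU).
STEADY_STATE_BMAX_RU = 500.0

#: Fab-blockade half-maximal inhibitory concentration (nM).
BLOCKADE_IC50_NM = 1.32

#: Fraction of receptor-positive cells detectably stained by pHLA-II multimer.
MULTIMER_POSITIVE_FRACTION = 0.19

#: Low / intermediate / high immobilized ligand densities (RU).
LIGAND_DENSITIES_RU = (244.0, 525.0, 1000.0)

#: 30 s association / 300 s dissociation injection protocol.
DEFAULT_PROTOCOL = InjectionProtocol(
    analyte_concentration=7.1e-6, association_duration=30.0,
    dissociation_duration=300.0, sampling_interval=1.0,
    baseline_duration=10.0)
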