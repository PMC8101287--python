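# Methods

## Binding models

The bivalent-analyte scheme tracks two surface species in response units:
`AB` (analyte bound through one site) and `AB2` (bridging two ligands).
Free ligand is `B = R_max − AB − AB2`: the doubly bound complex is assumed
to occupy one ligand equivalent of *analyte* capacity while consuming a
second ligand, and both species contribute one unit of mass response, since
the second binding event adds no analyte mass to the surface. This matches
the model family implemented in standard biosensor evaluation software.
Whether the instrument convention counts `AB2` against one or two ligand
equivalents is not observable from reported parameter tables, so the
alternative bookkeeping (`B = R_max − AB − 2·AB2`) is available through the
`stoichiometry="double"` switch on the simulator and fitter; it is off by
default and never silently applied.

Assumptions shared by both models: no mass-transport limitation, no
conformational-change step, homogeneous ligand, no carryover between
injection cycles, and isothermal operation (the reference data were
collected at 25 °C; temperature is not modelled). The bulk refractive-index
offset `RI` is a rectangle — present while analyte flows, absent
otherwise — because no drift model is reported for the reference data;
linear baseline drift is available in the synthetic generator only.

Integration uses LSODA with relative tolerance 1e-8 and absolute tolerance
1e-6 RU on the fixed output grid implied by the sampling interval. All
cycles of a global fit share rates and `R_max` and differ only in `C`, so
they are integrated as one block-diagonal system per solver call. Time zero
is injection start; baseline samples carry negative times.

## Kinetic fitting

The fit minimizes the sum of squared residuals over association and
dissociation samples (baseline excluded; the fitted window is the full
recorded phase). Rate constants and `R_max` are optimized as logarithms
with a trust-region-reflective solver (cost tolerance 1e-10), which
enforces positivity without penalty terms. Per-cycle `RI` enters the
response linearly on the association window only, so it is solved in
closed form inside the residual (variable projection, clipped at 0); this
is algebraically equivalent to optimizing `RI` jointly but keeps the
nonlinear search at five parameters regardless of cycle count. Five seeded
starts — the default guess plus four log-uniform jitters within half a
decade — guard against local minima; the best final cost wins and ties
break toward the first start, so repeated fits are bit-identical.

Default initial guesses: `k_on1 = 1e4 M⁻¹s⁻¹`, `k_off1 = 0.1 s⁻¹`,
`k_on2 = 1e-4 RU⁻¹s⁻¹`, `k_off2 = 1e-3 s⁻¹`, `R_max = 1.2 × max observed`.
Box bounds span several decades around physically plausible values; the
second-site on-rate may collapse to its lower bound (1e-12 RU⁻¹s⁻¹), which
is how an effectively monovalent dataset expresses itself under the
bivalent model.

Goodness of fit is reported two ways. The instrument-style statistic
`χ² = Σ(observed − expected)²/expected` follows the published formula, but
that denominator is unguarded as the expected response approaches zero at
late dissociation, so it is floored at 1 RU; the plain SSR is always
reported alongside and is the quantity actually minimized. Absolute χ²
values are properties of a particular recorded trace (they scale with the
noise realization), so model selection uses ranking only, with a
more-parameterized model flagged as over-parameterized when its χ² improves
on a simpler model's by less than 1%.

Global fits share `R_max` across cycles — a single printed capacity for a
multi-concentration fit implies one shared surface — while `RI` is
per-cycle, consistent with reported per-fit RI ranges.

## Unit conversion and derived constants

`k_on2` is stored natively in RU⁻¹ s⁻¹ and converted for reporting via
`k_on2 (M⁻¹s⁻¹) = k_on2 (RU⁻¹s⁻¹) × 100 × MW(Da)`. The analyte molecular
weight is required configuration with no silent default, because the
conversion is meaningless without it. The package's reference value for
the LAG-3:Fc analyte is 200 kDa — a realistic mass for a glycosylated
dimeric four-Ig-domain:Fc fusion — used only by the reference parameter
sets and demo designs; the published molar-unit constants are recovered
independent of this choice because the reference `k_on2_ru` is derived by
inverting the same conversion. `K_D1 = k_off1/k_on1` and
`K_D2 = k_off2/k_on2(molar)` hold exactly by construction.

## Steady-state analysis

The plateau readout is the sample nearest 30 s into the injection
(nearest-sample, not interpolated: at ≤1 s sampling the difference is
negligible) minus the mean baseline over the final 10 s before injection —
both defaults chosen here, as the source procedures do not state them. The
readout is treated as steady state by design at low density; an optional
slope check (last 5 s of association) can emit a warning. The one-site fit
optimizes `log K_D` and `B_max` with unconstrained `B_max`; a fit whose
`K_D` falls below half the lowest sampled concentration, or whose
covariance puts more than 100% relative uncertainty on `log K_D`, is
flagged `kd_constrained=False` (the saturated-design case).

Density-series analysis reports the apparent dissociation half-time (time
for the bound response to halve after injection stop, linearly
interpolated) and fractions remaining at 10/30/60 s. Under the bivalent
scheme more surface ligand means more second-site rescue and a longer
half-time; under 1:1 kinetics the half-time is `ln 2 / k_off` regardless of
density — the package's diagnostic for bivalency.

## Plate assays

Cross-titration positivity thresholds are package-defined (the source
assays make qualitative detected/not-detected calls): a row is positive
when peak fold-over-background ≥ 3 and the Spearman rank correlation of
signal vs donor concentration over the pre-hook region is ≥ 0.8. A hook is
flagged when signal past the maximum falls by ≥ 20% of that maximum.
Counts are arbitrary amplified units, modelled as continuous with
multiplicative Gaussian noise; no Poisson model. The 4PL blockade fit
optimizes `log IC50`, the Hill slope (fitted, not fixed at 1), top and
bottom; a series whose max/min ratio is below 2 is rejected as having no
transition rather than returning an unstable fit.

## Flow quantification

gMFI is `exp(mean(log I))` over live events, with nonpositive intensities
rejected rather than clipped. The positivity gate is the 99.9th percentile
of the reference (FMO or irrelevant-multimer) sample — a standard choice;
the source figures show gates without stating the rule. FMO subtraction
and blockade normalization floor at zero and flag when the floor binds.
Event tables are plain CSV (intensity + live flag); cytometry file parsing,
compensation and upstream gating are out of scope, keeping the module
instrument-agnostic.

## Synthetic data

Generators emulate the reference study designs: twofold dilution series
0.11–7.1 µM (kinetics) and 0.11–57 µM (steady state) with 30 s
association / 300 s dissociation at 1 s sampling; one-in-three plate
dilutions (0.3–300 nM cross-titrations, 0.01–1000 nM blockade); and
two-population log-normal event mixtures. Defaults the sources do not
state and that were fixed here once: sensorgram noise sd 2 RU
(instrument-typical white noise), plate CV 5%, flow log-sd 0.5,
per-cycle RI interpolated across the reported 4.6–16.9 RU range, absolute
plate count scale 1000 (arbitrary, flagged as such). Noise is i.i.d.
Gaussian; the generators do not emulate reference-cell subtraction
artifacts, correlated drift, mass-transport distortion, spike artifacts at
injection boundaries, or inter-cycle carryover — so passing recovery tests
demonstrate estimator correctness under the stated noise model, not
robustness to every instrument pathology. Every generator is deterministic
per seed and embeds its ground truth in output metadata.

## Problem sizes

Recovery checks use 20 seeded replicates of each design: global bivalent
fits over 7 concentrations × ~330 fitted samples per cycle, 10-point
isotherms, and 12-point inhibition series. A full 20-replicate kinetic
recovery takes about a minute on one core; single fits take a few seconds.

## Known limitations

* The bivalent fitter assumes all cycles in a global fit share one
  surface; regenerated or multi-chip series must be fitted separately.
* Mass-transport-limited, two-state and heterogeneous-ligand models are
  out of scope, as are avidity constants from density series (treated
  qualitatively, mirroring the source analysis).
* Apparent half-times are resolution-limited by the sampling interval for
  very fast dissociation.
* The χ² floor (1 RU) makes the instrument-style statistic well-defined
  but means its absolute value is not comparable to values computed with a
  different guard.
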