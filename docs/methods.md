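# Methods

## Gas-log preprocessing

Gas meters report incremental volumes at meter temperature and pressure.
Each increment is converted to STP by the ideal-gas ratio
`V_stp = V · (273.15/T) · (P/101.325)`; no water-vapor correction is applied
(the headspace is treated as dry — loggers that already dry the gas make the
correction redundant, and applying it without knowing the meter's internal
handling would double-correct). On a methane basis each increment is
multiplied by its CH4 fraction before accumulation.

Blank subtraction follows the standard BMP convention: the inoculum-only
channels are averaged per gram of inoculum VS, interpolated onto the test
channel's time grid, scaled by the test channel's inoculum VS, subtracted,
and the remainder divided by substrate VS. Because specific yield is
physically non-negative and cumulative, negative blank-corrected values are
clamped at zero and the output made monotone by a running maximum; a blank
exceeding the test at the final time flags the curve and logs a warning
rather than failing. Channels are blank-corrected individually and replicate
statistics (mean ± sd) are computed afterwards; averaging first would hide
replicate-level meter faults.

Day binning anchors at t = 0: day d covers elapsed hours (24(d−1), 24d], so
the first calendar day of the assay is day 1. T_f (f = 0.5, 0.9, 0.95 by
default) is the smallest whole day whose cumulative value reaches f times
the measured final value — the measured curve, not a fitted asymptote, so the
statistic stays model-free; results are reported at whole-day resolution.
The termination rule scans the daily series for the first run of three
consecutive days each producing less than 1% of the running cumulative
total (window and threshold configurable).

## Kinetic models and fitting

The four B(t) forms (modified Gompertz, logistic, Cone, first-order) are
closed-form, monotone and bounded by B0. The Cone model's value at t = 0 is
defined as 0 by continuous extension of `B0/(1 + (kt)^(−n))`.

Fitting is bounded nonlinear least squares (trust-region reflective) with a
multi-start grid: heuristic initial values — B0 from the observed final
value, Rmax from the largest per-interval rate, λ from the first time the
curve exceeds 1% of its final value, k = 0.5 d⁻¹, n = 2 — each scaled by
{0.5, 1, 2}, best start by SS_res. Bounds: all parameters ≥ 0, λ ≤ assay
duration, B0 ≤ 3× the observed final (prevents divergent asymptotes on short
series). Tight solver tolerances (1e−15) let noiseless self-fits recover
parameters to ≤ 1e−6 relative, which the test suite asserts for all four
models on 26-point daily grids. R² = 1 − SS_res/SS_tot is plain (not
adjusted) and reported in percent to 2 d.p. The Cone shape parameter n is
always estimated freely and reported. The t = 0 point is included in fits
with its measured value.

First-order hydrolysis fitting defaults to nonlinear least squares on the
original concentration scale — the log transform inflates noise near
complete removal — with a log-linear regression available as an option and
used to initialize the NLS. A boundary candidate k = 0 (constant series) is
always evaluated so non-decaying inputs return exactly zero. Non-positive
concentrations are excluded with a warning. The single-point inversion
`k_deg = −ln(1 − removal)/t` agrees with the fitter on noiseless data.

## Buswell stoichiometry

TMP uses a 22.4 L/mol molar volume and nominal atomic masses 12/1/16/14 —
the constants of the conventional printed formula — rather than CODATA
values, so results bit-match the standard expression; the difference is
≈0.2% and irrelevant to BD at the precision reported. Sulfur is not part of
the total reaction. Subscripts from mass percentages are left unscaled
because TMP is homogeneous of degree 0 in them. An element-balance checker
verifies C/H/O/N closure of the reaction coefficients to 1e−9 relative; the
test suite additionally cross-checks TMP against an independent linear
solve of the element-balance system on 1,000 random compositions.

Biodegradability is reported with an explicit basis flag. EMP is per g VS
while elemental TMP is per g dry matter; the two bases can be aligned with a
VS/TS fraction when available. For a near-pure polysaccharide the repeating
unit (C5H8O4 for xylan, TMP 424.24 mL/g) and the measured elemental
composition give slightly different TMPs, hence different BDs (~90% vs ~95%
for a 381.91 mL/g VS yield); the package computes both conventions instead
of preferring one silently.

## Van Krevelen classification

The seven class boxes overlap on shared edges (O/C = 0.3 between lipids and
aliphatic/proteins, H/C = 1.5 between lignin/CRAM and the aliphatic classes,
O/C = 0.67 between lignin/CRAM and tannins). To make classification a
deterministic partition, boxes are applied in a fixed precedence order
(lipids, aliphatic/proteins, lignin/CRAM, carbohydrates, unsaturated
hydrocarbons, aromatics, tannins) with half-open [low, high) intervals; the
final box keeps its upper edges inclusive so the O/C = 1 boundary of the
tannin region is not lost. The order and boxes are configurable. Formulas
outside every box are retained as `unassigned` — partitions must sum to
100%. Element grouping (CHO/CHON/CHOS/CHONS) is by heteroatom presence;
oxygen-free formulas go to a logged `other` bucket. Intensity weighting is
the default summary (count weighting available) since spectral abundance
shares are the usual reporting convention; both are implemented because
exports differ in whether intensities are trustworthy across samples.
Inputs are assumed monoisotopic neutral formulas; adduct/isotopologue
handling is upstream of this package.

## Economics

SMY = EMP × reference_period / digestion_time is a pure ratio; the default
reference period is 100 days. Power = SMY (m³) × energy density ×
efficiency; benefit = power × tariff. Defaults: 9.97 kWh/m³ CH4 (≈35.9
MJ/m³, lower heating value), 60% combined-cycle efficiency, 0.75 CNY/kWh.
The percent benefit increase between scenarios sharing those constants
reduces exactly to the SMY ratio and is therefore independent of them — a
property the tests verify over random constants. Capital and operating
costs are out of scope.

## Synthetic data

The generator emulates a mesophilic triplicate BMP design: three substrate
groups at inoculum-to-substrate ratios 2/3/4 (2 g substrate VS each), three
inoculum-only blanks, hourly sampling for 25 days, meter at 308.15 K, 60%
CH4 in the biogas. True methane kinetics default to first-order with
ultimate yields 343.76/374.72/364.76 mL/g VS and rates 0.62/0.64/0.55 d⁻¹
for the three groups — the parameter range a fast, fully degradable
polysaccharide shows. The endogenous blank is modelled first-order with
B0 = 15 mL per g inoculum VS and k = 0.10 d⁻¹: small and slow relative to
the substrate signal, as degassed granular sludge behaves. Meter noise is
additive Gaussian on incremental volumes, truncated at zero (flow meters
cannot tick backwards), sd 0.3 mL ≈ 2% of early-phase hourly increments. A
direct curve-level generator (`generate_yield_curve`, relative noise on
per-interval increments) supports parameter-recovery studies on daily grids,
and the substrate-series generator uses multiplicative log-normal noise.
The formula-table generator draws classes multinomially from target shares
(defaults 62.57/22.97/11.00% for lignin-CRAM/aliphatic-proteins/lipids, the
remainder spread over the minor classes) and rejection-samples integer atom
counts (C between 4 and 40) inside each class box until the realized class
matches the intended one, so generator/classifier closure is exact by
construction. Every generator is a pure function of config + seed (default
seed 20260302, recorded in outputs).

What the generator does *not* emulate: early acidification transients and
pH-coupled lag structure, replicate-level systematic offsets, time-varying
CH4 fraction, meter drift, or correlated DOM intensity structure across
samples. Passing round-trip and recovery tests therefore demonstrates the
correctness of the computational chain under the stated statistical
assumptions, not robustness to every failure mode of real assays.

## Problem sizes and numerical choices

Tests and the acceptance script use 26-point daily grids for fitting
studies, 100 seeds for the noisy-recovery study, 1,000 random compositions
for the stoichiometry cross-check, 5,000–10,000 formulas for DOM checks,
and hourly 25-day logs (600 points × 12 channels) for preprocessing round
trips — sizes chosen to make sampling error negligible relative to the
tolerances asserted while keeping a full run in seconds. Share-recovery
assertions use the multinomial 99% CI at the target proportion. Seeds for
multi-part runs are derived via `numpy.random.SeedSequence` spawning.

## Known limitations

- Fitted Cone parameters are only comparable across datasets when the shape
  parameter n is reported alongside k; k alone is not identifiable of rate.
- T statistics at whole-day resolution saturate for very fast substrates
  (anything reaching 50% within day 1 reports T50 = 1).
- The economics module prices energy only; it is not a techno-economic model.
- BD depends on the TMP basis choice; always read the basis flag.
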