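# biomethane

Analysis toolkit for biochemical methane potential (BMP) assays of
well-characterized substrates, built around the full chain a digestion study
needs: raw gas-log preprocessing, methane-production kinetics, theoretical
yield stoichiometry, dissolved-organic-matter (DOM) composition, and
methane-to-electricity economics. It is aimed at environmental-biotechnology
researchers and engineers who run batch BMP tests (AMPTS-style loggers) on
substrates such as hemicellulose/xylan and want a reproducible, scripted
route from meter ticks to publishable tables.

## What it computes

**Gas preprocessing** (`biomethane.gas_preprocess`). Incremental gas volumes
are normalized to STP (273.15 K, 101.325 kPa), weighted by the CH4 fraction,
blank-corrected by the inoculum-only channels (scaled by inoculum volatile
solids), and expressed as cumulative mL CH4 per g substrate VS. Derived
statistics: daily/hourly production, T50/T90/T95 (earliest whole day reaching
50/90/95% of the final yield), and the termination day (three consecutive
days each below 1% of the running total).

**Kinetics** (`biomethane.kinetics`). Four models of the cumulative curve
B(t):

- modified Gompertz: `B = B0 exp(-exp(Rmax·e/B0 (λ - t) + 1))`
- logistic: `B = B0 / (1 + exp(4 Rmax/B0 (λ - t) + 2))`
- Cone: `B = B0 / (1 + (k t)^(-n))`
- first-order: `B = B0 (1 - exp(-k t))`

fitted by multi-start bounded nonlinear least squares, reported with R² (%).
First-order substrate hydrolysis `S(t) = S0 exp(-k_deg t)` is fitted from
concentration series or inverted from a single removal measurement.

**Stoichiometry** (`biomethane.stoichiometry`). The Buswell total reaction
for CnHaObNc gives the theoretical methane potential
`TMP = 22.4·1000·(n/2 + a/8 - b/4 - 3c/8) / (12n + a + 16b + 14c)` mL/g, and
biodegradability `BD = EMP/TMP × 100%`.

**DOM classification** (`biomethane.dom_classify`). FT-ICR-MS formula
assignments are binned on the Van Krevelen plane (H/C vs O/C) into seven
compound classes (lipids, aliphatic/proteins, lignin/CRAM-like,
carbohydrates, unsaturated hydrocarbons, aromatics, tannins) and into
CHO/CHON/CHOS/CHONS element groups, with intensity- or count-weighted shares.

**Economics** (`biomethane.economics`). Yield scaled to a 100-day reference
period (SMY), converted to electricity at a stated efficiency and energy
density, priced at a feed-in tariff.

**Synthetic data** (`biomethane.synthetic_data`). Seeded generators for gas
logs (substrate channels + blanks), substrate-decay series and formula
tables, each storing its ground truth, so the whole pipeline is testable
without any measurement files.

## Worked example

```python
import numpy as np
from biomethane import economics, kinetics, stoichiometry, synthetic_data
from biomethane.gas_preprocess import YieldCurve

# theoretical potential of the anhydroxylose unit C5H8O4
res = stoichiometry.buswell(stoichiometry.MolecularSubscripts(5, 8, 4))
print(f"TMP = {res.tmp:.2f} mL/g")            # TMP = 424.24 mL/g
bd = stoichiometry.biodegradability(381.91, res.tmp)
print(f"BD  = {bd.bd:.2f} %")                 # BD  = 90.02 %

# refit a first-order methane curve (ultimate yield 374.72 mL/g VS, k = 0.64/d)
t = np.arange(0.0, 26.0)
spec = kinetics.KineticModelSpec("first_order", {"B0": 374.72, "k": 0.64})
fit = kinetics.fit_kinetic(YieldCurve(t, kinetics.model_curve(spec, t)), "first_order")
print(f"k   = {fit.spec.params['k']:.2f} 1/d") # k   = 0.64 1/d

# electricity economics of that yield over a 100-day reference period
out = economics.power_and_benefit(economics.EconomicScenario(emp=381.91, digestion_time=25))
print(f"SMY = {out.smy:.2f} mL, power = {out.power:.2e} kWh, benefit = {out.benefit:.2e} CNY")
# SMY = 1527.64 mL, power = 9.14e-03 kWh, benefit = 6.85e-03 CNY
```

The TMP is the stoichiometric ceiling for methane from a xylan repeating
unit; BD says the measured yield realizes ~90% of it. The economics line
converts the yield to ~9.1 mWh of electricity per g VS at 60% generation
efficiency, worth ~0.007 CNY at a 0.75 CNY/kWh tariff.

A command-line surface mirrors the library:

```bash
biomethane simulate make-fixtures fixtures/ --seed 1
biomethane bmp preprocess --gas-logs fixtures/gas_logs.csv \
    --channel-meta fixtures/channel_meta.csv --out out/
biomethane run all --config run.yaml
```

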