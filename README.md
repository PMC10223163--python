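# rivddi

Population-pharmacokinetic prediction of the drug–drug interaction between
**rivaroxaban** (RIV, a direct oral anticoagulant and CYP3A4/Pgp–BCRP
substrate) and **carbamazepine** (CBZ, a strong inducer of those enzymes and
transporters). The package is aimed at pharmacometricians who want a fully
reproducible, tested implementation of the rat-to-human extrapolation
workflow: rat population-PK parameters → CBZ covariate effects → allometric /
liver-blood-flow scaling → Monte-Carlo population simulation → exposure-change
metrics.

## Model

Rivaroxaban kinetics follow a two-compartment disposition model with
first-order elimination and **mixed absorption**: a fraction *F1* of each oral
dose enters a first-order depot (rate constant *K*<sub>a</sub>, no lag) and
the remaining 1 − *F1* is delivered as a zero-order input of duration *D2*
starting *Alag2* h after the dose (solubility-limited uptake). All parameters
are apparent (per bioavailability *F*). CBZ pretreatment enters as a binary
covariate,

&nbsp;&nbsp;CL/F = TVCL · (1 + CL<sub>CBZ</sub>),&nbsp;&nbsp;
D2 = TVD2 · (1 + D2<sub>CBZ</sub>),

with CL<sub>CBZ</sub> = 2.11 and D2<sub>CBZ</sub> = 0.339 in the CBZ arm.
Rat per-kg parameters are extrapolated to a 60 kg human by simple allometry
(exponent 1) for volumes and by the ratio of absolute liver blood flows
(85 vs 21 mL/min/kg) for clearances; the human *K*<sub>a</sub> (0.97 h⁻¹)
comes from clinical data. Between-subject variability is log-normal on CL/F
(49 %CV) and V<sub>c</sub>/F (47 %CV); residual error is combined
additive (13.6 ng/mL) + proportional (23.2 %).

Concentration profiles are computed two independent ways — an exact
closed-form superposition of the two-compartment bolus/infusion responses and
an adaptive-step ODE integration with dose/lag/infusion breakpoints — which
agree to ≤0.1 % and cross-validate each other in the test suite.

## Worked example

```bash
rivddi simulate-human --n 1000 --seed 20230502 --out results/
```

prints

```
wrote results/report.md
first-dose AUC relative change: 51.9 %
first-dose Cmax relative change: 46.4 %
```

and `results/report.md` contains the full exposure table (mean and 5th–95th
percentile over 1000 replicate subjects per arm, paired etas):

```
metric                       control                    +CBZ  rel.change %
auc_first      1280.6 (747.9-1824.0)    615.6 (286.1-1045.5)          51.9
auc_ss         2493.8 (970.1-4892.3)    801.8 (311.9-1573.1)          67.8
cmax_first        133.4 (89.5-182.3)       71.5 (41.7-107.8)          46.4
cmax_ss          187.9 (103.2-311.3)       80.7 (43.9-132.8)          57.0
t_half                 6.3 (4.9-8.2)           4.5 (3.6-5.7)             -
```

Reading: co-administration of CBZ roughly halves first-dose rivaroxaban
exposure (AUC over the first 24 h falls from ≈1281 to ≈616 ng·h/mL, a 51.9 %
decrease) and cuts steady-state exposure by about two-thirds — a clinically
meaningful interaction. The control-arm predictions fall within two-fold of
observed clinical exposure (ratio column of the qualification block in the
report), which is the standard criterion for accepting the extrapolation.

The same pipeline is available from Python:

```python
import rivddi as rd

report = rd.run_pipeline(rd.PipelineConfig(n=1000, seed=20230502))
print(report.summary.relative_changes["auc_first"]["ratio_of_means"])  # 51.9
```

Other entry points: `rivddi simulate-rat-study` (synthetic two-group rat
dataset), `rivddi fit` (pooled maximum-likelihood parameter recovery, a
`PooledPKModel.fit()` → results-object API in Python), `rivddi nca`
(non-compartmental metrics for profile CSVs) and `rivddi evaluate`
(two-fold qualification report).

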