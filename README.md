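# maldiauxie

Bistability of the budding-yeast *MAL* regulon and quantification of
galactose–palatinose diauxie from plate-reader growth curves.

Budding yeast prioritises galactose over palatinose, a sucrose isomer it
imports through the Mal11 proton symporter and cleaves intracellularly
with the isomaltases Ima1/Ima5. In galactose–palatinose mixtures the
culture grows in two phases separated by a growth pause (diauxie): the
*MAL* regulon only switches on after galactose is exhausted. This package
implements, for modellers and for people analysing plate-reader data:

* **a dimensionless ODE model of the *MAL* regulon** with coupled
  positive feedback (Mal11 imports the inducer) and negative feedback
  (isomaltases destroy it), its steady states, stability, two-parameter
  bifurcation structure, hysteresis, and genotype predictions;
* **a plate-reader phenotyping pipeline**: blank subtraction, OD
  calibration, penalised-spline (or Gaussian-process) estimation of the
  specific growth rate µ(t) = d/dt log OD, diauxie detection, phase-yield
  quantification, lag and mid-log rate extraction, and Welch comparisons;
* **a synthetic two-sugar batch-culture simulator** (Monod kinetics with
  per-sugar yields, sequential/simultaneous/regulon-coupled consumption,
  realistic plate-reader noise and OD saturation) that supplies ground
  truth for every analysis stage.

## The model

With intracellular palatinose *p*, pooled isomaltase *I* and transporter
*T* (time in units of isomaltase turnover, concentrations in units of the
*IMA* induction EC50, K_I = 1):

```
dp/dt = v_T·T − I·p/(K_M + p)
dI/dt = u_I,max·pⁿ/(1 + pⁿ) − I
dT/dt = b_T + u_T,max·pⁿ/(K_Tⁿ + pⁿ) − d_T·T
```

with K_T > K_I, so isomaltases are induced before the transporter. The
regulon is **ON** when steady-state p/K_T > 1. Scanning repression
strength K_T against the expression-to-import ratio u_I,max/v_T yields
three regions — ON, OFF and a bistable band — and the ratio has a minimal
value (b_T + u_T,max)/d_T below which palatinose accumulates without
bound. Galactose acts by multiplying K_T (a GAL-induced repressor at the
*MAL11* promoter); hysteresis keeps cells entering the bistable band from
low palatinose locked OFF, producing diauxie.

## Worked example

`python examples/simulate_and_phenotype.py` simulates a galactose
gradient (0.2–0.8 % w/v, palatinose fixed at 0.5 %), renders it as a
noisy plate, and phenotypes every well:

```
well  conc_1  is_diauxic  t_switch  od_switch   od1   od2   lag  mu_midlog
  A1     0.2        True    14.167      0.222 0.202 0.487 2.167      0.250
  A4     0.4        True    16.833      0.402 0.385 0.542 0.000      0.243
  A7     0.6        True    18.500      0.627 0.603 0.489 0.000      0.239
 A12     0.8        True    19.167      0.840 0.820 0.499 0.000      0.245
...
OD1 vs galactose: slope 1.024 (95% CI 0.992-1.056), R^2 = 0.998
```

Every well is called diauxic; `od1` (OD at the growth-rate minimum minus
initial OD) tracks the galactose concentration with the simulator's unit
yield, while `od2` stays near the fixed palatinose yield of 0.5.

`python examples/genotype_predictions.py` prints the model's genotype
panel: the wild type is OFF with galactose and ON without (diauxie);
deleting *IMA1* or over-expressing *MAL11* switches the mixture
phenotype to ON (diauxie abolished); *gal80Δ* stays OFF in both
conditions until *IMA1* is also deleted. `bifurcation_scan.py` and
`hysteresis_loop.py` show the three-region plane (escape threshold
K_T\* ≈ 1.44 for the default parameters) and the hysteresis gap
(forward OFF at K_T ≈ 2.89 vs backward ON at ≈ 1.39).

There is also a CLI for shell use:

```sh
maldiauxie simulate --seed 1 --out-dir out/sim
maldiauxie phenotype --data out/sim/plate.csv --layout out/sim/layout.csv \
    --calibration out/sim/calibration.csv --out out/ph
maldiauxie bifurcate --out out/scan
maldiauxie scenarios --out out/scen
```

## Layout

```
src/maldiauxie/
  regulon.py      ODE model, steady states, classification, simulation
  bifurcation.py  two-parameter scan, hysteresis, escape threshold
  genotypes.py    genotype -> parameter mapping, scenario panel
  phenotyping.py  plate IO, preprocessing, mu(t), diauxie, yields, stats
  simulate.py     Monod two-sugar cultures, plate rendering, noise model
  config.py       YAML run configuration and provenance manifest
  cli.py          click command-line interface
docs/methods.md   modelling and analysis notes
examples/         one narrative script per capability
```
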