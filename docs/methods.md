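# Methods

## The regulon model

The *MAL* regulon is reduced to three variables: intracellular palatinose
*p*, pooled isomaltase *I* (Ima1 + Ima5, catalytic capacity absorbed into
its units) and transporter *T* (Mal11). Transcriptional activation by the
palatinose-bound regulators is modelled by Hill functions with a shared
Hill number *n*; isomaltase cleavage by Michaelis–Menten kinetics; only
*MAL11* carries a basal expression rate b_T (the isomaltase genes are
expressed from their regulated promoters alone, consistent with their
induction preceding *MAL11*'s). Time is nondimensionalised by isomaltase
turnover and concentrations by the *IMA* induction EC50, fixing K_I = 1.
The repression constraint K_T > K_I encodes that isomaltases are induced
at lower inducer levels than the transporter. The import rate v_T lumps
the extracellular palatinose concentration with the per-transporter
import kinetics; its functional dependence on the extracellular sugar is
left free, so v_T is treated as a parameter.

Assumptions worth keeping in mind: regulator dimerisation and
palatinose binding are fast (quasi-steady), isomaltase and transporter
synthesis respond instantaneously to *p* through their Hill functions,
and dilution by growth is folded into the degradation/turnover rates.

### Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| v_T | palatinose import rate per transporter | 1.0 |
| u_I,max | maximal isomaltase expression | 4.0 |
| u_T,max | maximal regulated *MAL11* expression | 3.0 |
| b_T | basal *MAL11* expression | 0.05 |
| d_T | Mal11 turnover | 1.0 |
| K_T | *MAL11* induction EC50 (units of K_I) | 1.2 |
| K_M | Michaelis constant of cleavage | 1.0 |
| n | Hill number | 3 |
| λ_gal | K_T elevation by galactose | 3.0 |

All rates are in units of the isomaltase turnover rate and all
concentrations in units of K_I. The defaults are frozen as a regression
fixture: they reproduce the three-region topology of the (K_T,
u_I,max/v_T) plane at n ∈ {2, 3, 4}, place the wild type ON in palatinose
(K_T = 1.2) and OFF under galactose (K_T = 3.6), and sit comfortably
above the boundedness threshold (b_T + u_T,max)/d_T = 3.05. The scanned
axes default to K_T ∈ [1.1, 5] and ratio ∈ [1.05, 10]·threshold.

### Steady states, stability and the scan

At steady state I and T are explicit functions of p, so the full
equilibrium problem reduces to one scalar residual
f(p) = v_T T\*(p) − I\*(p)·p/(K_M + p). Roots are bracketed by sign
changes on a log-spaced grid of 10⁴ points spanning [0, p_max] with
p_max = 10·max(K_T, p_balance) (p_balance is where saturated import
balances cleavage), refined by Brent's method, and merged when closer
than 10⁻⁶·p_max. Stability comes from the full 3×3 Jacobian's leading
eigenvalue; eigenvalues with |Re| < 10⁻⁸ are treated as non-hyperbolic
and the 1-D residual's crossing direction is used instead (I and T relax
with strictly negative rates, so the reduced criterion decides the slow
direction). The two-parameter scan exploits that f is affine in u_I,max
at fixed K_T: each K_T column shares one evaluation of the import and
cleavage profiles, brackets for all ratio cells are refined together by
vectorised bisection, and stability uses the Routh–Hurwitz conditions of
the same Jacobian — the scan is therefore exactly the pointwise
classification, only faster (verified cell-by-cell in the tests).

Classification follows the biological convention: cells approach from
low intracellular palatinose, so in the bistable band the low branch is
the attained state (OFF). ON means attained p/K_T > 1.

### The unbounded regime and genotype predictions

Below the ratio threshold (b_T + u_T,max)/d_T import outruns the
saturable cleavage for every large p and palatinose accumulates without
bound; `find_steady_states` labels such parameter sets UNBOUNDED rather
than listing states. A finite stable state can still coexist below the
threshold, so divergence is guaranteed only from initial conditions
beyond the largest finite root — the boundedness tests integrate from
there.

Genotypes map to multiplicative parameter changes: *ima1Δ* scales
u_I,max by 1/6 and *ima5Δ* by 5/6 (a five-fold *IMA1*:*IMA5* transcript
ratio with similar enzyme kinetics), *MAL11-OE* multiplies b_T by 40 (a
strong constitutive promoter), *gal80Δ* pins K_T at its
galactose-elevated value in both conditions, and galactose itself
multiplies K_T by λ_gal. With the frozen defaults, the bounded regime
spans less than a factor two in the ratio axis, so the large *ima1Δ* and
*MAL11-OE* perturbations land below the boundedness threshold. The
scenario layer reports that regime as ON by runaway induction — p grows
past any K_T, which is the model's way of saying the positive feedback
is unconditionally self-reinforcing — while `classify_regulon` itself
still reports UNBOUNDED. This single convention reproduces the full
qualitative genotype panel (WT diauxic; *ima1Δ*, *MAL11-OE* and
*gal80Δ·ima1Δ* non-diauxic; *ima5Δ* and *gal80Δ* still repressed).

The escape threshold (the largest K_T from which lowering the ratio can
reach ON) is found by bisection on K_T with an inner log-spaced ratio
sweep; the inner ON test uses the equivalent criterion that the residual
stays positive on [0, K_T]. With the frozen defaults it is K_T\* ≈ 1.44,
strictly inside the scanned range; its numerical value depends on the
parameter set, so it is reported, not asserted, beyond finiteness.

Hysteresis sweeps carry the state between K_T steps, relaxing it for 400
time units per step (the slowest rates are O(1), so this is deep
equilibration); transitions are read off p/K_T crossing 1.

## Growth-curve phenotyping

Preprocessing subtracts the median OD of the matching blank group (any
blank group, with a warning, when the exact medium has none), applies a
monotone calibration (PCHIP through a measured→corrected table) to undo
the OD–cell-density saturation, and floors OD at 10⁻⁴ before taking
logs. Technical replicates are averaged with their standard deviation
retained.

The specific growth rate µ(t) = d/dt log OD is the analytic derivative
of a penalised cubic smoothing spline fitted to log OD with
generalised-cross-validated penalty. Two numerical choices matter in
practice and are both data-driven:

* **weights** — log-OD noise explodes as the signal approaches the blank
  level, so points are weighted by the inverse variance estimated from a
  rolling median absolute deviation of second differences (second
  differences are trend-free, so growth itself is not mistaken for
  noise);
* **penalty cap** — on curves dominated by a long stationary phase GCV
  occasionally oversmooths away the second growth phase; the chosen
  penalty is located on a λ grid and capped at λ = 50 h⁴ (an equivalent
  bandwidth of roughly 2.7 h, comfortably below the shortest features of
  interest).

A Gaussian-process alternative (squared-exponential kernel,
maximum-likelihood hyperparameters, analytic posterior derivative and
derivative variance) is available through `SmootherConfig(method="gp")`.
The default uncertainty band is a cheap residual-based half-width; a
residual bootstrap (`n_boot > 0`) replaces it when calibrated bands are
needed.

Diauxie is called on µ(t): maxima with prominence ≥ 0.05 h⁻¹, separated
by ≥ 2 h, and reaching ≥ 20 % of max µ (growth phases run at comparable
rates; smaller bumps are noise on a non-growing baseline) qualify as
growth-rate peaks; the series is padded with its minimum so a record
already growing at its first read keeps its full prominence. A curve is
diauxic when the interior minimum between the two most prominent peaks
dips to ≤ 0.5× the smaller peak **and** stays below that level for
≥ 1.5 h — a genuine inter-phase pause is deep and sustained, while a
smoother ringing through a mere step-down between growth rates is
neither. OD_switch is the OD at that minimum; OD1 = OD_switch − OD(0)
and OD2 = OD(final) − OD_switch, so OD1 + OD2 equals the total yield
exactly by construction. Non-diauxic curves put the whole yield in OD1
with OD2 = 0 (a reporting convention of this package; phase yields are
only defined through OD_switch, which is why the yield-vs-concentration
regression uses diauxic wells only by default). Wells with total yield
below 0.01 OD are reported as no-growth.

The exponential window is the maximal contiguous interval around the µ
maximum with µ ≥ 0.9·max µ; the mid-log rate is the mean µ there; the
lag is the time until µ first reaches 0.5·max µ. Yield–concentration
regressions are ordinary least squares (statsmodels) with 95 %
confidence intervals; growth-rate group comparisons use Welch's t-test,
with the degenerate equal-and-constant case defined as t = 0, p = 1.

## The synthetic-data generator

The simulator is the package's ground truth, not a fit to any dataset.
Monod kinetics with per-sugar yields is the minimal structure producing
the observed linear yield–concentration relation: dB/dt = µ(S)·B,
dS/dt = −µ/Y·B, with defaults µ_max = 0.25 h⁻¹ (galactose) and
0.12 h⁻¹ (palatinose), K = 0.01 % w/v, Y = 1 OD per % w/v for both
sugars, B₀ = 0.02 OD, and a 2 h inoculation lag. Sequential mode inserts
a 3 h dead time between sugar-1 exhaustion and phase-2 growth;
regulon-coupled mode instead integrates the regulon model (K_T stepped
down at exhaustion) and starts phase 2 when T crosses 2·b_T/d_T, with
4 h per dimensionless time unit (isomaltase turnover at typical growth
rates is a few hours). Under that coupling the *ima1Δ* parameterisation
induces faster than the wild type, reproducing the observed lag
ordering. An optional reporter (phase-2 expression proxy, 1 h⁻¹ rise)
emulates an isomaltase-GFP fusion.

Rendering samples trajectories every 10 minutes and applies the
measurement model: measured OD = g(B)·e^(σ_m z) + background + ε with
g(B) = B/(1 + 0.25·B), multiplicative σ_m = 0.02, additive σ_a = 0.005
OD and background 0.04 OD; blank wells carry background plus noise only.
The exact inverse of g is written as the calibration table, so
calibrate(od − median blank) recovers B exactly in the noise-free limit.
One master seed expands into per-well substreams (sorted well order),
making equal seeds byte-identical.

What the generator does **not** emulate: ethanol/acetate re-consumption,
single-cell heterogeneity, autofluorescence spectra (background
subtraction stands in for spectral unmixing), plate-position effects,
evaporation, and the gradual (rather than stepwise) repression relief
real cells show. Passing the end-to-end tests therefore demonstrates
that the pipeline recovers truth under this idealised but
realistically noisy measurement model — not that every threshold is
optimal for any particular instrument.

## Problem sizes and reproducibility

Default analysis sizes: 10⁴-point root grids, 60×60 scan grids (the
escape threshold is cross-checked against a 400×400 grid), 60-step
hysteresis paths, 100 seeded plates of 13 wells for the recovery
studies. All randomness flows from a single integer seed through
`numpy.random.SeedSequence` substreams. CSVs are written with fixed
float formatting so reruns are byte-identical.

## Known limitations

* The equation forms and default parameter values are this package's own
  canonical reconstruction; with a different parameter table the
  quantitative outputs (escape threshold, region sizes) shift, though
  the qualitative structure is robust across n = 2–4.
* The unbounded regime is a model artifact of saturable cleavage with
  non-saturable import; real cells are bounded by osmotic and transport
  limits. Interpreting it as "ON by runaway induction" is the only
  consistent reading but extrapolates beyond the model's validity.
* Diauxie-detection thresholds are tuned to be robust at the simulator's
  default noise; real instruments may need different prominence/pause
  settings (all exposed in `DetectionConfig`).
* The growth-rate "shoulder" sometimes seen in fructose–palatinose
  mixtures is not modelled or detected.
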