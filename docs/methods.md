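# Methods

This note documents the models, numerical choices and limitations behind
`respcrit`, in the order a measurement flows through the package.

## Oxygen solubility and unit conversion

All oxygen quantities are interconverted through the partial pressure in
kPa. Air-saturated concentration is the Garcia & Gordon combined fit to
the Benson & Krause data, evaluated in µmol/kg and converted to per-litre
units with the one-atmosphere seawater equation of state
(Millero & Poisson); water vapour pressure is the Benson & Krause
empirical formula in temperature only (the salinity correction is <0.1%
and ignored); the dry-air O₂ mole fraction is fixed at 0.20946 and torr is
treated as identical to mmHg (they differ by 2×10⁻⁷). The solubility
coefficient is β = C_sat / PO₂_airsat with
PO₂_airsat = 0.20946 × (P_baro − p_w); barometric pressure defaults to
760 mmHg, the assumption applied to literature values that do not report
it. Non-standard pressure scales C_sat by the dry-gas ratio
(P − p_w)/(P₀ − p_w). Valid domain: −2–40 °C, 0–100 PSU, 400–800 mmHg;
out-of-range inputs raise naming the offending field. Round-trip
conversions reproduce inputs to 1 part in 10⁹ (property-tested).

## MO₂ extraction

Closed chambers use the slope form of the depletion equation: within each
window the concentration-vs-time least-squares slope replaces the endpoint
difference (identical for two-sample windows, more robust to probe noise
otherwise), and MO₂ = (V_r − V_f)·(−slope)/bw. Integer sample-count
windows share endpoints so their spans tile the trace; summing
MO₂·span·bw then telescopes to the total O₂ removed (conservation is
tested to 1%). Windows with rising O₂ yield MO₂ ≤ 0 and are retained
flagged `suspect` rather than dropped; MO₂ is positive for declining O₂ by
convention. An optional blank (background respiration) constant can be
subtracted; the default is zero.

Flow-through chambers apply the Fick principle per sample with
concentrations in mg/L and report the outflow PO₂. No wash-out
deconvolution is attempted: samples within a configurable horizon
(default 3 chamber residence times, V_r/F_w) of the trace start or of any
step in the inflow concentration are flagged `washout` and left in place.

Intermittent-flow traces are split into contiguous `measure` phases;
each phase with ≥3 samples is fit like a closed window and reports its
slope r²; shorter phases are skipped, not errors. The averaging window is
always a caller decision — source studies do not standardise it, so no
default is imposed.

## SMR/RMR and P_crit estimation

Four baseline-rate estimators mirror the field's practice: the single
lowest normoxic MO₂, the mean of the N lowest, an empirical quantile
(linear interpolation; p = 0.15 default), and the exponentiated intercept
of ln(MO₂) against swimming speed. At least five normoxic values are
required for the order-statistic methods.

The primary P_crit estimator is a broken-stick (segmented) regression:
two least-squares segments constrained to meet at the breakpoint, the
breakpoint chosen by exhaustive search over every interior observed PO₂
and the midpoints of adjacent observed values, ties broken toward lower
PO₂. The continuity constraint matches the trait's definition as an
inflection of one response curve and rules out disjoint pathological fits.
Because the search is discrete, the estimator resolves the breakpoint to
the local candidate spacing; on noiseless piecewise-linear data whose
breakpoint coincides with a candidate it is exact (tested). The series
must contain ≥8 points spanning at least a 4-fold PO₂ range.

Classification uses BIC: a single straight line (2 parameters) against the
two-segment model (4: intercept, two slopes, breakpoint). If the line is
preferred the series is classified `oxyconformer` and no P_crit is
reported — obligate oxyconformers genuinely have none. Fits with
machine-level residuals on both models are treated as tied perfect fits
and resolved toward the simpler model. The conforming segment is not
forced through the origin. Confidence intervals come from a nonparametric
residual bootstrap (opt-in `bootstrap=` argument; 1000 seeded resamples is
the recommended setting — left opt-in so batch parameter-recovery loops
stay fast).

The intersection estimator re-uses the broken-stick split to choose the
conforming points, fits an unconstrained line through them, and intersects
it with the horizontal SMR/RMR level; a non-positive conforming slope is
an error (no intersection exists), and SMR = 0 yields the degenerate
P_crit = 0, flagged. The nonlinear alternative fits
MO₂ = MO₂max·PO₂/(K + PO₂) by multi-start least squares and reports the
PO₂ at a stated fraction of the asymptote (default 0.90, i.e. 9K), with
the fraction recorded in the result — a hyperbola has no breakpoint, so
any "P_crit" from it is definitional, and at the 0.90 default it sits far
above breakpoint-style estimates on typical regulator data. The two kinds
of estimate are not interchangeable and the package makes no attempt to
reconcile them. A K collapsing toward zero (flat data) is flagged.

Rate-of-depletion effects on P_crit are real but unquantified in the
literature; the simulator exposes the depletion rate (via chamber/fish
scaling or a programmed ramp) so users can study them, and no correction
is applied.

## Closed-respirometer CO₂ model

The carbonate system is solved on the NBS pH scale with the constant set
that CO2SYS pairs with that scale: K₀ from Weiss (1974); K₁/K₂ from the
original Mehrbach (1973) fits (natively NBS; verified pK₁ = 6.000,
pK₂ = 9.114 at 25 °C/35 PSU against the published values); K_B from Lyman
(1969); K_W from Millero (1995) converted to NBS via f_H; f_H from
Takahashi (1982); total borate 410.6·S/35 µmol/kg. Hydrogen ion enters
all equilibria as the NBS activity a_H = 10^(−pH); the free proton in the
alkalinity balance is a_H/f_H. Final pCO₂ is sensitive to the constant
choice, so the set is pinned and recorded here rather than configurable.
Note one consequence of the scale convention: at pH 8.0 (NBS) in
equilibrium with 395 µatm at 15 °C/35 PSU the water holds DIC ≈ 1379
µmol/kg — lower than the ~2100 familiar from total-scale calculations,
because NBS pH runs ≈0.13 units above the total scale. Validity domain
0–40 °C and 19–43 PSU; freshwater carbonate systems are out of scope.

TA is defined as HCO₃⁻ + 2CO₃²⁻ + B(OH)₄⁻ + OH⁻ − H⁺; nutrient terms are
zero, consistent with deriving TA from pH and atmospheric equilibrium
alone. The forward direction speciates from (pH, pCO₂); the inverse
solves for pH by Brent's method on the alkalinity residual over pH 2–12
(|ΔTA| < 10⁻⁴ µmol/kg at convergence; no randomness). The two directions
are mutual inverses to 10⁻⁶ relative (tested over a grid), and the
inverse agrees to <0.5% with an independent solver in the test suite that
clears denominators and takes polynomial roots in H instead of iterating.

The accumulation model: for each (starting pH, salinity) cell, speciate
the initial water from the pH at equilibrium with the atmospheric pCO₂
(default 395 µatm); add the respired CO₂ (default 140 µmol/kg — the DIC
produced by depleting O₂ from air saturation to ~6 kPa at RQ 0.85, which
`delta_dic_from_o2` computes as ≈150 µmol/kg at 15 °C/35 PSU, the
scenario's round figure) to DIC with TA held constant; solve the final
state. TA conservation is asserted on every cell. The "µM" of the
scenario is treated as µmol/kg; the ≤2% density difference is far inside
the model's precision. Default grids are pH {7.5…8.5 by 0.25} ×
salinity {20…40 by 5} at 15 °C. The published endpoint readings
correspond to the least-buffered (lowest-salinity) curve of that surface:
~650 µatm at pH 8.5 and ~3500 µatm at pH 7.5, a 5-fold span; the model
reports the full grid so either convention can be read off.

## Trait-database pipeline

Tables are pandas DataFrames; loading validates per row (mandatory
species, P_crit value/unit and trial temperature; vocabulary checks where
method fields are present) and returns a rejection report rather than
raising. Unit harmonisation attaches kPa always (pressure units need no
conditions) and mg/L where temperature and salinity permit, flagging the
rest; it is idempotent. The control filter implements the three inclusion
rules — unfed/post-absorptive, no additional abiotic stressor, acclimation
strictly longer than 2 days — with per-row exclusion reasons; missing
fields exclude with `missing_field`. Climate zones derive from |latitude|
with configurable cutoffs defaulting to the astronomical tropic (23.44°)
and polar (66.56°) circles plus a conventional 35° subtropical bound.

Statistics: one-way fixed-effects ANOVA (polar excluded as historically
too sparse) with pooled-MSE pairwise t-tests Šidák-adjusted
(p_adj = 1 − (1 − p)^m); within-species Student's unpaired t-tests across
respirometry types for species with >2 records per method;
Mann–Whitney U with the tie-corrected normal approximation for the
freshwater/seawater contrast, run on both the kPa and mg/L
representations (group sizes in the hundreds make exact enumeration
unnecessary); and OLS of P_crit (kPa) on salinity, temperature, body mass
and RMR, either all-in or by forward selection with F-to-enter p < 0.05
(direction and threshold configurable and recorded in the output).
Reported per predictor: unstandardised b, standardised β, squared
semipartial sr². Complete-case analysis throughout — no imputation, and
exclusion counts are always reported. A design matrix with condition
number above 10¹⁰ is refused.

## Synthetic data

The metabolic profile is the idealised piecewise abstraction: regulators
hold RMR above P_crit and decline linearly through the origin below it
(the simplest form with MO₂(0) = 0); obligate conformers are proportional
to PO₂ throughout. Facultative metabolic depression below P_crit is not
simulated. Probe noise is multiplicative Gaussian (optode error scales
with signal). The closed-chamber simulator integrates
d[O₂]/dt = −MO₂(PO₂)·bw/(V_r − V_f) with fixed-step RK4 at one tenth of
the sampling interval, stopping at 0.5 kPa or a set duration; oxygen
conservation holds to 0.5% at the default step (tested). A programmed-ramp
mode depletes PO₂ at a set rate instead, and a flush schedule produces
labelled intermittent-flow traces. All generators are deterministic given
their seed, which is recorded in the output metadata.

The trait-database generator draws (salinity, temperature, mass, RMR)
from a Gaussian copula. Mass and RMR marginals are log-normal,
moment-matched to their target mean/SD — their published SDs exceed their
means, which no positive normal variate can achieve — and the latent
correlations are adjusted analytically (normal–log-normal and
log-normal–log-normal attenuation formulas) so the observed variables
carry the target pairwise correlations; an infeasible target matrix
raises with a nearest-PSD suggestion. P_crit follows the linear model
5.689 + 0.047·S − 0.083·T + 1.931·M + 0.001·RMR plus Gaussian noise.
The noise SD is calibrated against the realized covariate draw so the
generated dataset's signal-to-noise matches the target explained variance
(default r² = 0.195): with heavy-tailed log-normal covariates the sample
signal variance of any one draw falls systematically below its
expectation, so calibrating against the population covariance would leave
typical sample r² well under target. Convergence checks on the log-normal
marginals use the population SD implied by the log-scale sample moments,
since the direct sample SD of a CV≈2.6 log-normal converges too slowly to
test at any practical n.

Metadata columns (feeding state, stressor, acclimation, latitude, species
with a rank-skewed abundance so a few workhorse species recur, method
vocabularies at field-realistic frequencies, mixed reporting units) are
filled so every pipeline stage is exercisable; at the default 331 rows
exactly 297 pass the control filter. Two purpose-built fixtures mirror
specific published contrasts: a climate-zone table with zone means
4.92/5.0/5.74/7.9 kPa and SEM-implied SDs, and a freshwater/seawater
table in which freshwater P_crit (kPa) sits 23% below seawater. In the
latter, the freshwater group's mean temperature is solved at run time from
the condition that the two groups' expected mg/L means coincide —
freshwater compilations are cooler on average than reef-dominated marine
ones, and this is the mechanism by which a clear partial-pressure contrast
can vanish on the concentration scale.

## What the synthetic data does and does not show

Passing tests demonstrate that the estimators recover known generating
parameters under the stated noise model and that the pipeline's statistics
behave correctly on data with the published moment/correlation structure.
Real respirometry traces have autocorrelated probe drift, activity bursts
and habituation trends that the white multiplicative noise model does not
emulate; real trait compilations have phylogenetic structure, shared-study
pseudoreplication and non-random missingness that the copula does not
represent. Results on synthetic data therefore validate the computations,
not the biology.

## Problem sizes

Defaults used by the test suite and acceptance checks: 30-point MO₂
series with 5% noise and 200 replicates for parameter recovery; 60 random
instances for the breakpoint-oracle comparison; n = 1159 rows for the
regression-variance check and n = 10⁵ for moment convergence; the CO₂
model runs its full 5×5 grid. These sizes were chosen to estimate each
quantity stably while keeping the whole suite fast enough to run on every
change.
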