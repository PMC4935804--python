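# Methods

## Model

One cell is a deterministic ODE system in molecule numbers (per-minute
rates). Three layers are chained:

1. **Receptor signal.** Each cytokine branch X ∈ {TNFα, IL-1β} receives a
   dimensionless signal TR_X(t): a saturating Hill function of dose,
   φ(d) = d^h/(d^h + K_d^h) with h = 1 and K_d = 0.05 ng/ml (so a 0.1 ng/ml
   pulse still activates a first response), constant during a pulse and
   decaying as exp(−t/τ_w), τ_w = 2 min, after washout. Receptor levels are
   constant: surface receptor availability is unchanged by pulsing, so the
   receptor is a static gain, and no trafficking is modelled.

2. **IKKK/A20 transduction module.** Each branch owns a three-state kinase
   pool (neutral → active → inactive → neutral) standing in for the
   receptor-proximal network (TRAF/RIP/TAK1 and friends):

       dIKKKa_X/dt = ka_X · TR_X · IKKKn_X · kA20_X/(kA20_X + A20) − ki · IKKKa_X
       dIKKKi_X/dt = ki · IKKKa_X − m3 · IKKKi_X

   A20 inhibits activation divisively (the simplest saturating form; a
   subtractive variant was not pursued). The two branches share the A20
   pool but differ in their half-inhibition constants, with
   kA20_T ≪ kA20_I: the TNFα branch is strongly A20-inhibited, the IL-1β
   branch only weakly — this single asymmetry carries the TNFα/IL-1β
   cross-talk phenomenology. The branches keep separate kinase pools; a
   partially shared pool would be an alternative reading of the cross-talk
   data and is not implemented.

3. **IKK and the NF-κB/IκBα core.** IKK cycles neutral → active →
   inactive → neutral with activation kact·IKKn·S²/(sIKKK² + S²),
   S = IKKKa_T + IKKKa_I (Hill coefficient 2), inactivation k1 and
   recycling k4. Active IKK degrades free and complexed IκBα; free NF-κB
   enters the nucleus, drives Hill transcription (coefficient 2) of the
   IκBα and A20 genes, is re-captured by newly made IκBα and exported in
   the complex. Per-branch IKKK totals, the IKK total and total NF-κB are
   conserved exactly by construction (neutral forms are reconstructed from
   totals).

State: 15 species (4 branch-kinase states, 2 IKK states, free/complexed
NF-κB and IκBα in both compartments, two mRNAs, A20 protein).

## Parameters and calibration

The transduction-module structure fixes the parameter names; the numbers
are not published. All nominal rates in `ModelParameters` were calibrated
in-repo, in two stages, against the printed summary statistics only:

* single 5-min 10 ng/ml TNFα pulse: total-IκBα trough at 20 ± 5 min,
  resynthesis peak at 125 ± 15 min, return to within 5 % of baseline by
  300 min, resting nuclear NF-κB below the 15 % responder threshold;
* continuous TNFα: out-of-phase NF-κB/IκBα oscillations with ~100-min
  trough spacing over 800 min;
* paired 5-min pulses: second-pulse response thresholds θ(Δ) positioned so
  that a single truncated-normal IKKK distribution (μ = 10⁶ molecules)
  reproduces responder fractions of 93/70/30/5 % at Δ = 100/70/60/50 min,
  ~40 % at Δ = 50 min when σ is widened to 0.9 μ, and the cross-talk
  fractions (TNFα→IL-1β ≈ 95 %, IL-1β→IL-1β ≈ 75 %, IL-1β→TNFα ≈ 54 % at
  Δ = 60 min).

Stage one was a stochastic search over the core-feedback rates against the
single-pulse and oscillation features; stage two jointly refined the
transduction-module rates (ka, ki, m3, sIKKK, kA20, A20 turnover) against
the threshold quantiles while guarding the stage-one features. The mean
total IKKK of 10⁶ molecules per branch anchors the absolute scale; IKK and
NF-κB totals (2·10⁵ and 10⁵) are set relative to it.

The calibrated model places the single-pulse trough at 17 min and the
resynthesis peak at 111 min — inside the measured windows, though the peak
sits at the early edge; pushing it later trades directly against the
50-min-interval responder fraction, and the joint optimum favours the
fraction curve.

Units caveat: "molecules" are effective copy numbers on the IKKK-anchored
scale, not literally counted molecules; only ratios and fractions are
compared with data.

## Quantile calibration

`calibrate_ikkk_distribution` finds, for each probed interval Δ, the
minimal branch-IKKK total θ(Δ) for which a cell responds to the second
pulse (geometric bisection to 0.1 %, responder rule below), then fits σ of
the zero-truncated Normal(μ, σ) minimising the squared error between
P(IKKK > θ(Δ)) and the measured fractions. With the nominal parameters the
fit gives σ ≈ 0.18 μ. Lognormal per-cell distributions are available as an
alternative family; the data do not discriminate between them.

Calibrated populations draw both branch totals independently from the
fitted distribution. The headline fit only constrains the TNFα branch, but
the IL-1β pulsing fractions (75 % response to paired IL-1β pulses) require
the same kind of spread in the IL-1β branch, so both are drawn from the
same distribution. Draws are quantile-stratified by default (one draw per
probability slice, jittered within the slice, order shuffled, seeded):
this mirrors the quantile construction used in calibration and removes
binomial sampling noise from the 300-cell fraction estimates, so the
reported fractions reflect the calibrated response curve rather than the
sampling luck of one 300-cell draw. Plain iid sampling is the default for
generic `PopulationSpec` use and remains available everywhere.

## Responder rules

* **Model rule** (`classify_responder_model`): net peak nuclear NF-κB
  within 45 min of the pulse, relative to the level at stimulation,
  strictly greater than 15 % of the cell's total NF-κB. The rule operates
  on fractions of total, so it is invariant to rescaling the molecule unit.
* **Trace rule** (`classify_responder_trace`): least-squares slope of the
  total-IκBα reporter over [pulse + 5, pulse + 25] min non-positive
  (degradation visible by 20 min after the pulse). The printed rule names
  only "the gradient at the time of stimulation"; the 5-min lag and 20-min
  window are this package's concrete reading and are configurable.
* **N/T rule** (`classify_responder_nt`): the model rule applied to
  measured-style nuclear/total reporter ratios.

The two trace-level rules have different effective thresholds near the
refractory boundary (a cell just below the model-rule threshold can still
show a weakly negative IκBα slope), so cross-rule comparisons are only
made on well-separated cells.

## Noise models

* **Extrinsic**: per-cell parameter values drawn once (truncated normal,
  σ = 0.3 μ in the all-parameter mode; Hill exponents and dose constants
  excluded) and fixed for the cell's lifetime — imprinted states.
  Re-stimulating the same cell reproduces its responses exactly, provided
  it has fully returned to rest (below).
* **Intrinsic**: the two feedback genes switch ON/OFF as telegraph
  processes — ON-switch hazard `switch_on` · (NF-κB Hill term), OFF-switch
  hazard `switch_off` constant (defaults 0.2 and 0.1 /min: ~10-min
  switching, resting ON-probability set by the resting NF-κB level).
  While ON, transcription runs at the Hill rate divided by the stationary
  ON-occupancy, so the fast-switching limit and the ensemble mean
  reproduce the deterministic rates at every activity level. Species are
  integrated deterministically between switches; switch times come from
  integrated-hazard inversion (next-reaction scheme), reproducible per
  cell seed. Switch rates are not published; the defaults are exposed.

**Equilibrated pulse pairs.** Two pulse pairs separated by a long gap
discriminate the noise models: extrinsic cells repeat their second-pulse
call exactly; intrinsic cells do not (the measured reference is 3 of 79
cells discordant; the package reports the discordant fraction and leaves
hypothesis testing to the user). The determinism statement requires the
cell to be fully at rest when the second pair starts. The experimental
design used a 4-h gap; in this model the slow tail of the IκBα overshoot
(~3 % above baseline at 4 h) shifts the second-pair threshold slightly and
flips a few percent of borderline calls, so the helper enforces its
stated precondition numerically (nuclear fraction and total IκBα within
0.5 % of rest) and defaults to an 8-h gap, where extrinsic discordance is
exactly zero out of 300 cells.

## Trace statistics

Trough detection uses local minima with prominence ≥ 5 % of the trace
range and ≥ 40-min separation. For oscillation statistics the early
synchronous-degradation phase (t ≤ 35 min) is discarded — the same cut the
power-spectrum analysis uses — so the stimulation transient does not enter
the spacing statistics. Dominant periods come from the zero-padded (4×)
discrete-Fourier power spectrum of the mean-removed, linearly detrended
trace, restricted to 40–300 min. In heterogeneous populations a minority
of cells damp after a few cycles; their spectra are dominated by the decay
envelope and report long pseudo-periods, so period summaries are made over
cells with at least three detected troughs.

Responder clustering is 2-means (10 restarts, fixed seed) on the
renormalized IκBα segment over the 40 min after the pulse, with the
deeper-dipping cluster labelled responding; the clustering method used for
the published analysis is not named, and 2-means is this package's choice.
Sub-trajectory PCA z-scores each pooled 140-min segment per feature before
projection.

## Sensitivity analysis

Latin hypercube over ±50 % around each nominal value, k slices per
parameter, one uniform draw per slice with slice order permuted per
parameter (the Latin property is checked by construction). Outputs per
sample: second-pulse responder indicator, net amplitude, nuclear-NF-κB AUC
after the second pulse, and (optionally) the continuous-stimulation
oscillation period. Spearman ρ per parameter × output with average ranks
for ties; binary outputs use the same rank correlation (rank-biserial
equivalent); zero-variance outputs are flagged and reported as ρ = 0.
Damped cells have no period and are excluded pairwise. The test suite runs
the full k = 1000 design (the compiled right-hand side makes this cheap);
one-at-a-time dynamic sensitivity is out of scope.

## Synthetic data

Generators corrupt model observables with multiplicative lognormal noise
(default s.d. 0.05, unit mean — microscopy intensity noise is
scale-dependent) and a slow linear drift (default −0.02 %/min) on the
IκBα intensity only, the N/T ratio being self-normalizing. Label-mode
traces splice responder/non-responder template responses from
nominal-parameter model runs at branch-IKKK totals of 2.5 μ and 0.6 μ —
both respond fully to the first pulse, only the former to later pulses.
Daughter pairs share their IKKK draw; a controlled fraction of pairs
diverges, by default to the opposite side of the second-pulse response
threshold (with a 10 % exclusion margin so all classifiers agree on the
class), so measured concordance is 1 − divergence probability, matching
the observed ~85 % over 56 pairs at a divergence probability of 0.15; an
independent-redraw mode provides the independence reference. Panel counts
are negative-binomial around baseline · (1 + coefficient · condition
activity) with size parameter 100 (~10 % biological CV), flat housekeeping
and positive controls, near-zero negative controls.

What passing the recovery tests shows: the analysis stages invert the
generators' known constructions under realistic noise. What it does not
show: robustness to segmentation artefacts, photobleaching nonlinearity,
cell movement or division during imaging, or any feature of real data the
generators do not emulate.

## Expression utilities

Panel normalization follows the standard nCounter-style recipe: per-sample
scaling by the positive-control geometric-mean ratio, stringent background
subtraction (mean + 2 s.d. of negative controls, floored at zero), then
housekeeping geometric-mean scaling; geometric means are computed on
counts + 0.5 to tolerate zeros, and the positive-control step precedes the
housekeeping step as a fixed convention. Fold changes are medians of log2
ratios over replicate pairings against the untreated condition;
differential-expression testing (moderated t-statistics, FDR control) is
deliberately left to standard packages. Activity correlation is Pearson,
per gene, between linear fold changes and integrated nuclear NF-κB across
conditions.

## Numerical choices

LSODA integration piecewise between pulse boundaries (discontinuities are
never stepped over), rtol 1e-7, atol 1e-4 molecules, output step 1 min;
the right-hand side is JIT-compiled. The resting steady state solves the
nine-species core fixed point (pre-equilibration plus Newton polish); the
kinase cycles are exactly off at rest, so the steady state is reused
across cells that differ only in their IKKK totals. Conservation is
checked on every trajectory at relative tolerance 1e-6. Threshold
bisection brackets [0.01 μ, 30 μ]: above ~30 μ the first response is so
strong that its A20/baseline after-effects make the second-pulse response
non-monotone in the total, so the bracket stays below that regime.
Problem sizes: 300-cell populations for fraction estimates (matching the
reported simulations), 100 cells for the continuous-stimulation period
statistics, k = 1000 for sensitivity.

## Known limitations

* The IκBα resynthesis peak sits at 111 min against the measured 125 min;
  the trough at 17 min against 20 min.
* TNFα→IL-1β cross-talk at a 60-min interval yields ~93 % responders
  against the measured 95 %: the failing cells are pool-limited in the
  IL-1β branch while riding the elevated nuclear baseline of their first
  response, and this residual is insensitive to the IL-1β-branch rates.
* Oscillations in heterogeneous populations are sustained in most but not
  all cells; damped cells bias spectral period estimates and are handled
  by the three-trough rule above.
* No receptor trafficking, MAP-kinase/IRF branches, spatial effects, or
  IκBε/IκBβ isoforms; the IL-1β neutralizing-antibody step is represented
  by protocol washout only.
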