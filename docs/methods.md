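# Methods

## Model structure

Both models are deterministic mass-action ODE systems integrated in
seconds (grids are specified in minutes).  Species are molar
concentrations; every rate law is one of three kinds: elementary
bimolecular (k·[A]·[B]), Michaelis-type saturable supply
(vmax·[S]/(km+[S]), used only for the G6PD NADPH-regeneration step R8),
and first-order transport (k·A·[S], used for membrane uptake R7 and the
enzymatic SOD term).  The NOX-catalysed NADPH/O2 reaction (cellular R4)
carries an optional dimensionless saturating modulation
[In_Dox_q]/([In_Dox_q]+K), K = 1e-7 M, encoding the observation that
doxorubicin activates NOX; a "table-literal" mode without the modulation
is selectable per scenario.

The cell-free network has 9 state variables (CPR_red, CPR_ox, Dox_q,
Dox_sq, NADPH, NADP, O2, O2•−, H2O2) and reactions R1–R6; the cellular
network has 10 (extracellular and intracellular quinone are distinct,
plus intracellular semiquinone) and reactions R1–R8.  k2 is tied to k1
under every construction path.  All constants and initial conditions are
shipped as commented YAML under `src/doxcycle/data/` and are the
published table values; EU3-Sens values are produced by fold-change
scaling of EU1-Res values, with the multipliers derived from the printed
pairs so both representations agree to machine precision.

## Oxygen bookkeeping in dismutation

Superoxide dismutation chemically returns half an O2 per O2•− pair.  In
the cell-free network the *spontaneous* dismutation R6 is modelled as a
terminal sink (2 O2•− → H2O2, no O2 return).  This is a deliberate
kinetic simplification: the NADPH-driven metabolic switch requires that
abundant NADPH can competitively exhaust the assay's O2 pool, and with
half-return the 270 µM O2 pool can never be depleted by 500 µM NADPH, so
no reductive conversion would ever occur.  The *enzymatic* SOD term (and
the cellular R6, which lumps SOD1 activity) does return O2
(O2•− → ½H2O2 + ½O2): SOD-dependent O2 regeneration is precisely the
mechanism by which SOD restores redox cycling at high NADPH, and the
model reproduces that restoration.

## Uptake and volume coupling

Doxorubicin uptake is first-order in the extracellular concentration
with rate constant k7 (cm/s) times the aggregate surface factor
A = 10⁻³ L·cm⁻³ × 6.15×10⁻⁶ cm² × 10⁹ cells/L = 6.15 — the depletion
rate of the *medium* concentration, which is what the extracellular-
depletion data used to fit k7 measure.  The cytosol occupies a volume
fraction ρ of the culture (default 10⁻³: 10⁹ cells/L at ~1 pL per
lymphoblast), so the intracellular concentration gains the same molar
flux 1/ρ-fold: d[In]/dt = +k7·A·[Ex]/ρ, d[Ex]/dt = −k7·A·[Ex].  The
conserved drug total is therefore Ex + ρ·(In_q + In_sq).  With ρ = 1 the
intracellular quinone would stay in the low nM range, NADPH would be
numerically untouched and every pharmacological intervention would be
inert; concentrative uptake is also the well-documented behaviour of
doxorubicin in cells.  ρ is a scenario field.  A hook exists for a
saturable (carrier-mediated) uptake component and for time-varying
permeability; both ship disabled because their published functional
forms are not available.  The 100 nM condition uses a 10× higher
permeability constant, as tabulated.

Intracellular O2 is dynamic by default (initial 1.5×10⁻⁹ M, the
tabulated estimate for leukemia cells); an oxygen-clamp flag holds it at
that value.

## Parameter fitting

The cost is U = Σ_j Σ_k (y_exp(t_k) − y_model(t_k))², optionally after
max-normalizing each series (data and prediction alike), which makes U
invariant to positive rescaling of a dataset.  Each unknown constant is
fitted alone — the study design fits each to a dataset from a different
experimental condition — by deterministic bounded scalar minimisation
(scipy's golden-section/parabolic `bounded` method) in log10 parameter
space, because the constants span decades.  Convergence is a relative
parameter change below 10⁻⁶; bounds default to [10⁻³, 10³]× the initial
guess; the default guess is one decade above the tabulated scale, so
recovery tests start 10× off the truth.  Stages: cell-free k1 (redox-
cycling dataset, 100 µM NADPH), k4 (reductive conversion, 500 µM), k5
(SOD condition); cellular k7 (raw extracellular depletion, EU1-Res
10 µM), then k8 (max-normalized NADPH depletion).  Fitted values are
carried into later stages; EU3-Sens is never fitted, only fold-scaled.

## Synthetic data

The generator integrates a scenario's model on the measurement grid
(11 points 0–20 min cell-free, 7 points 0–60 min cellular), maps it to
plate-reader-style observables (max-normalized quinone and NADPH
cell-free; quinone, NADPH fraction, cumulative superoxide signal and
extracellular doxorubicin cellular) and adds seeded additive Gaussian
noise, σ expressed as a fraction of each series' maximum (default 0.02,
3 replicates — matching triplicate assays with a few-percent error).
Normalized cell-free values are clipped to [0, 1.05] and negatives to 0,
as absorbance readings would be; clipped points are counted.  The
superoxide observable is the running time-integral of the two
superoxide-producing rates (R3 + R4), emulating an irreversibly oxidised
turn-on dye read every 10 min, not the instantaneous O2•− concentration.
What the generator does *not* emulate: instrument drift, well effects,
proportional (signal-dependent) noise, and biological replicate
variability beyond additive noise — so passing recovery tests shows
self-consistency of the fitting machinery under the stated noise model,
not robustness to real assay artefacts.

## Sensitivity and flux analyses

Normalized sensitivity coefficients use the central difference
S_i = [O(x(1+δ)) − O(x(1−δ))]/O(x)/(2δ) with δ = 0.10, at the 60-min
endpoint of three readouts (quinone accumulation, absolute NADPH
depletion, cumulative superoxide production), on the EU1-Res 10 µM model
by default.  Readouts with ~zero baseline are flagged undefined rather
than reported.  Fluxes are trapezoidal time-integrals of a reaction rate
along the trajectory (semiquinone formation = R1; NADPH-dependent
superoxide = R4) over the 60-min treatment window, evaluated on a
241-point grid.  The metabolic-mode classifier calls a trajectory
reductive conversion when the quinone loss 1 − q(end)/max(q) exceeds
θ = 0.2 (a package convention; the source classifies qualitatively), and
is invariant to uniform concentration rescaling.

## Numerical choices

LSODA with rtol 10⁻⁸, atol 10⁻¹⁴ M (species span ~10⁻¹¹–10⁻⁴ M), with a
BDF fallback for the extreme trial constants an optimizer may visit.
Solutions are reported exactly at grid points.  Negative concentrations
from integrator overshoot are clamped to zero in rate evaluation only
(tolerance 10⁻¹² M); the state is never modified.  The stoichiometry
matrix is float-valued: the per-encounter SOD stoichiometry
(O2•− → ½H2O2 + ½O2) and the 1/ρ uptake coupling are non-integer; all
R1–R8 entries are integers.  Problem sizes throughout (241-point flux
grids, 20-seed Monte-Carlo recovery, 60 s RK4 oracle horizon) were
chosen as the smallest that resolve the quantities they measure.

## Known limitations

* **Cellular directional claims.**  With the tabulated constants the
  G6PD supply r8 = k8·[NADP]/(k9+[NADP]) (k8 = 1.8 µM/s, k9 = 57 µM)
  re-equilibrates NADPH at under ~10% depletion against any demand the
  network can generate: uptake-driven CPR demand is ≤ ~7×10⁻⁸ M/s and
  NOX demand ≤ k4·[NADPH]·[O2] ≈ 2×10⁻⁹ M/s at 1.5 nM O2.  NADPH can
  therefore never crash far enough to throttle the CPR cycle
  (k2·[NADPH] ≫ k1·[In_Dox_q] always), and three reported cell
  behaviours do not emerge under any shipped option combination: the
  quinone-accumulation reversal (resistant line higher) at 10 µM, a
  DHEA-induced reduction of semiquinone flux at 10 µM, and DHEA-induced
  superoxide reduction at 100 nM.  The corresponding assertions are kept
  in the test suite and fail with a report of the measured values.  The
  behaviours that do emerge: the full cell-free switch, the 100 nM
  quinone ordering and early-peak shape, larger NADPH depletion and
  lower superoxide in the resistant line at 10 µM, DHEA semiquinone
  neutrality at 100 nM, and DHEA superoxide reduction at 10 µM that is
  strongest in the NADPH-poor resistant line.
* **k5 identifiability.**  The superoxide→quinone flux is production-
  limited (superoxide consumption is dominated by that branch), so k5
  cancels out of the realised flux and the SOD-condition time courses
  are insensitive to it over two decades.  Noiseless refits recover it
  through the residual microscopic gradient; under any measurable noise
  it is unconstrained.
* **Small cellular signals.**  Extracellular depletion is ~2.4% and
  NADPH depletion ~6% over the hour, so at 2% replicate noise k7 and k8
  recover only to order of magnitude (medians ~30% and ~22%).
* Scope: cytosolic bioactivation only — no mitochondrial/NADH pathway,
  no nuclear compartment, no glutathione detoxification, no efflux
  transport, and no quantitative viability link.
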