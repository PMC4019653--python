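# Methods

## The model

`cdkcycle` implements a single-compartment, mass-action ODE model of
mammalian cell-cycle regulation with 25 state variables and 103 kinetic
rate constants.  It merges two classical layers:

* an **entry block** — growth-signal early/delayed response genes
  (ERG/DRG), cyclin D:Cdk4/6 with CKI binding, an Rb phosphorylation
  cascade (hypo-, mono- and hyper-phosphorylated Rb) and an explicit
  E2F/Rb binding equilibrium — giving a mechanistic restriction point
  rather than an algebraic switch; and
* a **mitotic engine** — cyclins E, A and B, the CKI Kip1,
  Wee1/Cdc25 control of CycB:Cdk1, the APC/C activators Cdh1 and Cdc20
  (with an intermediary enzyme IEP delaying Cdc20 activation), and a
  shared G2 transcription factor (TFAB) for the mitotic cyclins.

Structural features that distinguish this model from its ancestors, all
motivated by dense cytometry-derived expression profiles of cyclin A2,
cyclin B1 and PHH3:

1. **Cdh1-mediated cyclin A degradation.**  APC/C-Cdh1 degrades cyclin A
   strongly during G1 (`k_da_h1`), so detectable cyclin A is delayed
   until Cdh1 switches off near the G1/S boundary (~21% of the cycle),
   even though E2F-driven transcription starts earlier.
2. **Autocatalytic E2F with APC/C-mediated clearance.**  E2F synthesis
   is autocatalytic (`k_se2f`, softly saturating at `J_se2f`), producing
   the accelerating S/G2 rise of both mitotic cyclins.  Cyclin A/Cdk
   (weakly, `k_pe2f_a`) and CycB:Cdk1 (strongly, `k_pe2f_b`)
   phosphorylate E2F; phospho-E2F is degraded by Cdc20 and Cdh1
   (`k_de2f_20`, `k_de2f_h1`).  This clearance resets E2F to a
   reproducible low level at the end of every cycle and is required for
   stable repetitive cycling.
3. **E2F-regulated cyclin B (and A) transcription** (`k_sb_e2f`,
   `k_sa_e2f`) — the source of the nonlinear primary rise of cyclin B
   through S phase.
4. **Cyclin A/Cdk-driven Wee1 inactivation** (`k_iw_a`).  The mitotic
   trigger is the late-G2 crossing of cyclin A/Cdk activity through the
   Wee1 switch threshold (`k_aw / k_iw_a`); once a little CycB:Cdk1
   activity escapes, the Cdc25 positive feedback (`k_a25_b`, `k_25_b`)
   ignites and activity rises 10→90% in under 5% of the cycle.  A weaker
   retained CycB:Cdk1 term on Wee1 (`k_iw_b`) stabilizes the mitotic
   state while cyclin A is being destroyed; the *trigger* is cyclin
   A/Cdk alone.
5. **Cyclin A/Cdk-activated G2 transcription factor (TFAB)** shared by
   cyclins A and B (`k_atf`; inactivated at mitotic entry by active
   CycB:Cdk1, `k_itf_b`), producing the biphasic S-versus-G2 synthesis
   rates, with a larger relative G2 boost for cyclin B.
6. **CycB:Cdk1-proportional cyclin B synthesis through mitosis**
   (`k_sb_b`), which, together with a slower Cdc20-mediated degradation
   for cyclin B than for cyclin A (`k_db_20` ≪ `k_da_20`), staggers the
   mitotic degradations: total cyclin A reaches half-peak before total
   cyclin B in every cycle.
7. **Two cyclin A pools.**  Synthesis is split between CycA:Cdk2 and
   CycA:Cdk1 with a fixed fraction `cyclinA_cdk2_synthesis_fraction`
   (default 0.8, encoding the preferential binding of cyclin A to Cdk2;
   the exact proportion is a structural option, not a fitted constant).
   Both pools act in unison everywhere cyclin A/Cdk activity appears;
   neither is subject to Wee1/Cdc25 control or (for the Cdk2 pool beyond
   CKI binding) inhibitory phosphorylation.

Activity switches (Wee1, Cdc25, Cdh1, Cdc20 activation, IEP, TFAB) use
Michaelis–Menten interconversion between active and inactive forms with
small saturation constants — the dynamic counterpart of the
Goldbeter–Koshland zero-order ultrasensitive switch, whose closed-form
steady state is exposed as `goldbeter_koshland`.

## Units and time base

Concentrations are in arbitrary units; time is expressed as a fraction
of the total cell-cycle time Tc, and the default parameterization is
scaled so that the wild-type limit cycle has period 1.0.  With a Tc of
~30 h (plausible for slowly cycling K562 cultures, whose G1 is ~21% of
Tc, i.e. ~6 h), `to_real_time` converts cycle fractions to hours.  Rate
constants are therefore "per unit Tc"; only time scales, not absolute
concentrations, are meaningful.

## Simulation protocol

Integration uses a stiff solver (LSODA via `scipy.integrate.solve_ivp`),
default tolerances rtol 1e-8 / atol 1e-10; the vector field is JIT
compiled with numba when available (a pure-Python fallback is identical).
Repeated cycling follows an event protocol: a **division** is the
downward crossing of active CycB:Cdk1 through 10% of its running peak
after the peak (located by linear interpolation on dense output); at
each division the G1 entry variables (DRG and both cyclin D pools) are
reset to their start-of-cycle values, and integration continues.  Mass
and growth are implicit: the reset protocol plays the role of division.
The packaged initial state is a point on the converged limit cycle
(taken at a division event), so cycle 1 already reproduces the
asymptotic cycle; period and cyclin B amplitude drift between successive
cycles is below 0.1%.

Division detection is armed only after activity rises appreciably above
its start-of-cycle residual, so the post-mitotic tail of the previous
cycle is never mistaken for a new division.  If no division occurs
within a safety horizon (3 nominal periods by default; knockout
experiments use 8) a `NonCyclingError` is raised, which the calibration
layer converts to a fixed penalty cost (1e6) and the experiments layer
converts to a `stalled` report flag.

## Calibration of the default constants

The packaged constants were calibrated manually and iteratively (no
automated fit), targeting the programmed-expression features of the
profiles: cyclin A detectable (>1% of peak) only after ~21% of the
period; cyclin B onset earlier than cyclin A; biphasic rises with a
steeper G2 phase; CycB:Cdk1 activation onset in the final 5% of the
cycle with a 10→90% rise under 5% of the period; cyclin A half-decay
preceding cyclin B's; stable repetitive cycling; and surviving cyclin D
and D+E deletions with lengthened G1.  On the default cycle these
measure: cyclin A onset 21.7%, cyclin B onset 19.0%, activation onset
96.2%, rise 2.8%, half-decays 97.7% vs 98.6%.

## Observables and normalization

Measured channels are totals (antibodies do not discriminate bound/free
or active/inactive): total cyclin A sums CycA:Cdk2 + CycA:Cdk1 +
CKI-bound cyclin A; total cyclin B is the CycB pool (active plus
Tyr15-phosphorylated).  Model outputs are normalized to [0, 1] per
channel per cycle before comparison or plotting.  PHH3 is a *timing*
proxy for CycB:Cdk1 activation: only the onset time (default threshold
0.5 of the normalized activity) is compared, never the curve shape,
since histone H3 phosphorylation persists after cyclin B degradation.
"Detectable expression" is 1% of the per-cycle maximum — below
cytometric noise floors and robust to solver tolerance.  Onset detection
searches from the channel minimum, so a decaying residual inherited
across a division is not misread as expression onset.

## Synthetic reference data

The generator reproduces the qualitative structure of the cytometry
profiles on a uniform cycle-fraction grid (default 501 points):
piecewise backbones with phase boundaries G1/S = 0.21 (measured), G2/M
= 0.97 (mitosis occupies the final ~3% of the cycle) and S/G2 = 0.72 (a
configurable placeholder — the true boundary is not recoverable from the
profiles; the value makes S longer than G2, as is typical of transformed
lines).  Cyclin B1's onset leads cyclin A2's by 0.05 Tc (the profiles
show "earlier" without a number).  Channel values at detectable onset
are 2% of maximum, just above the 1% detection floor.  Decays are
exponential, cyclin A2's beginning just after G2/M and reaching
half-peak before cyclin B1's decay begins; the exact decay curvature is
not data-constrained.  Noise is additive Gaussian truncated at zero
(default sd 0.02 of the normalized range), from a seeded generator; a
shape-clause checker asserts every qualitative feature on the noiseless
backbone for any valid boundaries.  What the generator does *not*
emulate: cell-to-cell population variability, instrument-specific
spectral overlap, the skewed noise of low-expression bins, or raw
per-cell event data — so tests passing against it validate the model's
programmed-expression logic, not cytometric measurement physics.

`generate_from_model` produces datasets from the model itself (for
parameter-recovery benchmarks): normalized totals on a uniform grid, a
thresholded onset step for PHH3, a DNA ramp synthesized between the
cyclin A onset and the nominal S/G2 boundary, plus the same noise model.

## Calibration machinery

The cost is a weighted sum: mean squared error of the normalized cyclin
A and B channels on the data grid (weights 1, 1) plus the squared
mitotic-onset difference (weight 10 — timing errors in squared
cycle-fraction units are numerically small and would otherwise be
ignored).  Searches run in log10 space within multiplicative bounds
(default ×/÷10) around the start, optionally restricted to the most
sensitive 10% or 30% of the constants; sensitivity is one-at-a-time
central difference of the cost at ±10%.  A multiplicative perturbation
of a zero-valued constant is a no-op, so dormant constants score exactly
zero and rank last.

Optimizers: simulated annealing (Metropolis walk, geometric cooling and
proposal-scale annealing), a generational GA (tournament selection,
blend crossover, elitism), and SRES — a (20, 140) evolution strategy
with log-normal self-adaptation and stochastic ranking (Pf = 0.45).  The
SRES population is seeded at the incumbent parameter set and initialized
tightly around it (σ ≈ 1/16 of the box in log10), because the intended
use is budget-limited refinement of a working parameterization, not a
blind global restart.  All optimizers finish with a deterministic
coordinate-descent polish (20% of the evaluation budget, walking each
coordinate under a shrinking trust radius).  A master seed drives every
stochastic component; identical configuration gives bit-identical
results.

Two recovery benchmarks probe the stack.  Single-parameter recovery is
well-posed: perturbing any one top-10%-sensitivity constant by ×1.5,
generating noiseless data from the perturbed model, and refitting only
that constant recovers it to within a few percent.  Joint recovery of
the five top-ranked constants from 2%-noise data, searching the full
top-10% subspace, is instead **identifiability-limited**: the top-ranked
constants include switch-threshold pairs that act through their ratio
(`k_aw`/`k_iw_a` set the Wee1 threshold; `k_i25`/`k_a25_b` the Cdc25
collapse point) and mitotic-exit constants with in-subspace compensators
(`k_a20`/`k_iie`), so the noisy cost has near-flat valleys through the
generating values.  Empirically, fits reach the noise floor of the cost
(within ~1% of the cost evaluated at the generating parameters) with
individual constants displaced 30–60%, and tripling the evaluation
budget does not change this — the displaced minimum is a property of the
noise realization and the flat directions (classic sloppy-model
behavior), not of the optimizer.  Parameter recovery claims from
profile-shaped data should therefore be made per identifiable
combination, not per constant.

## In-silico knockouts

Knockout = zeroing the targeted synthesis constants (`k_sd` for cyclin
D; `k_se` and `k_se_basal` for cyclin E), never removing species.
Without cyclin D, Rb phosphorylation must wait for the slower cyclin
E-driven feedback (basal cyclin E synthesis → partial Rb phosphorylation
→ E2F release → more cyclin E), roughly tripling G1; without D and E,
only basal E2F synthesis overflowing the Rb pool and the E2F-driven
cyclin A pressure on Cdh1 remain, extending G1 to beyond one wild-type
period.  Both knockouts still complete cycles; the committed period
(period − G1) contracts relative to wild type, partially offsetting the
G1 lengthening.  G1 is measured from the division event to detectable
total cyclin A (1% of per-cycle max) — a surrogate for the G1/S DNA
boundary the model does not represent — and knockout durations are
reported as fractions of the wild-type period (WT cycle time ≡ 1).

## Numerical choices and degenerate inputs

* Event location: first crossing by linear interpolation between dense
  output points.
* States are clamped at zero after integration (solver undershoot is
  bounded by atol); the vector field keeps the nonnegative orthant
  forward-invariant by construction.
* A zero-length integration span returns the initial state unchanged;
  constant series cannot be normalized (degenerate-range error); an
  all-zero activity channel yields a distinct "no onset" result rather
  than an error.
* Conserved quantities: the Rb moiety (Rb + pRb + ppRb + E2F:Rb) has no
  synthesis or degradation and is conserved along trajectories to
  machine precision; active pools (CycB:Cdk1, Cdc20) never exceed their
  totals.

## Problem sizes used by the shipped analyses

The analysis drivers use three-cycle wild-type runs, 501-point datasets,
single-cycle cost evaluations at rtol 1e-6, sensitivity ranking over all
103 constants (207 simulations), and SRES budgets of 2000 evaluations
per seed — sizes chosen so a full analysis pass completes in minutes on
a laptop while leaving every qualitative conclusion unchanged at larger
sizes.

## Known limitations

* The spindle-assembly checkpoint is not modeled; the staggered cyclin
  degradations arise solely from continued cyclin B synthesis and the
  slower Cdc20-mediated degradation of cyclin B.
* Absolute concentrations are arbitrary; only time scales are
  calibrated.
* Cyclin E dynamics are inherited from the ancestral models and are not
  fitted to data (real K562 cyclin E behaves differently from primary
  cells); the entry block is "highly stylized" signalling.
* The S/G2 boundary of the synthetic data (0.72) is a placeholder, not a
  measured value.
* Single-cell variability is not represented: the model simulates a
  typical (median) cell.
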