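# Methods

## Model structure and assumptions

The model tracks the cis and trans isomers of permethrin/cypermethrin in
parallel through linear first-order compartments: route-specific input
depots (gut GI, skin D, respiratory tract R), a central pool B lumping
blood with rapidly equilibrating tissues, a storage pool S for slowly
releasing tissue stores (lipids, protein-bound), body burdens of the three
monitored metabolites (cis-DCCA, trans-DCCA per isomer; 3-PBA fed by both
isomers), cumulative urinary and fecal excretion, and a lumped sink for
non-monitored metabolites.  Everything is in moles; rates are h⁻¹.

Assumptions worth stating explicitly:

* **Linearity.**  All transfers are first-order; there is no saturation,
  so every output is exactly proportional to dose.  This underlies both
  the closed-form ω re-solving during fits and the closed-form dose
  reconstruction.
* **Bolus dosing.**  A dose event adds `f_abs × amount` to the route depot
  as a discrete state jump; the non-bioavailable remainder never enters
  the system.  Dermal wash-off zeroes the skin depot at the stated time
  (the removed amount is tracked so mass balance stays exact).
* **Storage is the slow process.**  The biphasic urinary decline is
  attributed to slow return from storage (k_SB ~ 0.04–0.07 h⁻¹), with
  metabolism and metabolite elimination fast by comparison.  The fitting
  pipeline enforces k_SB < k_elim; without that constraint the likelihood
  has a mirror basin attributing the terminal phase to slow metabolite
  elimination instead, which contradicts the compartment's meaning.
* **Identifiability.**  Urine data pin only `k_elim = k_MU + k_MF` and
  `ω = k_BM·k_MU` per metabolite.  The default split convention is
  all-urinary (`k_MF = 0`); any other split with `k_BM·k_MU = ω` produces
  identical urinary outputs (validated to 1e-10 relative).
* **3-PBA apportioning.**  The calibrated data give one combined 3-PBA
  yield (12.9% of an oral 50:50 dose).  The default apportions it as equal
  per-absorbed-mole yields for the two isomers
  (`ω_3PBA,i = y₃ · k_metabolism,i · k_elim_3PBA` with shared y₃), which
  reproduces the 50:50 result; the data do not resolve the split, and
  mixture-dependent alternatives can be expressed through the per-isomer
  `omega_3PBA` fields.
* **Dermal 3-PBA factor.**  Dermal exposure appears to need a
  multiplicative correction to 3-PBA urinary output (dermal metabolism);
  its calibrated value was never published, so the default is 1.  The
  factor scales only the *reported* urinary 3-PBA series and is excluded
  from the mass balance.

## Key parameters (bundled `table2_mean` preset)

| parameter | cis | trans | meaning |
|---|---|---|---|
| k_abs_oral (h⁻¹) | 0.317 | 0.457 | gut absorption |
| k_abs_dermal (h⁻¹) | 0.033 | 0.047 | skin absorption (see below) |
| f_abs_oral | 0.80 | 0.80 | oral bioavailability |
| f_abs_dermal | 0.0125 | 0.0082 | dermal bioavailability |
| k_BS / k_SB (h⁻¹) | 3.20 / 0.041 | 10.4 / 0.072 | storage uptake / release |
| k_metabolism (h⁻¹) | 13.9 | 20.8 | total biotransformation |
| k_elim (h⁻¹) | 0.184 | 0.157 | DCCA elimination |
| urinary yield (% oral 50:50 dose) | 9.51 | 18.4 | asymptotic DCCA |
| k_elim_3PBA (h⁻¹) | 0.095 | | 3-PBA elimination |
| 3-PBA yield (% oral 50:50 dose) | 12.9 | | combined |

ω values are derived from the printed yields:
`ω = (yield/100)/(0.8×0.5) × k_metabolism × k_elim`.

**Dermal rate assignment.**  The two published dermal absorption rates
(0.033, 0.047 h⁻¹) are attributed inconsistently across the published
sources: the tabulated rows label 0.033 as trans, while the inference text
(whose cis/trans slash convention is fixed by the oral rates) implies
cis = 0.033, trans = 0.047.  The package defaults to the latter because it
reproduces the published dermal early-excretion ordering and storage peaks;
`table2_mean(dermal_rate_assignment="table2")` selects the other reading.

**Half-recovery time.**  The published half-recovery times (8.6 h oral,
31.2 h dermal) are described as referring to total urinary metabolites, but
under this reconstruction the three-metabolite sum gives 10.5 h (oral) /
30.4 h (dermal), while the cis-DCCA cumulative curve gives 8.62 h and
31.3 h — matching both printed values to 0.3%.  Two independent matches are
not coincidence, so the package reports the published half-recovery
quantity from the cis-DCCA curve; `excretion_summary` exposes t50 for every
analyte and for the sum, so either convention is available.

## Simulation

`simulate` integrates the piecewise-constant linear system with scipy's
adaptive Runge-Kutta (DOP853; rtol 1e-9, atol 1e-12 mol per mol of dose),
splitting at dose/wash-off events and auto-refining the grid near events so
that blood peaks minutes after a bolus are resolved; peak times are then
refined below the grid spacing by a local quadratic fit.  `method="eig"`
selects an exact eigendecomposition propagator of the same system matrix —
the fast path used inside fitting loops (~0.3 ms per candidate) and the
independent oracle in tests.  For a single bolus,
`analytic_bolus_solution` provides hand-derived exponential-sum evaluators
(depot → two-eigenvalue blood/storage block → metabolite elimination via
partial fractions); when any two cascade rates coincide within 1e-7
relative, the partial fractions degenerate and the evaluator switches
automatically to the exact matrix-exponential limit form.

Summary metrics require the cumulative urinary curves to have plateaued
(relative rise < 1e-4 over the final 10% of the grid); the default
acceptance horizons are 500 h (oral) and 900 h (dermal), chosen as ~20
half-lives of the slowest mode.  t50 is found by root-finding on a
monotone PCHIP interpolant.

## Calibration pipeline

1. **Initialisers.**  k_SB and k_elim start from log-linear regressions of
   ln(void rate) on void midpoint over 66–114 h and 6–30 h.  Note the
   terminal slope is the slow eigenvalue of the blood–storage block —
   k_SB scaled down by the storage branching — so these are initialisers,
   not estimates.
2. **Sensitivity windows.**  Each of k_BS, k_SB, k_elim is perturbed ±50%
   and its window is where the designated profile (cumulative for k_BS,
   rate otherwise) moves by more than 5%.  The shipped defaults (k_BS
   12–48 h cumulative, k_SB 42–114 h rate, k_elim 6–30 h rate) are the
   historically established windows; absorption and metabolism rates act
   globally and carry no window.
3. **Coordinate descent** cycles bounded 1-D minimisations of each
   parameter's windowed SSE, re-solving ω in closed form after every step
   (urinary output is proportional to ω).  Convergence: largest relative
   parameter change < 1e-4, cap 50 sweeps.  Two numerical safeguards:
   log-space over-relaxation (accepted only when the whole-profile SSE
   improves) against the slow crawl along the correlated k_BS/k_SB ridge,
   and the k_SB < 0.9·k_elim constraint against the mirror basin.  A final
   joint Nelder-Mead polish minimises whole-profile *relative* residuals
   (the variance-matched metric for multiplicative measurement noise) with
   ω re-solved as the mean observed/model ratio; without it the windowed
   stage alone is statistically inefficient (30%+ errors even at 6%
   noise).  Reported reliability factors remain plain absolute SSEs.
4. **Grid search** over (k_abs_oral, k_metabolism) per isomer (default 8
   log-spaced points per axis; tests and examples use 1–3): trans fitted
   first, cis only on grid points satisfying the physiological ordering
   (trans absorbed and metabolised faster; cis storing longer, i.e.
   k_SB_cis ≤ k_SB_trans, checked on the fitted values), then the shared
   3-PBA pair (k_elim_3PBA by 1-D search, the yield y₃ in closed form).
5. **Rank aggregation.**  Each admissible candidate gets six reliability
   factors (rate + cumulative SSE per metabolite), a per-column rank
   (ties averaged) and their sum; smallest rank sum wins, ties broken by
   total SSE.  Rank aggregation is invariant to monotone rescaling of any
   single column.
6. **Dermal fit.**  With internal kinetics frozen, f_abs_dermal is gridded
   and k_abs_dermal solved by 1-D least squares per grid value; the pair
   is selected by rank aggregation over the isomer's two profiles.

Bounds default to the calibrated values bracketed ×10 each way; the
historically printed per-minute physiological limits are shipped as
`PAPER_PRINTED_BOUNDS` but are mutually inconsistent with the calibrated
magnitudes and therefore not the default.

## Synthetic data

The generator emulates the controlled volunteer designs behind the
calibration: a 3.3 mg oral cypermethrin bolus (50:50) or a 31 mg dermal
application (56:44, skin cleaned at 8 h) with per-void urine collection
over 120 h, plus two dermal permethrin designs (3 g whole-body cream,
215 mg scalp solution; cis fraction 0.25 assumed for technical permethrin —
the source designs do not print it).  Void schedules advance ~4 h with 30%
jitter, one long overnight void per night, and t = 0 at 08:00 (controlled
dosing happens in the morning; starting the clock at midnight would merge
the information-rich first hours into the overnight void).  Per-void
amounts are the model's cumulative increments times mean-one lognormal
noise (default CV 0.15); incomplete voids retain a stated fraction and are
flagged (flagged voids are excluded from all fitting residuals).
`synthesize_cohort_average` reproduces the original calibration input — the
average time course of six volunteers sharing a schedule.

What passing the recovery tests does and does not show: the generator
draws from the model itself, so recovery demonstrates the estimator is
consistent and efficient under the assumed noise, not that the model is
correct for real urine data; real data add inter-individual kinetic
variability, schedule irregularity, assay limits of detection and
model misspecification that the generator deliberately omits.

A Cramér-Rao analysis of the single-subject design (23 voids, 15% CV)
bounds the best attainable sd at ~17% for k_elim and ω — single-subject
fits at that noise cannot beat ~12% median error, which is why the noisy
recovery study (like the original calibration) uses six-volunteer
averages (effective noise 15%/√6 ≈ 6%, observed median errors ~7–8%).

## Dose reconstruction

* **Steady state**: daily dose = daily urinary excretion / asymptotic
  molar yield, valid once repeated exposure has reached its periodic
  steady state (the slowest mode has ~1-day half-life, so within a few
  days; the repeated-dosing test shows < 1% day-to-day change by day 9).
* **Time course**: with the scenario shape known and the magnitude
  unknown, linearity makes the estimate a closed-form weighted
  least-squares scale between observed void amounts and unit-dose model
  increments.  The default weighting (1/model², i.e. the mean of per-void
  observed/model ratios) matches constant-CV multiplicative noise and has
  ~1% median error at 15% noise; plain OLS (`weighting="ols"`) is ~6×
  more variable because a few large voids dominate it.  Negative
  solutions are clipped to zero with a warning.

Only amount-based inputs (timed voids, 24-h collections) are supported;
concentration-based spot samples would require urine-flow or creatinine
normalisation, which is the documented extension point (convert
concentrations to amounts upstream).

## Known limitations

* Inhalation kinetics accept a user-supplied k_abs_inh but no calibrated
  value is bundled (none was ever determined); inhalation events without
  it raise an error.
* No inter-individual variability model and no formal uncertainty
  quantification (the source calibration reported only best fits and
  ranges).
* The non-observed metabolite pool is a cumulative sink; its elimination
  kinetics are unspecified, so body-burden statements about "total
  metabolites" including it are out of reach.
* Cumulative-profile residuals treat the running observed sum as the
  comparison target; downstream of an incomplete void the observed
  cumulative is biased low, so subjects with many incomplete voids should
  be excluded (as the source studies did) rather than merely flagged.
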