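# pyretk

Toxicokinetics of permethrin and cypermethrin urinary biomarkers: a
two-isomer compartmental model with closed-form bolus solutions, a staged
windowed least-squares calibration pipeline, a synthetic urine-void data
generator, and biomarker-based dose reconstruction.

## The problem

Population exposure to the pyrethroid insecticides permethrin and
cypermethrin is monitored through urinary metabolites — *cis*- and
*trans*-DCCA (3-(2,2-dichlorovinyl)-2,2-dimethylcyclopropane carboxylic
acid, isomer-specific) and 3-PBA (3-phenoxybenzoic acid, common to both
isomers and to other pyrethroids).  Interpreting such biomonitoring data
requires the quantitative link between an absorbed dose and the urinary
time course.  `pyretk` provides that link for scientists doing exposure
assessment: forward simulation of biomarker kinetics under arbitrary oral,
dermal and inhalation exposure scenarios, calibration of the kinetic
constants from per-void urine collections, and the inverse problem —
reconstructing doses from measured biomarkers.

## The model

Each isomer *i* ∈ {cis, trans} moves through first-order compartments
(amounts in mol, rates in h⁻¹):

```
dGIᵢ/dt = −k_abs_oral,ᵢ · GIᵢ                     (gut depot)
dDᵢ/dt  = −k_abs_dermal,ᵢ · Dᵢ                    (skin depot)
dBᵢ/dt  = k_abs·(depots) + k_SB,ᵢ·Sᵢ − (k_BS,ᵢ + k_metabolism,ᵢ)·Bᵢ
dSᵢ/dt  = k_BS,ᵢ·Bᵢ − k_SB,ᵢ·Sᵢ                   (storage tissues)
dMᵢ/dt  = k_BM,ᵢ·Bᵢ − k_elim,ᵢ·Mᵢ                 (DCCA body burden)
dUᵢ/dt  = k_MU,ᵢ·Mᵢ        dFᵢ/dt = k_MF,ᵢ·Mᵢ     (urine, feces)
dM₃PBA/dt = Σᵢ k_BM_3PBA,ᵢ·Bᵢ − k_elim_3PBA·M₃PBA
```

A dose event places the bioavailable fraction `f_abs · amount` in the
route's depot as a discrete jump; a dermal wash-off empties the skin depot
at a stated time.  Mass is conserved exactly (every column of the system
matrix sums to zero), so at all times the bioavailable dose equals the sum
of all burdens plus cumulative excreta.

Urine data identify only `k_elim = k_MU + k_MF` and `ω = k_BM · k_MU` per
metabolite; the asymptotic urinary yield per absorbed mole is the
branching fraction `ω / (k_metabolism · k_elim)`.  All urinary observables
are provably invariant to how `k_elim` is split between urine and feces.

The bundled preset `table2_mean` carries the calibrated best-fit mean
constants (e.g. `k_metabolism_trans = 20.8 h⁻¹`, `k_SB_cis = 0.041 h⁻¹`,
urinary yields 9.51/18.4/12.9% of an oral 50:50 dose for cis-DCCA,
trans-DCCA and 3-PBA).

Calibration follows the staged scheme the constants were originally
derived with: log-linear initialisers from the excretion-rate slopes,
per-parameter sensitivity windows, cyclic 1-D windowed least squares with
ω re-solved in closed form at every step (plus a joint variance-matched
polish), an outer grid over absorption/metabolism constants with the trans
isomer fitted first and physiological ordering constraints on the cis
isomer, rank-sum aggregation over six reliability factors (rate and
cumulative SSE per metabolite), and a final dermal absorption fit with the
internal kinetics frozen.

## A worked example

```python
from pyretk import ExposureScenario, mg_to_mol, simulate, table2_mean
from pyretk.summary import excretion_summary

params = table2_mean()
dose = mg_to_mol(3.3, "cypermethrin")          # 7.927 umol, 50:50 cis:trans
scen = ExposureScenario.single_bolus("oral", dose, cis_fraction=0.5,
                                     duration=500.0)
sm = excretion_summary(simulate(params, scen))
print(sm.peaks["B_cis"].pct_of_dose, sm.peaks["B_cis"].time_h * 60)
print(sm.urinary["transDCCA"].yield_pct_of_dose)
```

prints

```
0.6883799635574592 14.378481026270297
18.39999999961946
```

— the cis parent compound in blood peaks ~14 min after the dose at 0.69%
of the administered dose, and 18.4% of the dose is eventually excreted as
trans-DCCA.  The `examples/` directory has one short narrative script per
capability (simulation, dermal wash-off, closed-form solutions, cohort
calibration, dose reconstruction, repeated dosing); each prints the
numbers it computes and what they mean.

A thin CLI wraps the same functions:

```sh
pyretk simulate --fixture woollen_oral -o sim.csv --summary-out summary.json
pyretk synth --seed 1 --cv 0.15 -o voids.csv
pyretk fit -i voids.csv --fixture woollen_oral --grid-points 3 -o fit.json
pyretk reconstruct -i voids.csv --mode timecourse --fixture woollen_oral
```

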