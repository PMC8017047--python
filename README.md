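# petquant

Kinetic quantification of dynamic brain PET for reversible radioligands,
built around the comparison workflow used to validate simplified
quantification methods against compartmental modelling — here in the
setting of [¹⁸F]LSN3316612, a radioligand for the ubiquitously expressed
enzyme O-GlcNAcase (OGA).

Because OGA is expressed everywhere in the brain, no true reference region
exists and quantification must rely on the arterial input function.  The
package implements the full chain a PET modelling group needs to decide
which estimator to trust:

- **Arterial input function**: tri-exponential fits of whole-blood and
  total-plasma activity, a Hill-function fit of the plasma parent fraction
  (the input is their product), and a grid-search correction of the
  artery-to-brain arrival delay.
- **Two-tissue compartment model (2TCM)** — the gold standard.  With
  plasma-to-tissue rates K₁/k₂ and bound-compartment rates k₃/k₄, the
  outcome measure is the total distribution volume
  **V_T = (K₁/k₂)(1 + k₃/k₄)** (mL·cm⁻³).  Measured activity includes a
  fixed 5% vascular contribution:
  C_PET = (1 − V_b)·(h ⊛ C_p) + V_b·C_wb.
- **Logan graphical analysis** and **Ichise's multilinear analysis-1
  (MA1)**: linearisations valid past an equilibration time t*, selected
  once per session from the whole-brain TAC (≤ 10% maximum deviation from
  the Logan regression line).
- **Spectral analysis (SA)**: nonnegative decomposition of the tissue
  response into input-convolved exponentials, C_T ≈ Σ αⱼ (C_p ⊛ e^(−βⱼt)),
  giving V_T = Σ αⱼ/βⱼ and the tissue impulse response function, reported
  at 120 min (**IRF₁₂₀**).
- **Parametric imaging**: all of the above (except 2TCM, whose nonlinear
  fit is unsuitable voxelwise) applied per voxel, with atlas region means.
- **SUV / SUVR**: late-window (100–120 min) standardized uptake values
  relative to the corpus callosum, the lowest-V_T pseudo-reference region.
- **Test–retest statistics**: TRV, aTRV, one-way ICC
  = (BSMSS − WSMSS)/(BSMSS + WSMSS), percentage bias, Pearson correlation,
  repeated-measures ANOVA with Fisher's LSD, and the arteriovenous plasma
  difference at fixed timepoints.
- **Synthetic cohort generator**: a deterministic 10-subject test–retest
  study (45-frame/180-min scans, 16 regions, corpus callosum lowest,
  duration-dependent frame noise, a predominantly positive retest shift,
  and an arteriovenous difference profile crossing zero near 60 min) so the
  entire pipeline runs and is testable without any data download.

## Worked example

```python
import numpy as np
import petquant as pq

# analytic input function: tri-exponential plasma peaking at 1.5 min,
# Hill-decaying parent fraction, whole blood at 85% of plasma
amps, rates = np.array([90.0, 15.0, 4.0]), np.array([2.5, 0.25, 0.012])
plasma = pq.TriExpFit(1.5, amps, rates, np.array([0.0, 1.5]), np.array([0.0, amps.sum()]))
whole_blood = pq.TriExpFit(1.5, 0.85 * amps, rates, np.array([0.0, 1.5]),
                           np.array([0.0, 0.85 * amps.sum()]))
inp = pq.InputFunction(plasma, pq.HillFit(0.12, 1.8, 35.0), whole_blood)

schedule = pq.default_schedule().truncate(120.0)   # first 120 min only
true = pq.KineticParameters(K1=0.3, k2=0.15, k3=0.05, k4=0.03, vb=0.05)
tac = pq.simulate_2tcm(true, inp, schedule)

est, diag = pq.fit_2tcm(tac, inp)
print(f"2TCM  V_T = {est.vt:.4f} mL/cm3 (truth {true.vt:.4f})")
t_star = pq.select_t_star(tac, inp)
print(f"t* from the whole-brain Logan criterion: {t_star} min")
print(f"Logan V_T = {pq.logan_vt(tac, inp, t_star).vt:.4f} mL/cm3")
print(f"MA1   V_T = {pq.ma1_vt(tac, inp, t_star).vt:.4f} mL/cm3")
sa = pq.spectral_fit(tac, inp)
print(f"SA    V_T = {sa.vt:.4f} mL/cm3, IRF(120) = {pq.irf_at(sa, 120.0):.5f} min^-1")
```

prints

```
2TCM  V_T = 5.3333 mL/cm3 (truth 5.3333)
t* from the whole-brain Logan criterion: 22.5 min
Logan V_T = 5.2853 mL/cm3
MA1   V_T = 5.2453 mL/cm3
SA    V_T = 5.3341 mL/cm3, IRF(120) = 0.00703 min^-1
```

The 2TCM fit recovers its own simulation exactly.  Logan and MA1 land ~1%
*below* the truth — the transient of the slowly equilibrating bound
compartment has not fully decayed at t*, a real property of graphical
analyses that grows with noise — while SA matches V_T to 0.01% on noiseless
data and overestimates it under noise.

## The analysis pipeline

The study workflow is organised as numbered drivers under `analysis/`,
each writing its tables into `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 42 --out results   # synthetic cohort
python analysis/02_fit_blood.py       --out results             # input-function fits
python analysis/03_quantify_regions.py --out results            # 2TCM/Logan/MA1/SA/IRF per region
python analysis/04_quantify_voxels.py --out results             # parametric maps + SUVR
python analysis/05_compare_report.py  --out results             # correlation / bias / TRV / ICC tables
python analysis/06_arteriovenous.py   --out results             # A–V equilibrium profile
```

Stage 01 writes the cohort manifest (config + seed); later stages
regenerate the cohort deterministically from it, so everything is exactly
reproducible.

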