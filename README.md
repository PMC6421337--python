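# myopower

Non-invasive assessment of muscle fibre-type composition from maximum
mechanical power normalised to muscle volume and specific contractile
strength — with a fully synthetic, ground-truth dynamometry/MRI/biopsy
cohort generator that makes every stage of the pipeline testable.

## The problem

The percentage area of fast (type II) fibres, Area%TypeII, is a key
biomarker of training state, but measuring it requires a needle biopsy.
Peak mechanical muscle power is an attractive non-invasive surrogate —
fast fibres produce roughly threefold the peak power of slow fibres — yet
raw power also scales with how much muscle there is (volume *V*) and how
strong it is per unit cross-section (specific tension). The assessment
parameter implemented here removes both confounders:

```
SCS = M_max / ACSA_max                    [Nm · cm⁻²]
NPI = P_max / (V · SCS)                   [cm⁻¹ · s⁻¹]
```

where *M*max is the maximal isometric plantar-flexion moment, ACSA_max the
maximal anatomical cross-sectional area from MRI contours, and *P*max the
best window-averaged joint power (ankle angle 0–5° plantar flexion) over
three maximal isokinetic efforts at each of seven velocities
(60–240 °/s). NPI correlates with Area%TypeII; raw power does not once
cohorts are morphologically heterogeneous.

The underlying mechanics is the concentric Hill relation per fibre type,

```
f(u) = (1 − u) / (1 + u/k),   u = v / V_max,   k = a/F₀
```

mixed by area fraction φ: `f_mix = (1−φ) f_I + φ f_II`, with
`V_max,II = 3 V_max,I` and equal curvature `k = 0.25`, so that peak power
occurs at ≈30% of V_max and the pure-fast : pure-slow peak-power ratio is
exactly 3.

Because the original per-subject data are not public, the package ships a
calibrated synthetic cohort generator (`myopower.cohort`) producing raw
torque–angle–velocity–EMG traces with realistic corruption layers (axis
misalignment, footplate gravity/inertia, foot-segment gravity, antagonist
co-activation, sensor noise), MRI-like contour stacks and biopsy fibre
tables — each with known ground truth, so the dynamometry corrections can
be verified exactly.

## Worked example

```bash
myopower simulate --out demo_cohort --seed 20 --n-subjects 20
myopower analyze --cohort demo_cohort --out results.json --table table.csv
myopower report --results results.json
```

prints (abridged):

```
analysed n=20; r(NPI, Area%TypeII) = 0.766 (p = 0.0001)
  NPI vs Area%TypeII           r = +0.766  p = 0.0001
  max power vs Area%TypeII     r = +0.469  p = 0.0370
  volume vs max power          r = +0.806  p = 0.0000
  SCS vs max power             r = +0.287  p = 0.2197
  type I vs II total areas     t = +8.962  p = 2.985e-08
cohort means +/- SD:
  max_power_W                 139.418 +/- 31.814
  velocity_at_max_deg_s       141.000 +/- 40.249
  area_pct_type_ii             23.644 +/- 12.432
  npi_1_cm_s                    0.038 +/- 0.007
```

Reading: on this synthetic 20-subject cohort the normalised index
correlates strongly with the biopsy-measured type-II area (r = 0.77) while
raw power correlates weakly (r = 0.47) — raw power is dominated by muscle
volume (r = 0.81) — and type I fibres cover significantly more section
area than type II, as in real soleus. The same analysis runs unchanged on
any directory following the cohort layout (per-subject `trials/*.csv`,
`contours.csv`, `biopsy.csv`, `ta_calibration.csv`, shared `baselines/`).

The library API mirrors the CLI: `simulate_cohort(SimConfig(...))`,
`run_pipeline(cohort)`, `calibrate_generator(targets)`,
`sensitivity_analysis(config, conditions)`.

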