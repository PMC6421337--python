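# Methods

## Generative joint model

Each synthetic subject is a rigid-tendon, single-joint Hill model of the
plantar flexors (soleus-dominant, knee flexed to suppress gastrocnemius):

* **Isometric force** `F₀ = σ · PCSA`, with specific tension σ [N·cm⁻²] and
  physiological cross-sectional area `PCSA = V / L₀` (muscle volume over
  optimal fibre length).
* **Force–velocity**: concentric Hill hyperbola per fibre type,
  `f(u) = (1 − u)/(1 + u/k)` for `u = v/V_max ∈ [0, 1]`, zero beyond
  `V_max`; a whole muscle is the area-fraction mixture
  `f_mix(v) = (1 − φ) f_I(v/V_I) + φ f_II(v/V_II)`. Defaults
  `k_I = k_II = 0.25` and `V_II = 3 V_I` make the peak-power optimum sit at
  ≈31% of `V_max` and give exactly a threefold fast:slow peak-power ratio —
  the minimal parameter set consistent with classic fibre physiology. The
  eccentric branch is not modelled (the protocol never loads it).
* **Force–length**: Gaussian factor in joint angle, peak at 10°
  dorsiflexion, SD 25°. The 0–5° plantar-flexion power window is therefore
  slightly off-peak (mean FL ≈ 0.88), which makes the window rule a real
  part of the measurement rather than a no-op.
* **Kinematic coupling**: fibre velocity `v = r·ω` with a constant effective
  moment arm r (rigid tendon). Joint moment
  `M = a·F₀·FL(θ)·f_mix(r·ω)·r`, with voluntary activation a = 1
  isometrically and a per-velocity draw from U[0.92, 1.0] isokinetically
  (isokinetic efforts are often slightly submaximal).

The geometric constants (fibre length 4 ± 0.3 cm, moment arm 5 ± 0.3 cm)
are *effective joint-level* parameters chosen to reproduce joint
observables; they make no claim of sarcomere-level fidelity.

## Cohort distributions and calibration

Subject parameters are truncated normals. The stated mean is the mean of
the **truncated** distribution (the parent location is solved internally),
so asymmetric truncation — notably of the type-II fraction
φ ~ (0.206, SD 0.111, bounds [0.02, 0.60]) — does not bias cohort means.
Body mass is 74 ± 9 kg, volume 483 ± 84 cm³, muscle length 27.5 ± 1.5 cm,
and the longitudinal area profile is beta-shaped,
`A(x) ∝ x^(a−1)(1−x)^(b−1)` with a, b ~ (2.5, SD 0.06): this makes the
emergent maximal ACSA ≈ 30 cm² and keeps the shape family tight enough
that the simplified volume estimate (below) retains its published ~5%
precision.

Two constants are free: the mean specific tension and the slow-fibre
`V_max` (with `V_II/V_I = 3` fixed). `calibrate_generator` solves them so
the simulated cohort means of the **extracted** maximum mechanical power
and of the velocity at maximum power equal 138 W and 139 °/s. The shipped
defaults (σ = 38.46 N·cm⁻², `V_I` = 7.171 L₀/s) come from a calibration
run in `observable="pipeline"` mode (n = 500, seed 12345), in which each
evaluation simulates raw traces and runs the full analysis, so
noise-selection bias (max over three contractions, argmax over seven noisy
velocities, ≈ +2% power, ≈ +3 °/s) is calibrated away rather than ignored.
A fast closed-form mode (`observable="model"`) exists for exploration and
is exact in the corruption-free limit.

With only two free constants the third natural target — the MVC moment —
is not independently adjustable: the off-peak force–length window and
submaximal isokinetic activation both depress power relative to the
isometric maximum, so matching power and velocity pushes the simulated
mean MVC to ≈ 238 Nm (within the published mean ± 2 SD band of
189 ± 38 Nm, but high) and mean SCS to ≈ 7.7 Nm·cm⁻². This trade-off is
reported in the calibration audit record and is a known limitation of the
two-parameter joint model.

## Corruption layers and their corrections

Each instrument effect is generated so that the corresponding correction in
`myopower.dynamometry` removes it exactly when its inputs are exact:

| Layer | Generation | Correction |
|---|---|---|
| Axis misalignment | all ankle-side moments scaled by `d_dyn/d_ankle` (ratio per subject, U[0.9, 1.1]) | multiply by `d_ankle/d_dyn` |
| Footplate gravity + inertia | `4·cos(θ + 0.4) + I·ω̇` Nm at the sensor | subtract unloaded baseline interpolated in angle |
| Foot gravity | `m_foot·g·0.10·cos θ`, `m_foot = 0.0145·body mass` | same anthropometric model (from `meta.json`) |
| Antagonist | TA dorsiflexion moment `gain·EMG`, co-activation EMG = 0.05 | add back `ĝain·EMG`, ĝain from a through-origin least-squares calibration |
| Sensor noise | white, SD 2 Nm | attenuated by window averaging |

Order: misalignment → baseline → foot gravity → antagonist; the middle two
are additive and commute (asserted in tests). The unloaded-footplate
baseline is recorded as the average of 8 passes (`baseline_repeats`): the
baseline is shared by every subject, so residual baseline noise acts as a
*cohort-wide* systematic — with single passes it shifted the cohort mean
velocity-at-maximum by several °/s between seeds. Baselines are stored
once per cohort, not per subject.

With all layers disabled (`SimConfig.noise_free()`) the pipeline
reproduces the closed-form observables to machine precision; this
generative-identity oracle is the backbone of the test suite. Biopsy fibre
sampling is deliberately *not* part of `noise_free()` — it is the
reference measurement itself (150 fibres per sample; type probability
solved so the expected type-II **area** fraction equals φ; per-fibre areas
log-normal, type I 4 500 µm² vs type II 3 500 µm², CV 0.3, reproducing the
type-I dominance of section areas).

## Extraction rules and numerics

* **MVC**: highest sample over the three corrected isometric trials (no
  plateau averaging). With sensor noise this max-over-samples rule carries
  a small positive bias (~3%), as it does on real unfiltered signals.
* **Power**: per contraction, the arithmetic mean of instantaneous `M·ω`
  over samples with angle in [0°, 5°] plantar flexion; best of three per
  velocity; maximum over the seven velocities, ties to the lowest
  velocity. On the isokinetic plateau this equals mean(M)·mean(ω) to
  <0.1% (tested).
* **Volume**: slab sum `Σ areaᵢ · 1.8 mm` (contiguous slices); muscle
  length is the distance between marginal non-zero slices. The simplified
  estimate `V̂ = c · ACSA_max · length` uses a shape coefficient fitted once
  by through-origin least squares on noise-free stacks and then frozen;
  worst-case held-out error on the default family is ≈ 2.6% (≤ 5%).
* **Area%TypeII**: pooled ratio of summed areas × 100 (per-section
  averaging available as an option). Labelled-mask input counts pixels per
  class (0 background / 1 type I / 2 type II).
* **Statistics**: Pearson r with the exact two-sided t-transform p (n−2
  df); paired t-test (n−1 df); α = 0.05, no multiplicity adjustment (four
  correlations reported separately). Subjects failing any stage are
  dropped with a logged reason; fewer than three survivors is fatal.
* **Peak search**: mixture power curves can be bimodal at small φ, so
  `mixture_peak_power` brackets the global maximum on a 513-point grid
  before bounded refinement (velocity tolerance 10⁻⁶).
* **Determinism**: every draw descends from `master_seed` through
  per-subject and per-trial seed chains; cohort directories are
  byte-identical across runs.

## What the simulations do and do not show

Problem sizes: unit tests use 6–20-subject cohorts; cohort-level
statistics use n = 500 (≈ 4 s to simulate and analyse); replicate-cohort
properties use 20–30 cohorts.

Measured behaviour at the default conditions:

* Cohort means (n = 500) land on the calibration targets: ≈ 137–141 W,
  ≈ 139–145 °/s, Area%TypeII ≈ 19.8–22, volume ≈ 480 cm³ across seeds.
* The NPI–Area%TypeII correlation on corruption-free n = 20 cohorts
  averages ≈ 0.70 (SD ≈ 0.12 across cohorts), i.e. at or above the in-vivo
  estimate of 0.654; with all corruption layers on it averages ≈ 0.65.
* The normalised index out-correlates raw power in 20/20 replicate
  cohorts of n = 100; at the study's own n = 20 the ordering holds in
  ≈ 82% of replicates — at that sample size the contrast is real but not
  guaranteed in any single cohort.
* Sensitivity analysis (20 paired replicate cohorts): raising sensor noise
  to SD 15 Nm lowers the mean NPI correlation by ≈ 0.06 and doubling the
  biopsy fibre count raises it by ≈ 0.02, while an isokinetic activation
  deficit drawn from U[0.8, 1.0] changes it by ≲ 0.01 — voluntary
  activation is a minor noise source next to anatomical heterogeneity.
* NPI ranks subjects by true φ with mean Spearman ρ ≈ 0.70 on clean
  n = 20 cohorts: residual anatomical heterogeneity (moment arm, muscle
  length, shape) and the 30 °/s grid bound the attainable correlation well
  below 1 even without instrument noise.

The generator emulates *joint-level* observables with plausible corruption
magnitudes; it does not model tendon compliance (rigid-tendon `v = r·ω`),
eccentric loading, history effects or fatigue, image-realistic MRI or
stained sections, female or child anthropometry, or training-induced
longitudinal change. Passing tests therefore demonstrate that the analysis
pipeline is internally correct and that the normalisation argument holds
under realistic heterogeneity — not that the in-vivo error budget of the
original instrumentation is reproduced, which is unknowable from published
summary statistics.
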