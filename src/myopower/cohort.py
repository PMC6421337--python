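"""Synthetic dynamometry / MRI / biopsy cohort generator with known ground truth.

Emulates a single-muscle (soleus) study in which each subject undergoes

* three maximal isometric plantar-flexion efforts (MVC) at 0, 5 and 10
  degrees of dorsiflexion,
* three maximal isokinetic plantar-flexion efforts at each of seven
  angular velocities (60-240 deg/s) over a 40-degree range of motion,
* unloaded-footplate baseline movements at the same velocities,
* an antagonist (tibialis anterior) EMG-to-moment calibration series,
* a transverse MRI contour stack (1.8 mm contiguous slices), and
* a needle biopsy yielding a fibre type/area table.

The generative joint model is deliberately low-dimensional: a rigid-tendon
Hill mixture with isometric force ``F0 = sigma * V / L0`` (specific tension
times physiological cross-sectional area), joint moment ``M = F0 * FL(theta)
* f_mix(r * omega) * r`` and fibre velocity ``v = r * omega``.  Instrument
corruption layers (axis misalignment, footplate gravity/inertia, foot
gravity, antagonist co-activation, sensor noise) are applied on top of the
true muscle moment and are each individually removable by the corrections in
:mod:`myopower.dynamometry`; with all layers disabled the analysis pipeline
recovers the closed-form observables exactly, which is the central oracle
of the test suite.

All randomness flows from ``SimConfig.master_seed`` through per-subject and
per-trial seed chains; outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import SimConfig, TruncNorm, load_config, save_config
from .fibre_mechanics import FibreParams, MixtureParams, mixture_force
from .tissue import BiopsySample, ContourStack

__all__ = [
    "SubjectTruth",
    "TorqueTrace",
    "SubjectData",
    "Cohort",
    "fl_factor",
    "foot_gravity_moment",
    "sample_cohort",
    "simulate_isometric_trial",
    "simulate_isokinetic_trial",
    "simulate_baseline_trial",
    "simulate_static_baseline",
    "simulate_ta_calibration",
    "simulate_mri_stack",
    "simulate_biopsy",
    "render_section_mask",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "load_cohort",
    "expected_measures",
    "calibrate_generator",
]

GRAVITY = 9.81  # m/s^2

# Force-length factor: Gaussian in joint angle, peaking at 10 deg dorsiflexion
# (plantar flexion positive convention) with a mild 25-deg width, so the
# 0-5 deg plantar-flexion power window sits slightly off-peak.
FL_PEAK_DEG = -10.0
FL_WIDTH_DEG = 25.0

# Foot segment model used both to generate and to correct the gravitational
# foot moment: segment mass as a fraction of body mass, centre-of-mass lever.
FOOT_MASS_FRACTION = 0.0145
FOOT_COM_LEVER_M = 0.10

D_DYN_CM = 10.0  # lever distance of the footplate force line about the dyn axis

# Power-extraction window (deg of plantar flexion), where angular velocity is
# constant during the isokinetic efforts.
POWER_WINDOW_DEG = (0.0, 5.0)

ISOMETRIC_DURATION_S = 3.0

# rng stream tags (second word of per-trial seed chains)
_TAG_ISOK = 1000
_TAG_ISOM = 2000
_TAG_TA = 3000
_TAG_MRI = 4000
_TAG_BIOPSY = 5000
_TAG_BASELINE = 777


def fl_factor(angle_deg):
    """Normalised force-length factor of the plantar flexors at a joint angle."""
    a = np.asarray(angle_deg, dtype=float)
    f = np.exp(-((a - FL_PEAK_DEG) ** 2) / (2.0 * FL_WIDTH_DEG**2))
    return f if f.ndim else float(f)


def foot_gravity_moment(angle_deg, foot_mass_kg: float, com_lever_m: float = FOOT_COM_LEVER_M):
    """Gravitational plantar-flexion moment of the foot segment (Nm).

    The foot centre of mass lies ``com_lever_m`` anterior to the ankle axis
    at the neutral angle; its horizontal lever shortens with plantar flexion
    as ``cos(theta)``.
    """
    a = np.radians(np.asarray(angle_deg, dtype=float))
    m = foot_mass_kg * GRAVITY * com_lever_m * np.cos(a)
    return m if m.ndim else float(m)


@dataclass(frozen=True)
class SubjectTruth:
    """Ground-truth generative parameters of one synthetic subject."""

    subject_id: str
    body_mass: float  # kg
    phi_true: float  # type-II area fraction, [0, 1]
    volume_true: float  # cm^3
    fibre_length: float  # cm
    moment_arm: float  # cm
    specific_tension: float  # N/cm^2
    muscle_length: float  # cm
    shape_a: float
    shape_b: float
    ta_gain: float  # Nm per unit normalised EMG
    axis_ratio: float  # d_ankle / d_dyn of this subject's setup
    activation_isokinetic: tuple  # one level per investigated velocity
    seed: int

    def __post_init__(self) -> None:
        for name in (
            "body_mass",
            "volume_true",
            "fibre_length",
            "moment_arm",
            "specific_tension",
            "muscle_length",
            "ta_gain",
            "axis_ratio",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.phi_true <= 1.0:
            raise ValueError("phi_true must lie in [0, 1]")
        if any(not 0 < a <= 1 for a in self.activation_isokinetic):
            raise ValueError("activation levels must lie in (0, 1]")

    @property
    def pcsa_cm2(self) -> float:
        """Physiological cross-sectional area, volume / fibre length."""
        return self.volume_true / self.fibre_length

    @property
    def f0_n(self) -> float:
        """Maximum isometric muscle force, specific tension * PCSA."""
        return self.specific_tension * self.pcsa_cm2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["activation_isokinetic"] = list(self.activation_isokinetic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectTruth":
        d = dict(d)
        d["activation_isokinetic"] = tuple(d["activation_isokinetic"])
        return cls(**d)


def mixture_of(truth: SubjectTruth, config: SimConfig) -> MixtureParams:
    """Hill mixture of a subject: cohort-level fibre constants, subject phi."""
    type_i = FibreParams(config.vmax_i_norm, config.curvature_type_i)
    type_ii = FibreParams(
        config.vmax_i_norm * config.vmax_ratio, config.curvature_type_ii
    )
    return MixtureParams(type_i, type_ii, truth.phi_true)


_TRACE_COLUMNS = (
    "time_s",
    "angle_deg",
    "angvel_deg_s",
    "moment_Nm",
    "ta_emg",
    "d_dyn_cm",
    "d_ankle_cm",
)


@dataclass
class TorqueTrace:
    """One trial's sampled time series in the dynamometer frame.

    Plantar flexion is positive for both angle and moment; 0 deg means the
    tibia is perpendicular to the foot sole.  ``d_dyn`` / ``d_ankle`` are the
    lever distances of the footplate force line about the dynamometer and
    ankle axes (equal when the axes are aligned).
    """

    mode: str  # isometric | isokinetic | baseline
    set_velocity: float  # deg/s, 0 for isometric/static
    time: np.ndarray
    angle: np.ndarray
    angvel: np.ndarray
    moment: np.ndarray
    ta_emg: np.ndarray
    d_dyn: np.ndarray
    d_ankle: np.ndarray

    def __post_init__(self) -> None:
        n = self.time.size
        for name in ("angle", "angvel", "moment", "ta_emg", "d_dyn", "d_ankle"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name} is not aligned with time")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                zip(
                    _TRACE_COLUMNS,
                    (
                        self.time,
                        self.angle,
                        self.angvel,
                        self.moment,
                        self.ta_emg,
                        self.d_dyn,
                        self.d_ankle,
                    ),
                )
            )
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, mode: str, set_velocity: float) -> "TorqueTrace":
        cols = [frame[c].to_numpy(dtype=float) for c in _TRACE_COLUMNS]
        return cls(mode, set_velocity, *cols)


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


def sample_cohort(config: SimConfig) -> list[SubjectTruth]:
    """Draw the ground truth of ``config.n_subjects`` subjects.

    Deterministic given ``master_seed``; each subject receives an
    independent child seed that also drives all of their trial-level noise.
    """
    root = np.random.SeedSequence(config.master_seed)
    truths = []
    for i, child in enumerate(root.spawn(config.n_subjects)):
        seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        rng = np.random.default_rng(seed)
        truths.append(
            SubjectTruth(
                subject_id=f"S{i:03d}",
                body_mass=config.body_mass_kg.sample(rng),
                phi_true=config.phi_type_ii.sample(rng),
                volume_true=config.volume_cm3.sample(rng),
                fibre_length=config.fibre_length_cm.sample(rng),
                moment_arm=config.moment_arm_cm.sample(rng),
                specific_tension=config.specific_tension_n_cm2.sample(rng),
                muscle_length=config.muscle_length_cm.sample(rng),
                shape_a=config.shape_a.sample(rng),
                shape_b=config.shape_b.sample(rng),
                ta_gain=config.ta_gain_nm.sample(rng),
                axis_ratio=float(
                    rng.uniform(config.axis_ratio_low, config.axis_ratio_high)
                ),
                activation_isokinetic=tuple(
                    rng.uniform(
                        config.activation_low,
                        config.activation_high,
                        size=len(config.velocities_deg_s),
                    )
                ),
                seed=seed,
            )
        )
    return truths


# ---------------------------------------------------------------------------
# kinematics and moment composition
# ---------------------------------------------------------------------------


def _isokinetic_kinematics(set_velocity: float, config: SimConfig):
    """Time, angle, velocity and acceleration of one isokinetic sweep.

    Constant-acceleration ramp over ``ramp_angle_deg`` at each end of the
    range of motion, constant set velocity in between; the plateau fully
    covers the power-extraction window.
    """
    lo, hi = config.rom_deg
    ramp = config.ramp_angle_deg
    w = float(set_velocity)
    alpha = w * w / (2.0 * ramp)
    t1 = w / alpha
    t2 = t1 + (hi - lo - 2.0 * ramp) / w
    total = t2 + t1
    t = np.arange(int(math.ceil(total * config.sample_rate_hz)) + 1) / config.sample_rate_hz
    t = t[t <= total + 1e-12]

    theta = np.empty_like(t)
    omega = np.empty_like(t)
    acc = np.empty_like(t)

    m1 = t < t1
    m2 = (t >= t1) & (t < t2)
    m3 = t >= t2
    theta[m1] = lo + 0.5 * alpha * t[m1] ** 2
    omega[m1] = alpha * t[m1]
    acc[m1] = alpha
    theta[m2] = lo + ramp + w * (t[m2] - t1)
    omega[m2] = w
    acc[m2] = 0.0
    tau = np.minimum(t[m3] - t2, t1)
    theta[m3] = hi - ramp + w * tau - 0.5 * alpha * tau**2
    omega[m3] = np.maximum(w - alpha * tau, 0.0)
    acc[m3] = -alpha
    return t, theta, omega, acc


def _footplate_moment(angle_deg, acc_deg_s2, config: SimConfig):
    """Gravitational + inertial moment of the unloaded footplate (Nm).

    ``footplate_amp_nm == 0`` switches the whole layer off (gravity and
    inertia together): the layer models one physical object.
    """
    if config.footplate_amp_nm == 0:
        return np.zeros(np.shape(angle_deg))
    grav = config.footplate_amp_nm * np.cos(np.radians(angle_deg) + 0.4)
    inertial = config.footplate_inertia_kg_m2 * np.radians(acc_deg_s2)
    return grav + inertial


def _compose_dyn_moment(
    muscle_nm, angle_deg, acc_deg_s2, ta_emg, truth: SubjectTruth, config: SimConfig, rng
):
    """Stack the corruption layers on the true muscle moment.

    All physiological moment sources (muscle, foot gravity, antagonist) are
    expressed at the ankle; the axis-misalignment layer rescales them by the
    lever ratio ``d_dyn / d_ankle`` on the way to the dynamometer sensor.
    The unloaded-footplate contribution is already a dynamometer-side
    quantity (it is what the baseline protocol measures) and the sensor
    noise is additive white noise at the sensor.
    """
    m = np.asarray(muscle_nm, dtype=float).copy()
    if config.foot_gravity:
        foot_mass = FOOT_MASS_FRACTION * truth.body_mass
        m += foot_gravity_moment(angle_deg, foot_mass)
    m -= truth.ta_gain * np.asarray(ta_emg, dtype=float)
    m /= truth.axis_ratio
    m += _footplate_moment(angle_deg, acc_deg_s2, config)
    if config.sensor_noise_sd_nm > 0:
        m += rng.normal(0.0, config.sensor_noise_sd_nm, size=m.shape)
    return m


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


# ---------------------------------------------------------------------------
# trial simulators
# ---------------------------------------------------------------------------


def simulate_isometric_trial(
    truth: SubjectTruth, angle_deg: float, config: SimConfig
) -> TorqueTrace:
    """One maximal isometric effort at a fixed ankle angle.

    The voluntary effort ramps up smoothly, holds a full-activation plateau
    (activation 1 for isometric MVCs) and ramps down; on the plateau the
    true muscle moment is ``F0 * FL(angle) * r``.
    """
    lo, hi = config.rom_deg
    if not lo <= angle_deg <= hi:
        raise ValueError(f"angle {angle_deg} outside dynamometer range {config.rom_deg}")
    idx = list(config.isometric_angles_deg).index(angle_deg) if angle_deg in config.isometric_angles_deg else 9
    rng = np.random.default_rng([truth.seed, _TAG_ISOM + idx])
    n = int(ISOMETRIC_DURATION_S * config.sample_rate_hz) + 1
    t = np.arange(n) / config.sample_rate_hz
    env = _smoothstep((t - 0.3) / 0.6) * (1.0 - _smoothstep((t - 2.3) / 0.6))
    angle = np.full(n, float(angle_deg))
    omega = np.zeros(n)
    acc = np.zeros(n)
    r_m = truth.moment_arm / 100.0
    muscle = env * truth.f0_n * fl_factor(angle_deg) * r_m
    ta_emg = config.ta_coactivation * env
    moment = _compose_dyn_moment(muscle, angle, acc, ta_emg, truth, config, rng)
    d_dyn = np.full(n, D_DYN_CM)
    return TorqueTrace(
        "isometric", 0.0, t, angle, omega, moment, ta_emg, d_dyn, d_dyn * truth.axis_ratio
    )


def simulate_isokinetic_trial(
    truth: SubjectTruth, set_velocity: float, repeat_index: int, config: SimConfig
) -> TorqueTrace:
    """One maximal isokinetic plantar-flexion sweep at a set velocity.

    Within the constant-velocity plateau the true muscle moment is
    ``activation * F0 * FL(theta) * f_mix(r * omega) * r``; the ramp phases
    at the ends of the range of motion sit outside the extraction window.
    """
    if set_velocity not in config.velocities_deg_s:
        raise ValueError(
            f"set velocity {set_velocity} not in investigated set {config.velocities_deg_s}"
        )
    i_vel = list(config.velocities_deg_s).index(set_velocity)
    rng = np.random.default_rng([truth.seed, _TAG_ISOK + 10 * i_vel + repeat_index])
    t, theta, omega, acc = _isokinetic_kinematics(set_velocity, config)
    act = truth.activation_isokinetic[i_vel]
    r_m = truth.moment_arm / 100.0
    l0_m = truth.fibre_length / 100.0
    v_fib = r_m * np.radians(omega)
    mix = mixture_of(truth, config)
    muscle = act * truth.f0_n * fl_factor(theta) * mixture_force(v_fib, mix, l0_m) * r_m
    ta_emg = np.full(t.size, config.ta_coactivation)
    moment = _compose_dyn_moment(muscle, theta, acc, ta_emg, truth, config, rng)
    d_dyn = np.full(t.size, D_DYN_CM)
    return TorqueTrace(
        "isokinetic",
        float(set_velocity),
        t,
        theta,
        omega,
        moment,
        ta_emg,
        d_dyn,
        d_dyn * truth.axis_ratio,
    )


def simulate_baseline_trial(
    set_velocity: float, config: SimConfig, rng: np.random.Generator
) -> TorqueTrace:
    """Unloaded-footplate sweep at a set velocity (subject-independent).

    Only the footplate's own gravitational and inertial moments (plus sensor
    noise) are present; axes are aligned in the unloaded configuration.  The
    recording is the average of ``config.baseline_repeats`` passes, because
    any residual noise in the baseline is subtracted from *every* subject
    and would otherwise act as a cohort-wide systematic error.
    """
    if set_velocity not in config.velocities_deg_s:
        raise ValueError(
            f"set velocity {set_velocity} not in investigated set {config.velocities_deg_s}"
        )
    t, theta, omega, acc = _isokinetic_kinematics(set_velocity, config)
    moment = _footplate_moment(theta, acc, config)
    if config.sensor_noise_sd_nm > 0:
        sd = config.sensor_noise_sd_nm / math.sqrt(config.baseline_repeats)
        moment = moment + rng.normal(0.0, sd, size=t.size)
    zeros = np.zeros(t.size)
    d = np.full(t.size, D_DYN_CM)
    return TorqueTrace("baseline", float(set_velocity), t, theta, omega, moment, zeros, d, d)


def simulate_static_baseline(
    angle_deg: float, config: SimConfig, rng: np.random.Generator
) -> TorqueTrace:
    """Static unloaded-footplate recording at one isometric test angle."""
    n = int(ISOMETRIC_DURATION_S * config.sample_rate_hz) + 1
    t = np.arange(n) / config.sample_rate_hz
    angle = np.full(n, float(angle_deg))
    moment = _footplate_moment(angle, np.zeros(n), config)
    if config.sensor_noise_sd_nm > 0:
        sd = config.sensor_noise_sd_nm / math.sqrt(config.baseline_repeats)
        moment = moment + rng.normal(0.0, sd, size=n)
    zeros = np.zeros(n)
    d = np.full(n, D_DYN_CM)
    return TorqueTrace("baseline", 0.0, t, angle, zeros, moment, zeros, d, d)


def simulate_ta_calibration(
    truth: SubjectTruth, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(EMG, dorsiflexion moment) pairs of the tibialis anterior as agonist.

    Ground truth is a through-origin linear gain stored in the subject's
    truth record; pairs carry additive moment noise.
    """
    rng = np.random.default_rng([truth.seed, _TAG_TA])
    n = config.ta_calib_n_pairs
    levels = np.linspace(0.05, 1.0, max(n // 5, 2))
    emg = np.resize(levels, n)
    moment = truth.ta_gain * emg
    if config.ta_calib_noise_sd_nm > 0:
        moment = moment + rng.normal(0.0, config.ta_calib_noise_sd_nm, size=n)
    return emg, moment


def _shape_profile(truth: SubjectTruth, n_slices: int) -> np.ndarray:
    """Normalised longitudinal area profile (beta-shaped, unit maximum)."""
    x = (np.arange(n_slices) + 0.5) / n_slices
    prof = x ** (truth.shape_a - 1.0) * (1.0 - x) ** (truth.shape_b - 1.0)
    return prof / prof.max()


def simulate_mri_stack(truth: SubjectTruth, config: SimConfig) -> ContourStack:
    """MRI-like contour stack: profile scaled to the true volume, then noised.

    Slice areas follow the subject's beta-shaped longitudinal profile,
    scaled so the discrete slab integral equals ``volume_true`` exactly;
    contour-tracing error is multiplicative log-normal with CV
    ``config.contour_cv`` (unit mean).
    """
    rng = np.random.default_rng([truth.seed, _TAG_MRI])
    t_cm = config.slice_thickness_mm / 10.0
    n_slices = int(round(truth.muscle_length / t_cm))
    prof = _shape_profile(truth, n_slices)
    areas = prof * (truth.volume_true / (prof.sum() * t_cm))
    if config.contour_cv > 0:
        s = math.sqrt(math.log(1.0 + config.contour_cv**2))
        areas = areas * rng.lognormal(-0.5 * s * s, s, size=n_slices)
    return ContourStack(config.slice_thickness_mm, areas)


def simulate_biopsy(
    truth: SubjectTruth, n_fibres: int, config: SimConfig
) -> BiopsySample:
    """Needle-biopsy fibre table with expected type-II area fraction phi.

    Fibre types are Bernoulli draws whose probability is chosen so that the
    *expected area* fraction of type II equals ``phi_true`` given the
    type-specific mean section areas; per-fibre areas are log-normal with a
    common coefficient of variation.
    """
    if n_fibres < 1:
        raise ValueError("n_fibres must be >= 1")
    rng = np.random.default_rng([truth.seed, _TAG_BIOPSY])
    mu_i = config.fibre_area_um2_type_i
    mu_ii = config.fibre_area_um2_type_ii
    phi = truth.phi_true
    denom = phi * mu_i + (1.0 - phi) * mu_ii
    q = phi * mu_i / denom if denom > 0 else 0.0
    is_ii = rng.random(n_fibres) < q
    s = math.sqrt(math.log(1.0 + config.fibre_area_cv**2))
    areas = np.where(
        is_ii,
        rng.lognormal(math.log(mu_ii) - 0.5 * s * s, s, size=n_fibres),
        rng.lognormal(math.log(mu_i) - 0.5 * s * s, s, size=n_fibres),
    )
    types = np.where(is_ii, "II", "I").astype(object)
    return BiopsySample(types, areas)


def render_section_mask(
    sample: BiopsySample, pixel_size_um2: float, width: int = 1024
) -> np.ndarray:
    """Rasterise a biopsy sample into a labelled two-class section mask.

    Synthetic stand-in for a stained-section label image: each fibre
    occupies ``round(area / pixel_size)`` pixels laid out in row-major runs
    separated by single background pixels.  Labels: 0 background, 1 type I,
    2 type II.
    """
    if not pixel_size_um2 > 0:
        raise ValueError("pixel_size_um2 must be > 0")
    counts = np.maximum(np.rint(sample.areas_um2 / pixel_size_um2).astype(int), 1)
    total = int(counts.sum() + counts.size)
    height = total // width + 2
    flat = np.zeros(height * width, dtype=np.uint8)
    pos = 0
    for c, ftype in zip(counts, sample.types):
        label = 1 if ftype == "I" else 2
        flat[pos : pos + c] = label
        pos += c + 1  # background separator
    return flat.reshape(height, width)


# ---------------------------------------------------------------------------
# whole-subject / whole-cohort simulation and the cohort directory dialect
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    """Everything measured (or loadable) for one subject; truth optional."""

    subject_id: str
    meta: dict
    isometric: list  # list[TorqueTrace]
    isokinetic: dict  # set velocity -> list[TorqueTrace]
    ta_emg: np.ndarray
    ta_moment: np.ndarray
    contours: ContourStack
    biopsy: BiopsySample
    truth: SubjectTruth | None = None


@dataclass
class Cohort:
    """A simulated (or loaded) cohort plus the shared baseline recordings."""

    subjects: list  # list[SubjectData]
    baselines_isokinetic: dict  # set velocity -> TorqueTrace
    baselines_isometric: dict  # angle -> TorqueTrace
    meta: dict
    config: SimConfig | None = None


def _subject_meta(truth: SubjectTruth, config: SimConfig) -> dict:
    foot_mass = FOOT_MASS_FRACTION * truth.body_mass if config.foot_gravity else 0.0
    return {
        "subject_id": truth.subject_id,
        "body_mass_kg": truth.body_mass,
        "foot_mass_kg": foot_mass,
        "foot_com_lever_m": FOOT_COM_LEVER_M,
        "slice_thickness_mm": config.slice_thickness_mm,
        "sample_rate_hz": config.sample_rate_hz,
    }


def simulate_subject(truth: SubjectTruth, config: SimConfig) -> SubjectData:
    """All measurement artefacts of one subject (baselines live cohort-side)."""
    isometric = [
        simulate_isometric_trial(truth, a, config) for a in config.isometric_angles_deg
    ]
    isokinetic = {
        v: [simulate_isokinetic_trial(truth, v, r, config) for r in range(3)]
        for v in config.velocities_deg_s
    }
    ta_emg, ta_moment = simulate_ta_calibration(truth, config)
    contours = simulate_mri_stack(truth, config)
    biopsy = simulate_biopsy(truth, config.biopsy_n_fibres, config)
    return SubjectData(
        subject_id=truth.subject_id,
        meta=_subject_meta(truth, config),
        isometric=isometric,
        isokinetic=isokinetic,
        ta_emg=ta_emg,
        ta_moment=ta_moment,
        contours=contours,
        biopsy=biopsy,
        truth=truth,
    )


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate the full cohort, including the shared baseline protocol."""
    truths = sample_cohort(config)
    rng_base = np.random.default_rng([config.master_seed, _TAG_BASELINE])
    baselines_isok = {
        v: simulate_baseline_trial(v, config, rng_base) for v in config.velocities_deg_s
    }
    baselines_isom = {
        a: simulate_static_baseline(a, config, rng_base)
        for a in config.isometric_angles_deg
    }
    subjects = [simulate_subject(t, config) for t in truths]
    meta = {
        "n_subjects": config.n_subjects,
        "master_seed": config.master_seed,
        "velocities_deg_s": list(config.velocities_deg_s),
        "isometric_angles_deg": list(config.isometric_angles_deg),
        "sample_rate_hz": config.sample_rate_hz,
        "slice_thickness_mm": config.slice_thickness_mm,
    }
    return Cohort(subjects, baselines_isok, baselines_isom, meta, config)


def _angle_token(angle: float) -> str:
    return f"{'m' if angle < 0 else 'p'}{abs(angle):04.1f}"


def _parse_angle_token(tok: str) -> float:
    sign = -1.0 if tok[0] == "m" else 1.0
    return sign * float(tok[1:])


_CSV_FLOAT_FMT = "%.6g"


def write_cohort(cohort: Cohort, path, include_truth: bool = True) -> None:
    """Write a cohort directory.

    Layout: ``<subject_id>/trials/*.csv`` (one trace per file),
    ``contours.csv``, ``biopsy.csv``, ``ta_calibration.csv``, ``meta.json``
    and (optionally) ``truth.json`` per subject; shared ``baselines/*.csv``
    and ``meta.json`` (plus ``config.yaml`` when available) at the root.
    Baselines are stored once because the unloaded-footplate protocol is
    subject-independent.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    (root / "meta.json").write_text(json.dumps(cohort.meta, indent=1))
    if cohort.config is not None:
        save_config(cohort.config, root / "config.yaml")
    bdir = root / "baselines"
    bdir.mkdir(exist_ok=True)
    for v, tr in cohort.baselines_isokinetic.items():
        tr.to_frame().to_csv(
            bdir / f"baseline_v{int(v):03d}.csv", index=False, float_format=_CSV_FLOAT_FMT
        )
    for a, tr in cohort.baselines_isometric.items():
        tr.to_frame().to_csv(
            bdir / f"baseline_iso_a{_angle_token(a)}.csv",
            index=False,
            float_format=_CSV_FLOAT_FMT,
        )
    for s in cohort.subjects:
        sdir = root / s.subject_id
        tdir = sdir / "trials"
        tdir.mkdir(parents=True, exist_ok=True)
        (sdir / "meta.json").write_text(json.dumps(s.meta, indent=1))
        if include_truth and s.truth is not None:
            (sdir / "truth.json").write_text(json.dumps(s.truth.to_dict(), indent=1))
        for i, tr in enumerate(s.isometric):
            tok = _angle_token(tr.angle[0])
            tr.to_frame().to_csv(
                tdir / f"isometric_a{tok}.csv", index=False, float_format=_CSV_FLOAT_FMT
            )
        for v, trs in s.isokinetic.items():
            for r, tr in enumerate(trs):
                tr.to_frame().to_csv(
                    tdir / f"isokinetic_v{int(v):03d}_r{r}.csv",
                    index=False,
                    float_format=_CSV_FLOAT_FMT,
                )
        pd.DataFrame({"emg": s.ta_emg, "moment_Nm": s.ta_moment}).to_csv(
            sdir / "ta_calibration.csv", index=False, float_format=_CSV_FLOAT_FMT
        )
        s.contours.to_frame().to_csv(
            sdir / "contours.csv", index=False, float_format=_CSV_FLOAT_FMT
        )
        s.biopsy.to_frame().to_csv(
            sdir / "biopsy.csv", index=False, float_format=_CSV_FLOAT_FMT
        )


def load_cohort(path, with_truth: bool = False) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`.

    Ground truth is withheld from the analysis by default.
    """
    root = Path(path)
    meta = json.loads((root / "meta.json").read_text())
    cfg = load_config(root / "config.yaml") if (root / "config.yaml").exists() else None
    baselines_isok = {}
    baselines_isom = {}
    for f in sorted((root / "baselines").glob("baseline_v*.csv")):
        v = float(f.stem.split("_v")[1])
        baselines_isok[v] = TorqueTrace.from_frame(pd.read_csv(f), "baseline", v)
    for f in sorted((root / "baselines").glob("baseline_iso_a*.csv")):
        a = _parse_angle_token(f.stem.split("_a")[1])
        baselines_isom[a] = TorqueTrace.from_frame(pd.read_csv(f), "baseline", 0.0)
    subjects = []
    for sdir in sorted(p for p in root.iterdir() if p.is_dir() and p.name != "baselines"):
        smeta = json.loads((sdir / "meta.json").read_text())
        isometric = []
        isokinetic: dict[float, list[TorqueTrace]] = {}
        for f in sorted((sdir / "trials").glob("isometric_a*.csv")):
            isometric.append(TorqueTrace.from_frame(pd.read_csv(f), "isometric", 0.0))
        for f in sorted((sdir / "trials").glob("isokinetic_v*_r*.csv")):
            v = float(f.stem.split("_v")[1].split("_r")[0])
            isokinetic.setdefault(v, []).append(
                TorqueTrace.from_frame(pd.read_csv(f), "isokinetic", v)
            )
        ta = pd.read_csv(sdir / "ta_calibration.csv")
        contours = ContourStack.from_frame(
            pd.read_csv(sdir / "contours.csv"), smeta["slice_thickness_mm"]
        )
        biopsy = BiopsySample.from_frame(pd.read_csv(sdir / "biopsy.csv"))
        truth = None
        if with_truth and (sdir / "truth.json").exists():
            truth = SubjectTruth.from_dict(json.loads((sdir / "truth.json").read_text()))
        subjects.append(
            SubjectData(
                subject_id=smeta["subject_id"],
                meta=smeta,
                isometric=isometric,
                isokinetic=isokinetic,
                ta_emg=ta["emg"].to_numpy(float),
                ta_moment=ta["moment_Nm"].to_numpy(float),
                contours=contours,
                biopsy=biopsy,
                truth=truth,
            )
        )
    return Cohort(subjects, baselines_isok, baselines_isom, meta, cfg)


# ---------------------------------------------------------------------------
# closed-form expected observables and generator calibration
# ---------------------------------------------------------------------------


def window_fl_means(config: SimConfig, window=POWER_WINDOW_DEG) -> dict:
    """Per-velocity mean force-length factor over the in-window samples.

    The sample angles inside the extraction window are fixed by the
    (subject-independent) sweep kinematics, so the discrete window mean of
    ``FL(theta)`` is a per-velocity constant.
    """
    out = {}
    for v in config.velocities_deg_s:
        _, theta, _, _ = _isokinetic_kinematics(v, config)
        m = (theta >= window[0]) & (theta <= window[1])
        out[v] = float(fl_factor(theta[m]).mean())
    return out


def expected_measures(
    truth: SubjectTruth, config: SimConfig, window_fl: dict | None = None
) -> dict:
    """Closed-form observables implied by a subject's ground truth.

    Mirrors what the dynamometry pipeline extracts from corruption-free
    traces: the MVC moment (best isometric angle), the per-velocity
    window-averaged power, their maximum and the velocity achieving it
    (lowest velocity on ties).
    """
    if window_fl is None:
        window_fl = window_fl_means(config)
    r_m = truth.moment_arm / 100.0
    l0_m = truth.fibre_length / 100.0
    mix = mixture_of(truth, config)
    mvc = truth.f0_n * r_m * max(fl_factor(a) for a in config.isometric_angles_deg)
    per_velocity = {}
    for i, v in enumerate(config.velocities_deg_s):
        omega = math.radians(v)
        act = truth.activation_isokinetic[i]
        p = act * truth.f0_n * window_fl[v] * mixture_force(r_m * omega, mix, l0_m) * r_m * omega
        per_velocity[v] = float(p)
    best_v = max(sorted(per_velocity), key=lambda v: per_velocity[v])
    # max() with sorted keys returns the lowest velocity on exact ties
    best_v = min(v for v in per_velocity if per_velocity[v] == per_velocity[best_v])
    return {
        "mvc_nm": float(mvc),
        "per_velocity_power_w": per_velocity,
        "max_power_w": per_velocity[best_v],
        "velocity_at_max_deg_s": float(best_v),
    }


def _expected_cohort_means(config: SimConfig, n: int, seed: int) -> dict:
    cfg = config.replace(n_subjects=n, master_seed=seed)
    truths = sample_cohort(cfg)
    wfl = window_fl_means(cfg)
    mvc, power, vel = [], [], []
    for t in truths:
        m = expected_measures(t, cfg, wfl)
        mvc.append(m["mvc_nm"])
        power.append(m["max_power_w"])
        vel.append(m["velocity_at_max_deg_s"])
    return {
        "mvc_nm": float(np.mean(mvc)),
        "max_power_w": float(np.mean(power)),
        "velocity_at_max_deg_s": float(np.mean(vel)),
    }


def _measured_cohort_means(config: SimConfig, n: int, seed: int) -> dict:
    """Cohort means of the *extracted* measures, corruption layers included.

    Runs the full trace simulation and analysis pipeline, so noise-selection
    effects (max over contractions, argmax over noisy velocities) are part
    of the observable the calibration matches.
    """
    from .assessment import run_pipeline  # deferred: assessment imports cohort

    cfg = config.replace(n_subjects=n, master_seed=seed)
    result = run_pipeline(simulate_cohort(cfg))
    s = result.stats["summary"]
    return {
        "mvc_nm": s["mvc_moment_Nm"]["mean"],
        "max_power_w": s["max_power_W"]["mean"],
        "velocity_at_max_deg_s": s["velocity_at_max_deg_s"]["mean"],
    }


def calibrate_generator(
    targets: dict,
    config: SimConfig | None = None,
    n: int = 2000,
    seed: int = 12345,
    rtol: float = 2e-3,
    observable: str = "model",
) -> tuple[SimConfig, dict]:
    """Solve the two free generator constants against cohort-level targets.

    ``targets`` must provide ``max_power_w`` and ``velocity_at_max_deg_s``
    (cohort means); ``mvc_nm`` may be supplied and is reported in the audit
    but not solved for, because with the fibre-velocity scale fixed by the
    velocity target and specific tension fixed by the power target the MVC
    mean is no longer free.  The solve runs on an ``n``-subject calibration
    cohort:

    1. the slow-fibre maximum shortening velocity ``vmax_i_norm`` is
       bisected so the mean extracted velocity at maximum power matches;
    2. the mean specific tension is rescaled iteratively (power is nearly
       proportional to it) until the mean maximum power matches.

    ``observable`` selects what "extracted" means: ``"model"`` uses the
    fast closed-form noise-free observables, ``"pipeline"`` runs the full
    trace simulation and analysis per evaluation so that noise-selection
    bias is calibrated away too (much slower; used to derive the shipped
    defaults).  Returns the calibrated config and an audit record.
    """
    for key in ("max_power_w", "velocity_at_max_deg_s"):
        if key not in targets:
            raise ValueError(f"targets must contain {key!r}")
    if observable not in ("model", "pipeline"):
        raise ValueError(f"unknown observable {observable!r}")
    means_fn = _expected_cohort_means if observable == "model" else _measured_cohort_means
    cfg = config if config is not None else SimConfig()

    def vel_residual(vmax: float) -> float:
        means = means_fn(cfg.replace(vmax_i_norm=vmax), n, seed)
        return means["velocity_at_max_deg_s"] - targets["velocity_at_max_deg_s"]

    lo, hi = 3.0, 15.0
    if vel_residual(lo) > 0 or vel_residual(hi) < 0:
        raise RuntimeError(
            "velocity calibration failed: target outside the bracket "
            f"[{lo}, {hi}] fibre lengths/s"
        )
    xtol = 1e-3 if observable == "model" else 5e-3
    vmax = float(brentq(vel_residual, lo, hi, xtol=xtol))
    cfg = cfg.replace(vmax_i_norm=vmax)

    st = cfg.specific_tension_n_cm2
    history = []
    for iteration in range(12):
        means = means_fn(cfg, n, seed)
        achieved = means["max_power_w"]
        history.append(achieved)
        rel = abs(achieved - targets["max_power_w"]) / targets["max_power_w"]
        if rel < rtol:
            break
        st = TruncNorm(
            st.mean * targets["max_power_w"] / achieved, st.sd, st.lower, st.upper
        )
        cfg = cfg.replace(specific_tension_n_cm2=st)
    else:
        raise RuntimeError(
            f"specific-tension calibration did not converge: history={history}"
        )
    means = means_fn(cfg, n, seed)
    audit = {
        "n": n,
        "seed": seed,
        "observable": observable,
        "vmax_i_norm": vmax,
        "specific_tension_mean_n_cm2": st.mean,
        "achieved": means,
        "targets": dict(targets),
        "power_iterations": len(history),
    }
    if "mvc_nm" in targets:
        audit["mvc_residual_nm"] = means["mvc_nm"] - targets["mvc_nm"]
    return cfg, audit
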