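"""Reduction of raw dynamometer traces to functional muscle measures.

The raw dynamometer moment is contaminated by four well-understood effects,
each removed by a dedicated correction:

1. **Axis misalignment** — the ankle and dynamometer rotation axes do not
   coincide, so the footplate force line has different lever distances about
   the two axes; the ankle-side moment is the dynamometer moment scaled by
   ``d_ankle / d_dyn``.
2. **Footplate gravity/inertia** — measured directly by moving the unloaded
   footplate over the same range at the same set velocity and subtracted by
   interpolation in joint angle.
3. **Foot-segment gravity** — a model term ``m_foot * g * lever(theta)``
   using anthropometric foot mass and centre-of-mass lever.
4. **Antagonist co-activation** — the tibialis anterior produces a
   dorsiflexion moment during plantar-flexion efforts; a through-origin
   linear EMG-to-moment calibration converts its EMG into the moment that
   is added back.

After correction, the maximum plantar-flexion moment is the highest sample
across the isometric MVCs, and the maximum mechanical power is the highest
window-averaged ``M * omega`` (0-5 deg plantar flexion) across contractions
and velocities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import (
    FOOT_COM_LEVER_M,
    FOOT_MASS_FRACTION,
    POWER_WINDOW_DEG,
    SubjectData,
    TorqueTrace,
    foot_gravity_moment,
)

__all__ = [
    "EmgMomentFit",
    "PowerResult",
    "correct_axis_misalignment",
    "subtract_baseline",
    "correct_foot_gravity",
    "fit_emg_moment",
    "correct_antagonist",
    "correct_trace",
    "extract_mvc",
    "compute_power",
    "extract_max_power",
    "analyze_subject_dynamometry",
]

_STATIC_ANGLE_TOL_DEG = 0.5


@dataclass(frozen=True)
class EmgMomentFit:
    """Through-origin linear EMG-to-moment calibration of the antagonist."""

    gain: float  # Nm per unit normalised EMG
    residual_sd: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("a negative EMG-to-moment gain is not physical")


@dataclass(frozen=True)
class PowerResult:
    """Maximum mechanical power with its velocity and per-velocity table."""

    max_power: float  # W
    velocity_at_max: float  # deg/s
    per_velocity_power: dict  # set velocity -> best window-average power (W)


def correct_axis_misalignment(trace: TorqueTrace) -> np.ndarray:
    """Transfer the measured moment from the dynamometer to the ankle axis.

    Per sample: ``M_ankle = M_dyn * d_ankle / d_dyn``.
    """
    if np.any(trace.d_dyn <= 0):
        raise ValueError("d_dyn must be > 0 at every sample")
    return trace.moment * (trace.d_ankle / trace.d_dyn)


def subtract_baseline(
    trace: TorqueTrace, baseline: TorqueTrace, moment: np.ndarray | None = None
) -> np.ndarray:
    """Remove the unloaded-footplate moment, interpolated at the same angle.

    The baseline must have been recorded at the trace's set velocity and
    must cover its angle range.  For static (isometric) baselines the mean
    baseline moment at the common angle is subtracted instead.
    """
    m = trace.moment if moment is None else np.asarray(moment, dtype=float)
    if baseline.set_velocity != trace.set_velocity:
        raise ValueError(
            f"baseline set velocity {baseline.set_velocity} does not match "
            f"trace set velocity {trace.set_velocity}"
        )
    b_angle = baseline.angle
    if b_angle.max() - b_angle.min() < _STATIC_ANGLE_TOL_DEG:
        if np.any(np.abs(trace.angle - b_angle.mean()) > _STATIC_ANGLE_TOL_DEG):
            raise ValueError("static baseline does not cover the trace angle")
        return m - baseline.moment.mean()
    if trace.angle.min() < b_angle.min() - 1e-9 or trace.angle.max() > b_angle.max() + 1e-9:
        raise ValueError("baseline does not cover the trace angle range")
    order = np.argsort(b_angle, kind="stable")
    return m - np.interp(trace.angle, b_angle[order], baseline.moment[order])


def correct_foot_gravity(
    trace: TorqueTrace,
    foot_mass_kg: float,
    com_lever_m: float = FOOT_COM_LEVER_M,
    moment: np.ndarray | None = None,
) -> np.ndarray:
    """Remove the angle-dependent gravitational moment of the foot segment."""
    if foot_mass_kg < 0:
        raise ValueError("foot mass must be >= 0")
    m = trace.moment if moment is None else np.asarray(moment, dtype=float)
    return m - foot_gravity_moment(trace.angle, foot_mass_kg, com_lever_m)


def fit_emg_moment(emg, moment) -> EmgMomentFit:
    """Least-squares line through the origin relating antagonist EMG to moment.

    ``gain = sum(e * m) / sum(e^2)``; requires at least two pairs with
    non-zero EMG variance of input.
    """
    e = np.asarray(emg, dtype=float)
    m = np.asarray(moment, dtype=float)
    if e.size != m.size:
        raise ValueError("emg and moment must be aligned")
    if e.size < 2:
        raise ValueError("need at least 2 calibration pairs")
    if not np.any(e != 0):
        raise ValueError("all-zero EMG cannot be calibrated")
    gain = float((e * m).sum() / (e * e).sum())
    resid = m - gain * e
    return EmgMomentFit(gain=gain, residual_sd=float(resid.std(ddof=1)), n_pairs=e.size)


def correct_antagonist(moment, ta_emg, fit: EmgMomentFit) -> np.ndarray:
    """Add back the antagonist's dorsiflexion moment: ``M + gain * EMG``."""
    m = np.asarray(moment, dtype=float)
    e = np.asarray(ta_emg, dtype=float)
    if m.size != e.size:
        raise ValueError("moment and EMG series must be aligned")
    return m + fit.gain * e


def correct_trace(
    trace: TorqueTrace,
    baseline: TorqueTrace | None,
    foot_mass_kg: float,
    emg_fit: EmgMomentFit,
    com_lever_m: float = FOOT_COM_LEVER_M,
) -> np.ndarray:
    """Full correction chain: misalignment, baseline, foot gravity, antagonist."""
    m = correct_axis_misalignment(trace)
    if baseline is not None:
        m = subtract_baseline(trace, baseline, moment=m)
    m = correct_foot_gravity(trace, foot_mass_kg, com_lever_m, moment=m)
    return correct_antagonist(m, trace.ta_emg, emg_fit)


def extract_mvc(corrected_moments) -> float:
    """Maximum plantar-flexion moment: highest sample over all MVC trials."""
    series = [np.asarray(m, dtype=float) for m in corrected_moments]
    if not series:
        raise ValueError("need at least one isometric trial")
    return float(max(s.max() for s in series))


def compute_power(moment, angvel_deg_s) -> np.ndarray:
    """Instantaneous joint power ``M * omega`` in W (omega converted to rad/s)."""
    m = np.asarray(moment, dtype=float)
    w = np.asarray(angvel_deg_s, dtype=float)
    if m.size != w.size:
        raise ValueError("moment and angular velocity series must be aligned")
    return m * np.radians(w)


def extract_max_power(trials_by_velocity: dict, window=POWER_WINDOW_DEG) -> PowerResult:
    """Maximum window-averaged mechanical power over contractions and velocities.

    ``trials_by_velocity`` maps each set velocity to a list of
    ``(trace, corrected_moment)`` pairs.  Per contraction, instantaneous
    power is averaged over the samples whose joint angle lies in ``window``;
    the best contraction is kept per velocity and the overall maximum is
    taken across velocities (lowest velocity on exact ties).
    """
    if not trials_by_velocity:
        raise ValueError("no isokinetic trials provided")
    lo, hi = window
    per_velocity = {}
    for v, pairs in trials_by_velocity.items():
        if not pairs:
            raise ValueError(f"no trials at velocity {v}")
        best = None
        for trace, moment in pairs:
            mask = (trace.angle >= lo) & (trace.angle <= hi)
            if not mask.any():
                raise ValueError(
                    f"no samples inside the window [{lo}, {hi}] deg at velocity {v}"
                )
            p = float(compute_power(moment, trace.angvel)[mask].mean())
            best = p if best is None else max(best, p)
        per_velocity[float(v)] = best
    best_v = min(
        per_velocity, key=lambda v: (-per_velocity[v], v)
    )  # ties -> lowest velocity
    return PowerResult(
        max_power=per_velocity[best_v],
        velocity_at_max=best_v,
        per_velocity_power=dict(sorted(per_velocity.items())),
    )


def analyze_subject_dynamometry(
    subject: SubjectData,
    baselines_isokinetic: dict,
    baselines_isometric: dict,
    window=POWER_WINDOW_DEG,
) -> dict:
    """Per-subject functional measures from raw traces.

    Fits the antagonist calibration, runs the correction chain on every
    trial (matching each to its baseline) and extracts the MVC moment and
    the maximum mechanical power.
    """
    fit = fit_emg_moment(subject.ta_emg, subject.ta_moment)
    foot_mass = subject.meta.get("foot_mass_kg", FOOT_MASS_FRACTION * subject.meta["body_mass_kg"])
    lever = subject.meta.get("foot_com_lever_m", FOOT_COM_LEVER_M)

    iso_corrected = []
    for trace in subject.isometric:
        angle = float(trace.angle[0])
        base = baselines_isometric.get(angle)
        iso_corrected.append(correct_trace(trace, base, foot_mass, fit, lever))
    mvc = extract_mvc(iso_corrected)

    trials = {}
    for v, traces in subject.isokinetic.items():
        base = baselines_isokinetic.get(v)
        trials[v] = [(t, correct_trace(t, base, foot_mass, fit, lever)) for t in traces]
    power = extract_max_power(trials, window=window)
    return {
        "mvc_moment_Nm": mvc,
        "max_power_W": power.max_power,
        "velocity_at_max_deg_s": power.velocity_at_max,
        "per_velocity_power_W": power.per_velocity_power,
        "emg_fit": fit,
    }
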