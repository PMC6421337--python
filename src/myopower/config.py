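"""Simulation configuration: cohort distributions and corruption settings.

The synthetic cohort emulates a dynamometry/MRI/biopsy study of the human
soleus muscle in young male adults (n = 20).  Cohort-level parameters are
drawn from truncated normal distributions whose *realised* (post-truncation)
means equal the stated means: the parent location is shifted internally so
that truncation does not bias the cohort mean away from the published
cohort statistics the generator is calibrated to.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .fibre_mechanics import DEFAULT_CURVATURE, DEFAULT_VMAX_RATIO

__all__ = ["TruncNorm", "SimConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class TruncNorm:
    """Truncated normal distribution matching a target mean under truncation.

    ``mean`` is the mean of the *truncated* distribution; the parent
    location is solved for once so that samples average to ``mean`` even
    with asymmetric bounds.  ``sd`` is the parent standard deviation.
    """

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if not self.upper > self.lower:
            raise ValueError(
                f"degenerate truncation: upper ({self.upper}) <= lower ({self.lower})"
            )
        if self.sd > 0 and not (self.lower < self.mean < self.upper):
            raise ValueError(
                f"target mean {self.mean} must lie inside ({self.lower}, {self.upper})"
            )

    @cached_property
    def _parent_loc(self) -> float:
        if self.sd == 0:
            return self.mean
        if math.isinf(self.lower) and math.isinf(self.upper):
            return self.mean

        def truncated_mean(loc: float) -> float:
            a = (self.lower - loc) / self.sd
            b = (self.upper - loc) / self.sd
            return float(truncnorm.mean(a, b, loc=loc, scale=self.sd))

        lo, hi = self.mean - 6 * self.sd, self.mean + 6 * self.sd
        return float(brentq(lambda m: truncated_mean(m) - self.mean, lo, hi, xtol=1e-10))

    def sample(self, rng: np.random.Generator, size=None):
        """Draw samples; deterministic given ``rng`` state."""
        if self.sd == 0:
            return (
                float(self.mean) if size is None else np.full(size, float(self.mean))
            )
        loc = self._parent_loc
        a = (self.lower - loc) / self.sd
        b = (self.upper - loc) / self.sd
        out = truncnorm.rvs(a, b, loc=loc, scale=self.sd, size=size, random_state=rng)
        return float(out) if size is None else out

    def to_dict(self) -> dict:
        d = {"mean": self.mean, "sd": self.sd}
        if math.isfinite(self.lower):
            d["lower"] = self.lower
        if math.isfinite(self.upper):
            d["upper"] = self.upper
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruncNorm":
        return cls(
            mean=float(d["mean"]),
            sd=float(d["sd"]),
            lower=float(d.get("lower", -math.inf)),
            upper=float(d.get("upper", math.inf)),
        )


# Calibrated generator constants: specific tension (N/cm^2) and slow-fibre
# maximum shortening velocity (fibre lengths/s) are solved once by
# ``synthetic_cohort.calibrate_generator`` so that the simulated cohort means
# of extracted maximum mechanical power and of the velocity at maximum power
# match the published cohort means (138 W at 139 deg/s); see docs/methods.md.
CALIBRATED_SPECIFIC_TENSION = 38.46
CALIBRATED_VMAX_I = 7.171

_TN = TruncNorm  # local alias for default factories


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic cohort generator.

    Distribution fields are :class:`TruncNorm`; scalar fields are either
    physiological constants or corruption-layer magnitudes (set a magnitude
    to zero, or a range to a point, to disable a layer).
    """

    master_seed: int = 0
    n_subjects: int = 20

    # --- anthropometry & muscle morphology (cohort distributions) ---
    body_mass_kg: TruncNorm = field(default_factory=lambda: _TN(74.0, 9.0, 50.0, 110.0))
    phi_type_ii: TruncNorm = field(default_factory=lambda: _TN(0.206, 0.111, 0.02, 0.60))
    volume_cm3: TruncNorm = field(default_factory=lambda: _TN(483.0, 84.0, 250.0, 760.0))
    fibre_length_cm: TruncNorm = field(default_factory=lambda: _TN(4.0, 0.3, 3.0, 5.0))
    moment_arm_cm: TruncNorm = field(default_factory=lambda: _TN(5.0, 0.3, 4.0, 6.0))
    specific_tension_n_cm2: TruncNorm = field(
        default_factory=lambda: _TN(CALIBRATED_SPECIFIC_TENSION, 2.5, 20.0, 60.0)
    )
    muscle_length_cm: TruncNorm = field(default_factory=lambda: _TN(27.5, 1.5, 22.0, 33.0))
    shape_a: TruncNorm = field(default_factory=lambda: _TN(2.5, 0.06, 2.2, 2.8))
    shape_b: TruncNorm = field(default_factory=lambda: _TN(2.5, 0.06, 2.2, 2.8))
    ta_gain_nm: TruncNorm = field(default_factory=lambda: _TN(40.0, 5.0, 20.0, 60.0))

    # --- Hill mechanics ---
    curvature_type_i: float = DEFAULT_CURVATURE
    curvature_type_ii: float = DEFAULT_CURVATURE
    vmax_i_norm: float = CALIBRATED_VMAX_I  # fibre lengths / s
    vmax_ratio: float = DEFAULT_VMAX_RATIO

    # --- voluntary activation during isokinetic efforts (per velocity) ---
    activation_low: float = 0.92
    activation_high: float = 1.0

    # --- corruption layers ---
    sensor_noise_sd_nm: float = 2.0
    axis_ratio_low: float = 0.9  # d_ankle / d_dyn
    axis_ratio_high: float = 1.1
    footplate_amp_nm: float = 4.0
    footplate_inertia_kg_m2: float = 0.02
    baseline_repeats: int = 8  # unloaded-footplate passes averaged per baseline
    foot_gravity: bool = True
    ta_coactivation: float = 0.05  # antagonist EMG level during plantar flexion
    ta_calib_noise_sd_nm: float = 2.0
    ta_calib_n_pairs: int = 200
    contour_cv: float = 0.02
    biopsy_n_fibres: int = 150
    fibre_area_um2_type_i: float = 4500.0
    fibre_area_um2_type_ii: float = 3500.0
    fibre_area_cv: float = 0.3

    # --- acquisition geometry & protocol ---
    sample_rate_hz: float = 250.0
    slice_thickness_mm: float = 1.8
    velocities_deg_s: tuple = (60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0)
    isometric_angles_deg: tuple = (0.0, -5.0, -10.0)  # plantar flexion positive
    rom_deg: tuple = (-20.0, 20.0)
    ramp_angle_deg: float = 4.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        for name in (
            "sensor_noise_sd_nm",
            "footplate_amp_nm",
            "ta_coactivation",
            "ta_calib_noise_sd_nm",
            "contour_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.activation_low <= self.activation_high <= 1.0):
            raise ValueError("activation range must satisfy 0 < low <= high <= 1")
        if not (0 < self.axis_ratio_low <= self.axis_ratio_high):
            raise ValueError("axis ratio range must be positive and ordered")
        if self.biopsy_n_fibres < 1:
            raise ValueError("biopsy_n_fibres must be >= 1")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def noise_free(self) -> "SimConfig":
        """Copy with every corruption layer disabled and full activation.

        Biopsy fibre sampling remains (it is the measurement itself, not an
        instrument corruption); set ``biopsy_n_fibres`` large to shrink it.
        """
        return self.replace(
            sensor_noise_sd_nm=0.0,
            axis_ratio_low=1.0,
            axis_ratio_high=1.0,
            footplate_amp_nm=0.0,
            foot_gravity=False,
            ta_coactivation=0.0,
            ta_calib_noise_sd_nm=0.0,
            contour_cv=0.0,
            activation_low=1.0,
            activation_high=1.0,
        )

    # --- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, TruncNorm):
                out[f.name] = v.to_dict()
            elif isinstance(v, tuple):
                out[f.name] = list(v)
            else:
                out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for name, value in d.items():
            if name not in fields:
                raise ValueError(f"unknown config field: {name!r}")
            default = fields[name].default_factory() if fields[name].default_factory is not dataclasses.MISSING else fields[name].default  # type: ignore[misc]
            if isinstance(default, TruncNorm):
                kwargs[name] = TruncNorm.from_dict(value)
            elif isinstance(default, tuple):
                kwargs[name] = tuple(value)
            else:
                kwargs[name] = value
        return cls(**kwargs)


def save_config(config: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path) -> SimConfig:
    return SimConfig.from_dict(yaml.safe_load(Path(path).read_text()))
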