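"""Morphometry and histology measures.

Muscle volume is the integral of MRI contour cross-sectional areas along
the muscle's longitudinal axis (contiguous slabs, no inter-slice gap);
muscle length is the distance between the two marginal slices with
non-zero area.  The simplified volume estimate replaces the full contour
integration with ``coefficient * ACSA_max * length``, the coefficient being
fitted once per shape family.

Histology reduces a fibre table (type I/II, area per fibre) or a labelled
two-class section mask to the percentage of total fibre area occupied by
type II fibres:

    Area%TypeII = TotalArea_II / (TotalArea_I + TotalArea_II) * 100
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ContourStack",
    "BiopsySample",
    "reconstruct_volume",
    "muscle_length",
    "max_acsa",
    "estimate_volume_simple",
    "fit_shape_coefficient",
    "area_percent_type_ii",
    "measure_mask_areas",
]

FIBRE_TYPES = ("I", "II")

# Labelled-mask palette: 0 background, 1 type I, 2 type II.
MASK_LABELS = {0: "background", 1: "I", 2: "II"}


@dataclass(frozen=True)
class ContourStack:
    """Ordered slice cross-sectional areas (cm^2) at fixed slice thickness (mm)."""

    slice_thickness_mm: float
    areas_cm2: np.ndarray

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas_cm2, dtype=float)
        object.__setattr__(self, "areas_cm2", areas)
        if not self.slice_thickness_mm > 0:
            raise ValueError("slice_thickness_mm must be > 0")
        if areas.size < 2:
            raise ValueError("a contour stack needs at least 2 slices")
        if not np.all(np.isfinite(areas)) or np.any(areas < 0):
            raise ValueError("slice areas must be finite and >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"slice_index": np.arange(self.areas_cm2.size), "area_cm2": self.areas_cm2}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, slice_thickness_mm: float) -> "ContourStack":
        frame = frame.sort_values("slice_index")
        return cls(slice_thickness_mm, frame["area_cm2"].to_numpy(dtype=float))


@dataclass(frozen=True)
class BiopsySample:
    """Per-fibre type-and-area table from a needle biopsy section."""

    types: np.ndarray  # array of "I" / "II"
    areas_um2: np.ndarray
    section_id: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        types = np.asarray(self.types, dtype=object)
        areas = np.asarray(self.areas_um2, dtype=float)
        object.__setattr__(self, "types", types)
        object.__setattr__(self, "areas_um2", areas)
        if types.size < 1:
            raise ValueError("a biopsy sample needs at least one fibre")
        if types.size != areas.size:
            raise ValueError("types and areas must be aligned")
        bad = set(types.tolist()) - set(FIBRE_TYPES)
        if bad:
            raise ValueError(f"unknown fibre types: {sorted(bad)}")
        if np.any(areas <= 0):
            raise ValueError("fibre areas must be > 0")
        if self.section_id is not None:
            sid = np.asarray(self.section_id)
            if sid.size != types.size:
                raise ValueError("section_id must be aligned with fibres")
            object.__setattr__(self, "section_id", sid)

    def total_area(self, fibre_type: str) -> float:
        """Summed fibre area of one type, in um^2."""
        if fibre_type not in FIBRE_TYPES:
            raise ValueError(f"unknown fibre type {fibre_type!r}")
        return float(self.areas_um2[self.types == fibre_type].sum())

    def to_frame(self) -> pd.DataFrame:
        d = {
            "fibre_id": np.arange(self.types.size),
            "type": self.types,
            "area_um2": self.areas_um2,
        }
        if self.section_id is not None:
            d["section_id"] = self.section_id
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BiopsySample":
        sid = frame["section_id"].to_numpy() if "section_id" in frame else None
        return cls(
            frame["type"].to_numpy(dtype=object),
            frame["area_um2"].to_numpy(dtype=float),
            sid,
        )


def reconstruct_volume(stack: ContourStack) -> float:
    """Muscle volume (cm^3) as the slab sum ``sum(area_i) * thickness``.

    Slices are contiguous slabs (no inter-slice spacing), so the discrete
    integral is a plain Riemann sum of area times slice thickness.
    """
    return float(stack.areas_cm2.sum() * (stack.slice_thickness_mm / 10.0))


def muscle_length(stack: ContourStack) -> float:
    """Muscle length (cm): distance between the two marginal non-zero slices."""
    pos = np.flatnonzero(stack.areas_cm2 > 0)
    if pos.size < 2:
        raise ValueError("need at least 2 slices with positive area")
    return float((pos[-1] - pos[0]) * stack.slice_thickness_mm / 10.0)


def max_acsa(stack: ContourStack) -> float:
    """Maximum anatomical cross-sectional area (cm^2) over the stack."""
    return float(stack.areas_cm2.max())


def estimate_volume_simple(
    acsa_max_cm2: float, length_cm: float, shape_coefficient: float
) -> float:
    """Simplified volume estimate ``coefficient * ACSA_max * length`` (cm^3)."""
    for name, v in (
        ("acsa_max_cm2", acsa_max_cm2),
        ("length_cm", length_cm),
        ("shape_coefficient", shape_coefficient),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return float(shape_coefficient * acsa_max_cm2 * length_cm)


def fit_shape_coefficient(stacks: Iterable[ContourStack]) -> float:
    """Least-squares shape coefficient of a contour-stack family.

    Regresses reconstructed volume on ``ACSA_max * length`` through the
    origin; the coefficient is then frozen and reused by
    :func:`estimate_volume_simple` for new members of the same family.
    """
    x = []
    y = []
    for stack in stacks:
        x.append(max_acsa(stack) * muscle_length(stack))
        y.append(reconstruct_volume(stack))
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size == 0:
        raise ValueError("need at least one stack to fit a shape coefficient")
    return float((x * y).sum() / (x * x).sum())


def area_percent_type_ii(sample: BiopsySample, per_section: bool = False) -> float:
    """Percentage of total fibre area occupied by type II fibres, in [0, 100].

    Multi-section samples are pooled before taking the ratio (single-ratio
    form); ``per_section=True`` instead averages per-section percentages.
    """
    if per_section and sample.section_id is not None:
        vals = []
        for sid in np.unique(sample.section_id):
            m = sample.section_id == sid
            sub = BiopsySample(sample.types[m], sample.areas_um2[m])
            vals.append(area_percent_type_ii(sub))
        return float(np.mean(vals))
    total_i = sample.total_area("I")
    total_ii = sample.total_area("II")
    total = total_i + total_ii
    if not total > 0:
        raise ValueError("total fibre area is zero")
    return float(total_ii / total * 100.0)


def measure_mask_areas(mask, pixel_size_um2: float) -> Mapping[str, float]:
    """Per-type total areas (um^2) from a labelled two-class section raster.

    ``mask`` is an integer array (or a path to an 8-bit palette image) with
    labels 0 = background, 1 = type I, 2 = type II; any other label raises.
    """
    if not pixel_size_um2 > 0:
        raise ValueError("pixel_size_um2 must be > 0")
    if isinstance(mask, (str, bytes)) or hasattr(mask, "__fspath__"):
        import imageio.v3 as iio

        mask = iio.imread(mask)
    mask = np.asarray(mask)
    labels = np.unique(mask)
    unknown = set(labels.tolist()) - set(MASK_LABELS)
    if unknown:
        raise ValueError(f"unknown mask labels: {sorted(unknown)}")
    return {
        "I": float((mask == 1).sum() * pixel_size_um2),
        "II": float((mask == 2).sum() * pixel_size_um2),
    }
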