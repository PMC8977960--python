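"""Quantification of abdominal muscle mass from proton-density fat-fraction maps.

A single axial slice at the lower endplate of L3 is quantified from two
inputs: a PDFF map whose intensities encode fat fraction on a 0-1000 scale
(0-100 %), and eight binary compartment masks (left/right psoas major,
quadratus lumborum, rectus abdominis, autochthonous back muscles) drawn on
the same grid.  The derived measures are:

* ``csa_total``    -- total muscle cross-sectional area: every mask voxel,
  fatty septa included, times the in-plane voxel area (mm**2).
* ``csa_fatfree``  -- fat-free area via the intensity-threshold rule
  ``CSA_total * N(<=200) / N(<=1000)``: voxels at or below intensity 200
  (20 % fat) contain at most intramyocellular lipids; anything above 200
  is counted as extramyocellular adipose tissue and excluded.
* ``ammi_total``, ``ammi_fatfree`` -- the areas normalised to body height
  squared (mm**2/m**2), the abdominal muscle mass indices.
* ``ratio``        -- 100 * AMMI_fatfree / AMMI_total, the share of
  functionally contractile tissue (%).
* ``pdff_muscle``  -- myosteatosis: mean PDFF over the *entire* mask union
  (septa included), in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "COMPARTMENTS",
    "FATFREE_THRESHOLD",
    "INTENSITY_MAX",
    "intensity_to_percent",
    "percent_to_intensity",
    "PDFFMap",
    "CompartmentMaskSet",
    "MuscleMeasures",
    "compute_csa_total",
    "compute_csa_fatfree",
    "compute_ammi",
    "compute_ratio",
    "compute_pdff_muscle",
    "quantify_subject",
]

#: The eight segmented abdominal compartments, in mask-label order (1..8).
COMPARTMENTS = (
    "psoas_L",
    "psoas_R",
    "quadratus_L",
    "quadratus_R",
    "rectus_L",
    "rectus_R",
    "autochthonous_L",
    "autochthonous_R",
)

#: Fat-free intensity threshold on the 0-1000 PDFF scale (== 20 % fat).
FATFREE_THRESHOLD = 200
INTENSITY_MAX = 1000


def intensity_to_percent(value):
    """Convert a 0-1000 map intensity to percent fat fraction."""
    return np.asarray(value, dtype=float) / (INTENSITY_MAX / 100.0)


def percent_to_intensity(percent):
    """Convert percent fat fraction to the 0-1000 map intensity scale."""
    return np.asarray(percent, dtype=float) * (INTENSITY_MAX / 100.0)


@dataclass
class PDFFMap:
    """2-D proton-density fat-fraction map.

    intensities are stored on the 0-1000 scale; values outside [0, 1000] are
    clamped on construction and the clamped-voxel count retained (analogous
    to flagging reconstruction artefacts rather than silently proceeding).
    """

    intensities: np.ndarray
    pixel_spacing: float  # mm per in-plane voxel edge (isotropic)
    slice_label: str = "L3"
    n_clamped: int = field(default=0, init=False)

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2:
            raise ValueError("PDFF map must be a 2-D array")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive (mm)")
        out_of_range = (arr < 0) | (arr > INTENSITY_MAX)
        self.n_clamped = int(out_of_range.sum())
        if self.n_clamped:
            warnings.warn(
                f"clamped {self.n_clamped} voxel(s) outside [0, {INTENSITY_MAX}]",
                stacklevel=2,
            )
            arr = np.clip(arr, 0, INTENSITY_MAX)
        self.intensities = arr

    @property
    def voxel_area_mm2(self) -> float:
        """In-plane voxel area (mm**2); slice thickness never enters CSA."""
        return self.pixel_spacing**2


@dataclass
class CompartmentMaskSet:
    """Eight binary compartment masks congruent with a PDFF map."""

    masks: dict  # compartment name -> 2-D bool array

    def __post_init__(self):
        missing = set(COMPARTMENTS) - set(self.masks)
        if missing:
            raise ValueError(f"missing compartment masks: {sorted(missing)}")
        shapes = {np.asarray(m).shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError("compartment masks must share one grid shape")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        stacked = np.stack([self.masks[c] for c in COMPARTMENTS])
        if (stacked.sum(axis=0) > 1).any():
            raise ValueError("compartment masks overlap; they must be disjoint")

    @property
    def shape(self):
        return next(iter(self.masks.values())).shape

    def union(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for m in self.masks.values():
            out |= m
        return out

    def to_label_image(self) -> np.ndarray:
        """Single label image: 0 background, 1..8 in COMPARTMENTS order."""
        lab = np.zeros(self.shape, dtype=np.uint8)
        for i, c in enumerate(COMPARTMENTS, start=1):
            lab[self.masks[c]] = i
        return lab

    @classmethod
    def from_label_image(cls, label_img) -> "CompartmentMaskSet":
        lab = np.asarray(label_img)
        return cls({c: lab == i for i, c in enumerate(COMPARTMENTS, start=1)})


@dataclass
class MuscleMeasures:
    """Per-subject MRI muscle-mass outputs."""

    csa_total: float  # mm**2
    csa_fatfree: float  # mm**2
    ammi_total: float  # mm**2/m**2
    ammi_fatfree: float  # mm**2/m**2
    ratio: float  # %
    pdff_muscle: float  # %
    compartment_csa: dict = field(default_factory=dict)  # per-compartment mm**2

    def __post_init__(self):
        if not 0 <= self.csa_fatfree <= self.csa_total + 1e-9:
            raise ValueError("require 0 <= csa_fatfree <= csa_total")
        if not 0 <= self.pdff_muscle <= 100:
            raise ValueError("pdff_muscle must lie in [0, 100] %")


def _check_congruent(masks: CompartmentMaskSet, pdff: PDFFMap):
    if masks.shape != pdff.intensities.shape:
        raise ValueError(
            f"mask grid {masks.shape} does not match map grid "
            f"{pdff.intensities.shape}"
        )


def compute_csa_total(masks: CompartmentMaskSet, pdff: PDFFMap) -> float:
    """Total muscle CSA (mm**2): all mask voxels regardless of intensity."""
    _check_congruent(masks, pdff)
    n = int(masks.union().sum())
    if n == 0:
        warnings.warn("empty mask set: CSA_total = 0", stacklevel=2)
    return n * pdff.voxel_area_mm2


def compute_csa_fatfree(
    masks: CompartmentMaskSet, pdff: PDFFMap, threshold: float = FATFREE_THRESHOLD
) -> float:
    """Fat-free CSA (mm**2) via the threshold rule.

    CSA_fatfree = CSA_total * N(<= threshold) / N(<= 1000); with intensities
    clamped to [0, 1000] the denominator is the full mask voxel count, so the
    result equals (fat-free voxel count) * voxel area.  The comparison is
    inclusive: a voxel exactly at the threshold still counts as fat-free.
    """
    if not 0 < threshold <= INTENSITY_MAX:
        raise ValueError(f"threshold must lie in (0, {INTENSITY_MAX}]")
    _check_congruent(masks, pdff)
    union = masks.union()
    n_total = int(union.sum())
    if n_total == 0:
        return 0.0
    vals = pdff.intensities[union]
    n_fatfree = int((vals <= threshold).sum())
    csa_total = n_total * pdff.voxel_area_mm2
    return csa_total * n_fatfree / n_total


def compute_ammi(csa_mm2: float, height_m: float) -> float:
    """Abdominal muscle mass index (mm**2/m**2): CSA / height**2."""
    if not height_m > 0:
        raise ValueError("height_m must be positive")
    return csa_mm2 / height_m**2


def compute_ratio(ammi_fatfree: float, ammi_total: float) -> float:
    """Ratio AMMI_fatfree / AMMI_total in percent."""
    if not ammi_total > 0:
        raise ValueError("ratio undefined for non-positive AMMI_total")
    if ammi_fatfree > ammi_total * (1 + 1e-12):
        raise ValueError("ammi_fatfree exceeds ammi_total")
    return 100.0 * ammi_fatfree / ammi_total


def compute_pdff_muscle(masks: CompartmentMaskSet, pdff: PDFFMap) -> float:
    """Myosteatosis (%): mean intensity over the full mask union / 10.

    The average runs over the *total* segmented compartments, fatty septa
    included, mirroring how total CSA is defined.
    """
    _check_congruent(masks, pdff)
    union = masks.union()
    if not union.any():
        raise ValueError("pdff_muscle undefined for an empty mask union")
    return float(pdff.intensities[union].mean()) / (INTENSITY_MAX / 100.0)


def quantify_subject(
    pdff: PDFFMap,
    masks: CompartmentMaskSet,
    height_m: float,
    threshold: float = FATFREE_THRESHOLD,
    subject_id: str | None = None,
) -> MuscleMeasures:
    """Full per-subject quantification at one axial slice."""
    _check_congruent(masks, pdff)
    union = masks.union()
    if not union.any():
        who = f" for subject {subject_id}" if subject_id else ""
        raise ValueError(f"empty compartment masks{who}: nothing to quantify")
    csa_total = compute_csa_total(masks, pdff)
    csa_fatfree = compute_csa_fatfree(masks, pdff, threshold)
    ammi_total = compute_ammi(csa_total, height_m)
    ammi_fatfree = compute_ammi(csa_fatfree, height_m)
    ratio = compute_ratio(ammi_fatfree, ammi_total)
    pdff_muscle = compute_pdff_muscle(masks, pdff)
    per_comp = {
        c: int(m.sum()) * pdff.voxel_area_mm2 for c, m in masks.masks.items()
    }
    return MuscleMeasures(
        csa_total=csa_total,
        csa_fatfree=csa_fatfree,
        ammi_total=ammi_total,
        ammi_fatfree=ammi_fatfree,
        ratio=ratio,
        pdff_muscle=pdff_muscle,
        compartment_csa=per_comp,
    )
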