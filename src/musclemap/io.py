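"""File I/O: cohort/measures CSVs and NIfTI map/mask pairs."""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .quant import CompartmentMaskSet, PDFFMap

__all__ = [
    "write_cohort", "read_cohort", "write_measures", "read_measures",
    "write_subject_images", "read_subject_images", "measures_to_row",
]

_CSV_FLOAT_FORMAT = "%.10g"  # fixed formatting keeps replays byte-identical


def write_cohort(cohort: pd.DataFrame, path):
    cohort.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_measures(measures: pd.DataFrame, path):
    measures.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def read_measures(path) -> pd.DataFrame:
    return pd.read_csv(path)


def measures_to_row(subject_id: str, m) -> dict:
    """Flatten a MuscleMeasures into one CSV row."""
    row = {
        "subject_id": subject_id,
        "csa_total": m.csa_total,
        "csa_fatfree": m.csa_fatfree,
        "ammi_total": m.ammi_total,
        "ammi_fatfree": m.ammi_fatfree,
        "ratio": m.ratio,
        "pdff_muscle": m.pdff_muscle,
    }
    for comp, csa in m.compartment_csa.items():
        row[f"csa_{comp}"] = csa
    return row


def _affine(pixel_spacing: float) -> np.ndarray:
    return np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])


def write_subject_images(subject_id, pdff_map: PDFFMap, masks: CompartmentMaskSet,
                         out_dir):
    """Write `<id>_pdff.nii.gz` (float32, 0-1000 scale) and `<id>_mask.nii.gz`
    (uint8 labels 1-8 in compartment order, 0 background)."""
    os.makedirs(out_dir, exist_ok=True)
    aff = _affine(pdff_map.pixel_spacing)
    img = nib.Nifti1Image(
        pdff_map.intensities.astype(np.float32)[:, :, None], aff
    )
    img.header.set_zooms((pdff_map.pixel_spacing, pdff_map.pixel_spacing, 1.0))
    nib.save(img, os.path.join(out_dir, f"{subject_id}_pdff.nii.gz"))
    lab = nib.Nifti1Image(masks.to_label_image()[:, :, None], aff)
    nib.save(lab, os.path.join(out_dir, f"{subject_id}_mask.nii.gz"))


def read_subject_images(subject_id, image_dir):
    """Load a NIfTI pair back into (PDFFMap, CompartmentMaskSet)."""
    pdff_path = os.path.join(image_dir, f"{subject_id}_pdff.nii.gz")
    mask_path = os.path.join(image_dir, f"{subject_id}_mask.nii.gz")
    pdff_img = nib.load(pdff_path)
    spacing = float(pdff_img.header.get_zooms()[0])
    intensities = np.asarray(pdff_img.dataobj)[:, :, 0].astype(float)
    label = np.asarray(nib.load(mask_path).dataobj)[:, :, 0]
    return (
        PDFFMap(intensities, pixel_spacing=spacing),
        CompartmentMaskSet.from_label_image(label),
    )
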