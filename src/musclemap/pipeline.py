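"""Pipeline orchestration: simulate -> quantify -> analyze, with a manifest.

Each stage is a thin wrapper over the library so results are reproducible
from a config file and a seed alone.  Per-subject quality events (clamped
voxels, PDFF feasibility projections) are aggregated into the run manifest
rather than silently dropped — the source protocol likewise excluded
subjects for image artefacts instead of quantifying them blindly.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import io as mio
from .cohort import CohortModel
from .config import ConfigError, GeneratorConfig, load_config, save_config
from .phantom import simulate_images
from .quant import FATFREE_THRESHOLD, quantify_subject
from .stats import run_full_analysis

__all__ = ["RunManifest", "run_pipeline", "quantify_directory", "make_fixtures"]


@dataclass
class RunManifest:
    seed: int
    config_digest: str
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    warnings: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _config_digest(cfg: GeneratorConfig) -> str:
    from .config import _to_plain
    import yaml

    blob = yaml.safe_dump(_to_plain(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    config,
    out_dir,
    seed: int | None = None,
    skip_images: bool = False,
    write_images: bool = False,
) -> RunManifest:
    """Execute the full synthetic study: cohort, slices, measures, report.

    ``skip_images`` performs a cohort-only statistical run, using the
    generator's per-subject targets in place of image-derived measures.
    ``write_images`` additionally saves every NIfTI pair (slow for large n).
    """
    if not isinstance(config, GeneratorConfig):
        config = load_config(config)
    seed = config.seed if seed is None else int(seed)
    os.makedirs(out_dir, exist_ok=True)
    manifest = RunManifest(
        seed=seed,
        config_digest=_config_digest(config),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    stage = "simulate"
    try:
        model = CohortModel(config)
        cohort = model.sample(config.n_subjects, seed)
        cohort_path = os.path.join(out_dir, "cohort.csv")
        mio.write_cohort(cohort, cohort_path)
        manifest.stages.append(stage)
        manifest.outputs["cohort"] = cohort_path

        stage = "quantify"
        if skip_images:
            measures = pd.DataFrame({
                "subject_id": cohort["subject_id"],
                "csa_total": cohort["target_csa_total"],
                "csa_fatfree": cohort["target_ratio"] * cohort["target_csa_total"],
                "ammi_total": cohort["target_ammi_total"],
                "ammi_fatfree": cohort["target_ammi_fatfree"],
                "ratio": 100.0 * cohort["target_ratio"],
                "pdff_muscle": cohort["target_pdff_muscle"],
            })
            manifest.warnings["skip_images"] = True
        else:
            rows, n_projected, n_clamped = [], 0, 0
            image_dir = os.path.join(out_dir, "images")
            for row, pdff_map, mask_set, info in simulate_images(
                cohort, config, seed=seed
            ):
                m = quantify_subject(
                    pdff_map, mask_set, row["height"],
                    subject_id=row["subject_id"],
                )
                rows.append(mio.measures_to_row(row["subject_id"], m))
                n_projected += info["projected"]
                n_clamped += pdff_map.n_clamped
                if write_images:
                    mio.write_subject_images(
                        row["subject_id"], pdff_map, mask_set, image_dir
                    )
            measures = pd.DataFrame(rows)
            manifest.warnings["pdff_feasibility_projections"] = n_projected
            manifest.warnings["clamped_voxels"] = n_clamped
            if write_images:
                manifest.outputs["images"] = image_dir
        measures_path = os.path.join(out_dir, "measures.csv")
        mio.write_measures(measures, measures_path)
        manifest.stages.append(stage)
        manifest.outputs["measures"] = measures_path

        stage = "analyze"
        tables = run_full_analysis(cohort, measures, bonferroni_m=None)
        for name, tbl in tables.items():
            path = os.path.join(out_dir, f"{name}.csv")
            tbl.to_csv(path, index=False, float_format="%.10g")
            manifest.outputs[name] = path
        manifest.stages.append(stage)
    except Exception as exc:
        manifest.warnings["failed_stage"] = stage
        manifest.write(os.path.join(out_dir, "manifest.json"))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    config_path = os.path.join(out_dir, "config.yaml")
    save_config(config, config_path)
    manifest.outputs["config"] = config_path
    manifest.write(os.path.join(out_dir, "manifest.json"))
    return manifest


def quantify_directory(image_dir, cohort_path, out_path,
                       threshold: float = FATFREE_THRESHOLD) -> pd.DataFrame:
    """Quantify every `<id>_pdff.nii.gz` / `<id>_mask.nii.gz` pair on disk."""
    cohort = mio.read_cohort(cohort_path)
    heights = dict(zip(cohort["subject_id"], cohort["height"]))
    rows = []
    for sid, height in heights.items():
        pdff_path = os.path.join(image_dir, f"{sid}_pdff.nii.gz")
        if not os.path.exists(pdff_path):
            continue
        pdff_map, mask_set = mio.read_subject_images(sid, image_dir)
        m = quantify_subject(pdff_map, mask_set, height,
                             threshold=threshold, subject_id=sid)
        rows.append(mio.measures_to_row(sid, m))
    if not rows:
        raise FileNotFoundError(f"no image pairs found in {image_dir}")
    measures = pd.DataFrame(rows)
    mio.write_measures(measures, out_path)
    return measures


def make_fixtures(out_dir):
    """Write tiny hand-checkable fixtures for tests and demos.

    A 12 x 12 PDFF map with a known voxel split (30 of 100 mask voxels above
    the fat-free threshold), a 4-subject cohort CSV, and an
    expected-measures CSV computed by an explicit voxel-by-voxel recount
    (independent of the vectorised implementation).  Regeneration is
    idempotent: the fixtures contain no randomness.
    """
    import numpy as np

    from .quant import COMPARTMENTS, CompartmentMaskSet, PDFFMap

    os.makedirs(out_dir, exist_ok=True)
    grid = 12
    spacing = 2.0
    intensities = np.full((grid, grid), 800.0)  # fat background
    # 100 mask voxels: a 10 x 10 block split into eight horizontal bands
    label = np.zeros((grid, grid), dtype=int)
    block_rows = [(0, 13), (1, 13), (2, 13), (3, 13),
                  (4, 12), (5, 12), (6, 12), (7, 12)]
    flat = [(r, c) for r in range(1, 11) for c in range(1, 11)]
    pos = 0
    for comp_idx, (band, count) in enumerate(block_rows, start=1):
        for _ in range(count):
            r, c = flat[pos]
            label[r, c] = comp_idx
            pos += 1
    assert pos == 100
    # 30 voxels above threshold (septa at 500), 70 at 150 (fat-free)
    mask_coords = [(r, c) for r in range(1, 11) for c in range(1, 11)]
    for i, (r, c) in enumerate(mask_coords):
        intensities[r, c] = 500.0 if i < 30 else 150.0
    np.savetxt(os.path.join(out_dir, "fixture_pdff.txt"), intensities, fmt="%.1f",
               header=f"pixel_spacing_mm={spacing}")
    np.savetxt(os.path.join(out_dir, "fixture_mask.txt"), label, fmt="%d",
               header="labels 1-8 = " + ",".join(COMPARTMENTS))

    cohort = pd.DataFrame({
        "subject_id": ["F01", "F02", "F03", "F04"],
        "height": [2.0, 1.7, 1.6, 1.8],
        "sex": ["male", "female", "female", "male"],
        "age": [50.0, 60.0, 45.0, 70.0],
    })
    cohort.to_csv(os.path.join(out_dir, "fixture_cohort.csv"), index=False)

    # expected measures via naive recount
    pdff_map = PDFFMap(intensities, pixel_spacing=spacing)
    masks = CompartmentMaskSet.from_label_image(label)
    n_total = n_ff = 0
    acc = 0.0
    for r in range(grid):
        for c in range(grid):
            if label[r, c] > 0:
                n_total += 1
                acc += intensities[r, c]
                if intensities[r, c] <= 200:
                    n_ff += 1
    rows = []
    for _, subj in cohort.iterrows():
        csa_total = n_total * spacing**2
        csa_ff = csa_total * n_ff / n_total
        h2 = subj["height"] ** 2
        rows.append({
            "subject_id": subj["subject_id"],
            "csa_total": csa_total,
            "csa_fatfree": csa_ff,
            "ammi_total": csa_total / h2,
            "ammi_fatfree": csa_ff / h2,
            "ratio": 100.0 * n_ff / n_total,
            "pdff_muscle": acc / n_total / 10.0,
        })
    pd.DataFrame(rows).to_csv(
        os.path.join(out_dir, "fixture_expected_measures.csv"), index=False
    )
    return out_dir
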