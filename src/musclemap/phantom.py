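"""Synthetic axial PDFF slices with compartment masks.

Each subject's slice is a digital phantom built to reproduce that subject's
target quantification exactly (up to voxel rounding): eight disjoint
ellipse-shaped compartments whose summed voxel area equals the target total
CSA, a contiguous-cluster septum population of high-fat voxels (> 200 on the
0-1000 scale, i.e. extramyocellular fat) sized so the fat-free voxel share
equals the target ratio, and intramyocellular intensities (<= 200) whose
mean is solved so the mask-wide mean equals the target PDFF_muscle.

No multi-echo Dixon signal model is simulated; the map is generated directly
on the 0-1000 intensity scale.  The phantom therefore exercises the
quantification arithmetic, not fat-water separation.
"""

from __future__ import annotations

import numpy as np

from .config import GeneratorConfig
from .quant import COMPARTMENTS, PDFFMap, CompartmentMaskSet, INTENSITY_MAX

__all__ = ["generate_pdff_slice", "simulate_images", "plan_intensities"]

_CELL_LAYOUT = {
    # compartment -> (row block, col block) in a 2 x 4 grid of cells
    "rectus_L": (0, 1),
    "rectus_R": (0, 2),
    "quadratus_L": (0, 0),
    "quadratus_R": (0, 3),
    "psoas_L": (1, 1),
    "psoas_R": (1, 2),
    "autochthonous_L": (1, 0),
    "autochthonous_R": (1, 3),
}
_CELL_MARGIN = 1  # voxels kept free at every cell edge, guarantees disjointness


def _apportion(total: int, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of `total` by `fractions`."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def _ellipse_mask(box_shape, n_voxels, aspect, rng):
    """Boolean mask of exactly n_voxels forming a filled quasi-ellipse.

    Voxels inside the box are ranked by an anisotropic quadratic metric
    around a jittered centre and the n smallest are taken; level sets of the
    metric are convex, so the digitized region is 4-connected.
    """
    nr, nc = box_shape
    capacity = (nr - 2 * _CELL_MARGIN) * (nc - 2 * _CELL_MARGIN)
    if n_voxels > capacity:
        raise ValueError(
            f"compartment needs {n_voxels} voxels but its cell holds {capacity}; "
            "increase grid_size"
        )
    cr = nr / 2 + rng.integers(-2, 3)
    cc = nc / 2 + rng.integers(-2, 3)
    rr, cols = np.mgrid[0:nr, 0:nc]
    # aspect = col half-axis / row half-axis (< 1 means taller than wide)
    metric = (rr - cr) ** 2 + ((cols - cc) / aspect) ** 2
    metric[:_CELL_MARGIN, :] = np.inf
    metric[nr - _CELL_MARGIN:, :] = np.inf
    metric[:, :_CELL_MARGIN] = np.inf
    metric[:, nc - _CELL_MARGIN:] = np.inf
    flat = metric.ravel()
    idx = np.argpartition(flat, n_voxels - 1)[:n_voxels] if n_voxels else np.array([], int)
    mask = np.zeros(nr * nc, dtype=bool)
    mask[idx] = True
    return mask.reshape(nr, nc)


def _septum_voxels(comp_mask, n_septum, rng):
    """Pick n_septum voxels of one compartment as contiguous fat clusters."""
    coords = np.argwhere(comp_mask)
    n = len(coords)
    if n_septum >= n:
        return coords
    if n_septum == 0:
        return coords[:0]
    # cluster count grows with the septum budget (one per ~150 voxels)
    n_clusters = max(1, int(round(n_septum / 150)))
    seeds = coords[rng.choice(n, size=min(n_clusters, n), replace=False)]
    d = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    take = np.argpartition(d, n_septum - 1)[:n_septum]
    return coords[take]


def plan_intensities(target_ratio, target_pdff, n_voxels, septum_range_pct):
    """Solve the two-class intensity plan for one subject.

    Returns (n_septum, septum_mean, intra_mean, achieved_pdff, projected):
    counts and class means on the 0-1000 intensity scale such that the
    fat-free voxel share equals target_ratio (to one voxel) and the mask
    mean equals 10 * achieved_pdff.  When the (ratio, PDFF) pair is jointly
    infeasible for the two-class model, PDFF is projected to the nearest
    feasible value (`projected` is True).
    """
    lo_i = septum_range_pct[0] * (INTENSITY_MAX / 100.0)
    hi_i = septum_range_pct[1] * (INTENSITY_MAX / 100.0)
    v = int(n_voxels)
    n_s = int(round((1.0 - target_ratio) * v))
    n_i = v - n_s
    total = target_pdff * (INTENSITY_MAX / 100.0) * v
    projected = False
    if n_s == 0:
        mu_i = total / v
        if mu_i > 200.0:
            mu_i, projected = 200.0, True
        return 0, 0.0, mu_i, mu_i / 10.0, projected
    if n_i == 0:
        m_s = float(np.clip(total / n_s, lo_i, hi_i))
        projected = abs(m_s * n_s - total) > 1e-6
        return n_s, m_s, 0.0, m_s / 10.0, projected
    m_mid = 0.5 * (lo_i + hi_i)
    mu_i = (total - n_s * m_mid) / n_i
    m_s = m_mid
    if mu_i < 0.0:
        m_s = float(np.clip(total / n_s, lo_i, m_mid))
        mu_i = (total - n_s * m_s) / n_i
        if mu_i < -1e-9:  # even the lowest septum mean overshoots the target
            mu_i, projected = 0.0, True
        mu_i = max(mu_i, 0.0)
    elif mu_i > 200.0:
        m_s = float(np.clip((total - 200.0 * n_i) / n_s, m_mid, hi_i))
        mu_i = (total - n_s * m_s) / n_i
        if mu_i > 200.0 + 1e-9:
            mu_i, projected = 200.0, True
        mu_i = min(mu_i, 200.0)
    achieved = (n_s * m_s + n_i * mu_i) / v / (INTENSITY_MAX / 100.0)
    return n_s, m_s, mu_i, achieved, projected


def generate_pdff_slice(subject, config: GeneratorConfig, rng=None):
    """Build the (PDFFMap, CompartmentMaskSet) pair for one subject.

    `subject` is any mapping with target_csa_total (mm**2), target_ratio,
    target_pdff_muscle (%) and optionally subject_id.  Returns
    (pdff_map, mask_set, info) where info records voxel counts and whether
    the feasibility projection was applied.
    """
    if rng is None:
        sid = abs(hash(str(subject.get("subject_id", "anon")))) % (2**31)
        rng = np.random.default_rng([int(config.seed), sid])
    csa = float(subject["target_csa_total"])
    ratio = float(subject["target_ratio"])
    pdff = float(subject["target_pdff_muscle"])
    if not (csa > 0 and 0 < ratio <= 1 and 0 <= pdff <= 100):
        raise ValueError(
            f"invalid targets for subject {subject.get('subject_id', '?')}: "
            f"csa={csa}, ratio={ratio}, pdff={pdff}"
        )
    g = config.grid_size
    voxel_area = config.pixel_spacing**2
    v_total = max(8, int(round(csa / voxel_area)))

    names = list(COMPARTMENTS)
    fractions = np.array([config.compartment_geometry[c]["fraction"] for c in names])
    per_comp = _apportion(v_total, fractions)

    cell_h, cell_w = g // 2, g // 4
    masks = {}
    for name, n_vox in zip(names, per_comp):
        br, bc = _CELL_LAYOUT[name]
        sub = _ellipse_mask(
            (cell_h, cell_w), int(n_vox),
            config.compartment_geometry[name]["aspect"], rng,
        )
        full = np.zeros((g, g), dtype=bool)
        full[br * cell_h:(br + 1) * cell_h, bc * cell_w:(bc + 1) * cell_w] = sub
        masks[name] = full
    mask_set = CompartmentMaskSet(masks)

    n_s, m_s, mu_i, achieved_pdff, projected = plan_intensities(
        ratio, pdff, v_total, config.septum_fat_fraction_range
    )
    lo_i = config.septum_fat_fraction_range[0] * (INTENSITY_MAX / 100.0)
    hi_i = config.septum_fat_fraction_range[1] * (INTENSITY_MAX / 100.0)

    # background: subcutaneous/visceral fat intensities
    img = rng.uniform(600.0, 950.0, size=(g, g))

    n_per_comp_septum = _apportion(n_s, per_comp / per_comp.sum())
    for name, n_vox, k_s in zip(names, per_comp, n_per_comp_septum):
        comp = masks[name]
        coords = np.argwhere(comp)
        # intramyocellular class, mean mu_i, kept <= 200 (inclusive threshold)
        w_i = min(mu_i, 200.0 - mu_i, 40.0)
        img[comp] = rng.uniform(mu_i - w_i, mu_i + w_i, size=len(coords))
        if k_s:
            sep = _septum_voxels(comp, int(k_s), rng)
            w_s = max(0.0, min(m_s - lo_i, hi_i - m_s, 15.0))
            img[sep[:, 0], sep[:, 1]] = rng.uniform(m_s - w_s, m_s + w_s, size=len(sep))

    pdff_map = PDFFMap(img, pixel_spacing=config.pixel_spacing)
    info = {
        "subject_id": subject.get("subject_id"),
        "n_voxels": v_total,
        "n_septum": int(n_s),
        "projected": bool(projected),
        "pdff_target_used": achieved_pdff,
    }
    return pdff_map, mask_set, info


def simulate_images(cohort, config: GeneratorConfig, seed=None):
    """Yield (subject row, PDFFMap, CompartmentMaskSet, info) per subject.

    Per-subject RNG streams are spawned from one seed sequence so results do
    not depend on consumption order.
    """
    seed = config.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(len(cohort))
    for (_, row), ss in zip(cohort.iterrows(), streams):
        rng = np.random.default_rng(ss)
        pdff_map, mask_set, info = generate_pdff_slice(row, config, rng=rng)
        yield row, pdff_map, mask_set, info
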