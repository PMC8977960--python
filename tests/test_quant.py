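"""Quantification arithmetic against a naive voxel-by-voxel oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from musclemap import (
    COMPARTMENTS,
    CompartmentMaskSet,
    PDFFMap,
    compute_ammi,
    compute_csa_fatfree,
    compute_csa_total,
    compute_pdff_muscle,
    compute_ratio,
    quantify_subject,
)


def naive_measures(intensities, label, spacing, threshold=200.0):
    """Brute-force recount, independent of the vectorised implementation."""
    n_total = n_ff = 0
    acc = 0.0
    rows, cols = np.asarray(intensities).shape
    for r in range(rows):
        for c in range(cols):
            if label[r, c] > 0:
                n_total += 1
                acc += intensities[r][c]
                if intensities[r][c] <= threshold:
                    n_ff += 1
    pdff = (acc / n_total) / 10.0 if n_total else None
    return n_total, n_ff, pdff


def random_case(rng, max_side=20):
    side = int(rng.integers(6, max_side + 1))
    intensities = rng.uniform(0, 1000, (side, side))
    label = rng.integers(0, 9, (side, side))
    spacing = float(rng.uniform(0.5, 3.0))
    return intensities, label, spacing


def as_objects(intensities, label, spacing):
    pdff = PDFFMap(intensities, pixel_spacing=spacing)
    masks = CompartmentMaskSet.from_label_image(label)
    return pdff, masks


def test_matches_bruteforce_oracle_on_random_grids(rng):
    for _ in range(200):
        intensities, label, spacing = random_case(rng)
        if (label > 0).sum() == 0:
            continue
        pdff, masks = as_objects(intensities, label, spacing)
        n_total, n_ff, exp_pdff = naive_measures(intensities, label, spacing)
        area = pdff.voxel_area_mm2
        # voxel counts agree exactly; areas are counts times the voxel area
        assert compute_csa_total(masks, pdff) == n_total * area
        assert compute_csa_fatfree(masks, pdff) == pytest.approx(
            n_total * area * n_ff / n_total, rel=1e-12
        )
        assert compute_pdff_muscle(masks, pdff) == pytest.approx(exp_pdff,
                                                                 rel=1e-12)


def test_csa_total_is_count_times_area():
    label = np.zeros((40, 40), dtype=int)
    label.flat[:1000] = 1  # 1000 voxels of psoas_L
    pdff, masks = as_objects(np.full((40, 40), 100.0), label, 1.5)
    assert compute_csa_total(masks, pdff) == pytest.approx(2250.0)


def test_empty_masks_give_zero_with_warning():
    pdff, masks = as_objects(np.zeros((8, 8)), np.zeros((8, 8), int), 1.0)
    with pytest.warns(UserWarning, match="empty mask"):
        assert compute_csa_total(masks, pdff) == 0.0
    with pytest.raises(ValueError, match="subject S1"):
        quantify_subject(pdff, masks, 1.7, subject_id="S1")


def test_fatfree_threshold_semantics():
    label = np.zeros((10, 10), dtype=int)
    label[:4, :] = 1
    intensities = np.zeros((10, 10))
    # half at 150, half at 500 -> fat-free share exactly one half
    intensities[:2, :] = 150.0
    intensities[2:4, :] = 500.0
    pdff, masks = as_objects(intensities, label, 2.0)
    assert compute_csa_fatfree(masks, pdff) == pytest.approx(
        0.5 * compute_csa_total(masks, pdff)
    )
    # everything below threshold -> fat-free equals total
    pdff2, _ = as_objects(np.full((10, 10), 100.0), label, 2.0)
    assert compute_csa_fatfree(masks, pdff2) == compute_csa_total(masks, pdff2)
    # a voxel exactly at 200 (20 % fat) still counts as fat-free
    pdff3, _ = as_objects(np.full((10, 10), 200.0), label, 2.0)
    assert compute_csa_fatfree(masks, pdff3) == compute_csa_total(masks, pdff3)


@given(data=st.data())
@settings(max_examples=30, deadline=None)
def test_fatfree_monotone_in_threshold(data):
    seed = data.draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    intensities, label, spacing = random_case(rng, max_side=15)
    label = np.where(label > 0, 1, 0)
    if label.sum() == 0:
        return
    pdff, masks = as_objects(intensities, label, spacing)
    thresholds = sorted(data.draw(
        st.lists(st.floats(1, 1000), min_size=2, max_size=5)
    ))
    vals = [compute_csa_fatfree(masks, pdff, t) for t in thresholds]
    assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
    assert compute_csa_fatfree(masks, pdff, 1000.0) == pytest.approx(
        compute_csa_total(masks, pdff)
    )


def test_scale_equivariance(rng):
    intensities, label, _ = random_case(rng)
    label = np.where(label > 0, 1 + label % 8, 0)
    if (label > 0).sum() == 0:
        label[0, 0] = 1
    p1, m1 = as_objects(intensities, label, 1.0)
    p2, m2 = as_objects(intensities, label, 2.0)
    r1 = quantify_subject(p1, m1, 1.7)
    r2 = quantify_subject(p2, m2, 1.7)
    assert r2.csa_total == pytest.approx(4 * r1.csa_total)
    assert r2.csa_fatfree == pytest.approx(4 * r1.csa_fatfree)
    assert r2.ratio == pytest.approx(r1.ratio)
    assert r2.pdff_muscle == pytest.approx(r1.pdff_muscle)


def test_compartment_label_permutation_invariance(rng):
    intensities, label, spacing = random_case(rng)
    label = label % 9
    if (label > 0).sum() == 0:
        label[0, 0] = 1
    perm = 1 + rng.permutation(8)
    permuted = np.where(label > 0, perm[label - 1], 0)
    p1, m1 = as_objects(intensities, label, spacing)
    p2, m2 = as_objects(intensities, permuted, spacing)
    r1 = quantify_subject(p1, m1, 1.6)
    r2 = quantify_subject(p2, m2, 1.6)
    assert r1.csa_total == r2.csa_total
    assert r1.csa_fatfree == pytest.approx(r2.csa_fatfree)
    assert r1.pdff_muscle == pytest.approx(r2.pdff_muscle)


def test_pdff_muscle_examples():
    label = np.zeros((10, 10), dtype=int)
    label[2:6, 2:6] = 3
    pdff, masks = as_objects(np.full((10, 10), 115.0), label, 1.0)
    assert compute_pdff_muscle(masks, pdff) == pytest.approx(11.5)
    # half the mask at 0, half at 1000 -> 50 %
    intens = np.zeros((10, 10))
    intens[2:4, 2:6] = 1000.0
    pdff2, _ = as_objects(intens, label, 1.0)
    assert compute_pdff_muscle(masks, pdff2) == pytest.approx(50.0)


def test_ammi_and_ratio():
    assert compute_ammi(8670.0, 1.7) == pytest.approx(3000.0)
    assert compute_ammi(0.0, 1.9) == 0.0
    assert compute_ammi(1234.0, 1.0) == 1234.0
    assert compute_ratio(1709.5, 2954.6) == pytest.approx(57.859, abs=1e-3)
    assert compute_ratio(2954.6, 2954.6) == 100.0
    assert compute_ratio(0.0, 2954.6) == 0.0
    with pytest.raises(ValueError):
        compute_ratio(1.0, 0.0)


def test_contract_violations():
    label = np.zeros((6, 6), dtype=int)
    label[1, 1] = 1
    pdff, masks = as_objects(np.zeros((6, 6)), label, 1.0)
    bad = PDFFMap(np.zeros((7, 7)), pixel_spacing=1.0)
    with pytest.raises(ValueError, match="does not match"):
        compute_csa_total(masks, bad)
    with pytest.raises(ValueError):
        compute_csa_fatfree(masks, pdff, threshold=0.0)
    with pytest.raises(ValueError):
        compute_csa_fatfree(masks, pdff, threshold=1500.0)
    with pytest.raises(ValueError):
        compute_ammi(100.0, 0.0)


def test_intensity_clamping_warns_and_counts():
    vals = np.full((5, 5), 500.0)
    vals[0, 0] = -5.0
    vals[0, 1] = 1200.0
    with pytest.warns(UserWarning, match="clamped 2"):
        pdff = PDFFMap(vals, pixel_spacing=1.0)
    assert pdff.n_clamped == 2
    assert pdff.intensities.min() == 0.0
    assert pdff.intensities.max() == 1000.0


def test_mask_set_rejects_overlap_and_missing():
    grid = np.zeros((4, 4), dtype=bool)
    grid[0, 0] = True
    masks = {c: np.zeros((4, 4), dtype=bool) for c in COMPARTMENTS}
    masks["psoas_L"] = grid
    masks["psoas_R"] = grid  # overlaps
    with pytest.raises(ValueError, match="overlap"):
        CompartmentMaskSet(masks)
    with pytest.raises(ValueError, match="missing"):
        CompartmentMaskSet({"psoas_L": grid})
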