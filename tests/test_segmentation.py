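"""The five-step segmentation: per-step toys with hand-computed expectations,
phantom-truth comparisons, and pipeline invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from legcomp import (
    PhantomSpec,
    SegmentationConfig,
    classify_fat_water,
    component_circularity,
    compute_adaptive_kernel_size,
    dice,
    finalize_muscle,
    generate_phantom,
    segment_leg_boundary,
    segment_muscle,
    segment_sat,
    segment_volume,
)


def disc(shape, center, radius):
    rr, cc = np.indices(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


# ---------------------------------------------------------------------------
# adaptive kernel size
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("hbox, expected", [(0, 1), (8, 7), (100, 75)])
def test_kernel_size_hand_values(hbox, expected):
    assert compute_adaptive_kernel_size(hbox, 0.75) == expected


@given(hbox=st.integers(min_value=0, max_value=5000),
       scalar=st.floats(min_value=0.05, max_value=1.0))
@settings(derandomize=True, max_examples=200)
def test_kernel_size_always_odd_and_positive(hbox, scalar):
    s = compute_adaptive_kernel_size(hbox, scalar)
    assert s >= 1 and s % 2 == 1
    assert s <= hbox * scalar + 1 + 1e-9


def test_kernel_size_negative_hbox_rejected():
    with pytest.raises(ValueError):
        compute_adaptive_kernel_size(-1)


# ---------------------------------------------------------------------------
# leg boundary
# ---------------------------------------------------------------------------

def test_leg_boundary_recovers_truth_on_clean_slice(segmented_noiseless, noiseless_phantom):
    _, vol, truth = noiseless_phantom
    k = vol.n_slices // 2
    leg = segment_leg_boundary(vol.in_phase[k])
    tp = (leg & truth.leg[k]).sum() / truth.leg[k].sum()
    fp = (leg & ~truth.leg[k]).sum() / (~truth.leg[k]).sum()
    assert tp >= 0.99 and fp <= 0.01


def test_leg_boundary_empty_slice_warns(caplog):
    with caplog.at_level("WARNING", logger="legcomp.segmentation"):
        mask = segment_leg_boundary(np.zeros((32, 32)))
    assert not mask.any()
    assert any("all-background" in r.message for r in caplog.records)


def test_leg_boundary_includes_external_bright_blob(noiseless_phantom):
    """Anatomy outside the legs (an arm in the field of view) is foreground at
    this step; exclusion happens only through masking of the fat/water images."""
    _, vol, truth = noiseless_phantom
    k = vol.n_slices // 2
    img = vol.in_phase[k].copy()
    blob = disc(img.shape, (10, 96), 7)
    assert not (blob & truth.leg[k]).any()
    img[blob] = 1.0
    mask = segment_leg_boundary(img)
    assert (mask & blob).sum() >= 0.8 * blob.sum()
    n_components = ndimage.label(mask)[1]
    assert n_components == 3  # two legs + blob
    legs_only = segment_leg_boundary(vol.in_phase[k])
    assert ndimage.label(legs_only)[1] == 2


# ---------------------------------------------------------------------------
# fat/water classification
# ---------------------------------------------------------------------------

def test_adaptive_threshold_matches_local_mean_oracle():
    """20x20 toy, half bright / half dark, kernel within one half: foreground
    is exactly the bright half (brute-force local-mean check)."""
    img = np.zeros((20, 20))
    img[:, 10:] = 1.0
    leg = np.ones((20, 20), dtype=bool)
    fat_mask, _ = classify_fat_water(img, np.zeros_like(img), leg, 9)
    assert fat_mask[:, 10:].all()
    assert not fat_mask[:, :10].any()
    # brute-force oracle: replicate-padded local means
    pad = np.pad(img, 4, mode="edge")
    for r in range(20):
        for c in range(0, 20, 3):
            local_mean = pad[r:r + 9, c:c + 9].mean()
            expected = img[r, c] >= local_mean and img[r, c] > 0
            assert fat_mask[r, c] == expected


def test_adaptive_threshold_beats_global_otsu_under_bias():
    """The motivating failure mode: a strong bias field breaks a single global
    threshold but not the locally adaptive one."""
    from skimage.filters import threshold_otsu

    spec = PhantomSpec(n_slices=6, seed=13, bias_field_amplitude=0.45, noise_sigma=0.02)
    vol, truth = generate_phantom(spec)
    k = 5  # most superior slice: strongest bias ramp
    leg = truth.leg[k]
    hbox = np.flatnonzero(leg.any(axis=1))
    kernel = compute_adaptive_kernel_size(hbox[-1] - hbox[0] + 1)
    fat_mask, _ = classify_fat_water(vol.fat[k], vol.water[k], leg, kernel)
    truth_fat = (truth.sat | truth.marrow | truth.imat)[k]
    adaptive_dice = dice(fat_mask, truth_fat)
    otsu_mask = (vol.fat[k] > threshold_otsu(vol.fat[k][leg])) & leg
    assert adaptive_dice >= 0.95
    assert adaptive_dice > dice(otsu_mask, truth_fat)


def test_all_zero_fat_slice_gives_empty_mask():
    leg = np.ones((16, 16), dtype=bool)
    fat_mask, water_mask = classify_fat_water(
        np.zeros((16, 16)), np.ones((16, 16)), leg, 5)
    assert not fat_mask.any()
    assert water_mask.all()


def test_even_kernel_rejected():
    with pytest.raises(ValueError, match="odd"):
        classify_fat_water(np.ones((4, 4)), np.ones((4, 4)),
                           np.ones((4, 4), bool), 4)


# ---------------------------------------------------------------------------
# muscle segmentation
# ---------------------------------------------------------------------------

def test_muscle_annulus_hole_flood_filled():
    """A water annulus around a bone-sized hole: the hole survives the small-
    hole filter (area >= 18 px) and is closed by the final flood fill, so the
    filled area equals annulus + hole."""
    shape = (48, 48)
    outer = disc(shape, (24, 24), 14)
    hole = disc(shape, (24, 24), 5)   # 81 px > 18: a bone, not a small hole
    water = outer & ~hole
    leg = ndimage.binary_dilation(outer, iterations=3)
    out = segment_muscle(water, np.zeros(shape, bool), leg, "lower")
    filled_truth = ndimage.binary_fill_holes(water)
    assert (out & hole).sum() == hole.sum()
    assert out.sum() == pytest.approx(filled_truth.sum(), abs=0.02 * filled_truth.sum())


def test_muscle_empty_water_mask():
    shape = (20, 20)
    leg = disc(shape, (10, 10), 8)
    out = segment_muscle(np.zeros(shape, bool), np.zeros(shape, bool), leg, "upper")
    assert not out.any()


def test_muscle_small_objects_removed():
    shape = (40, 40)
    leg = np.ones(shape, bool)
    water = np.zeros(shape, bool)
    water[5:8, 5:8] = True       # 9 px < 10: removed
    water[20:30, 20:30] = True   # 100 px: kept
    out = segment_muscle(water, np.zeros(shape, bool), leg, "lower")
    assert not out[5:8, 5:8].any()
    assert out[21:29, 21:29].all()


def test_muscle_unknown_region_rejected():
    shape = (8, 8)
    with pytest.raises(ValueError, match="slice_region"):
        segment_muscle(np.ones(shape, bool), np.zeros(shape, bool),
                       np.ones(shape, bool), "middle")


def test_muscle_dice_on_phantom_calf_slice(segmented_small, small_phantom):
    _, vol, truth = small_phantom
    masks, _, _ = segmented_small
    k = 2  # calf-like (inferior) slice
    filled_truth = ndimage.binary_fill_holes(
        (truth.muscle | truth.marrow | truth.imat)[k])
    assert dice(masks[k].muscle_filled, filled_truth) >= 0.95


# ---------------------------------------------------------------------------
# SAT segmentation and circularity
# ---------------------------------------------------------------------------

def crescent(shape, center, r_out, r_in, shift):
    return disc(shape, center, r_out) & ~disc(shape, (center[0], center[1] + shift), r_in)


def test_sat_keeps_crescent_removes_disc():
    """Hand circularity 4*pi*A/P^2: a crescent scores ~0.4-0.5 (kept), a
    radius-6 disc scores ~1 (removed as marrow-like)."""
    shape = (64, 96)
    cres = crescent(shape, (32, 24), 12, 10, 6)
    ball = disc(shape, (32, 70), 6)
    assert component_circularity(cres) < 0.6
    assert component_circularity(ball) > 0.8
    fat = cres | ball
    out = segment_sat(fat, np.zeros(shape, bool))
    assert not (out & ball).any()
    assert (out & cres).sum() >= 0.7 * cres.sum()  # opening trims thin tips


@pytest.mark.parametrize("radius", [4, 6, 9, 14])
def test_perfect_disc_always_removed_from_sat(radius):
    shape = (40, 40)
    ball = disc(shape, (20, 20), radius)
    out = segment_sat(ball, np.zeros(shape, bool))
    assert not out.any()


def test_thin_arc_never_removed_by_circularity():
    shape = (64, 64)
    rr, cc = np.indices(shape)
    rad = np.sqrt((rr - 32.0) ** 2 + (cc - 32.0) ** 2)
    arc = (np.abs(rad - 20) <= 0.9) & (cc > 32)  # connected 1-2 px wide arc
    from scipy import ndimage as ndi
    assert ndi.label(arc)[1] == 1
    assert component_circularity(arc) < 0.3


def test_sat_empty_fat_mask():
    out = segment_sat(np.zeros((16, 16), bool), np.zeros((16, 16), bool))
    assert not out.any()


def test_sat_dice_on_phantom_thigh_slice(segmented_small, small_phantom):
    _, vol, truth = small_phantom
    masks, _, _ = segmented_small
    k = vol.n_slices - 2  # thigh-like (superior) slice
    assert dice(masks[k].sat, truth.sat[k]) >= 0.95


# ---------------------------------------------------------------------------
# final muscle mask
# ---------------------------------------------------------------------------

def test_finalize_removes_fat_streak_pixels():
    shape = (32, 32)
    muscle = disc(shape, (16, 16), 12)
    streak = np.zeros(shape, bool)
    streak[15:17, 8:24] = True  # 2-px-wide fat streak across the muscle
    streak &= muscle
    out = finalize_muscle(muscle, streak, np.zeros(shape, bool))
    assert not (out & streak).any()
    assert (muscle.sum() - out.sum()) == streak.sum()


def test_finalize_noop_when_fat_is_all_sat():
    shape = (24, 24)
    muscle = disc(shape, (12, 12), 8)
    fat = disc(shape, (12, 4), 3)
    out = finalize_muscle(muscle, fat, fat)
    np.testing.assert_array_equal(out, muscle)


def test_final_muscle_excludes_imat_on_phantom(segmented_small, small_phantom):
    _, _, truth = small_phantom
    masks, _, _ = segmented_small
    final = np.stack([m.muscle_final for m in masks])
    leaked = (final & truth.imat).sum() / truth.imat.sum()
    assert leaked <= 0.1


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def test_segment_volume_invariants(segmented_small, small_phantom):
    _, vol, _ = small_phantom
    masks, _, _ = segmented_small
    assert len(masks) == vol.n_slices
    for m in masks:
        assert not (m.sat & m.muscle_final).any()
        assert not (m.sat & ~m.leg).any()
        assert not (m.muscle_final & ~m.leg).any()
        assert m.kernel_size % 2 == 1 and m.kernel_size >= 1
        m.validate()


def test_segment_volume_deterministic(noiseless_phantom, default_config):
    _, vol, _ = noiseless_phantom
    a = segment_volume(vol, default_config)
    b = segment_volume(vol, default_config)
    for ma, mb in zip(a, b):
        np.testing.assert_array_equal(ma.sat, mb.sat)
        np.testing.assert_array_equal(ma.muscle_final, mb.muscle_final)


def test_segment_volume_override_passthrough(noiseless_phantom, default_config):
    from legcomp import SliceMasks

    _, vol, _ = noiseless_phantom
    shape = vol.fat.shape[1:]
    marker = np.zeros(shape, bool)
    marker[0, 0] = True
    override = SliceMasks(leg=np.ones(shape, bool), fat=marker, water=marker,
                          muscle_filled=marker, sat=marker,
                          muscle_final=np.zeros(shape, bool), hbox=1, kernel_size=1)
    masks = segment_volume(vol, default_config, overrides={3: override})
    assert masks[3] is override
    np.testing.assert_array_equal(masks[3].sat, marker)


def test_segment_volume_high_dice_in_noiseless_limit(segmented_noiseless, noiseless_phantom):
    _, vol, truth = noiseless_phantom
    masks, _, _ = segmented_noiseless
    for k, m in enumerate(masks):
        assert dice(m.sat, truth.sat[k]) >= 0.98
        assert dice(m.muscle_final, truth.muscle[k]) >= 0.98


def test_config_validation():
    with pytest.raises(ValueError):
        SegmentationConfig(min_object_area=0)
    with pytest.raises(ValueError):
        SegmentationConfig(circularity_cutoff=1.5)
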