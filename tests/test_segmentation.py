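"""Intensity classification, damaged-slice repair, region growing, down-sampling."""

import numpy as np
import pytest
from conftest import bfs_component, random_label_volume
from hypothesis import given, settings
from hypothesis import strategies as st

from histovol import (
    ClassThresholds,
    LabelVolume,
    classify_volume,
    interpolate_damaged_slices,
    region_grow_cleanup,
    volume_downsample,
)
from histovol.errors import SegmentationError
from histovol.preprocess import GraySlice
from histovol.volume import Label, VolumeMeta


def _gray(pixels, k=0, damaged=False):
    return GraySlice(np.asarray(pixels, dtype=np.uint8), k, damaged, True)


def _vol(labels):
    return LabelVolume(np.asarray(labels, dtype=np.uint8))


# ------------------------------------------------------------ classification


@pytest.mark.parametrize(
    "intensity, expected",
    [
        (2, Label.BACKGROUND),
        (3, Label.NEGATIVE),
        (80, Label.NEGATIVE),
        (81, Label.POSITIVE),
        (0, Label.BACKGROUND),
        (255, Label.POSITIVE),
    ],
)
def test_classification_boundaries(intensity, expected):
    vol = classify_volume([_gray(np.full((2, 2), intensity))])
    assert (vol.labels == expected).all()


def test_class_counts_partition_total():
    rng = np.random.default_rng(0)
    stack = [_gray(rng.integers(0, 256, (30, 20)), k) for k in range(5)]
    vol = classify_volume(stack)
    counts = vol.class_counts()
    assert sum(counts.values()) == vol.meta.n_voxels == 30 * 20 * 5


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    positive_above=st.integers(0, 255),
    background_below=st.integers(0, 255),
)
def test_partition_holds_for_any_thresholds(seed, positive_above, background_below):
    if background_below > positive_above:
        background_below, positive_above = positive_above, background_below
    rng = np.random.default_rng(seed)
    stack = [_gray(rng.integers(0, 256, (10, 10)), k) for k in range(3)]
    vol = classify_volume(stack, ClassThresholds(positive_above, background_below))
    assert sum(vol.class_counts().values()) == 300


def test_raising_positive_threshold_never_adds_positives():
    rng = np.random.default_rng(1)
    stack = [_gray(rng.integers(0, 256, (20, 20)), k) for k in range(4)]
    previous = None
    for pa in (40, 80, 120, 200):
        vol = classify_volume(stack, ClassThresholds(pa, 3))
        n_pos = vol.class_counts()[Label.POSITIVE]
        if previous is not None:
            assert n_pos <= previous
        previous = n_pos


def test_invalid_threshold_order_rejected():
    with pytest.raises(SegmentationError, match="background_below"):
        ClassThresholds(positive_above=10, background_below=40)


def test_nonuniform_stack_rejected():
    with pytest.raises(SegmentationError, match="uniform"):
        classify_volume([_gray(np.zeros((4, 4))), _gray(np.zeros((4, 5)), 1)])


# --------------------------------------------------------------- repair


def test_no_damaged_slices_is_identity():
    labels = random_label_volume(np.random.default_rng(2), (8, 8, 4))
    vol = _vol(labels)
    out = interpolate_damaged_slices(vol, [])
    np.testing.assert_array_equal(out.labels, labels)


def test_damaged_slice_copies_nearest_neighbour_labels():
    labels = np.zeros((6, 6, 3), dtype=np.uint8)
    labels[1:5, 1:5, 0] = Label.NEGATIVE
    labels[1:5, 1:5, 2] = Label.NEGATIVE
    # damaged middle slice: only a positive speck survives imaging
    labels[2, 2, 1] = Label.POSITIVE
    out = interpolate_damaged_slices(_vol(labels), [1])
    # tissue mask of the repaired slice equals the neighbours'
    expected = labels[:, :, 0].copy()
    expected[2, 2] = Label.POSITIVE  # preserved positive voxel
    np.testing.assert_array_equal(out.labels[:, :, 1], expected)
    # intact slices untouched
    np.testing.assert_array_equal(out.labels[:, :, 0], labels[:, :, 0])
    np.testing.assert_array_equal(out.labels[:, :, 2], labels[:, :, 2])


def test_tie_breaks_toward_lower_z():
    labels = np.zeros((2, 2, 3), dtype=np.uint8)
    labels[..., 0] = Label.NEGATIVE  # lower neighbour: tissue
    labels[..., 2] = Label.POSITIVE  # upper neighbour: positive
    out = interpolate_damaged_slices(_vol(labels), [1])
    assert (out.labels[:, :, 1] == Label.NEGATIVE).all()


def test_all_slices_damaged_rejected():
    labels = np.zeros((4, 4, 2), dtype=np.uint8)
    with pytest.raises(SegmentationError, match="all slices"):
        interpolate_damaged_slices(_vol(labels), [0, 1])


def test_damaged_index_out_of_range_rejected():
    labels = np.zeros((4, 4, 2), dtype=np.uint8)
    with pytest.raises(SegmentationError, match="out of range"):
        interpolate_damaged_slices(_vol(labels), [5])


# --------------------------------------------------------- region growing


def test_speckles_removed_blob_kept():
    labels = np.zeros((12, 12, 6), dtype=np.uint8)
    labels[3:9, 3:9, 1:5] = Label.NEGATIVE
    labels[5, 5, 2] = Label.POSITIVE
    rng = np.random.default_rng(3)
    speckles = []
    while len(speckles) < 10:
        y, x, z = rng.integers(0, 12), rng.integers(0, 12), rng.integers(0, 6)
        if not (2 <= y <= 9 and 2 <= x <= 9 and 0 <= z <= 5 and labels[y, x, z]):
            if labels[max(y-1,0):y+2, max(x-1,0):x+2, max(z-1,0):z+2].sum() == 0:
                labels[y, x, z] = Label.NEGATIVE
                speckles.append((y, x, z))
    vol = _vol(labels)
    cleaned, removed = region_grow_cleanup(vol, connectivity=26, seed=(5, 5, 2))
    assert removed == len(speckles)
    for y, x, z in speckles:
        assert cleaned.labels[y, x, z] == Label.BACKGROUND
    # the blob survives with labels intact, including the positive voxel
    assert cleaned.labels[5, 5, 2] == Label.POSITIVE
    assert (
        cleaned.labels[3:9, 3:9, 1:5] == labels[3:9, 3:9, 1:5]
    ).all()


def test_fully_connected_volume_unchanged():
    labels = np.full((5, 5, 3), int(Label.NEGATIVE), dtype=np.uint8)
    cleaned, removed = region_grow_cleanup(_vol(labels), seed="auto")
    assert removed == 0
    np.testing.assert_array_equal(cleaned.labels, labels)


def test_seed_on_background_is_an_error():
    labels = np.zeros((4, 4, 2), dtype=np.uint8)
    labels[2, 2, 0] = Label.NEGATIVE
    with pytest.raises(SegmentationError, match=r"\(0, 0, 0\)"):
        region_grow_cleanup(_vol(labels), seed=(0, 0, 0))


def test_no_tissue_is_an_error():
    labels = np.zeros((4, 4, 2), dtype=np.uint8)
    with pytest.raises(SegmentationError, match="no tissue"):
        region_grow_cleanup(_vol(labels))


@pytest.mark.parametrize("connectivity", [6, 26])
def test_region_growing_equals_bfs_oracle(connectivity):
    rng = np.random.default_rng(17)
    for _ in range(20):
        labels = random_label_volume(rng, (12, 12, 6), p_tissue=0.3)
        tissue = labels != Label.BACKGROUND
        if not tissue.any():
            continue
        coords = np.argwhere(tissue)
        y, x, z = coords[rng.integers(len(coords))]
        cleaned, _ = region_grow_cleanup(
            _vol(labels), connectivity=connectivity, seed=(int(x), int(y), int(z))
        )
        keep = bfs_component(tissue, (int(y), int(x), int(z)), connectivity)
        expected = labels.copy()
        expected[tissue & ~keep] = Label.BACKGROUND
        np.testing.assert_array_equal(cleaned.labels, expected)


def test_auto_seed_lands_on_tissue_near_centroid():
    labels = np.zeros((9, 9, 5), dtype=np.uint8)
    labels[2:7, 2:7, 1:4] = Label.NEGATIVE
    cleaned, removed = region_grow_cleanup(_vol(labels), seed="auto")
    assert removed == 0
    np.testing.assert_array_equal(cleaned.labels, labels)


# --------------------------------------------------------- down-sampling


def test_factor_one_is_identity():
    labels = random_label_volume(np.random.default_rng(4), (8, 10, 3))
    vol = _vol(labels)
    out = volume_downsample(vol, 1)
    np.testing.assert_array_equal(out.labels, labels)
    assert out.meta.spacing == vol.meta.spacing


def test_majority_rule_in_blocks():
    labels = np.zeros((2, 2, 1), dtype=np.uint8)
    labels[0, 0, 0] = Label.POSITIVE  # 1 positive vs 3 background
    out = volume_downsample(_vol(labels), 2)
    assert out.labels.shape == (1, 1, 1)
    assert out.labels[0, 0, 0] == Label.BACKGROUND


def test_tie_breaks_favour_signal():
    labels = np.zeros((2, 2, 1), dtype=np.uint8)
    labels[0, :, 0] = Label.POSITIVE  # 2 positive vs 2 background
    out = volume_downsample(_vol(labels), 2)
    assert out.labels[0, 0, 0] == Label.POSITIVE
    labels[:] = Label.NEGATIVE
    labels[0, :, 0] = Label.BACKGROUND  # 2 negative vs 2 background
    out = volume_downsample(_vol(labels), 2)
    assert out.labels[0, 0, 0] == Label.NEGATIVE


def test_dims_spacing_and_partial_edge_blocks():
    labels = np.full((5, 7, 2), int(Label.NEGATIVE), dtype=np.uint8)
    vol = LabelVolume(labels, VolumeMeta((7, 5, 2), spacing=(2.0, 3.0, 4.0)))
    out = volume_downsample(vol, 3)
    assert out.meta.dims == (3, 2, 2)  # ceil(7/3), ceil(5/3), z kept
    assert out.meta.spacing == (6.0, 9.0, 4.0)
    # partial edge blocks contain only NEGATIVE real voxels
    assert (out.labels == Label.NEGATIVE).all()


def test_z_axis_never_downsampled():
    labels = random_label_volume(np.random.default_rng(5), (8, 8, 5))
    out = volume_downsample(_vol(labels), 2)
    assert out.labels.shape[2] == 5


def test_factor_exceeding_extent_rejected():
    labels = np.zeros((4, 4, 2), dtype=np.uint8)
    with pytest.raises(SegmentationError, match="exceeds"):
        volume_downsample(_vol(labels), 5)


def test_end_to_end_positive_fraction_on_synthetic_stack(small_stack):
    """Classified + cleaned synthetic stack recovers the generator's
    positive fraction within 5% relative (aligned-frame, no warping)."""
    from dataclasses import replace as dc_replace

    from histovol import StackSpec, generate_stack
    from histovol.preprocess import PreprocessParams, preprocess_section
    from histovol.synthetic import MisalignmentSpec

    spec, _, _ = small_stack
    spec = dc_replace(spec, misalignment=MisalignmentSpec(0.0, 0.0))
    sections, truth = generate_stack(spec)
    grays = [preprocess_section(s, PreprocessParams()) for s in sections]
    vol = classify_volume(grays)
    vol, _ = region_grow_cleanup(vol, seed="auto")
    assert vol.positive_fraction() == pytest.approx(
        truth.positive_fraction, rel=0.05
    )
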