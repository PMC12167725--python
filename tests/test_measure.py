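"""Label decoding, largest-component cleanup and the LRF% statistic."""

import numpy as np
import pytest
from collections import deque

import srfseg as s
from srfseg.errors import ContractError, DataError, MeasurementError
from srfseg.measure import (
    compute_srf,
    keep_largest_component,
    mask_volume_ml,
    predict_scores_tiled,
    scores_to_labels,
)
from srfseg.volumes import ImageVolume, LabelVolume, Modality, mirror_left_right

SP = (2.73, 2.73, 2.79)


def _labels(data):
    return LabelVolume(np.asarray(data, dtype=np.uint8), SP)


def _pet(data):
    return ImageVolume(np.asarray(data, dtype=float), SP, modality=Modality.PET_SUV)


# ---- scores_to_labels ------------------------------------------------------


def test_one_hot_scores_decode_exactly():
    rng = np.random.default_rng(0)
    labels = (rng.random((5, 5, 5)) * 3).astype(np.uint8)
    scores = np.zeros((3, 5, 5, 5))
    for k in range(3):
        scores[k][labels == k] = 1.0
    out = scores_to_labels(scores, SP)
    np.testing.assert_array_equal(out.data, labels)


def test_all_equal_scores_tie_break_to_background():
    out = scores_to_labels(np.zeros((3, 4, 4, 4)), SP)
    assert (out.data == 0).all()


def test_random_scores_stay_in_codomain():
    scores = np.random.default_rng(1).normal(size=(3, 6, 6, 6))
    out = scores_to_labels(scores, SP)
    assert set(np.unique(out.data)) <= {0, 1, 2}


def test_non_finite_scores_rejected():
    scores = np.zeros((3, 2, 2, 2))
    scores[1, 0, 0, 0] = np.nan
    with pytest.raises(DataError):
        scores_to_labels(scores, SP)


# ---- keep_largest_component ------------------------------------------------


def bfs_largest_component(mask: np.ndarray) -> np.ndarray:
    """Independent brute-force largest 26-connected component via BFS."""
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    best, best_size, best_seed = None, -1, None
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = []
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.append(v)
            for off in offsets:
                w = tuple(v[i] + off[i] for i in range(3))
                if all(0 <= w[i] < shape[i] for i in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        seed_lin = min(np.ravel_multi_index(v, shape) for v in comp)
        if len(comp) > best_size or (len(comp) == best_size and seed_lin < best_seed):
            best, best_size, best_seed = comp, len(comp), seed_lin
    out = np.zeros(shape, dtype=bool)
    if best:
        out[tuple(np.array(best).T)] = True
    return out


def test_single_blob_unchanged():
    data = np.zeros((6, 6, 6), dtype=np.uint8)
    data[1:4, 1:4, 1:4] = 1
    out = keep_largest_component(_labels(data), 1)
    np.testing.assert_array_equal(out.data, data)


def test_small_component_removed_large_kept():
    data = np.zeros((10, 10, 10), dtype=np.uint8)
    data[0:5, 0:5, 0:4] = 1  # 100 voxels
    data[8, 8, 3:8] = 1  # 5 voxels, detached
    out = keep_largest_component(_labels(data), 1)
    assert out.data[0:5, 0:5, 0:4].all()
    assert not out.data[8, 8, 3:8].any()


def test_corner_contact_counts_as_connected():
    data = np.zeros((4, 4, 4), dtype=np.uint8)
    data[0, 0, 0] = 1
    data[1, 1, 1] = 1  # shares only a corner
    out = keep_largest_component(_labels(data), 1)
    assert out.data.sum() == 2  # both kept: one 26-connected component


def test_other_class_untouched():
    data = np.zeros((8, 8, 8), dtype=np.uint8)
    data[0:2, 0:2, 0:2] = 1
    data[5:7, 5:7, 5:7] = 1
    data[3, 3, 3] = 2
    out = keep_largest_component(_labels(data), 1)
    assert out.data[3, 3, 3] == 2


def test_keep_largest_matches_bfs_oracle_on_random_grids():
    rng = np.random.default_rng(12345)
    for _ in range(30):
        data = (rng.random((20, 20, 20)) < 0.12).astype(np.uint8)  # class-1 blobs
        labels = _labels(data)
        out = keep_largest_component(labels, 1)
        if not data.any():
            np.testing.assert_array_equal(out.data, data)
            continue
        expected = bfs_largest_component(data == 1)
        np.testing.assert_array_equal(out.data == 1, expected)


def test_keep_largest_is_idempotent():
    rng = np.random.default_rng(7)
    data = (rng.random((15, 15, 15)) < 0.15).astype(np.uint8)
    once = keep_largest_component(_labels(data), 1)
    twice = keep_largest_component(once, 1)
    np.testing.assert_array_equal(once.data, twice.data)


# ---- volumes and LRF% ------------------------------------------------------


def test_mask_volume_examples():
    data = np.zeros((10, 10, 10), dtype=np.uint8)
    assert mask_volume_ml(_labels(data), 1) == 0.0
    data[:, :, :] = 1  # 1000 voxels
    vol = mask_volume_ml(_labels(data), 1)
    assert vol == pytest.approx(1000 * 2.73 * 2.73 * 2.79 / 1000.0, abs=1e-9)
    assert vol == pytest.approx(20.7936, abs=1e-3)
    doubled = LabelVolume(data, tuple(2 * x for x in SP))
    assert mask_volume_ml(doubled, 1) == pytest.approx(8 * vol, rel=1e-12)


def test_compute_srf_hand_sums():
    pet = np.zeros((4, 4, 4))
    labels = np.zeros((4, 4, 4), dtype=np.uint8)
    pet[3, 0, 0], pet[3, 1, 0] = 10.0, 20.0
    labels[3, 0, 0] = labels[3, 1, 0] = 1
    pet[0, 0, 0] = 10.0
    labels[0, 0, 0] = 2
    r = compute_srf(_pet(pet), _labels(labels))
    assert r.lrf_percent == pytest.approx(75.0, abs=1e-12)
    assert r.left_suv_sum == 30.0 and r.right_suv_sum == 10.0


def test_srf_mirror_symmetry_is_exact():
    rng = np.random.default_rng(3)
    pet = np.abs(rng.normal(2, 1, size=(8, 8, 8)))
    labels = np.zeros((8, 8, 8), dtype=np.uint8)
    labels[5:8, 2:5, 2:5] = 1
    labels[0:3, 3:6, 3:6] = 2
    lrf = compute_srf(_pet(pet), _labels(labels)).lrf_percent
    mirrored = compute_srf(
        mirror_left_right(_pet(pet)), mirror_left_right(_labels(labels))
    ).lrf_percent
    assert mirrored == pytest.approx(100.0 - lrf, abs=1e-12)


def test_solitary_left_kidney_gives_100():
    pet = np.ones((4, 4, 4))
    labels = np.zeros((4, 4, 4), dtype=np.uint8)
    labels[3, :, :] = 1
    assert compute_srf(_pet(pet), _labels(labels)).lrf_percent == 100.0


def test_no_renal_uptake_is_an_error():
    pet = np.ones((4, 4, 4))
    labels = np.zeros((4, 4, 4), dtype=np.uint8)
    with pytest.raises(MeasurementError, match="no renal uptake"):
        compute_srf(_pet(pet), _labels(labels))
    pet0 = np.zeros((4, 4, 4))
    labels[0, 0, 0] = 1
    with pytest.raises(MeasurementError):
        compute_srf(_pet(pet0), _labels(labels))


def test_geometry_mismatch_rejected():
    pet = _pet(np.ones((4, 4, 4)))
    labels = LabelVolume(np.zeros((4, 4, 5), dtype=np.uint8), SP)
    with pytest.raises(ContractError):
        compute_srf(pet, labels)


def test_srf_invariant_to_voxel_permutation():
    rng = np.random.default_rng(5)
    pet = np.abs(rng.normal(size=(6, 6, 6)))
    labels = (rng.random((6, 6, 6)) * 3).astype(np.uint8)
    r1 = compute_srf(_pet(pet), _labels(labels))
    perm = rng.permutation(216)
    pet2 = pet.reshape(-1)[perm].reshape(6, 6, 6)
    labels2 = labels.reshape(-1)[perm].reshape(6, 6, 6)
    r2 = compute_srf(_pet(pet2), _labels(labels2))
    assert r1.lrf_percent == pytest.approx(r2.lrf_percent, abs=1e-12)
    assert r1.left_suv_sum == pytest.approx(r2.left_suv_sum, abs=1e-9)


# ---- tiled inference -------------------------------------------------------


class _LinearScorer:
    """Analytic stand-in model: scores depend only on local PET intensity,
    so tiled and whole-volume inference must agree."""

    spacing = SP
    patch_edge = 0
    divisor = 1

    def predict(self, x):
        pet = x[1]
        return np.stack([2.0 - pet, pet - 2.0, np.full_like(pet, -10.0)])


def test_tiled_inference_equals_single_pass():
    rng = np.random.default_rng(8)
    ct = rng.normal(40, 20, size=(32, 32, 32))
    pet = np.abs(rng.normal(2, 2, size=(32, 32, 32)))
    model = _LinearScorer()
    full = model.predict(np.stack([ct, pet]))
    tiled = predict_scores_tiled(model, ct, pet, patch_edge=16)
    np.testing.assert_allclose(tiled, full, atol=1e-6)


def test_segment_and_measure_propagates_empty_segmentation(symmetric_case):
    class AllBackground:
        spacing = SP
        patch_edge = 0
        divisor = 1

        def predict(self, x):
            bg = np.zeros(x.shape[1:])
            return np.stack([bg + 1.0, bg, bg])

    with pytest.raises(MeasurementError, match="no renal uptake"):
        s.segment_and_measure(symmetric_case.ct, symmetric_case.pet, AllBackground())
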