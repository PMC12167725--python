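"""Inference-side measurement: labels from scores, component cleanup and LRF%.

The split-renal-function statistic is

    LRF% = 100 * (sum of SUV over left-kidney voxels)
               / (sum of SUV over left- plus right-kidney voxels)

computed on the native PET grid. Before measuring, each kidney class is
reduced to its largest 26-connected component, which removes spurious
detections such as PSMA-avid lymph-node metastases mislabeled as kidney.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ContractError, DataError, MeasurementError
from .volumes import ImageVolume, LabelVolume, Modality, resample_to_grid

__all__ = [
    "SRFResult",
    "scores_to_labels",
    "keep_largest_component",
    "mask_volume_ml",
    "compute_srf",
    "segment_and_measure",
    "symmetrize_model",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

SMALL_COMPONENT_ML = 10.0  # kept components below this raise a warning flag


@dataclass
class SRFResult:
    """Per-kidney summed SUV, volumes in ml and the LRF% statistic."""

    left_suv_sum: float
    right_suv_sum: float
    left_volume_ml: float
    right_volume_ml: float
    lrf_percent: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def scores_to_labels(scores: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)) -> LabelVolume:
    """Per-voxel argmax over the three class scores.

    ``scores`` has shape (3, nx, ny, nz). Ties break toward the lowest class
    index, so an all-tied voxel is background.
    """
    scores = np.asarray(scores)
    if scores.ndim != 4 or scores.shape[0] != 3:
        raise ContractError(f"scores must have shape (3, nx, ny, nz), got {scores.shape}")
    if not np.all(np.isfinite(scores)):
        raise DataError("scores contain non-finite values")
    labels = np.argmax(scores, axis=0).astype(np.uint8)  # argmax returns first maximum
    return LabelVolume(labels, spacing, origin)


def keep_largest_component(labels: LabelVolume, target: int) -> LabelVolume:
    """Keep only the largest 26-connected component of one kidney class.

    All other voxels of that class are relabeled background; other classes
    are untouched. An equal-size tie keeps the component containing the
    smallest linear voxel index. Absent class: returned unchanged (a copy).
    """
    if target not in (LabelVolume.LEFT, LabelVolume.RIGHT):
        raise ContractError(f"target must be 1 or 2, got {target}")
    data = labels.data.copy()
    mask = data == target
    if not mask.any():
        return LabelVolume(data, labels.spacing, labels.origin)
    comp, ncomp = ndimage.label(mask, structure=_STRUCT26)
    if ncomp > 1:
        sizes = np.bincount(comp.ravel())[1:]
        best = np.flatnonzero(sizes == sizes.max()) + 1
        if len(best) == 1:
            keep = best[0]
        else:
            # tie: smallest minimum linear index; ndimage.label scans in raster
            # order, so the smallest qualifying component id wins
            keep = best.min()
        data[mask & (comp != keep)] = 0
    return LabelVolume(data, labels.spacing, labels.origin)


def mask_volume_ml(labels: LabelVolume, target: int) -> float:
    """Volume of one label class in milliliters (voxel count x voxel volume)."""
    count = int(np.count_nonzero(labels.data == target))
    return count * labels.voxel_volume_mm3() / 1000.0


def compute_srf(pet: ImageVolume, labels: LabelVolume) -> SRFResult:
    """Sum SUV per kidney and form the LRF% statistic.

    Raises :class:`MeasurementError` when neither kidney class carries any
    uptake ("no renal uptake segmented") rather than returning a number.
    """
    if pet.modality is not Modality.PET_SUV:
        raise ContractError(f"compute_srf needs a PET_SUV volume, got {pet.modality}")
    if not pet.same_geometry(labels):
        raise ContractError(
            f"PET and label geometry differ: {pet.shape}/{pet.spacing} vs {labels.shape}/{labels.spacing}"
        )
    left = float(pet.data[labels.data == LabelVolume.LEFT].sum())
    right = float(pet.data[labels.data == LabelVolume.RIGHT].sum())
    if left + right <= 0.0:
        raise MeasurementError("no renal uptake segmented")
    return SRFResult(
        left_suv_sum=left,
        right_suv_sum=right,
        left_volume_ml=mask_volume_ml(labels, LabelVolume.LEFT),
        right_volume_ml=mask_volume_ml(labels, LabelVolume.RIGHT),
        lrf_percent=100.0 * left / (left + right),
    )


def _tile_starts(n: int, patch: int, stride: int) -> list[int]:
    if n <= patch:
        return [0]
    starts = list(range(0, n - patch + 1, stride))
    if starts[-1] != n - patch:
        starts.append(n - patch)
    return starts


def predict_scores_tiled(
    model, ct: np.ndarray, pet: np.ndarray, patch_edge: int, stride: int | None = None
) -> np.ndarray:
    """Run a segmentation model over a full volume by overlapping patch tiling.

    Patches stride by half the patch edge and overlapping scores are averaged.
    Volumes smaller than the patch are padded (CT with -100 HU, PET with 0)
    and the scores cropped back.
    """
    stride = stride or max(1, patch_edge // 2)
    shape = ct.shape
    pad = [max(0, patch_edge - n) for n in shape]
    if any(pad):
        pw = [(p // 2, p - p // 2) for p in pad]
        ct = np.pad(ct, pw, constant_values=-100.0)
        pet = np.pad(pet, pw, constant_values=0.0)
    padded = ct.shape
    acc = np.zeros((3, *padded), dtype=np.float64)
    cnt = np.zeros(padded, dtype=np.float64)
    for i in _tile_starts(padded[0], patch_edge, stride):
        for j in _tile_starts(padded[1], patch_edge, stride):
            for k in _tile_starts(padded[2], patch_edge, stride):
                sl = (slice(i, i + patch_edge), slice(j, j + patch_edge), slice(k, k + patch_edge))
                x = np.stack([ct[sl], pet[sl]]).astype(np.float32)
                scores = model.predict(x)
                acc[(slice(None), *sl)] += scores
                cnt[sl] += 1.0
    acc /= cnt
    if any(pad):
        lo = [p // 2 for p in pad]
        acc = acc[:, lo[0] : lo[0] + shape[0], lo[1] : lo[1] + shape[1], lo[2] : lo[2] + shape[2]]
    return acc


def segment_and_measure(
    ct: ImageVolume, pet: ImageVolume, model
) -> tuple[LabelVolume, SRFResult]:
    """Full inference pipeline: resample, tile, segment, clean up, measure.

    Both volumes are resampled to the model's training grid spacing, tiled
    into overlapping patches whose scores are averaged, argmax-decoded, and
    each kidney class is reduced to its largest 26-connected component. The
    labels are then mapped back to the native PET grid (nearest neighbor)
    and LRF% is measured on the native, uninterpolated SUV values. A kept
    component smaller than 10 ml raises a non-fatal warning in the result,
    flagging a likely spurious segmentation.
    """
    if not ct.same_geometry(pet):
        raise ContractError("CT and PET must be co-registered on the same grid")
    spacing = tuple(getattr(model, "spacing", pet.spacing))
    ct_r = resample_to_grid(ct, spacing)
    pet_r = resample_to_grid(pet, spacing)
    div = int(getattr(model, "divisor", 1))
    patch_edge = int(getattr(model, "patch_edge", 0))
    if patch_edge <= 0:
        patch_edge = max(div, (min(ct_r.shape) // div) * div)
    scores = predict_scores_tiled(model, ct_r.data, pet_r.data, patch_edge)
    labels = scores_to_labels(scores, spacing, ct_r.origin)
    labels = keep_largest_component(labels, LabelVolume.LEFT)
    labels = keep_largest_component(labels, LabelVolume.RIGHT)
    native = resample_to_grid(labels, pet.spacing)
    native = _match_shape(native, pet)
    result = compute_srf(pet, native)
    for side, vol in (("left", result.left_volume_ml), ("right", result.right_volume_ml)):
        if 0.0 < vol < SMALL_COMPONENT_ML:
            result.warnings.append(
                f"{side} kidney component is only {vol:.1f} ml (< {SMALL_COMPONENT_ML:.0f} ml); "
                "possibly a spurious segmentation"
            )
    return native, result


def _match_shape(labels: LabelVolume, ref: ImageVolume) -> LabelVolume:
    """Crop/pad labels by at most one voxel per axis to match the reference grid."""
    if labels.shape == ref.shape:
        return LabelVolume(labels.data, ref.spacing, ref.origin)
    data = labels.data
    out = np.zeros(ref.shape, dtype=np.uint8)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(data.shape, ref.shape))
    out[sl] = data[sl]
    return LabelVolume(out, ref.spacing, ref.origin)


class _SymmetrizedModel:
    def __init__(self, model):
        self._model = model
        self.spacing = getattr(model, "spacing", None)
        self.patch_edge = getattr(model, "patch_edge", 0)
        self.divisor = getattr(model, "divisor", 1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        direct = self._model.predict(x)
        mirrored = self._model.predict(np.ascontiguousarray(x[:, ::-1]))
        # flip back and swap the kidney channels
        back = mirrored[:, ::-1][[0, 2, 1]]
        return 0.5 * (direct + back)


def symmetrize_model(model):
    """Wrap a model so its predictions are exactly left-right mirror-consistent.

    The wrapper averages the direct prediction with the mirror-swapped
    prediction on the mirrored input; mirroring the input then provably
    mirror-swaps the output, so LRF%(mirrored case) = 100 - LRF%(case) up to
    tiling asymmetries.
    """
    return _SymmetrizedModel(model)
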