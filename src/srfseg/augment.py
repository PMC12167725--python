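"""Paired spatial and intensity augmentation of (CT, PET, label) patches.

One affine transform (scale o rotate o shear o translate, drawn once per
call) is applied identically to all three patches — trilinearly to CT and
PET, nearest-neighbor to labels — so the triple stays geometrically paired.
Intensity perturbations (additive shift, multiplicative scale, Gaussian
smoothing, additive Gaussian noise) apply to the CT channel only, since
they emulate Hounsfield-unit variation between contrast-enhanced and
low-dose CT; PET intensity jitter would corrupt the SUV sums the LRF%
statistic is built on and is therefore off by default, behind a flag.

Out-of-field voxels created by the affine are filled with ambient values:
-100 HU for CT, 0 for PET and labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, ContractError

__all__ = ["AugmentParams", "augment_triple"]

CT_FILL_HU = -100.0
PET_FILL = 0.0


@dataclass
class AugmentParams:
    """Ranges for the random augmentation draws (all intervals low <= high).

    Each transform family (affine components and each intensity perturbation)
    is applied independently with probability ``apply_prob``. Defaults are
    conventional magnitudes for abdominal CT segmentation.
    """

    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_mm: tuple[float, float] = (-10.0, 10.0)
    rotate_deg: tuple[float, float] = (-10.0, 10.0)
    shear_range: tuple[float, float] = (-0.05, 0.05)
    hu_shift: tuple[float, float] = (-50.0, 50.0)
    hu_scale: tuple[float, float] = (0.9, 1.1)
    smooth_sigma_mm: tuple[float, float] = (0.0, 1.5)
    noise_sd_hu: tuple[float, float] = (0.0, 20.0)
    pet_noise_sd: tuple[float, float] = (0.0, 0.0)
    jitter_pet: bool = False
    apply_prob: float = 0.5

    def __post_init__(self):
        for name in ("scale_range", "translate_mm", "rotate_deg", "shear_range", "hu_shift",
                     "hu_scale", "smooth_sigma_mm", "noise_sd_hu", "pet_noise_sd"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} is not ordered: {lo} > {hi}")
        if not 0.0 <= self.apply_prob <= 1.0:
            raise ConfigError("apply_prob must lie in [0, 1]")

    @classmethod
    def identity(cls) -> "AugmentParams":
        """Degenerate ranges: augmentation becomes a no-op."""
        return cls(
            scale_range=(1.0, 1.0), translate_mm=(0.0, 0.0), rotate_deg=(0.0, 0.0),
            shear_range=(0.0, 0.0), hu_shift=(0.0, 0.0), hu_scale=(1.0, 1.0),
            smooth_sigma_mm=(0.0, 0.0), noise_sd_hu=(0.0, 0.0),
        )


def _rot(angles_rad):
    ax, ay, az = angles_rad
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _draw_affine(params: AugmentParams, rng: np.random.Generator, spacing):
    """Draw the voxel-space matrix A and translation t (content moves by +t)."""
    def maybe(rangespec, size=None, default=0.0):
        lo, hi = rangespec
        if rng.random() < params.apply_prob:
            return rng.uniform(lo, hi, size=size)
        return np.full(size, default) if size else default

    scale = maybe(params.scale_range, default=1.0)
    angles = np.deg2rad(maybe(params.rotate_deg, size=3))
    shears = maybe(params.shear_range, size=3)
    t_mm = maybe(params.translate_mm, size=3)

    sh = np.eye(3)
    sh[0, 1], sh[0, 2], sh[1, 2] = shears
    a = float(scale) * _rot(angles) @ sh
    t_vox = np.asarray(t_mm, dtype=np.float64) / np.asarray(spacing, dtype=np.float64)
    return a, t_vox


def _apply_affine(vol, a, t_vox, order, cval):
    center = (np.array(vol.shape, dtype=np.float64) - 1) / 2.0
    a_inv = np.linalg.inv(a)
    offset = center - a_inv @ (center + t_vox)
    # inverse mapping: input coordinate = A^-1 (output - center - t) + center
    return ndimage.affine_transform(
        vol, a_inv, offset=offset, order=order, mode="constant", cval=cval,
        prefilter=False,
    )


def augment_triple(
    ct: np.ndarray,
    pet: np.ndarray,
    labels: np.ndarray,
    params: AugmentParams,
    rng: np.random.Generator,
    spacing=(2.73, 2.73, 2.79),
):
    """Randomly augment one paired (CT, PET, label) patch triple.

    Returns new arrays; the inputs are never modified. Determinism: the
    output is a pure function of (inputs, params, rng state).
    """
    ct = np.asarray(ct, dtype=np.float32)
    pet = np.asarray(pet, dtype=np.float32)
    labels = np.asarray(labels)
    if not (ct.shape == pet.shape == labels.shape):
        raise ContractError(
            f"patch shapes differ: ct {ct.shape}, pet {pet.shape}, labels {labels.shape}"
        )

    a, t_vox = _draw_affine(params, rng, spacing)
    if not (np.allclose(a, np.eye(3), atol=0.0) and np.all(t_vox == 0.0)):
        ct = _apply_affine(ct, a, t_vox, order=1, cval=CT_FILL_HU).astype(np.float32)
        pet = _apply_affine(pet, a, t_vox, order=1, cval=PET_FILL).astype(np.float32)
        np.clip(pet, 0.0, None, out=pet)
        labels = _apply_affine(labels.astype(np.uint8), a, t_vox, order=0, cval=0)
    else:
        ct, pet, labels = ct.copy(), pet.copy(), labels.copy()

    # CT intensity chain: scale, shift, smooth, noise
    if rng.random() < params.apply_prob:
        ct *= rng.uniform(*params.hu_scale)
    if rng.random() < params.apply_prob:
        ct += rng.uniform(*params.hu_shift)
    if rng.random() < params.apply_prob:
        sigma_mm = rng.uniform(*params.smooth_sigma_mm)
        if sigma_mm > 0:
            sigma_vox = [sigma_mm / s for s in spacing]
            ct = ndimage.gaussian_filter(ct, sigma=sigma_vox, mode="reflect")
    if rng.random() < params.apply_prob:
        sd = rng.uniform(*params.noise_sd_hu)
        if sd > 0:
            ct = ct + rng.normal(0.0, sd, size=ct.shape).astype(np.float32)

    if params.jitter_pet and rng.random() < params.apply_prob:
        sd = rng.uniform(*params.pet_noise_sd)
        if sd > 0:
            pet = pet + rng.normal(0.0, sd, size=pet.shape).astype(np.float32)
            np.clip(pet, 0.0, None, out=pet)

    return ct.astype(np.float32), pet.astype(np.float32), labels.astype(np.uint8)
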