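"""Synthetic abdominal PET/CT phantom with analytically known split renal function.

The generator paints a simplified abdomen on the scanner's voxel grid
(default 2.73 x 2.73 x 2.79 mm): an elliptical body surrounded by air, a
bony spine landmark, moderate-uptake organs, two ellipsoidal kidneys with a
bright cortex shell and a low-uptake pelvis core, a high-uptake bladder and
optional para-aortic distractor lesions. PET is blurred by a Gaussian
point-spread function and degraded with additive noise; CT gets its own
noise. The ground-truth label volume and the true left-renal-function
percentage are computed from the *pre-blur, pre-noise* SUV field, so blur
and noise effects on the measured LRF% are quantifiable biases rather than
moving targets.

The default uptake palette (cortex 25, pelvis 5, bladder 60, background 1)
mimics the qualitative contrast of [18F]PSMA-1007 images, where the renal
cortex and urinary bladder dominate; it is freely overridable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .volumes import ImageVolume, LabelVolume, Modality

__all__ = [
    "KidneySpec",
    "PhantomSpec",
    "PhantomCase",
    "default_phantom_spec",
    "generate_phantom",
    "generate_cohort",
    "simulate_reader",
    "VARIANTS",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

VARIANTS = ("normal", "solitary", "hypoplastic", "low_symmetric", "low_asymmetric")


@dataclass
class KidneySpec:
    """One kidney: an ellipsoid with a cortex shell and a pelvis core.

    ``center`` and ``semi_axes`` are in mm (world coordinates, axis 0 toward
    patient left). The pelvis core is the inner ellipsoid with semi-axes
    scaled by ``pelvis_frac``. SUV fields are multiplied by ``uptake_scale``.
    """

    present: bool = True
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    semi_axes: tuple[float, float, float] = (20.0, 16.0, 32.0)
    cortex_suv: float = 25.0
    pelvis_suv: float = 5.0
    uptake_scale: float = 1.0
    pelvis_frac: float = 0.45

    def validate(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ConfigError(f"kidney semi_axes must be positive, got {self.semi_axes}")
        if not (self.cortex_suv > self.pelvis_suv >= 0):
            raise ConfigError(
                f"need cortex_suv > pelvis_suv >= 0, got {self.cortex_suv}, {self.pelvis_suv}"
            )
        if self.uptake_scale < 0:
            raise ConfigError("uptake_scale must be >= 0")
        if not 0 < self.pelvis_frac < 1:
            raise ConfigError("pelvis_frac must lie in (0, 1)")


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic abdomen."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.73, 2.73, 2.79)
    left: KidneySpec = field(default_factory=KidneySpec)
    right: KidneySpec = field(default_factory=KidneySpec)
    background_suv: float = 1.0
    background_hu: float = 40.0
    kidney_hu: float = 35.0
    air_hu: float = -1000.0
    body_semi_axes: tuple[float, float] | None = None  # mm; None -> 0.46/0.42 of extent
    spine: tuple[float, float] | None = (12.0, 700.0)  # (radius mm, HU) posterior midline rod
    bladder: tuple[tuple[float, float, float], float, float] | None = None  # (center, r mm, SUV)
    organs: tuple = ()  # (center mm, radius mm, SUV, HU) moderate-uptake spheres
    lesions: tuple = ()  # (center mm, radius mm, SUV) para-aortic distractors
    psf_fwhm: float = 4.0  # mm Gaussian blur on PET
    pet_noise_sd: float = 0.5  # SUV
    ct_noise_sd: float = 10.0  # HU
    seed: int = 0

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def validate(self) -> None:
        if any(n < 1 for n in self.shape) or any(s <= 0 for s in self.spacing):
            raise ConfigError("shape components must be >= 1 and spacing > 0")
        self.left.validate()
        self.right.validate()
        for name, val in (
            ("background_suv", self.background_suv),
            ("psf_fwhm", self.psf_fwhm),
            ("pet_noise_sd", self.pet_noise_sd),
            ("ct_noise_sd", self.ct_noise_sd),
        ):
            if val < 0:
                raise ConfigError(f"{name} must be >= 0, got {val}")
        if not (self.left.present or self.right.present):
            raise ConfigError("at least one kidney must be present")
        mid = self.extent_mm()[0] / 2.0
        if self.left.present and self.left.center[0] <= mid:
            raise ConfigError("left kidney center must lie on the patient-left half (axis 0 high)")
        if self.right.present and self.right.center[0] >= mid:
            raise ConfigError("right kidney center must lie on the patient-right half (axis 0 low)")


@dataclass
class PhantomCase:
    """A generated phantom: CT, PET, truth labels and the analytic LRF%."""

    ct: ImageVolume
    pet: ImageVolume
    truth: LabelVolume
    true_lrf_percent: float
    spec: PhantomSpec


def _world_grids(spec: PhantomSpec):
    # voxel center i sits at i * spacing (origin 0)
    return [
        np.arange(n, dtype=np.float64) * s for n, s in zip(spec.shape, spec.spacing)
    ]


def _ellipsoid_mask(grids, center, semi_axes) -> np.ndarray:
    gx, gy, gz = grids
    dx = (gx - center[0]) / semi_axes[0]
    dy = (gy - center[1]) / semi_axes[1]
    dz = (gz - center[2]) / semi_axes[2]
    return (
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    ) <= 1.0


def _sphere_mask(grids, center, radius) -> np.ndarray:
    return _ellipsoid_mask(grids, center, (radius, radius, radius))


def default_phantom_spec(
    shape=(64, 64, 64), spacing=(2.73, 2.73, 2.79), seed: int = 0
) -> PhantomSpec:
    """A mirror-symmetric two-kidney abdomen on the given grid.

    Kidney centers are placed symmetrically about the grid's mid-sagittal
    plane (voxel index (N-1)/2 on axis 0), so equal uptake yields a true
    LRF% of exactly 50.
    """
    nx, ny, nz = shape
    sx, sy, sz = spacing
    lx, ly, lz = nx * sx, ny * sy, nz * sz
    cx_left = 0.70 * (nx - 1) * sx
    cx_right = (nx - 1) * sx - cx_left
    cy, cz = 0.55 * (ny - 1) * sy, 0.50 * (nz - 1) * sz
    kid = dict(semi_axes=(20.0, 16.0, 32.0))
    return PhantomSpec(
        shape=tuple(shape),
        spacing=tuple(spacing),
        left=KidneySpec(center=(cx_left, cy, cz), **kid),
        right=KidneySpec(center=(cx_right, cy, cz), **kid),
        bladder=((0.5 * (nx - 1) * sx, 0.40 * ly, 0.16 * lz), 16.0, 60.0),
        organs=(
            ((0.28 * lx, 0.42 * ly, 0.80 * lz), 22.0, 4.0, 60.0),  # liver-like
            ((0.74 * lx, 0.42 * ly, 0.82 * lz), 14.0, 3.5, 50.0),  # spleen-like
        ),
        seed=seed,
    )


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Rasterize one phantom deterministically from its spec (incl. seed).

    Painting order: body/air, spine, organs, kidneys, bladder, lesions
    (assignment, later paint overwrites). Truth labels and the true LRF%
    come from the painted field *before* the PSF blur and noise; PET is then
    blurred, noised and clamped at 0.
    """
    spec.validate()
    grids = _world_grids(spec)
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    lx, ly, lz = spec.extent_mm()

    body_ax = spec.body_semi_axes or (0.46 * lx, 0.42 * ly)
    gx, gy, _ = grids
    bx = (gx - 0.5 * (nx - 1) * spec.spacing[0]) / body_ax[0]
    by = (gy - 0.5 * (ny - 1) * spec.spacing[1]) / body_ax[1]
    body = (bx[:, None] ** 2 + by[None, :] ** 2) <= 1.0  # elliptical cylinder along z
    body3 = np.broadcast_to(body[:, :, None], spec.shape)

    ct = np.full(spec.shape, spec.air_hu, dtype=np.float64)
    pet = np.zeros(spec.shape, dtype=np.float64)
    ct[body3] = spec.background_hu
    pet[body3] = spec.background_suv

    if spec.spine is not None:
        radius, hu = spec.spine
        sxg = (gx - 0.5 * (nx - 1) * spec.spacing[0]) / radius
        syg = (gy - 0.78 * ly) / radius
        spine = (sxg[:, None] ** 2 + syg[None, :] ** 2) <= 1.0
        ct[np.broadcast_to(spine[:, :, None], spec.shape)] = hu

    for center, radius, suv, hu in spec.organs:
        m = _sphere_mask(grids, center, radius)
        ct[m] = hu
        pet[m] = suv

    masks = {}
    for label, kid in ((LabelVolume.LEFT, spec.left), (LabelVolume.RIGHT, spec.right)):
        if not kid.present:
            masks[label] = np.zeros(spec.shape, dtype=bool)
            continue
        outer = _ellipsoid_mask(grids, kid.center, kid.semi_axes)
        inner = _ellipsoid_mask(
            grids, kid.center, tuple(a * kid.pelvis_frac for a in kid.semi_axes)
        )
        ct[outer] = spec.kidney_hu
        pet[outer] = kid.cortex_suv * kid.uptake_scale
        pet[inner] = kid.pelvis_suv * kid.uptake_scale
        masks[label] = outer
    if (masks[1] & masks[2]).any():
        raise ConfigError("left and right kidney ellipsoids overlap")

    kidney_any = masks[1] | masks[2]
    if spec.bladder is not None:
        center, radius, suv = spec.bladder
        m = _sphere_mask(grids, center, radius)
        if (m & kidney_any).any():
            raise ConfigError("bladder overlaps a kidney ellipsoid")
        pet[m] = suv
    for center, radius, suv in spec.lesions:
        m = _sphere_mask(grids, center, radius)
        if (m & kidney_any).any():
            raise ConfigError("a distractor lesion overlaps a kidney ellipsoid")
        pet[m] = suv

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[masks[1]] = LabelVolume.LEFT
    labels[masks[2]] = LabelVolume.RIGHT

    left_sum = float(pet[masks[1]].sum())
    right_sum = float(pet[masks[2]].sum())
    if left_sum + right_sum <= 0:
        raise ConfigError("phantom has zero total renal uptake")
    true_lrf = 100.0 * left_sum / (left_sum + right_sum)

    if spec.psf_fwhm > 0:
        sigma_vox = [
            spec.psf_fwhm * _FWHM_TO_SIGMA / s for s in spec.spacing
        ]
        pet = ndimage.gaussian_filter(pet, sigma=sigma_vox, mode="nearest")
    if spec.pet_noise_sd > 0:
        pet = pet + rng.normal(0.0, spec.pet_noise_sd, size=spec.shape)
    np.clip(pet, 0.0, None, out=pet)
    if spec.ct_noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.ct_noise_sd, size=spec.shape)

    return PhantomCase(
        ct=ImageVolume(ct, spec.spacing, modality=Modality.CT_HU),
        pet=ImageVolume(pet, spec.spacing, modality=Modality.PET_SUV),
        truth=LabelVolume(labels, spec.spacing),
        true_lrf_percent=true_lrf,
        spec=spec,
    )


def _variant_counts(n: int, mix: dict[str, float]) -> dict[str, int]:
    unknown = set(mix) - set(VARIANTS)
    if unknown:
        raise ConfigError(f"unknown cohort variants: {sorted(unknown)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"variant_mix fractions must sum to 1, got {total!r}")
    # largest-remainder rounding so counts sum to n
    raw = {v: n * mix.get(v, 0.0) for v in VARIANTS}
    counts = {v: int(np.floor(raw[v])) for v in VARIANTS}
    short = n - sum(counts.values())
    order = sorted(VARIANTS, key=lambda v: (-(raw[v] - counts[v]), VARIANTS.index(v)))
    for v in order[:short]:
        counts[v] += 1
    return counts


def generate_cohort(
    n: int,
    seed: int = 0,
    variant_mix: dict[str, float] | None = None,
    shape=(64, 64, 64),
    spacing=(2.73, 2.73, 2.79),
) -> list[PhantomCase]:
    """Generate ``n`` phantoms with per-case randomized anatomy.

    Variants model the clinical hard-case mix: ``solitary`` (one kidney
    absent), ``hypoplastic`` (one kidney half-sized), ``low_symmetric`` and
    ``low_asymmetric`` (global or one-sided uptake reduction). Kidney
    semi-axes are jittered by +-25%, uptake by +-50%, and positions by a few
    mm; everything is deterministic given (n, seed, mix).
    """
    if n < 1:
        raise ConfigError("cohort size must be >= 1")
    mix = dict(variant_mix) if variant_mix is not None else {"normal": 1.0}
    counts = _variant_counts(n, mix)
    variants: list[str] = []
    for v in VARIANTS:
        variants += [v] * counts[v]
    master = np.random.default_rng(seed)
    # deterministic interleave so variants are not ordered blocks
    order = master.permutation(n)
    variants = [variants[i] for i in order]

    cases = []
    for i, variant in enumerate(variants):
        case_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(case_seed)
        spec = default_phantom_spec(shape=shape, spacing=spacing, seed=case_seed)
        left, right = spec.left, spec.right

        def _jitter(kid: KidneySpec, side: str) -> KidneySpec:
            size = rng.uniform(0.75, 1.25)
            uptake = rng.uniform(0.5, 1.5)
            jit = rng.uniform(-4.0, 4.0, size=3)
            cx = kid.center[0] + float(np.clip(jit[0], -4.0, 4.0))
            mid = spec.extent_mm()[0] / 2.0
            # keep the kidney firmly in its half
            cx = max(cx, mid + 25.0) if side == "left" else min(cx, mid - 25.0)
            center = (cx, kid.center[1] + jit[1], kid.center[2] + jit[2])
            return replace(
                kid,
                center=center,
                semi_axes=tuple(a * size for a in kid.semi_axes),
                uptake_scale=kid.uptake_scale * uptake,
            )

        left, right = _jitter(left, "left"), _jitter(right, "right")
        which = "left" if rng.random() < 0.5 else "right"
        if variant == "solitary":
            if which == "left":
                left = replace(left, present=False)
            else:
                right = replace(right, present=False)
        elif variant == "hypoplastic":
            target = left if which == "left" else right
            shrunk = replace(target, semi_axes=tuple(a * 0.5 for a in target.semi_axes))
            left, right = (shrunk, right) if which == "left" else (left, shrunk)
        elif variant == "low_symmetric":
            left = replace(left, uptake_scale=left.uptake_scale * 0.3)
            right = replace(right, uptake_scale=right.uptake_scale * 0.3)
        elif variant == "low_asymmetric":
            target = left if which == "left" else right
            dimmed = replace(target, uptake_scale=target.uptake_scale * 0.3)
            left, right = (dimmed, right) if which == "left" else (left, dimmed)
        spec = replace(spec, left=left, right=right, seed=case_seed)
        cases.append(generate_phantom(spec))
    return cases


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _shift_mask(mask: np.ndarray, amount: float, rng: np.random.Generator) -> np.ndarray:
    """Dilate (amount > 0) or erode (amount < 0) a mask by a possibly
    fractional number of 26-connected boundary layers; the fractional layer
    is applied by random voxel toggling with that probability."""
    full, frac = int(np.floor(abs(amount))), abs(amount) - np.floor(abs(amount))
    grow = amount > 0
    for _ in range(full):
        op = ndimage.binary_dilation if grow else ndimage.binary_erosion
        mask = op(mask, structure=_STRUCT26)
    if frac > 0:
        if grow:
            shell = ndimage.binary_dilation(mask, structure=_STRUCT26) & ~mask
            mask = mask | (shell & (rng.random(mask.shape) < frac))
        else:
            shell = mask & ~ndimage.binary_erosion(mask, structure=_STRUCT26)
            mask = mask & ~(shell & (rng.random(mask.shape) < frac))
    return mask


def simulate_reader(truth: LabelVolume, max_shift_voxels: float, seed: int = 0) -> LabelVolume:
    """A surrogate human reader: style-consistent boundary dilation/erosion.

    Real readers segment generously or tightly in a consistent way, so the
    dominant perturbation — a boundary shift of up to ``max_shift_voxels``
    (possibly fractional) layers, drawn once per call — is applied to both
    kidneys, with a small independent per-kidney jitter on top. This
    reproduces the clinically observed pattern in which segmented volumes
    differ substantially between readers while the LRF% ratio barely moves.
    Dilated masks never overwrite the other kidney;
    ``max_shift_voxels == 0`` returns the truth unchanged.
    """
    if max_shift_voxels < 0:
        raise ConfigError("max_shift_voxels must be >= 0")
    if max_shift_voxels == 0:
        return LabelVolume(truth.data.copy(), truth.spacing, truth.origin)
    rng = np.random.default_rng(seed)
    style = rng.uniform(-max_shift_voxels, max_shift_voxels)
    out = np.zeros_like(truth.data)
    for label in (LabelVolume.LEFT, LabelVolume.RIGHT):
        mask = truth.mask(label)
        if not mask.any():
            continue
        amount = float(
            np.clip(style + 0.15 * max_shift_voxels * rng.standard_normal(),
                    -max_shift_voxels, max_shift_voxels)
        )
        mask = _shift_mask(mask, amount, rng)
        out[mask & (out == 0) & ~truth.mask(3 - label)] = label
    return LabelVolume(out, truth.spacing, truth.origin)


def spec_to_dict(spec: PhantomSpec) -> dict:
    """JSON-serializable form of a spec, for cohort manifests."""
    return json.loads(json.dumps(asdict(spec)))


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    d["left"] = KidneySpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in d["left"].items()})
    d["right"] = KidneySpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in d["right"].items()})
    for key in ("shape", "spacing", "body_semi_axes", "spine", "bladder"):
        if d.get(key) is not None:
            d[key] = _tuplify(d[key])
    for key in ("organs", "lesions"):
        d[key] = tuple(_tuplify(x) for x in d.get(key, ()))
    return PhantomSpec(**d)


def _tuplify(x):
    if isinstance(x, (list, tuple)):
        return tuple(_tuplify(v) for v in x)
    return x
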