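"""Preprocessing and the contour-augmentation engine.

Preprocessing follows the recipe of the quality network: volumes are
center-cropped (by default to half the in-plane extent, all slices kept),
intensity-normalized by mapping the 0th and 99th percentiles linearly onto
[0, 255], and stacked with the binary contour on a trailing channel axis to
form an (nx, ny, nz, 2) tensor.

Training pairs are manufactured so that their Dice targets cover far more
than the narrow band a deployed segmentation model produces: a "fake" pair
replaces a case's contour with one swapped from a different case and scales
it by a random factor in [0.55, 1.8]; both real and fake pairs then pass
through one sampled geometric transform chain (horizontal flip, in-plane
rotation within ±π/12, ±10% x/y translation, ±10% zoom, elastic
deformation) applied identically to the image, the contour and the ground
truth.  The Dice target of every emitted sample is recomputed from the
emitted contour channel against the identically transformed ground truth —
after all transforms, never copied from a pre-transform value — so targets
remain exact even under elastic deformation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from contourqa.core import Volume, as_mask, check_same_shape
from contourqa.metrics import dice
from contourqa.phantom import PhantomCase


@dataclass
class QaSample:
    """One network input: (x, y, z, 2) tensor plus an exact Dice target.

    Channel 0 is the normalized image, channel 1 the binary contour.
    """

    tensor: np.ndarray
    target: float
    is_fake: bool = False
    case_id: str = ""
    #: provenance of the sample (sampled transform parameters etc.),
    #: serialized into the JSONL audit trail by the sample dump helpers
    meta: dict = None

    def __post_init__(self) -> None:
        if self.tensor.ndim != 4 or self.tensor.shape[-1] != 2:
            raise ValueError(f"sample tensor must be (x, y, z, 2), got {self.tensor.shape}")
        if not 0.0 <= self.target <= 1.0:
            raise ValueError(f"target must be in [0, 1], got {self.target}")

    @property
    def image(self) -> np.ndarray:
        return self.tensor[..., 0]

    @property
    def contour(self) -> np.ndarray:
        return self.tensor[..., 1]


@dataclass(frozen=True)
class AugmentConfig:
    """Parameters of the geometric augmentation chain.

    Angles are radians; translation and zoom fractions are relative to the
    in-plane crop extent.  ``elastic_alpha`` is the displacement amplitude
    in voxels, ``elastic_sigma`` the smoothness of the displacement field.
    Set a range to 0 (or ``elastic_alpha`` to 0) to disable that stage.
    """

    scale_range: tuple[float, float] = (0.55, 1.8)
    rotation_range: float = math.pi / 12.0
    translate_frac: float = 0.10
    zoom_frac: float = 0.10
    hflip_prob: float = 0.5
    elastic_sigma: float = 6.0
    elastic_alpha: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError("scale_range must be positive")
        if min(self.rotation_range, self.translate_frac, self.zoom_frac,
               self.elastic_sigma, self.elastic_alpha) < 0:
            raise ValueError("augmentation ranges must be >= 0")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must be in [0, 1]")

    def identity(self) -> "AugmentConfig":
        """Config whose every stage is the identity transform."""
        return AugmentConfig(
            scale_range=(1.0, 1.0), rotation_range=0.0, translate_frac=0.0,
            zoom_frac=0.0, hflip_prob=0.0, elastic_sigma=self.elastic_sigma,
            elastic_alpha=0.0, seed=self.seed,
        )


ArrayOrVolume = Union[np.ndarray, Volume]


def center_crop(vol: ArrayOrVolume, out_shape: tuple[int, int, int]) -> ArrayOrVolume:
    """Spatially centered crop.

    For an odd margin the window starts at floor(margin / 2), so the extra
    voxel is dropped from the high-index side.
    """
    data = vol.data if isinstance(vol, Volume) else vol
    if any(o > i for o, i in zip(out_shape, data.shape)):
        raise ValueError(f"crop shape {out_shape} exceeds input shape {data.shape}")
    starts = [(i - o) // 2 for i, o in zip(data.shape, out_shape)]
    sl = tuple(slice(s, s + o) for s, o in zip(starts, out_shape))
    out = data[sl]
    if isinstance(vol, Volume):
        return Volume(out, vol.spacing)
    return out


def normalize_intensity(vol: Volume, clip: bool = False) -> Volume:
    """Affine intensity map sending the 0th percentile to 0 and the 99th to 255.

    Values above the 99th percentile follow the same affine map and may
    exceed 255 (their information is retained); pass ``clip=True`` to clamp
    into [0, 255] instead.  Raises for constant-like images (p0 == p99).
    """
    data = np.asarray(vol.data, dtype=np.float64)
    p0 = float(data.min())
    p99 = float(np.percentile(data, 99))
    if p99 <= p0:
        raise ValueError("cannot normalize: 0th and 99th percentiles coincide")
    out = (data - p0) * (255.0 / (p99 - p0))
    if clip:
        out = np.clip(out, 0.0, 255.0)
    return Volume(out, vol.spacing)


def stack_channels(image: Volume, contour: np.ndarray) -> np.ndarray:
    """Concatenate image and binary contour on a trailing channel axis."""
    contour = as_mask(contour, "contour")
    check_same_shape(image.data, contour)
    return np.stack([image.data, contour.astype(np.float64)], axis=-1)


def swap_contour(
    sample_case: str, pool: Sequence[PhantomCase], rng: np.random.Generator
) -> tuple[np.ndarray, str]:
    """Draw a contour from a pool case other than ``sample_case``."""
    donors = [c for c in pool if c.case_id != sample_case]
    if not donors:
        raise ValueError("contour swap needs a pool with >= 2 distinct cases")
    donor = donors[int(rng.integers(len(donors)))]
    mask, _ = donor.auto_contours[int(rng.integers(len(donor.auto_contours)))]
    return mask, donor.case_id


def scale_contour(mask: np.ndarray, factor: float) -> np.ndarray:
    """Isotropic in-plane scaling about the mask centroid (z untouched).

    Nearest-neighbor resampling; voxels scaled out of the field of view are
    dropped.  Raises if the result is empty.
    """
    mask = as_mask(mask, "mask")
    if factor <= 0:
        raise ValueError(f"scale factor must be > 0, got {factor}")
    if not mask.any():
        raise ValueError("cannot scale an empty mask")
    if factor == 1.0:
        return mask.copy()
    c = ndimage.center_of_mass(mask)
    matrix = np.diag([1.0 / factor, 1.0 / factor, 1.0])
    offset = np.array(c) - matrix @ np.array(c)
    out = ndimage.affine_transform(
        mask.astype(np.float32), matrix, offset=offset, order=0,
        mode="constant", cval=0.0, prefilter=False,
    ) > 0.5
    if not out.any():
        raise ValueError(f"scaling by {factor} left no voxels in the field of view")
    return out


@dataclass
class GeometricTransform:
    """One sampled transform chain, applicable to images and masks alike.

    The chain is flip → rotation → x/y translation → zoom → elastic
    deformation.  The flip is an exact axis reversal; the continuous stages
    are fused into a single inverse coordinate map so that each array is
    interpolated only once (linear for images, nearest for masks).
    """

    shape: tuple[int, int, int]
    flip: bool = False
    theta: float = 0.0
    translate: tuple[float, float] = (0.0, 0.0)
    zoom: float = 1.0
    disp: Optional[tuple[np.ndarray, np.ndarray]] = None  # (dx, dy) fields
    _coords: Optional[np.ndarray] = None

    @property
    def is_continuous_identity(self) -> bool:
        return (
            self.theta == 0.0 and self.translate == (0.0, 0.0)
            and self.zoom == 1.0 and self.disp is None
        )

    def _coordinate_map(self) -> np.ndarray:
        if self._coords is not None:
            return self._coords
        nx, ny, nz = self.shape
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        X, Y, Z = np.meshgrid(
            np.arange(nx, dtype=np.float32),
            np.arange(ny, dtype=np.float32),
            np.arange(nz, dtype=np.float32),
            indexing="ij",
        )
        # Inverse map: where each output voxel samples the input.
        u = X - cx - self.translate[0]
        v = Y - cy - self.translate[1]
        ct, st = math.cos(self.theta), math.sin(self.theta)
        xi = cx + (ct * u + st * v) / self.zoom
        yi = cy + (-st * u + ct * v) / self.zoom
        if self.disp is not None:
            xi = xi + self.disp[0]
            yi = yi + self.disp[1]
        self._coords = np.stack([xi, yi, Z])
        return self._coords

    def describe(self) -> dict:
        """JSON-serializable record of the sampled parameters."""
        return {
            "flip": self.flip,
            "theta": self.theta,
            "translate": list(self.translate),
            "zoom": self.zoom,
            "elastic": self.disp is not None,
        }

    def apply_image(self, data: np.ndarray) -> np.ndarray:
        out = np.flip(data, axis=0) if self.flip else data
        if self.is_continuous_identity:
            return out.copy() if out is data else out
        return ndimage.map_coordinates(
            out, self._coordinate_map(), order=1, mode="constant", cval=0.0
        )

    def apply_mask(self, mask: np.ndarray) -> np.ndarray:
        out = np.flip(mask, axis=0) if self.flip else mask
        if self.is_continuous_identity:
            return out.copy() if out is mask else out
        res = ndimage.map_coordinates(
            out.astype(np.float32), self._coordinate_map(), order=0,
            mode="constant", cval=0.0,
        )
        return res > 0.5


def sample_transform(
    shape: tuple[int, int, int], cfg: AugmentConfig, rng: np.random.Generator
) -> GeometricTransform:
    """Draw one transform chain from the configured ranges."""
    flip = bool(rng.uniform() < cfg.hflip_prob)
    theta = float(rng.uniform(-cfg.rotation_range, cfg.rotation_range)) \
        if cfg.rotation_range > 0 else 0.0
    tx = float(rng.uniform(-cfg.translate_frac, cfg.translate_frac)) * shape[0] \
        if cfg.translate_frac > 0 else 0.0
    ty = float(rng.uniform(-cfg.translate_frac, cfg.translate_frac)) * shape[1] \
        if cfg.translate_frac > 0 else 0.0
    zoom = float(rng.uniform(1.0 - cfg.zoom_frac, 1.0 + cfg.zoom_frac)) \
        if cfg.zoom_frac > 0 else 1.0
    disp = None
    if cfg.elastic_alpha > 0:
        fields = []
        for _ in range(2):
            f = ndimage.gaussian_filter(
                rng.standard_normal(shape), sigma=cfg.elastic_sigma
            )
            sd = f.std()
            fields.append((f / sd * cfg.elastic_alpha).astype(np.float32)
                          if sd > 0 else np.zeros(shape, np.float32))
        disp = (fields[0], fields[1])
    return GeometricTransform(
        shape=shape, flip=flip, theta=theta, translate=(tx, ty),
        zoom=zoom, disp=disp,
    )


def geometric_augment(
    image: Volume,
    masks: Sequence[np.ndarray],
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[Volume, list[np.ndarray]]:
    """Apply ONE sampled transform chain identically to image and masks.

    The image is interpolated linearly, masks nearest-neighbor and
    re-binarized; out-of-field regions are zero-filled.
    """
    for m in masks:
        check_same_shape(image.data, m)
    t = sample_transform(image.shape, cfg, rng)
    out_img = Volume(t.apply_image(image.data), image.spacing)
    out_masks = [t.apply_mask(as_mask(m)) for m in masks]
    return out_img, out_masks


def default_crop_shape(shape: tuple[int, int, int]) -> tuple[int, int, int]:
    """Half the in-plane extent, all slices kept (320×320×28 → 160×160×28)."""
    return (shape[0] // 2, shape[1] // 2, shape[2])


def preprocess_pair(
    case: PhantomCase,
    contour: np.ndarray,
    crop_shape: Optional[tuple[int, int, int]] = None,
    transform: Optional[GeometricTransform] = None,
    is_fake: bool = False,
    return_gt: bool = False,
    normalize_before_crop: bool = False,
):
    """Crop, normalize, optionally transform, stack, and recompute the target.

    Percentiles are computed on the cropped field of view by default;
    ``normalize_before_crop`` computes them on the full volume instead.
    The ground truth is carried through the identical crop/transform solely
    to recompute the Dice target, then discarded — unless ``return_gt`` is
    set, in which case (sample, transformed_gt) is returned so callers can
    verify target exactness independently.
    """
    crop_shape = crop_shape or default_crop_shape(case.image.shape)
    image = normalize_intensity(case.image) if normalize_before_crop else case.image
    img = center_crop(image, crop_shape)
    con = center_crop(as_mask(contour, "contour"), crop_shape)
    gt = center_crop(case.gt, crop_shape)
    if not normalize_before_crop:
        img = normalize_intensity(img)
    if transform is not None:
        img = Volume(transform.apply_image(img.data), img.spacing)
        con = transform.apply_mask(con)
        gt = transform.apply_mask(gt)
    if con.any() or gt.any():
        target = dice(con, gt)
    else:
        # Both masks transformed out of the field: identical empties.
        target = 1.0
    sample = QaSample(
        tensor=stack_channels(img, con), target=target,
        is_fake=is_fake, case_id=case.case_id,
        meta={"transform": transform.describe() if transform else None},
    )
    return (sample, gt) if return_gt else sample


def make_training_batch(
    real_case: PhantomCase,
    pool: Sequence[PhantomCase],
    cfg: AugmentConfig,
    rng: np.random.Generator,
    crop_shape: Optional[tuple[int, int, int]] = None,
    n_pairs: int = 1,
    return_gts: bool = False,
):
    """Build a training batch with a 1:1 real:fake sample ratio.

    Each real sample pairs a case's image with one of its own auto contours;
    each fake sample pairs a pool case's image with a contour swapped from a
    *different* case and scaled by a random factor from ``cfg.scale_range``.
    All samples then receive independent geometric augmentation, and every
    target is the Dice of the emitted contour channel against the
    identically transformed ground truth.  With ``return_gts`` the
    transformed ground truths are returned alongside for verification.
    """
    if len(pool) < 2:
        raise ValueError("training batch needs a pool of >= 2 cases")
    samples: list[QaSample] = []
    gts: list[np.ndarray] = []
    for _ in range(n_pairs):
        # Real pair.
        mask, _ = real_case.auto_contours[int(rng.integers(len(real_case.auto_contours)))]
        t = _sample_crop_transform(real_case, crop_shape, cfg, rng)
        s, gt = preprocess_pair(real_case, mask, crop_shape, t, is_fake=False,
                                return_gt=True)
        samples.append(s)
        gts.append(gt)
        # Fake pair: another image, swapped + scaled contour.
        img_case = pool[int(rng.integers(len(pool)))]
        swapped, _ = swap_contour(img_case.case_id, pool, rng)
        factor = float(rng.uniform(*cfg.scale_range))
        if swapped.any():  # a degraded donor contour may itself be empty
            swapped = scale_contour(swapped, factor)
        t = _sample_crop_transform(img_case, crop_shape, cfg, rng)
        s, gt = preprocess_pair(img_case, swapped, crop_shape, t, is_fake=True,
                                return_gt=True)
        samples.append(s)
        gts.append(gt)
        real_case = pool[int(rng.integers(len(pool)))]  # next pair's real case
    return (samples, gts) if return_gts else samples


def _sample_crop_transform(case, crop_shape, cfg, rng) -> GeometricTransform:
    shape = crop_shape or default_crop_shape(case.image.shape)
    return sample_transform(tuple(shape), cfg, rng)
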