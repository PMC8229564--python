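"""Reading, writing and geometric preparation of islet image planes.

The pipeline operates on 8-bit greyscale channel planes (insulin, laminin,
nuclei, optionally a membrane marker) stored one PNG per channel per z-plane,
plus integer instance-label maps stored as 16-bit PNG.  Confocal stacks are
anisotropic: the lateral pixel pitch (typically ~0.09 µm native, ~0.36 µm
after resizing to 512 x 512) differs from the z-step (~0.34 µm), so 3-D
volumes carry an explicit z/xy scale factor rather than resampled voxels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.transform import AffineTransform, resize as _sk_resize, warp

__all__ = [
    "IntensityPlane",
    "VoxelGeometry",
    "AugmentSpec",
    "Volume",
    "read_plane",
    "write_plane",
    "read_labels",
    "write_labels",
    "resize_plane",
    "sample_transform",
    "apply_transform",
    "augment_dataset",
    "stack_masks",
    "export_volume",
    "load_volume",
]


@dataclass(frozen=True)
class IntensityPlane:
    """A single-channel 2-D image plane with physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D 8-bit intensity array.
    pixel_size_um : float
        Physical edge length of one pixel in micrometres.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"plane must be 2-D, got shape {px.shape}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class VoxelGeometry:
    """Anisotropic voxel dimensions of a confocal stack (micrometres)."""

    xy_um: float
    z_um: float

    def __post_init__(self) -> None:
        if not (self.xy_um > 0 and self.z_um > 0):
            raise ValueError("voxel dimensions must be positive")

    @property
    def z_scale(self) -> float:
        """Axial-to-lateral spacing ratio (the 1:1:z display scale)."""
        return self.z_um / self.xy_um


@dataclass(frozen=True)
class AugmentSpec:
    """Random geometric augmentation settings for training-pair expansion.

    Each source image/mask pair yields ``n_iterations`` new pairs, each under
    one random affine transform combining rotation, shear, horizontal and
    vertical shifts, and optional mirror flips.  The same transform is always
    applied to an image and to its mask.
    """

    n_iterations: int = 8
    rotation_deg: float = 90.0
    shear: float = 0.15
    shift_frac: float = 0.10
    flip_h: bool = True
    flip_v: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")


@dataclass
class Volume:
    """A z-stacked volume with display anisotropy kept as metadata."""

    voxels: np.ndarray  # (z, rows, cols)
    geometry: VoxelGeometry

    @property
    def z_scale(self) -> float:
        return self.geometry.z_scale


# ---------------------------------------------------------------------------
# plane / label I/O


def read_plane(path, pixel_size_um: float = 1.0) -> IntensityPlane:
    px = np.asarray(iio.imread(path))
    if px.ndim == 3:  # collapse an RGB(A) PNG to grey by first channel
        px = px[..., 0]
    return IntensityPlane(px.astype(np.uint8), pixel_size_um)


def write_plane(path, plane: IntensityPlane) -> None:
    iio.imwrite(path, plane.pixels.astype(np.uint8))


def read_labels(path) -> np.ndarray:
    return np.asarray(iio.imread(path)).astype(np.int32)


def write_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label values must fit in uint16")
    iio.imwrite(path, labels.astype(np.uint16))


# ---------------------------------------------------------------------------
# resizing


def resize_plane(plane: IntensityPlane, target: int, kind: str = "intensity") -> IntensityPlane:
    """Resize a square plane to ``target`` x ``target`` pixels.

    Intensities are bilinearly interpolated; masks/labels use nearest
    neighbour so values stay in the original label set.  The physical pixel
    size is rescaled by input_size/target, e.g. a 2048-pixel plane at
    0.0901 µm/px becomes a 512-pixel plane at 0.3604 µm/px.
    """
    if target < 1:
        raise ValueError("target size must be >= 1")
    h, w = plane.shape
    if h != w:
        raise ValueError(f"resize_plane expects a square plane, got {h}x{w}")
    if kind not in ("intensity", "mask"):
        raise ValueError("kind must be 'intensity' or 'mask'")
    if target == h:
        return plane
    order = 1 if kind == "intensity" else 0
    out = _sk_resize(
        plane.pixels.astype(float),
        (target, target),
        order=order,
        anti_aliasing=False,
        preserve_range=True,
    )
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return IntensityPlane(out, plane.pixel_size_um * h / target)


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class _Transform:
    rotation_rad: float
    shear_rad: float
    shift_rc: tuple[float, float]
    flip_h: bool
    flip_v: bool


def sample_transform(spec: AugmentSpec, shape: tuple[int, int], rng: np.random.Generator) -> _Transform:
    """Draw one random transform from the ranges in ``spec``."""
    rot = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
    shear = rng.uniform(-spec.shear, spec.shear)
    dr = rng.uniform(-spec.shift_frac, spec.shift_frac) * shape[0]
    dc = rng.uniform(-spec.shift_frac, spec.shift_frac) * shape[1]
    fh = bool(spec.flip_h and rng.random() < 0.5)
    fv = bool(spec.flip_v and rng.random() < 0.5)
    return _Transform(rot, shear, (dr, dc), fh, fv)


def apply_transform(img: np.ndarray, tf: _Transform, kind: str) -> np.ndarray:
    """Apply a sampled transform to one array; ``kind`` picks interpolation."""
    arr = np.asarray(img, dtype=float)
    if tf.flip_h:
        arr = arr[:, ::-1]
    if tf.flip_v:
        arr = arr[::-1, :]
    h, w = arr.shape
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)
    affine = (
        AffineTransform(translation=-centre)
        + AffineTransform(rotation=tf.rotation_rad, shear=tf.shear_rad)
        + AffineTransform(translation=centre)
        + AffineTransform(translation=(tf.shift_rc[1], tf.shift_rc[0]))
    )
    order = 1 if kind == "intensity" else 0
    out = warp(arr, affine.inverse, order=order, mode="reflect", preserve_range=True)
    if kind == "mask":
        return (out > 0.5).astype(np.uint8)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment_dataset(images: list, masks: list, spec: AugmentSpec):
    """Expand a training set by random affine transforms.

    Returns exactly ``spec.n_iterations * len(images)`` new (image, mask)
    pairs, originals excluded; e.g. 95 annotated planes at the default eight
    iterations yield 760 augmented pairs.  Deterministic for a fixed
    ``spec.seed``.
    """
    if len(images) != len(masks):
        raise ValueError("images and masks must be aligned 1:1")
    rng = np.random.default_rng(spec.seed)
    aug_images, aug_masks = [], []
    for _ in range(spec.n_iterations):
        for img, msk in zip(images, masks):
            img = np.asarray(img)
            if img.shape != np.asarray(msk).shape:
                raise ValueError("image/mask shape mismatch")
            tf = sample_transform(spec, img.shape, rng)
            aug_images.append(apply_transform(img, tf, "intensity"))
            aug_masks.append(apply_transform(msk, tf, "mask"))
    return aug_images, aug_masks


# ---------------------------------------------------------------------------
# volumes


def stack_masks(planes: list, geometry: VoxelGeometry) -> Volume:
    """Assemble per-plane masks into a 3-D volume.

    The axial anisotropy (z_um / xy_um, ~3.7 for the reference confocal
    geometry) is stored as metadata for viewers to apply rather than by
    resampling voxels, which would be lossy.
    """
    if len(planes) == 0:
        raise ValueError("need at least one plane")
    arrs = [np.asarray(p) for p in planes]
    shape0 = arrs[0].shape
    for a in arrs:
        if a.shape != shape0:
            raise ValueError("all planes must share one shape")
    return Volume(np.stack(arrs, axis=0), geometry)


def export_volume(vol: Volume, path) -> None:
    """Write a volume as multi-page TIFF with voxel geometry metadata."""
    if vol.voxels.size == 0:
        raise ValueError("cannot export an empty volume")
    meta = {
        "xy_um": vol.geometry.xy_um,
        "z_um": vol.geometry.z_um,
        "z_scale": vol.geometry.z_scale,
    }
    tifffile.imwrite(path, vol.voxels, description=json.dumps(meta))


def load_volume(path) -> Volume:
    with tifffile.TiffFile(path) as tf:
        voxels = tf.asarray()
        desc = tf.pages[0].tags["ImageDescription"].value
    meta = json.loads(desc)
    return Volume(voxels, VoxelGeometry(meta["xy_um"], meta["z_um"]))
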