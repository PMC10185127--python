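"""Homogenize head volumes into per-eye volumes of interest.

Pipeline: detect the two eye-globe centroids with a 3D spherical Hough
transform, measure the in-plane head rotation from the inter-centroid
vector, rotate and resample to 0.3 mm isotropic in a single composed
transform, crop fixed-size per-eye VOIs and z-normalize intensities.
A polynomial bias-flattening hook substitutes for external N4 correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import BinaryMask, VolumeGrid

ISO_SPACING_MM = 0.3
VOI_SHAPE = (144, 240, 112)
VOI_ANTERIOR_MM = 20.0
ANGLE_THRESHOLD_DEG = 5.0
DEFAULT_RADIUS_RANGE_MM = (9.0, 14.0)  # documented guess; not stated for pediatric eyes


@dataclass
class EyePair:
    """Detected left/right eye centroids (world mm) and head-rotation angle."""

    left_centroid: np.ndarray
    right_centroid: np.ndarray
    rotation_angle: float  # degrees, in [0, 90)

    def __post_init__(self) -> None:
        self.left_centroid = np.asarray(self.left_centroid, dtype=float)
        self.right_centroid = np.asarray(self.right_centroid, dtype=float)
        if np.allclose(self.left_centroid, self.right_centroid):
            raise ValueError("centroids must be distinct")
        if not (0.0 <= self.rotation_angle < 90.0):
            raise ValueError("rotation angle must be in [0, 90)")

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.left_centroid + self.right_centroid)


def rotation_angle(pair_or_left, right=None) -> float:
    """In-plane (axial) angle in degrees between the inter-centroid vector
    and the left-right world axis."""
    if right is None:
        left, right = pair_or_left.left_centroid, pair_or_left.right_centroid
    else:
        left = pair_or_left
    v = np.asarray(right, dtype=float) - np.asarray(left, dtype=float)
    if np.hypot(v[0], v[1]) < 1e-12:
        raise ValueError("centroids coincide in the axial plane")
    return float(abs(np.degrees(np.arctan2(abs(v[1]), abs(v[0])))))


def signed_rotation_angle(pair: EyePair) -> float:
    """Signed axial angle; rotating the content by its negative aligns the
    centroids with the left-right axis."""
    v = pair.right_centroid - pair.left_centroid
    return float(np.degrees(np.arctan2(v[1], v[0])))


# --------------------------------------------------------------------------- #
# Eye detection: spherical Hough transform
# --------------------------------------------------------------------------- #

def detect_eye_centroids(
    vol: VolumeGrid,
    radius_range=DEFAULT_RADIUS_RANGE_MM,
    n_radii: int = 6,
    accumulator_bin_mm: float = 1.0,
    edge_percentile: float = 99.0,
    min_separation_mm: float = 20.0,
    score_ratio: float = 0.4,
) -> EyePair:
    """Locate the two bright quasi-spherical globes.

    Gradient-direction voting: every strong-gradient voxel casts votes at
    candidate centers displaced along its (inward-pointing) gradient by each
    candidate radius. The accumulator is Gaussian-smoothed; peaks are taken
    with non-max suppression at ``min_separation_mm``. Peak positions are
    refined to sub-voxel precision by an intensity center-of-mass inside the
    detected sphere.
    """
    data = np.asarray(vol.voxels, dtype=float)
    g = np.gradient(data, *vol.spacing)
    gmag = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
    thr = np.percentile(gmag, edge_percentile)
    edge = gmag > max(thr, 1e-12)
    if not np.any(edge):
        raise ValueError("eyes not found: no gradient edges")
    eidx = np.argwhere(edge)
    world = vol.voxel_to_world(eidx)
    if world.ndim == 1:
        world = world[None]
    # bright sphere: intensity increases toward the inside, so the gradient
    # points from the edge toward the center
    ghat = np.stack([g[a][edge] for a in range(3)], axis=1)
    ghat /= np.linalg.norm(ghat, axis=1, keepdims=True)
    weights = gmag[edge]

    lo = world.min(axis=0) - radius_range[1]
    hi = world.max(axis=0) + radius_range[1]
    nbins = np.maximum(np.ceil((hi - lo) / accumulator_bin_mm).astype(int) + 1, 1)
    acc = np.zeros(nbins)
    radii = np.linspace(radius_range[0], radius_range[1], n_radii)
    best_r = np.zeros(nbins)
    for r in radii:
        centers = world + r * ghat
        bins = np.round((centers - lo) / accumulator_bin_mm).astype(int)
        ok = np.all((bins >= 0) & (bins < nbins), axis=1)
        layer = np.zeros(nbins)
        np.add.at(layer, tuple(bins[ok].T), weights[ok])
        newmax = layer > acc
        best_r[newmax] = r
        acc = np.maximum(acc, layer)  # per-bin best radius response
    acc = ndimage.gaussian_filter(acc, sigma=1.0)

    peaks = []
    work = acc.copy()
    excl = int(np.ceil(min_separation_mm / accumulator_bin_mm))
    for _ in range(2):
        p = np.unravel_index(np.argmax(work), work.shape)
        score = work[p]
        peaks.append((np.asarray(p), score))
        sl = tuple(
            slice(max(0, p[a] - excl), min(nbins[a], p[a] + excl + 1)) for a in range(3)
        )
        work[sl] = 0.0
    if peaks[1][1] < score_ratio * peaks[0][1] or peaks[0][1] <= 0:
        raise ValueError("eyes not found")

    centers = []
    for p, _ in peaks:
        c0 = lo + p * accumulator_bin_mm
        r0 = best_r[tuple(p)] if best_r[tuple(p)] > 0 else radii.mean()
        centers.append(_refine_center(vol, c0, r0))
    centers.sort(key=lambda c: c[0])  # ascending world x: left first (RAS)
    ang = rotation_angle(centers[0], centers[1])
    return EyePair(centers[0], centers[1], ang)


def _refine_center(vol: VolumeGrid, center: np.ndarray, radius: float) -> np.ndarray:
    """Sub-voxel refinement: intensity center of mass of bright voxels inside
    the candidate sphere."""
    idx_c = vol.world_to_voxel(center)
    rad_vox = np.ceil(radius / vol.spacing).astype(int) + 2
    lo = np.maximum(np.round(idx_c).astype(int) - rad_vox, 0)
    hi = np.minimum(np.round(idx_c).astype(int) + rad_vox + 1, vol.shape)
    sub = np.asarray(vol.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]], dtype=float)
    ii, jj, kk = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = vol.voxel_to_world(pts).reshape(sub.shape + (3,))
    inside = np.linalg.norm(world - center, axis=-1) <= radius
    if not np.any(inside):
        return center
    vals = sub[inside]
    thr = 0.5 * (vals.max() + vals.min())
    bright = inside & (sub > thr)
    if not np.any(bright):
        return center
    w = sub * bright
    return (world * w[..., None]).sum(axis=(0, 1, 2)) / w.sum()


# --------------------------------------------------------------------------- #
# Rotation + resampling
# --------------------------------------------------------------------------- #

def _rot_z(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotate_resample(
    vol: VolumeGrid,
    angle: float,
    is_mask: bool = False,
    center: np.ndarray | None = None,
    out_spacing: float = ISO_SPACING_MM,
) -> VolumeGrid:
    """Rotate about the axial (z) axis and resample to isotropic spacing in
    one composed transform.

    The output value at world position p is the input sampled at
    ``c + R(angle) (p - c)``; linear interpolation for intensities,
    nearest-neighbour for masks. ``|angle|`` must be < 45 degrees.
    """
    if abs(angle) >= 45.0:
        raise ValueError("|angle| must be < 45 degrees")
    if center is None:
        center = vol.voxel_to_world(0.5 * (np.asarray(vol.shape) - 1))
    center = np.asarray(center, dtype=float)
    R = _rot_z(angle)

    # output FOV: input corner positions mapped by the inverse rotation
    corners_idx = np.array([[i, j, k] for i in (0, vol.shape[0] - 1)
                            for j in (0, vol.shape[1] - 1)
                            for k in (0, vol.shape[2] - 1)], dtype=float)
    corners = vol.voxel_to_world(corners_idx)
    mapped = (corners - center) @ _rot_z(-angle).T + center
    lo, hi = mapped.min(axis=0), mapped.max(axis=0)
    extent = hi - lo
    n = np.floor(extent / out_spacing + 1e-9).astype(int) + 1
    out_shape = tuple(int(v) for v in n)
    out_origin = lo

    # voxel index (output) -> voxel index (input)
    A_out = np.diag([out_spacing] * 3)
    A_in_inv = np.linalg.inv(vol.direction @ np.diag(vol.spacing))
    M = A_in_inv @ R @ A_out
    off = A_in_inv @ (R @ (out_origin - center) + center - vol.origin)

    src = np.asarray(vol.voxels, dtype=np.uint8 if is_mask else float)
    cval = 0 if is_mask else float(np.percentile(src, 1))
    out = ndimage.affine_transform(
        src, M, offset=off, output_shape=out_shape,
        order=0 if is_mask else 1, mode="constant", cval=cval,
    )
    spacing = np.full(3, out_spacing)
    if is_mask:
        return BinaryMask((out > 0).astype(np.uint8), spacing, out_origin)
    return VolumeGrid(out, spacing, out_origin)


def realign(
    vol: VolumeGrid,
    pair: EyePair,
    is_mask: bool = False,
    angle_threshold: float = ANGLE_THRESHOLD_DEG,
    out_spacing: float = ISO_SPACING_MM,
):
    """Apply the 5-degree rule: resample only if the head-rotation angle is at
    or below the threshold, otherwise rotate about the mid-centroid point
    simultaneously with resampling. Returns (volume, applied_angle)."""
    ang = signed_rotation_angle(pair)
    if abs(ang) <= angle_threshold:
        return rotate_resample(vol, 0.0, is_mask, pair.midpoint, out_spacing), 0.0
    return rotate_resample(vol, ang, is_mask, pair.midpoint, out_spacing), ang


# --------------------------------------------------------------------------- #
# VOI cropping
# --------------------------------------------------------------------------- #

def crop_voi(
    vol: VolumeGrid,
    pair: EyePair,
    side: str,
    shape: tuple = VOI_SHAPE,
    anterior_mm: float = VOI_ANTERIOR_MM,
) -> VolumeGrid:
    """Fixed-size per-eye VOI around the mid-centroid point.

    The box extends ``shape[0]`` voxels laterally toward the requested side,
    ``anterior_mm`` anteriorly (rest posterior) and is centered
    superior-inferior. Pads with the 1st-percentile intensity (with a
    warning) if the box exceeds the volume.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    h = vol.spacing
    mid_idx = np.round(vol.world_to_voxel(pair.midpoint)).astype(int)
    if np.any(mid_idx < 0) or np.any(mid_idx >= np.asarray(vol.shape)):
        raise ValueError("mid-centroid point lies outside the volume")

    n_ant = int(round(anterior_mm / h[1]))
    if side == "right":  # RAS: +x is the subject's right
        x0 = mid_idx[0]
    else:
        x0 = mid_idx[0] - (shape[0] - 1)
    y0 = mid_idx[1] - (shape[1] - n_ant - 1)
    z0 = mid_idx[2] - shape[2] // 2
    start = np.array([x0, y0, z0])
    stop = start + np.asarray(shape)

    is_mask = isinstance(vol, BinaryMask)
    pad_val = 0 if is_mask else float(np.percentile(vol.voxels, 1))
    out = np.full(shape, pad_val, dtype=vol.voxels.dtype if is_mask else float)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(stop, vol.shape)
    if np.any(src_lo > start) or np.any(src_hi < stop):
        warnings.warn("VOI exceeds the volume; padding with background", stacklevel=2)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = vol.voxels[
        src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
    ]
    origin = vol.voxel_to_world(start.astype(float))
    cls = BinaryMask if is_mask else VolumeGrid
    return cls(out, h.copy(), origin)


# --------------------------------------------------------------------------- #
# Intensity normalization
# --------------------------------------------------------------------------- #

def znormalize(vol: VolumeGrid) -> VolumeGrid:
    """Normalize voxel values to mean 0, variance 1."""
    x = np.asarray(vol.voxels, dtype=float)
    sd = x.std()
    if sd < 1e-12:
        raise ValueError("zero variance: cannot normalize a constant volume")
    return vol.with_voxels((x - x.mean()) / sd)


def _poly_basis(shape, order: int):
    coords = np.meshgrid(*[np.linspace(-1.0, 1.0, n) for n in shape], indexing="ij")
    basis = [np.ones(shape)]
    if order >= 1:
        basis += list(coords)
    if order >= 2:
        gx, gy, gz = coords
        basis += [gx * gx, gy * gy, gz * gz, gx * gy, gx * gz, gy * gz]
    if order >= 3:
        raise ValueError("polynomial order > 2 not supported")
    return np.stack([b.ravel() for b in basis], axis=1)


def flatten_bias(vol: VolumeGrid, order: int = 2, external_hook=None) -> VolumeGrid:
    """Divide by a fitted low-order polynomial field normalized to unit mean.

    ``external_hook``, if given, is called as ``hook(vol) -> VolumeGrid`` and
    replaces the polynomial fit (e.g. an external N4 implementation).
    """
    if external_hook is not None:
        return external_hook(vol)
    x = np.asarray(vol.voxels, dtype=float)
    if np.any(x <= 0):
        raise ValueError("bias flattening requires positive intensities")
    B = _poly_basis(vol.shape, order)
    coef, *_ = np.linalg.lstsq(B, x.ravel(), rcond=None)
    field = (B @ coef).reshape(vol.shape)
    if np.any(field <= 0):
        raise ValueError("fitted bias field is not positive")
    field /= field.mean()
    return vol.with_voxels(x / field)
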