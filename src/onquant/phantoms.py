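"""Synthetic tubular phantoms with analytic ground truth.

Generates volumes containing a bright spherical "globe", a dark curved tube
("nerve") of varying radius wrapped in a bright shell ("CSF") of variable
thickness, on a background tissue level, with a smooth multiplicative bias
field and seeded additive Gaussian noise. The geometry (centerline, radius
profile, cross-sectional area) is carried alongside as an analytic oracle so
every downstream stage can be tested without external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, interp1d
from scipy.spatial import cKDTree

from .grid import BinaryMask, VolumeGrid

_CURVE_STEP_MM = 0.05  # resampling step for the analytic centerline


@dataclass
class PhantomSpec:
    """Declarative description of one phantom volume.

    ``radius_profile`` and ``csf_thickness_profile`` are piecewise-linear
    functions of arc length, given as lists of ``(s_mm, value_mm)`` knots;
    a single ``(0, v)`` knot means a constant profile.
    """

    grid_shape: tuple = (96, 96, 96)
    spacing: tuple = (0.3, 0.3, 0.3)
    origin: tuple = (0.0, 0.0, 0.0)
    globe_centers: tuple = ()  # 0-2 world points, mm
    globe_radius: float = 11.0
    curve_control_points: tuple = ()
    radius_profile: tuple = ((0.0, 1.5),)
    csf_thickness_profile: tuple = ((0.0, 0.6),)
    intensities: dict = field(
        default_factory=lambda: {"background": 80.0, "nerve": 60.0, "csf": 260.0, "globe": 240.0}
    )
    noise_sigma: float = 0.0
    bias_coeffs: tuple = ()  # polynomial coefficients, see bias_field()
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.spacing) <= 0):
            raise ValueError("spacing must be positive")
        if self.globe_centers and self.globe_radius <= 0:
            raise ValueError("globe_radius must be positive")
        for s, r in self.radius_profile:
            if r <= 0:
                raise ValueError("all radii must be positive")
        for s, t in self.csf_thickness_profile:
            if t < 0:
                raise ValueError("csf thickness must be >= 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=lambda o: list(o))

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        for key in ("grid_shape", "spacing", "origin", "curve_control_points",
                    "radius_profile", "csf_thickness_profile", "bias_coeffs",
                    "globe_centers"):
            if key in d and d[key] is not None:
                d[key] = tuple(tuple(v) if isinstance(v, list) else v for v in d[key])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Analytic centerline, radius and area of a generated phantom."""

    centerline_points: np.ndarray  # (n, 3) world mm
    arclengths: np.ndarray  # (n,) mm, strictly increasing
    tangents: np.ndarray  # (n, 3) unit vectors
    radius_at_s: np.ndarray  # (n,) mm
    csf_outer_radius_at_s: np.ndarray  # (n,) mm

    @property
    def area_at_s(self) -> np.ndarray:
        return np.pi * self.radius_at_s**2

    @property
    def total_length(self) -> float:
        return float(self.arclengths[-1])

    def to_table(self) -> np.ndarray:
        return np.column_stack(
            [self.arclengths, self.centerline_points, self.radius_at_s, self.area_at_s]
        )


def _piecewise(profile, s: np.ndarray) -> np.ndarray:
    knots = np.asarray(profile, dtype=float)
    if knots.shape[0] == 1:
        return np.full_like(s, knots[0, 1], dtype=float)
    f = interp1d(knots[:, 0], knots[:, 1], bounds_error=False,
                 fill_value=(knots[0, 1], knots[-1, 1]))
    return f(s)


def build_curve(spec: PhantomSpec) -> PhantomTruth:
    """Arc-length-parameterized smooth curve through the control points.

    Natural cubic spline through the control points, reparameterized by
    cumulative chord length at fine sampling and resampled at 0.05 mm steps.
    """
    pts = np.asarray(spec.curve_control_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 control points")
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seglen < 1e-9):
        raise ValueError("coincident consecutive control points")

    t_knots = np.concatenate([[0.0], np.cumsum(seglen)])
    if pts.shape[0] == 2:
        # straight segment: exact linear parameterization
        n = max(2, int(np.ceil(t_knots[-1] / _CURVE_STEP_MM)) + 1)
        s = np.linspace(0.0, t_knots[-1], n)
        d = (pts[1] - pts[0]) / t_knots[-1]
        cpts = pts[0] + s[:, None] * d
        tans = np.tile(d / np.linalg.norm(d), (n, 1))
    else:
        spline = CubicSpline(t_knots, pts, bc_type="natural")
        # dense evaluation, then cumulative chord length
        t_fine = np.linspace(0.0, t_knots[-1], max(1000, 20 * len(t_knots)))
        p_fine = spline(t_fine)
        chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(p_fine, axis=0), axis=1))])
        total = chord[-1]
        n = max(2, int(np.ceil(total / _CURVE_STEP_MM)) + 1)
        s = np.linspace(0.0, total, n)
        t_of_s = interp1d(chord, t_fine)(s)
        cpts = spline(t_of_s)
        tans = spline(t_of_s, 1)
        tans /= np.linalg.norm(tans, axis=1, keepdims=True)
        s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(cpts, axis=0), axis=1))])

    r = _piecewise(spec.radius_profile, s)
    t_csf = _piecewise(spec.csf_thickness_profile, s)
    return PhantomTruth(cpts, s, tans, r, r + t_csf)


def bias_field(shape, coeffs) -> np.ndarray:
    """Low-order polynomial bias field, normalized to unit mean.

    ``coeffs`` are (c0, cx, cy, cz, cxx, cyy, czz, ...) over coordinates
    scaled to [-1, 1]; missing trailing coefficients are zero.
    """
    if not coeffs:
        return np.ones(shape)
    gx, gy, gz = np.meshgrid(
        *[np.linspace(-1.0, 1.0, n) for n in shape], indexing="ij"
    )
    basis = [np.ones(shape), gx, gy, gz, gx * gx, gy * gy, gz * gz, gx * gy, gx * gz, gy * gz]
    f = np.zeros(shape)
    for c, b in zip(coeffs, basis):
        f += c * b
    if np.any(f <= 0):
        raise ValueError("bias field must stay positive")
    return f / f.mean()


def rasterize_phantom(spec: PhantomSpec):
    """Render a spec into (intensity volume, nerve mask, csf mask, truth).

    The nerve mask contains voxels whose distance to the curve is <= r(s) at
    the nearest curve point; the CSF mask is the shell between r(s) and
    r(s) + thickness(s). Noise is applied to intensities only.
    """
    truth = build_curve(spec)
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    origin = np.asarray(spec.origin, dtype=float)

    # verify the tube stays inside the grid
    lo = origin - 0.5 * spacing
    hi = origin + (np.asarray(shape) - 0.5) * spacing
    # radial extent of the tube projected on each axis: r_out * sqrt(1 - t_ax^2)
    radial = truth.csf_outer_radius_at_s[:, None] * np.sqrt(
        np.clip(1.0 - truth.tangents**2, 0.0, 1.0))
    for ax, name in enumerate("xyz"):
        if np.any(truth.centerline_points[:, ax] - radial[:, ax] < lo[ax]) or np.any(
            truth.centerline_points[:, ax] + radial[:, ax] > hi[ax]
        ):
            raise ValueError(f"tube exits the grid along axis {name}")

    ii = np.arange(shape[0])[:, None, None]
    jj = np.arange(shape[1])[None, :, None]
    kk = np.arange(shape[2])[None, None, :]
    xs = origin[0] + ii * spacing[0]
    ys = origin[1] + jj * spacing[1]
    zs = origin[2] + kk * spacing[2]

    # distance of every voxel near the tube to the densely sampled curve
    tree = cKDTree(truth.centerline_points)
    max_r = float(truth.csf_outer_radius_at_s.max())
    pts = np.stack(np.broadcast_arrays(xs, ys, zs), axis=-1).reshape(-1, 3)
    # restrict the query to a bounding box around the curve for speed
    cmin = truth.centerline_points.min(axis=0) - max_r - 1.0
    cmax = truth.centerline_points.max(axis=0) + max_r + 1.0
    near = np.all((pts >= cmin) & (pts <= cmax), axis=1)
    dist = np.full(pts.shape[0], np.inf)
    idx = np.zeros(pts.shape[0], dtype=int)
    d, i = tree.query(pts[near], workers=-1)
    dist[near] = d
    idx[near] = i

    r_here = truth.radius_at_s[idx]
    r_out_here = truth.csf_outer_radius_at_s[idx]
    # flat tube ends: drop voxels lying axially beyond the curve endpoints,
    # so the tube volume matches the analytic integral of pi r(s)^2 ds
    in_ends = np.ones(pts.shape[0], dtype=bool)
    for end, tangent, beyond in ((truth.centerline_points[0], truth.tangents[0], -1),
                                 (truth.centerline_points[-1], truth.tangents[-1], +1)):
        at_end = idx == (0 if beyond < 0 else len(truth.arclengths) - 1)
        axial = (pts[at_end] - end) @ tangent
        keep = np.ones(at_end.sum(), dtype=bool)
        keep[beyond * axial > 1e-9] = False
        in_ends[np.flatnonzero(at_end)[~keep]] = False
    nerve = ((dist <= r_here) & in_ends).reshape(shape)
    csf = ((dist > r_here) & (dist <= r_out_here) & in_ends).reshape(shape)

    levels = spec.intensities
    vol = np.full(shape, float(levels["background"]))
    globes = np.zeros(shape, dtype=bool)
    for c in spec.globe_centers:
        c = np.asarray(c, dtype=float)
        g = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2 <= spec.globe_radius**2
        globes |= g
    vol[globes] = float(levels["globe"])
    vol[csf] = float(levels["csf"])
    vol[nerve] = float(levels["nerve"])

    vol *= bias_field(shape, spec.bias_coeffs)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=shape)

    grid = VolumeGrid(vol, spacing, origin)
    nerve_mask = BinaryMask(nerve.astype(np.uint8), spacing, origin)
    csf_mask = BinaryMask(csf.astype(np.uint8), spacing, origin)
    return grid, nerve_mask, csf_mask, truth


def min_bend_radius(truth: PhantomTruth) -> float:
    """Smallest curvature radius along the centerline."""
    dt = np.linalg.norm(np.diff(truth.tangents, axis=0), axis=1)
    ds = np.diff(truth.arclengths)
    kappa = np.max(dt / np.maximum(ds, 1e-12))
    return float(1.0 / max(kappa, 1e-12))


def random_tube_spec(seed: int, grid_shape=(64, 64, 64), spacing=0.3,
                     noise_sigma=8.0) -> PhantomSpec:
    """Random curved-tube spec filling a cube, for toy training/evaluation.

    The tube runs along y with smooth random lateral excursions, a varying
    radius, a CSF shell of varying thickness, mild bias field and noise.
    Draws are rejected until the minimum bending radius safely exceeds the
    tube's outer radius (the self-intersection invariant); the damping of
    lateral excursions increases with each retry.
    """
    rng = np.random.default_rng(seed)
    extent = (np.asarray(grid_shape) - 1) * spacing
    cx, cz = extent[0] / 2, extent[2] / 2
    margin = 3.2
    n_ctrl = 4
    if extent[1] <= 2 * margin or min(extent[0], extent[2]) / 2 <= margin + 0.5:
        raise ValueError("grid too small for a random tube (need > ~7.5 mm extent)")
    ys = np.linspace(margin, extent[1] - margin, n_ctrl)
    amp = min(extent[0], extent[2]) / 2 - margin - 0.5
    r0, r1 = rng.uniform(1.1, 1.9, 2)
    t0, t1 = rng.uniform(0.3, 0.8, 2)
    r_outer = max(r0, r1) + max(t0, t1)
    for attempt in range(20):
        damp = 0.5 / (1.0 + 0.3 * attempt)
        xs = cx + rng.uniform(-amp, amp, n_ctrl)
        zs = cz + rng.uniform(-amp, amp, n_ctrl)
        for arr in (xs, zs):
            for k in range(1, n_ctrl):
                arr[k] = arr[k - 1] + damp * (arr[k] - arr[k - 1])
        probe = PhantomSpec(curve_control_points=tuple(zip(xs, ys, zs)))
        if min_bend_radius(build_curve(probe)) > 1.6 * r_outer:
            break
    total = extent[1]  # approximate arc length for profile knots
    return PhantomSpec(
        grid_shape=tuple(int(v) for v in grid_shape),
        spacing=(spacing,) * 3,
        curve_control_points=tuple(zip(xs, ys, zs)),
        radius_profile=((0.0, float(r0)), (float(total), float(r1))),
        csf_thickness_profile=((0.0, float(t0)), (float(total), float(t1))),
        noise_sigma=noise_sigma,
        bias_coeffs=(1.0, float(rng.uniform(-0.15, 0.15)),
                     float(rng.uniform(-0.15, 0.15)), float(rng.uniform(-0.15, 0.15))),
        seed=int(seed),
    )


def toy_sample(seed: int, grid_shape=(64, 64, 64), spacing=0.3, noise_sigma=8.0):
    """(z-normalized volume, nerve mask) float32/uint8 arrays for training."""
    spec = random_tube_spec(seed, grid_shape, spacing, noise_sigma)
    vol, nerve, _, _ = rasterize_phantom(spec)
    x = np.asarray(vol.voxels, dtype=np.float64)
    x = (x - x.mean()) / x.std()
    return x.astype(np.float32), nerve.voxels.astype(np.float32)


def write_phantom(spec: PhantomSpec, outdir) -> None:
    """Write volume/masks as NIfTI, truth as CSV, spec as JSON."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    vol, nerve, csf, truth = rasterize_phantom(spec)
    vol.save(out / "volume.nii.gz")
    nerve.save(out / "nerve.nii.gz")
    csf.save(out / "csf.nii.gz")
    tbl = truth.to_table()
    header = "s_mm,x,y,z,r_mm,area_mm2"
    np.savetxt(out / "truth.csv", tbl, delimiter=",", header=header, comments="", fmt="%.6f")
    (out / "spec.json").write_text(spec.to_json())
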