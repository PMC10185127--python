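"""Mask -> surface model -> centerline -> diameter/area profile.

The centerline approximates the medial path of maximal inscribed spheres: a
shortest path between the tube endpoints under a cost that decays with the
interior distance-to-boundary field, pushing the path onto the ridge of the
distance transform. Cross-sections are exact mesh/plane intersection
polygons sampled every 0.1 mm of arc length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import interp1d, splev, splprep
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon
from skimage import measure

from .grid import BinaryMask

PROFILE_STEP_MM = 0.1
CENTERLINE_COST_EXPONENT = 2.0  # path cost ~ 1 / (eps + dist^p)
CENTERLINE_COST_EPS_VOX = 0.1

FLAG_OK = "ok"
FLAG_CAP = "cap"
FLAG_INVALID = "invalid"
FLAG_NEAREST = "nearest_polygon"


# --------------------------------------------------------------------------- #
# Surface model
# --------------------------------------------------------------------------- #

@dataclass
class SurfaceModel:
    vertices: np.ndarray  # (n, 3) world mm
    triangles: np.ndarray  # (m, 3) int vertex indices
    provenance: dict = field(default_factory=dict)

    @property
    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def area(self) -> float:
        tri = self.vertices[self.triangles]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def is_closed(self) -> bool:
        """Every edge shared by exactly two triangles."""
        edges = np.sort(
            np.concatenate([self.triangles[:, [0, 1]], self.triangles[:, [1, 2]],
                            self.triangles[:, [2, 0]]]), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


def mask_to_surface(mask: BinaryMask, smooth: str = "off",
                    taubin_iters: int = 10, taubin_lamb: float = 0.5,
                    taubin_mu: float = -0.53) -> SurfaceModel:
    """Iso-surface of the mask at the 0.5 level, in world coordinates.

    ``smooth='taubin'`` applies volume-preserving Taubin smoothing with the
    given parameters (logged in provenance); default off, since surface
    smoothing systematically shrinks thin structures.
    """
    if not mask.voxels.any():
        raise ValueError("mask is empty")
    padded = np.pad(mask.voxels.astype(float), 2)
    # anti-alias the binary field so the isosurface is free of staircase
    # area excess; sub-voxel sigma, negligible shrink at tube curvatures
    padded = ndimage.gaussian_filter(padded, sigma=0.8)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=tuple(mask.spacing))
    verts = verts - 2 * mask.spacing  # undo the two-voxel pad
    verts = mask.origin + verts @ mask.direction.T
    prov = {"smooth": smooth}
    surf = SurfaceModel(verts.astype(float), faces.astype(np.int64), prov)
    if smooth == "taubin":
        prov.update({"iters": taubin_iters, "lambda": taubin_lamb, "mu": taubin_mu})
        surf = taubin_smooth(surf, taubin_iters, taubin_lamb, taubin_mu)
    elif smooth != "off":
        raise ValueError("smooth must be 'off' or 'taubin'")
    return surf


def taubin_smooth(surf: SurfaceModel, iters: int, lamb: float, mu: float) -> SurfaceModel:
    n = len(surf.vertices)
    edges = np.concatenate([surf.triangles[:, [0, 1]], surf.triangles[:, [1, 2]],
                            surf.triangles[:, [2, 0]]])
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    w = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()
    w.data[:] = 1.0  # duplicate edges collapse to weight 1
    deg = np.asarray(w.sum(axis=1)).ravel()
    v = surf.vertices.copy()
    for _ in range(iters):
        for factor in (lamb, mu):
            lap = (w @ v) / deg[:, None] - v
            v = v + factor * lap
    return SurfaceModel(v, surf.triangles.copy(), dict(surf.provenance))


# --------------------------------------------------------------------------- #
# Centerline
# --------------------------------------------------------------------------- #

@dataclass
class Centerline:
    points: np.ndarray  # (n, 3) world mm
    arclength: np.ndarray  # (n,) mm, strictly increasing
    tangents: np.ndarray  # (n, 3) unit vectors
    inscribed_radius: np.ndarray  # (n,) mm

    def __post_init__(self) -> None:
        if np.any(np.diff(self.arclength) <= 0):
            raise ValueError("arclength must be strictly increasing")
        norms = np.linalg.norm(self.tangents, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("tangents must be unit vectors")

    @property
    def s(self) -> np.ndarray:
        return self.arclength

    @property
    def total_length(self) -> float:
        return float(self.arclength[-1])


def _mask_graph(mask: BinaryMask):
    """26-connectivity sparse graph over mask voxels with mm edge lengths."""
    idx = np.argwhere(mask.voxels)
    if idx.size == 0:
        raise ValueError("mask is empty")
    flat = np.full(mask.shape, -1, dtype=np.int64)
    flat[tuple(idx.T)] = np.arange(len(idx))
    offsets = [np.array(off) for off in
               (tuple(x - 1 for x in o) for o in np.ndindex(3, 3, 3))
               if off > (0, 0, 0)]
    rows, cols, lens = [], [], []
    for off in offsets:
        nb = idx + off
        ok = np.all((nb >= 0) & (nb < np.asarray(mask.shape)), axis=1)
        src = flat[tuple(idx[ok].T)]
        dst = flat[tuple(nb[ok].T)]
        valid = dst >= 0
        rows.append(src[valid])
        cols.append(dst[valid])
        lens.append(np.full(valid.sum(), np.linalg.norm(off * mask.spacing)))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    lens = np.concatenate(lens)
    return idx, flat, rows, cols, lens


def _refine_endpoint(world: np.ndarray, end: np.ndarray, spacing: np.ndarray,
                     radius_est: float) -> np.ndarray:
    """Move a farthest-pair voxel (typically a cap-corner) onto the local tube
    axis: local-PCA axis direction, then the centroid of the terminal
    cross-section slab perpendicular to it."""
    reach = max(4.0 * radius_est, 2.5)
    local = world[np.linalg.norm(world - end, axis=1) <= reach]
    if len(local) < 4:
        return end
    mu = local.mean(axis=0)
    _, _, vt = np.linalg.svd(local - mu, full_matrices=False)
    t = vt[0]
    if t @ (end - mu) < 0:
        t = -t
    ax = local @ t
    slab = ax >= ax.max() - 1.2 * float(np.min(spacing))  # terminal cap slice
    return local[slab].mean(axis=0)


def detect_endpoints(mask: BinaryMask, globe_center=None, override=None):
    """Geodesic farthest-point pair inside the mask (double Dijkstra sweep).

    ``override`` (two world points) is returned unchanged. The start point
    is the endpoint closer to ``globe_center`` if given, otherwise the one
    with the larger lateral (|x|) coordinate.
    """
    if override is not None:
        a, b = (np.asarray(p, dtype=float) for p in override)
        return a, b
    labels, n = ndimage.label(mask.voxels, structure=np.ones((3, 3, 3)))
    if n != 1:
        raise ValueError(
            f"mask has {n} connected components; apply largest_component first")
    idx, flat, rows, cols, lens = _mask_graph(mask)
    g = coo_matrix((np.concatenate([lens, lens]),
                    (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
                   shape=(len(idx), len(idx))).tocsr()
    d0 = dijkstra(g, indices=0)
    u = int(np.argmax(d0))
    du = dijkstra(g, indices=u)
    v = int(np.argmax(du))
    world = np.atleast_2d(mask.voxel_to_world(idx.astype(float)))
    dist_mm = ndimage.distance_transform_edt(mask.voxels, sampling=mask.spacing)
    pa, pb = (world[u], world[v])
    r_u = float(dist_mm[tuple(idx[np.linalg.norm(world - pa, axis=1) <= 3.0].T)].max())
    r_v = float(dist_mm[tuple(idx[np.linalg.norm(world - pb, axis=1) <= 3.0].T)].max())
    pa = _refine_endpoint(world, pa, mask.spacing, r_u)
    pb = _refine_endpoint(world, pb, mask.spacing, r_v)
    if globe_center is not None:
        gc = np.asarray(globe_center, dtype=float)
        if np.linalg.norm(pb - gc) < np.linalg.norm(pa - gc):
            pa, pb = pb, pa
    elif abs(pb[0]) > abs(pa[0]):
        pa, pb = pb, pa
    return pa, pb


def _extend_to_boundary(mask: BinaryMask, dist_mm: np.ndarray, start: np.ndarray,
                        direction: np.ndarray, step: float,
                        max_mm: float = 3.0) -> np.ndarray:
    """Points marching from ``start`` along ``direction`` to the cap face.

    Walks while inside the mask and while the distance field stays above a
    fraction of the local radius (so a tilted extension cannot slide along
    the tube wall); the remaining distance-to-boundary is appended as the
    final straight run to the cap.
    """
    shape = np.asarray(mask.shape)

    def edt_at(p):
        vi = np.round(mask.world_to_voxel(p)).astype(int)
        if np.any(vi < 0) or np.any(vi >= shape) or not mask.voxels[tuple(vi)]:
            return -1.0
        return float(ndimage.map_coordinates(dist_mm, mask.world_to_voxel(p)[:, None],
                                             order=1)[0])

    r_end = max(edt_at(start), 1e-3)
    out = []
    for k in range(1, int(max_mm / step) + 1):
        p = start + k * step * direction
        e = edt_at(p)
        if e < 0:
            break
        out.append(p)
        if e < 0.6 * r_end:
            # close to the cap: append the remaining distance and stop
            for j in range(1, int(e / step) + 1):
                q = p + j * step * direction
                if edt_at(q) < 0:
                    break
                out.append(q)
            break
    return np.asarray(out).reshape(-1, 3)


def extract_centerline(mask: BinaryMask, endpoints=None, step: float = PROFILE_STEP_MM,
                       cost_exponent: float = CENTERLINE_COST_EXPONENT,
                       cost_eps: float = CENTERLINE_COST_EPS_VOX,
                       smooth_window_mm: float = 1.2,
                       trim_mm: float = 1.2) -> Centerline:
    """Medial path between the endpoints, resampled at ``step`` mm.

    Shortest path over the mask voxel graph under edge cost
    ``length * 1/(eps + dist_vox^p)`` averaged over the edge ends, followed
    by moving-average smoothing, spline fitting and arc-length resampling.
    The inscribed radius is the interior distance field interpolated along
    the path.
    """
    if endpoints is None:
        endpoints = detect_endpoints(mask)
    dist_mm = ndimage.distance_transform_edt(mask.voxels, sampling=mask.spacing)
    idx, flat, rows, cols, lens = _mask_graph(mask)
    dist_vox = dist_mm[tuple(idx.T)] / float(np.min(mask.spacing))
    node_cost = 1.0 / (cost_eps + dist_vox**cost_exponent)
    w = lens * 0.5 * (node_cost[rows] + node_cost[cols])
    g = coo_matrix((np.concatenate([w, w]),
                    (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
                   shape=(len(idx), len(idx))).tocsr()

    ends = []
    for p in endpoints:
        vi = np.round(mask.world_to_voxel(np.asarray(p, dtype=float))).astype(int)
        vi = np.clip(vi, 0, np.asarray(mask.shape) - 1)
        if not mask.voxels[tuple(vi)]:
            # snap to the nearest mask voxel
            tree = cKDTree(idx * mask.spacing)
            _, k = tree.query(vi * mask.spacing)
            vi = idx[k]
        ends.append(int(flat[tuple(vi)]))
    dists, pred = dijkstra(g, indices=ends[0], return_predecessors=True)
    if not np.isfinite(dists[ends[1]]):
        raise ValueError("no interior path between the endpoints")
    path = [ends[1]]
    while path[-1] != ends[0]:
        path.append(int(pred[path[-1]]))
    path = path[::-1]
    pts = mask.voxel_to_world(idx[path].astype(float))
    pts = np.atleast_2d(pts)

    # moving-average smoothing (window in mm of path length)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    mean_step = max(float(seg.mean()), 1e-9)
    win = max(1, int(round(smooth_window_mm / mean_step)) | 1)
    if win > 1 and len(pts) > win:
        kernel = np.ones(win) / win
        sm = np.column_stack([
            np.convolve(np.pad(pts[:, a], win // 2, mode="edge"), kernel, mode="valid")
            for a in range(3)])
    else:
        sm = pts
    # drop near-duplicate points before spline fitting
    keep = np.concatenate([[True], np.linalg.norm(np.diff(sm, axis=0), axis=1) > 1e-6])
    sm = sm[keep]
    if len(sm) < 4:
        raise ValueError("centerline path too short")

    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(sm, axis=0), axis=1))])
    tck, _ = splprep(sm.T, u=chord / chord[-1], s=len(sm) * 0.02**2, k=3)
    u_fine = np.linspace(0, 1, max(1000, 4 * len(sm)))
    p_fine = np.column_stack(splev(u_fine, tck))
    s_fine = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(p_fine, axis=0), axis=1))])
    total = s_fine[-1]
    n = int(np.floor(total / step)) + 1
    s = np.arange(n) * step
    u_of_s = interp1d(s_fine, u_fine)(s)
    points = np.column_stack(splev(u_of_s, tck))
    deriv = np.column_stack(splev(u_of_s, tck, der=1))
    tangents = deriv / np.linalg.norm(deriv, axis=1, keepdims=True)

    # the first/last bit of the path transitions from the detected endpoint
    # onto the medial ridge and can be laterally off; trim it (at least two
    # local radii), then extend along the interior tangents to the tube caps
    k_in = min(int(round(2.0 / step)), (len(points) - 1) // 2)
    vox_ends = mask.world_to_voxel(points[[k_in, -1 - k_in]]).T
    r_ends = ndimage.map_coordinates(dist_mm, vox_ends, order=1)
    trim_mm = max(trim_mm, 2.0 * float(np.max(r_ends)))
    trim = min(int(round(trim_mm / step)), (len(points) - 4) // 2)
    if trim > 0:
        points = points[trim:-trim]
        tangents = tangents[trim:-trim]
    reach = trim_mm + 2.0
    head = _extend_to_boundary(mask, dist_mm, points[0], -tangents[0], step, reach)
    tail = _extend_to_boundary(mask, dist_mm, points[-1], tangents[-1], step, reach)
    if len(head) or len(tail):
        points = np.concatenate([head[::-1], points, tail])
        tangents = np.concatenate([np.tile(tangents[0], (len(head), 1)), tangents,
                                   np.tile(tangents[-1], (len(tail), 1))])
        s = np.arange(len(points)) * step

    vox_coords = mask.world_to_voxel(points).T
    r_ins = np.maximum(ndimage.map_coordinates(dist_mm, vox_coords, order=1), 1e-3)
    return Centerline(points, s, tangents, r_ins)


# --------------------------------------------------------------------------- #
# Cross-sectional profile
# --------------------------------------------------------------------------- #

@dataclass
class DiameterProfile:
    s: np.ndarray  # mm, 0.1 mm steps
    area: np.ndarray  # mm^2
    d_mis: np.ndarray  # mm
    flags: list  # per-sample flag strings

    def __post_init__(self) -> None:
        self.d_ce = 2.0 * np.sqrt(np.maximum(self.area, 0.0) / np.pi)

    def valid(self) -> np.ndarray:
        return np.array([f in (FLAG_OK, FLAG_NEAREST) for f in self.flags])

    def interior(self) -> np.ndarray:
        return np.array([f == FLAG_OK for f in self.flags])

    def to_table(self) -> list:
        rows = []
        for i in range(len(self.s)):
            rows.append((float(self.s[i]), float(self.area[i]), float(self.d_ce[i]),
                         float(self.d_mis[i]), self.flags[i]))
        return rows


def _plane_basis(normal: np.ndarray):
    n = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    return u, np.cross(n, u)


def plane_section_polygons(surf: SurfaceModel, point: np.ndarray, normal: np.ndarray,
                           candidate_tris: np.ndarray | None = None):
    """Closed polygons (as (k, 2) arrays in the plane's (u, v) basis) of the
    mesh/plane intersection. Coplanar vertices are epsilon-perturbed for
    deterministic chaining."""
    tris = surf.triangles if candidate_tris is None else surf.triangles[candidate_tris]
    d = (surf.vertices - point) @ normal
    d = np.where(np.abs(d) < 1e-12, 1e-9, d)  # deterministic tie-break
    dt = d[tris]
    crossing = ~(np.all(dt > 0, axis=1) | np.all(dt < 0, axis=1))
    tris = tris[crossing]
    if len(tris) == 0:
        return []
    u, v = _plane_basis(normal)

    segments = []  # ((edge_a, edge_b), (pt_a, pt_b)) with edges as frozen pairs
    for tri in tris:
        pts, edges = [], []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            ia, ib = int(tri[a]), int(tri[b])
            da, db = d[ia], d[ib]
            if (da > 0) != (db > 0):
                t = da / (da - db)
                p = surf.vertices[ia] + t * (surf.vertices[ib] - surf.vertices[ia])
                rel = p - point
                pts.append((float(rel @ u), float(rel @ v)))
                edges.append((min(ia, ib), max(ia, ib)))
        if len(pts) == 2:
            segments.append((tuple(edges), tuple(pts)))

    # chain segments into closed polygons via shared mesh edges
    adj: dict = {}
    for si, (edges, _) in enumerate(segments):
        for e in edges:
            adj.setdefault(e, []).append(si)
    used = [False] * len(segments)
    polys = []
    for start in range(len(segments)):
        if used[start]:
            continue
        chain = [segments[start][1][0], segments[start][1][1]]
        used[start] = True
        cur_edge = segments[start][0][1]
        while True:
            nxt = [s for s in adj.get(cur_edge, []) if not used[s]]
            if not nxt:
                break
            s = nxt[0]
            used[s] = True
            e0, e1 = segments[s][0]
            p0, p1 = segments[s][1]
            if e0 == cur_edge:
                chain.append(p1)
                cur_edge = e1
            else:
                chain.append(p0)
                cur_edge = e0
        if len(chain) >= 4:  # closed loop repeats the first point region
            polys.append(np.asarray(chain[:-1]) if np.allclose(chain[0], chain[-1])
                         else np.asarray(chain))
    return [p for p in polys if len(p) >= 3]


def cross_section_profile(surf: SurfaceModel, cl: Centerline,
                          max_invalid_frac: float = 0.1) -> DiameterProfile:
    """Cross-sectional area / CE diameter / MIS diameter every 0.1 mm.

    At each centerline sample, the plane through the point with the local
    tangent as normal is intersected with the mesh; the closed polygon
    containing the point (plane origin) provides the area. Samples within
    two local radii of either end are flagged as cap region; samples with no
    polygon are flagged invalid, never silently dropped.
    """
    centroids = surf.triangle_centroids
    tree = cKDTree(centroids)
    n = len(cl.s)
    area = np.full(n, np.nan)
    flags = []
    total = cl.total_length
    for i in range(n):
        r_loc = cl.inscribed_radius[i]
        cap = cl.s[i] < 2.0 * r_loc or total - cl.s[i] < 2.0 * r_loc
        radius = max(6.0 * r_loc, 3.0)
        cand = np.asarray(tree.query_ball_point(cl.points[i], radius), dtype=int)
        polys = plane_section_polygons(surf, cl.points[i], cl.tangents[i],
                                       cand if len(cand) else None)
        flag = FLAG_CAP if cap else FLAG_OK
        if not polys:
            flags.append(FLAG_INVALID if not cap else FLAG_CAP)
            continue
        chosen = None
        origin = Point(0.0, 0.0)
        shapely_polys = [Polygon(p) for p in polys]
        shapely_polys = [p if p.is_valid else p.buffer(0) for p in shapely_polys]
        for p in shapely_polys:
            if p.contains(origin):
                chosen = p
                break
        if chosen is None:
            chosen = min(shapely_polys, key=lambda p: origin.distance(p.centroid))
            if flag == FLAG_OK:
                flag = FLAG_NEAREST
        area[i] = chosen.area
        flags.append(flag)
    n_interior = sum(1 for f in flags if f != FLAG_CAP)
    n_invalid = sum(1 for f in flags if f == FLAG_INVALID)
    if n_interior and n_invalid / n_interior > max_invalid_frac:
        raise ValueError("centerline/surface inconsistent: "
                         f"{n_invalid}/{n_interior} interior samples have no section")
    return DiameterProfile(cl.s.copy(), area, 2.0 * cl.inscribed_radius, flags)


def write_profile_csv(path, profile: DiameterProfile) -> None:
    with open(path, "w") as fh:
        fh.write("s_mm,area_mm2,d_ce_mm,d_mis_mm,flag\n")
        for s, a, dce, dmis, flag in profile.to_table():
            fh.write(f"{s:.4f},{a:.6f},{dce:.6f},{dmis:.6f},{flag}\n")
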