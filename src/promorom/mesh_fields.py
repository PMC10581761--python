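"""Mesh I/O, articular-surface labels, distance fields and sphere fitting.

A distance field stores, on a regular grid spanning a padded bounding prism,
the exact shortest distance from each grid node to a triangle mesh surface.
Distances to closed (watertight) bone meshes are signed — negative inside,
positive outside — using angle-weighted pseudonormals, which give the correct
sign for queries nearest to a face, an edge or a vertex.  Open articular
patches get unsigned fields.  Between nodes the field is interpolated
trilinearly, so any point inside the prism can be queried in constant time;
this is what makes per-pose proximity evaluation cheap enough to optimize
over thousands of candidate humeral translations.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "DistanceField",
    "SphereFit",
    "load_mesh",
    "build_distance_field",
    "query_distance",
    "fit_sphere",
    "point_triangle_distance",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """A triangle mesh in millimetres with optional named face-subset labels.

    ``labels`` maps a region name (e.g. ``"glenoid_face"``,
    ``"head_articular"``) to an integer array of face indices into ``faces``.
    """

    vertices: np.ndarray  # (nv, 3) float, mm
    faces: np.ndarray  # (nf, 3) int
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index exceeds vertex count")
        for name, idx in self.labels.items():
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size == 0:
                raise ValueError(f"label {name!r} is empty")
            if idx.min() < 0 or idx.max() >= len(self.faces):
                raise ValueError(f"label {name!r} references out-of-range faces")
            self.labels[name] = idx

    # -- conversions --------------------------------------------------------

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def triangles(self, face_indices: np.ndarray | None = None) -> np.ndarray:
        """Triangle vertex coordinates, shape (nf, 3, 3)."""
        f = self.faces if face_indices is None else self.faces[face_indices]
        return self.vertices[f]

    def label_submesh(self, name: str) -> "TriangleMesh":
        """Extract a labelled region as its own (open) mesh."""
        if name not in self.labels:
            raise KeyError(f"no label {name!r}; have {sorted(self.labels)}")
        faces = self.faces[self.labels[name]]
        used, inverse = np.unique(faces, return_inverse=True)
        return TriangleMesh(self.vertices[used], inverse.reshape(-1, 3))

    def label_vertices(self, name: str) -> np.ndarray:
        """Unique vertex coordinates of a labelled region, (k, 3)."""
        if name not in self.labels:
            raise KeyError(f"no label {name!r}; have {sorted(self.labels)}")
        used = np.unique(self.faces[self.labels[name]])
        return self.vertices[used]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        v = self.vertices @ np.asarray(rotation).T + np.asarray(translation)
        return TriangleMesh(v, self.faces.copy(), {k: i.copy() for k, i in self.labels.items()})

    def face_areas(self, face_indices: np.ndarray | None = None) -> np.ndarray:
        t = self.triangles(face_indices)
        return 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)


@dataclass
class SphereFit:
    center: np.ndarray  # (3,), mm
    radius: float  # mm
    rms_residual: float  # mm


@dataclass
class DistanceField:
    """Regular-grid distance samples with trilinear interpolation.

    origin      -- grid node (0,0,0) position, mm
    spacing     -- per-axis grid step, mm
    grid_counts -- nodes per axis (nx, ny, nz)
    values      -- distances at nodes, shape (nx, ny, nz), mm
    signed      -- True for closed meshes (negative inside)
    """

    origin: np.ndarray
    spacing: np.ndarray
    grid_counts: tuple[int, int, int]
    values: np.ndarray
    signed: bool

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.spacing * (np.asarray(self.grid_counts) - 1)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= self.origin) & (p <= self.upper), axis=1)

    # -- queries ------------------------------------------------------------

    def query(self, points: np.ndarray, out_of_bounds: str = "raise") -> np.ndarray:
        """Trilinear distance at ``points``.

        ``out_of_bounds`` is ``"raise"`` (default) or ``"nan"``; extrapolation
        is never performed — a silently clamped query would feed the
        translation optimizer wrong distances near the prism boundary.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        inside = self.contains(p)
        if not inside.all():
            if out_of_bounds == "raise":
                raise ValueError(
                    f"{int((~inside).sum())} query point(s) outside the field prism"
                )
            elif out_of_bounds != "nan":
                raise ValueError("out_of_bounds must be 'raise' or 'nan'")
        out = np.full(len(p), np.nan)
        if inside.any():
            out[inside] = self._trilinear(p[inside])[0]
        return out if np.asarray(points).ndim == 2 else out[0]

    def query_with_gradient(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Value and spatial gradient of the interpolant (points must be inside)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if not self.contains(p).all():
            raise ValueError("query point(s) outside the field prism")
        return self._trilinear(p)

    def _trilinear(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nx, ny, nz = self.grid_counts
        u = (p - self.origin) / self.spacing
        i0 = np.floor(u).astype(np.int64)
        np.clip(i0, 0, np.array([nx - 2, ny - 2, nz - 2]), out=i0)
        f = u - i0  # fractional coordinate in the cell, in [0, 1]
        offs = getattr(self, "_corner_offsets", None)
        if offs is None:
            # flat-index offsets of the 8 cell corners, ordered
            # (x, y, z) bits: 000, 001, 010, 011, 100, 101, 110, 111
            offs = np.array(
                [0, 1, nz, nz + 1, ny * nz, ny * nz + 1, ny * nz + nz, ny * nz + nz + 1]
            )
            self._corner_offsets = offs
            self._flat_values = self.values.ravel()
        base = (i0[:, 0] * ny + i0[:, 1]) * nz + i0[:, 2]
        c = self._flat_values[base[:, None] + offs]
        c000, c001, c010, c011, c100, c101, c110, c111 = c.T
        fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
        gx_ = 1.0 - fx
        c00 = c000 * gx_ + c100 * fx
        c01 = c001 * gx_ + c101 * fx
        c10 = c010 * gx_ + c110 * fx
        c11 = c011 * gx_ + c111 * fx
        gy_ = 1.0 - fy
        c0 = c00 * gy_ + c10 * fy
        c1 = c01 * gy_ + c11 * fy
        val = c0 * (1.0 - fz) + c1 * fz

        grad = np.empty_like(p)
        dx00 = c100 - c000
        dx01 = c101 - c001
        dx10 = c110 - c010
        dx11 = c111 - c011
        grad[:, 0] = ((dx00 * gy_ + dx10 * fy) * (1.0 - fz)
                      + (dx01 * gy_ + dx11 * fy) * fz) / self.spacing[0]
        grad[:, 1] = ((c10 - c00) * (1.0 - fz) + (c11 - c01) * fz) / self.spacing[1]
        grad[:, 2] = (c1 - c0) / self.spacing[2]
        return val, grad

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        header = {
            "origin": self.origin.tolist(),
            "spacing": self.spacing.tolist(),
            "grid_counts": list(self.grid_counts),
            "signed": self.signed,
        }
        np.savez_compressed(
            path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            values=self.values.astype(np.float32),
        )

    @classmethod
    def load(cls, path) -> "DistanceField":
        with np.load(path) as z:
            header = json.loads(bytes(z["header"]).decode())
            values = z["values"].astype(float)
        return cls(
            origin=np.array(header["origin"], dtype=float),
            spacing=np.array(header["spacing"], dtype=float),
            grid_counts=tuple(header["grid_counts"]),
            values=values,
            signed=bool(header["signed"]),
        )


# ---------------------------------------------------------------------------
# Mesh loading
# ---------------------------------------------------------------------------


def load_mesh(path, label_spec=None) -> TriangleMesh:
    """Load a PLY/OBJ/STL mesh, merge duplicate vertices, drop degenerate faces.

    ``label_spec`` is an optional path to a JSON sidecar ``{"region":
    [face indices]}`` (0-based, indexing the cleaned face list) or an
    already-parsed dict of that shape.  Units are taken to be millimetres.
    """
    tm = trimesh.load_mesh(str(path), process=False)
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"{path}: empty or unreadable mesh")
    tm.merge_vertices(merge_tex=True, merge_norm=True)
    areas = 0.5 * np.linalg.norm(
        np.cross(
            tm.vertices[tm.faces[:, 1]] - tm.vertices[tm.faces[:, 0]],
            tm.vertices[tm.faces[:, 2]] - tm.vertices[tm.faces[:, 0]],
        ),
        axis=1,
    )
    keep = areas > 1e-12
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} degenerate face(s)")
    faces = tm.faces[keep]
    labels = {}
    if label_spec is not None:
        if not isinstance(label_spec, dict):
            with open(label_spec) as fh:
                label_spec = json.load(fh)
        labels = {k: np.asarray(v, dtype=np.int64) for k, v in label_spec.items()}
    mesh = TriangleMesh(np.asarray(tm.vertices, dtype=float), faces, labels)
    logger.info(
        "loaded %s: %d vertices, %d faces (%d degenerate dropped), labels=%s",
        path, len(mesh.vertices), len(mesh.faces), n_dropped, sorted(labels),
    )
    return mesh


# ---------------------------------------------------------------------------
# Exact point-to-triangle distance
# ---------------------------------------------------------------------------


def point_triangle_distance(points: np.ndarray, triangles: np.ndarray):
    """Closest point on each triangle for each paired query point.

    ``points`` is (n, 3), ``triangles`` (n, 3, 3); returns (distance (n,),
    closest point (n, 3), region code (n,)).  Region codes identify the
    closest feature — 0: face interior, 1/2/3: vertex a/b/c, 4/5/6: edge
    ab/bc/ca — which the pseudonormal sign test needs.
    """
    p = np.asarray(points, dtype=float)
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(p)
    region = np.zeros(len(p), dtype=np.int8)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    closest[m], region[m], done[m] = a[m], 1, True
    m = ~done & (d3 >= 0) & (d4 <= d3)  # vertex b
    closest[m], region[m], done[m] = b[m], 2, True
    m = ~done & (d6 >= 0) & (d5 <= d6)  # vertex c
    closest[m], region[m], done[m] = c[m], 3, True

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d1 / (d1 - d3)
    closest[m] = a[m] + t[m, None] * ab[m]
    region[m], done[m] = 4, True

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ca
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d2 / (d2 - d6)
    closest[m] = a[m] + t[m, None] * ac[m]
    region[m], done[m] = 6, True

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    closest[m] = b[m] + t[m, None] * (c[m] - b[m])
    region[m], done[m] = 5, True

    m = ~done  # face interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb / denom
        w = vc / denom
    closest[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    region[m] = 0
    dist = np.linalg.norm(p - closest, axis=1)
    return dist, closest, region


def _make_numba_kernel():
    """Compile a pairwise point-triangle kernel; None when numba is absent."""
    try:
        import numba
    except ImportError:  # pragma: no cover - numba is an optional accelerator
        return None

    @numba.njit(cache=True, fastmath=False)
    def kernel(p, tri):  # pragma: no cover - exercised via _MeshDistance
        n = p.shape[0]
        dist = np.empty(n)
        closest = np.empty((n, 3))
        region = np.zeros(n, dtype=np.int8)
        for i in range(n):
            ax, ay, az = tri[i, 0, 0], tri[i, 0, 1], tri[i, 0, 2]
            bx, by, bz = tri[i, 1, 0], tri[i, 1, 1], tri[i, 1, 2]
            cx, cy, cz = tri[i, 2, 0], tri[i, 2, 1], tri[i, 2, 2]
            px, py, pz = p[i, 0], p[i, 1], p[i, 2]
            abx, aby, abz = bx - ax, by - ay, bz - az
            acx, acy, acz = cx - ax, cy - ay, cz - az
            apx, apy, apz = px - ax, py - ay, pz - az
            d1 = abx * apx + aby * apy + abz * apz
            d2 = acx * apx + acy * apy + acz * apz
            if d1 <= 0.0 and d2 <= 0.0:
                qx, qy, qz, reg = ax, ay, az, 1
            else:
                bpx, bpy, bpz = px - bx, py - by, pz - bz
                d3 = abx * bpx + aby * bpy + abz * bpz
                d4 = acx * bpx + acy * bpy + acz * bpz
                if d3 >= 0.0 and d4 <= d3:
                    qx, qy, qz, reg = bx, by, bz, 2
                else:
                    cpx, cpy, cpz = px - cx, py - cy, pz - cz
                    d5 = abx * cpx + aby * cpy + abz * cpz
                    d6 = acx * cpx + acy * cpy + acz * cpz
                    if d6 >= 0.0 and d5 <= d6:
                        qx, qy, qz, reg = cx, cy, cz, 3
                    else:
                        vc = d1 * d4 - d3 * d2
                        if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                            t = d1 / (d1 - d3)
                            qx, qy, qz, reg = ax + t * abx, ay + t * aby, az + t * abz, 4
                        else:
                            vb = d5 * d2 - d1 * d6
                            if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                                t = d2 / (d2 - d6)
                                qx, qy, qz, reg = ax + t * acx, ay + t * acy, az + t * acz, 6
                            else:
                                va = d3 * d6 - d5 * d4
                                if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
                                    t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                                    qx = bx + t * (cx - bx)
                                    qy = by + t * (cy - by)
                                    qz = bz + t * (cz - bz)
                                    reg = 5
                                else:
                                    denom = va + vb + vc
                                    v = vb / denom
                                    w = vc / denom
                                    qx = ax + v * abx + w * acx
                                    qy = ay + v * aby + w * acy
                                    qz = az + v * abz + w * acz
                                    reg = 0
            dx, dy, dz = px - qx, py - qy, pz - qz
            dist[i] = (dx * dx + dy * dy + dz * dz) ** 0.5
            closest[i, 0], closest[i, 1], closest[i, 2] = qx, qy, qz
            region[i] = reg
        return dist, closest, region

    return kernel


_NUMBA_KERNEL = None
_NUMBA_TRIED = False


def _pairwise_point_triangle(points: np.ndarray, triangles: np.ndarray):
    """Dispatch to the compiled kernel when available, else the numpy path."""
    global _NUMBA_KERNEL, _NUMBA_TRIED
    if not _NUMBA_TRIED:
        _NUMBA_TRIED = True
        _NUMBA_KERNEL = _make_numba_kernel()
    if _NUMBA_KERNEL is not None:
        p = np.ascontiguousarray(points, dtype=np.float64)
        t = np.ascontiguousarray(triangles, dtype=np.float64)
        return _NUMBA_KERNEL(p, t)
    return point_triangle_distance(points, triangles)


class _MeshDistance:
    """Exact unsigned/signed distance queries against one mesh.

    Candidate triangles come from a KD-tree over triangle centroids; a
    guaranteed second pass widens the candidate set wherever the k-nearest
    upper bound cannot certify the true minimum, so returned distances are
    exact, not approximate.
    """

    def __init__(self, mesh: TriangleMesh, face_indices: np.ndarray | None = None):
        self.mesh = mesh
        self.tri = mesh.triangles(face_indices)
        if face_indices is None:
            self.face_map = np.arange(len(mesh.faces))
        else:
            self.face_map = np.asarray(face_indices)
        cent = self.tri.mean(axis=1)
        # circumscribing radius bound: max distance from centroid to a vertex
        self.tri_radius = np.linalg.norm(self.tri - cent[:, None, :], axis=2).max(axis=1)
        self.max_radius = float(self.tri_radius.max()) if len(self.tri) else 0.0
        self.median_radius = float(np.median(self.tri_radius)) if len(self.tri) else 0.0
        self.tree = cKDTree(cent)
        self.cent = cent

    def unsigned(self, points: np.ndarray, k: int = 8, return_features: bool = False):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        k = min(k, len(self.tri))
        dc, idx = self.tree.query(p, k=k)
        if k == 1:
            dc, idx = dc[:, None], idx[:, None]
        n = len(p)
        pts_rep = np.repeat(p, k, axis=0)
        tris = self.tri[idx.ravel()]
        d, cp, reg = _pairwise_point_triangle(pts_rep, tris)
        d = d.reshape(n, k)
        best = d.argmin(axis=1)
        rows = np.arange(n)
        dist = d[rows, best]
        tri_id = idx[rows, best]
        flat_best = rows * k + best
        reg = reg[flat_best]
        closest = cp[flat_best]
        # second pass: the true nearest triangle must have its centroid within
        # dist + max triangle radius; if the k-th candidate centroid is nearer
        # than that bound, triangles beyond the first k could be closer.  The
        # certification is restricted to a near-surface band: beyond it the
        # k-nearest candidates already bracket the minimum to within
        # O(h^2 / dist) (h = triangle radius), far below grid resolution.
        band = 6.0 * self.median_radius
        need = np.flatnonzero((dc[:, -1] < dist + self.max_radius) & (dist < band))
        if len(need):
            lists = self.tree.query_ball_point(p[need], dist[need] + self.max_radius)
            lengths = np.array([len(l) for l in lists])
            keep = lengths > k
            need, lists, lengths = need[keep], [l for l, m in zip(lists, keep) if m], lengths[keep]
        if len(need):
            cand = np.concatenate([np.asarray(l) for l in lists])
            seg = np.repeat(np.arange(len(need)), lengths)
            di, cpi, ri = _pairwise_point_triangle(p[need][seg], self.tri[cand])
            order = np.lexsort((di, seg))
            firsts = order[np.searchsorted(seg[order], np.arange(len(need)))]
            better = di[firsts] < dist[need]
            upd = need[better]
            fb = firsts[better]
            dist[upd], tri_id[upd], reg[upd], closest[upd] = (
                di[fb], cand[fb], ri[fb], cpi[fb],
            )
        if return_features:
            return dist, tri_id, reg, closest
        return dist

    def signed(self, points: np.ndarray, k: int = 8) -> np.ndarray:
        dist, tri_id, reg, closest = self.unsigned(points, k=k, return_features=True)
        pn = self._pseudonormals()
        p = np.atleast_2d(np.asarray(points, dtype=float))
        normal = self._feature_normal(tri_id, reg, pn)
        sign = np.where(np.einsum("ij,ij->i", p - closest, normal) >= 0, 1.0, -1.0)
        return sign * dist

    # -- angle-weighted pseudonormals ---------------------------------------

    def _pseudonormals(self):
        if hasattr(self, "_pn"):
            return self._pn
        mesh = self.mesh
        tm = mesh.as_trimesh()
        face_n = np.asarray(tm.face_normals)
        nv = len(mesh.vertices)
        vert_n = np.zeros((nv, 3))
        tri = mesh.vertices[mesh.faces]
        for corner in range(3):
            e1 = tri[:, (corner + 1) % 3] - tri[:, corner]
            e2 = tri[:, (corner + 2) % 3] - tri[:, corner]
            cosang = np.einsum("ij,ij->i", e1, e2) / (
                np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
            )
            ang = np.arccos(np.clip(cosang, -1, 1))
            np.add.at(vert_n, mesh.faces[:, corner], ang[:, None] * face_n)
        # summed face normals per undirected edge, stored per (face, corner)
        edge_n = {}
        for fi, f in enumerate(mesh.faces):
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                key = (min(a, b), max(a, b))
                edge_n[key] = edge_n.get(key, 0) + face_n[fi]
        edge_n_per_face = np.empty((len(mesh.faces), 3, 3))
        for fi, f in enumerate(mesh.faces):
            for e, (a, b) in enumerate(((f[0], f[1]), (f[1], f[2]), (f[2], f[0]))):
                edge_n_per_face[fi, e] = edge_n[(min(a, b), max(a, b))]
        self._pn = (face_n, vert_n, edge_n_per_face)
        return self._pn

    def _feature_normal(self, tri_id, reg, pn):
        face_n, vert_n, edge_n_per_face = pn
        global_face = self.face_map[tri_id]
        faces = self.mesh.faces[global_face]
        out = np.empty((len(tri_id), 3))
        m = reg == 0
        out[m] = face_n[global_face[m]]
        for r in (1, 2, 3):  # closest to vertex a/b/c
            m = reg == r
            out[m] = vert_n[faces[m, r - 1]]
        for r, e in ((4, 0), (5, 1), (6, 2)):  # closest to edge ab/bc/ca
            m = reg == r
            out[m] = edge_n_per_face[global_face[m], e]
        return out


# ---------------------------------------------------------------------------
# Field construction
# ---------------------------------------------------------------------------


def build_distance_field(
    mesh: TriangleMesh,
    points_per_axis: int = 200,
    padding_fraction: float = 0.5,
    signed: bool = True,
    face_indices: np.ndarray | None = None,
) -> DistanceField:
    """Sample exact surface distances on a padded regular grid.

    The grid prism is the mesh bounding box enlarged by ``padding_fraction``
    on each axis (0.5 means 50% larger overall).  ``signed=True`` requires a
    watertight mesh.  ``face_indices`` restricts the surface to a face subset
    (used for open articular patches, which must be unsigned).
    """
    if points_per_axis < 8:
        raise ValueError("points_per_axis must be >= 8")
    if signed:
        if face_indices is not None:
            raise ValueError("signed fields require the full closed mesh")
        if not mesh.is_watertight:
            raise ValueError("signed distance field requires a watertight mesh")
    pts = mesh.vertices if face_indices is None else mesh.triangles(face_indices).reshape(-1, 3)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    extent = hi - lo
    extent = np.where(extent <= 0, 1e-6, extent)
    lo = lo - extent * padding_fraction / 2
    hi = hi + extent * padding_fraction / 2
    n = points_per_axis
    spacing = (hi - lo) / (n - 1)
    xs = [lo[i] + spacing[i] * np.arange(n) for i in range(3)]
    grid = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1).reshape(-1, 3)
    md = _MeshDistance(mesh, face_indices)
    vals = np.empty(len(grid))
    chunk = 65536
    if signed:
        md._pseudonormals()
    for s in range(0, len(grid), chunk):
        block = grid[s:s + chunk]
        vals[s:s + chunk] = md.signed(block) if signed else md.unsigned(block)
    logger.info(
        "distance field: %d^3 nodes, spacing %s mm, signed=%s",
        n, np.round(spacing, 4), signed,
    )
    return DistanceField(
        origin=lo, spacing=spacing, grid_counts=(n, n, n),
        values=vals.reshape(n, n, n), signed=signed,
    )


def query_distance(field: DistanceField, point: np.ndarray) -> float:
    """Trilinear distance at a single point (must lie inside the prism)."""
    return float(field.query(np.asarray(point, dtype=float)[None])[0])


# ---------------------------------------------------------------------------
# Sphere fitting
# ---------------------------------------------------------------------------


def fit_sphere(points: np.ndarray) -> SphereFit:
    """Algebraic least-squares sphere through ``points``.

    Solves the linearized normal equations for center c and radius r from
    |p|^2 = 2 p.c + (r^2 - |c|^2).  Requires at least 4 points not all on a
    common plane.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 4:
        raise ValueError("need at least 4 points of shape (n, 3)")
    A = np.hstack([2 * p, np.ones((len(p), 1))])
    b = np.einsum("ij,ij->i", p, p)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate (coplanar) point set: sphere is not identifiable")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("degenerate point set: non-positive squared radius")
    radius = float(np.sqrt(r2))
    resid = np.linalg.norm(p - center, axis=1) - radius
    return SphereFit(center=center, radius=radius, rms_residual=float(np.sqrt(np.mean(resid**2))))
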