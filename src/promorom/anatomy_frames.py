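"""Anatomical coordinate systems for the scapula and humerus.

Both frames are right-handed orthonormal triads: x is medial–lateral,
y cranial–caudal, z anterior–posterior.  The scapula's y axis follows the
medial (vertebral) border with x perpendicular to it in the blade plane and
pointing toward the glenoid; the humerus's y axis follows the long axis of
the proximal shaft, with the lesser tubercle fixing the azimuth of x about
it.  Because both y axes are defined this way, the abduction angle reported
downstream is exactly the inclination of the humeral long axis relative to
the scapular medial border.

Frame constructors take explicit geometric primitives (border points, blade
points, a head patch, a tubercle point) rather than auto-detecting features,
so synthetic fixtures and digitized landmarks alike can drive them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .mesh_fields import TriangleMesh, fit_sphere

__all__ = ["AnatomicalFrame", "scapula_frame", "humerus_frame", "to_joint_coordinates"]


@dataclass
class AnatomicalFrame:
    """Origin plus right-handed orthonormal axes (rows: x, y, z)."""

    origin: np.ndarray  # (3,), mm
    axes: np.ndarray  # (3, 3); axes[i] is the i-th axis direction in world coords

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise ValueError("axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("axes must be right-handed (det +1)")

    @property
    def x(self) -> np.ndarray:
        return self.axes[0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[2]

    def world_to_frame(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) @ self.axes.T

    def frame_to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.axes + self.origin

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"origin": self.origin.tolist(), "axes": self.axes.tolist()}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AnatomicalFrame":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["origin"]), np.array(d["axes"]))

    @classmethod
    def identity(cls) -> "AnatomicalFrame":
        return cls(np.zeros(3), np.eye(3))


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"{what} has zero length")
    return v / n


def scapula_frame(
    medial_border_points: np.ndarray,
    blade_points: np.ndarray,
    glenoid_centroid: np.ndarray,
    side: str = "right",
) -> AnatomicalFrame:
    """Scapular frame from the medial border, the blade plane and the glenoid.

    y runs along the medial border (cranial positive: from the first border
    point toward the last), z is the blade-plane normal, and x = y × z
    re-orthogonalized and oriented toward the glenoid.  The construction
    yields a right-handed triad for either side; ``side="left"`` documents
    that the caller mirrored a left specimen into right-side convention
    before frame construction.
    """
    if side not in ("right", "left"):
        raise ValueError("side must be 'right' or 'left'")
    border = np.asarray(medial_border_points, dtype=float)
    blade = np.asarray(blade_points, dtype=float)
    g = np.asarray(glenoid_centroid, dtype=float)
    if len(border) < 2:
        raise ValueError("need at least 2 medial-border points")
    if len(blade) < 3:
        raise ValueError("need at least 3 blade points")
    y = _unit(border[-1] - border[0], "medial border direction")
    centered = blade - blade.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-300):
        raise ValueError("blade points are collinear; plane normal undefined")
    z = vt[2]
    # make x point from the blade toward the glenoid
    x = np.cross(y, z)
    if x @ (g - blade.mean(axis=0)) < 0:
        z = -z
        x = -x
    x = _unit(x - (x @ y) * y, "medial-lateral axis")
    z = np.cross(x, y)
    return AnatomicalFrame(origin=g, axes=np.array([x, y, z]))


def humerus_frame(
    shaft_axis_points: np.ndarray,
    head_patch,
    lesser_tubercle_point: np.ndarray,
) -> AnatomicalFrame:
    """Humeral frame from the proximal shaft axis, head patch and lesser tubercle.

    y runs along the shaft (cranial positive: from the distal shaft point
    toward the proximal), the origin is the centre of a sphere fit to the
    articular patch, and the head-centre→lesser-tubercle vector fixes x (the
    medial–lateral axis) in the plane orthogonal to y; z = x × y.

    ``head_patch`` is either an (n, 3) point array or a :class:`TriangleMesh`.
    """
    shaft = np.asarray(shaft_axis_points, dtype=float)
    if len(shaft) < 2:
        raise ValueError("need at least 2 shaft-axis points")
    pts = head_patch.vertices if isinstance(head_patch, TriangleMesh) else np.asarray(head_patch)
    sphere = fit_sphere(pts)
    y = _unit(shaft[-1] - shaft[0], "shaft axis")
    t = np.asarray(lesser_tubercle_point, dtype=float) - sphere.center
    x = t - (t @ y) * y
    if np.linalg.norm(x) < 1e-9:
        raise ValueError(
            "lesser tubercle lies on the shaft axis through the head centre: azimuth undefined"
        )
    x = _unit(x, "medial-lateral axis")
    z = np.cross(x, y)
    return AnatomicalFrame(origin=sphere.center, axes=np.array([x, y, z]))


def to_joint_coordinates(mesh_or_points, frame: AnatomicalFrame):
    """Express a mesh or point array in ``frame`` coordinates (rigid transform)."""
    if isinstance(mesh_or_points, TriangleMesh):
        return TriangleMesh(
            frame.world_to_frame(mesh_or_points.vertices),
            mesh_or_points.faces.copy(),
            {k: v.copy() for k, v in mesh_or_points.labels.items()},
        )
    return frame.world_to_frame(mesh_or_points)
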