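"""ROM metrics in sine-corrected angle space.

Admissible poses are projected onto a 2D joint map with an equal-area
sinusoidal (sine-corrected) projection: x = plane_of_elevation * sin(abd),
y = abd, with abduction playing the role of colatitude measured from the
abd = 0 pole.  The Jacobian determinant of the projection is sin(abd), so
areas on the map equal solid-angle areas on the joint sphere (in square
degrees) and small geodesic steps keep their length.

Three summary metrics are computed from the projected cloud:

* mobility — the volume of an alpha shape around the 3D cloud
  (x, abduction, axial), in cubic map degrees;
* functional centre — the map location whose geodesic search circle (radius
  proportional to the cube root of mobility) maximizes the mean axial
  rotational intensity; and
* circumduction envelope — the area of an alpha shape around the 2D cloud.

The alpha shape is the union of Delaunay simplices whose circumradius is at
most the alpha radius (default 5 map degrees).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

logger = logging.getLogger(__name__)

__all__ = [
    "MapPoint",
    "IntensityMap",
    "ROMMetrics",
    "project_sine",
    "project_poses",
    "alpha_shape_volume",
    "alpha_shape_area",
    "mobility",
    "axial_intensity",
    "functional_centre",
    "circumduction_envelope",
    "regress_metrics",
    "compute_metrics",
]


@dataclass(frozen=True)
class MapPoint:
    x: float  # sine-corrected longitude, degrees
    y: float  # abduction, degrees
    axial: float | None = None


@dataclass
class IntensityMap:
    """Axial-rotation intensity at each in-ROM (poe, abd) grid node.

    ``intensity`` is the total achievable axial rotation in degrees:
    (number of admissible axial samples) x increment, a total measure rather
    than a max-minus-min span so split axial ranges are counted correctly.
    """

    poe: np.ndarray  # (n,) degrees
    abd: np.ndarray  # (n,) degrees
    intensity: np.ndarray  # (n,) degrees of axial freedom
    increment: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"poe_deg": self.poe, "abd_deg": self.abd, "intensity_deg": self.intensity}
        )


@dataclass
class ROMMetrics:
    mobility: float  # cubic map degrees
    functional_centre: tuple[float, float]  # (poe, abd) degrees
    fc_abduction: float  # degrees
    circumduction_envelope: float  # square map degrees
    alpha_radius: float
    radius_coeff: float
    n_admissible: int


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


def project_sine(pose) -> MapPoint:
    """Sine-corrected (equal-area sinusoidal) projection of one pose."""
    x = pose.plane_of_elevation * np.sin(np.radians(pose.abduction))
    return MapPoint(float(x), float(pose.abduction), float(pose.axial))


def project_poses(poses, three_d: bool = False) -> np.ndarray:
    """Project admissible poses to map coordinates.

    Accepts ``OptimizedPose`` or bare ``Pose`` objects.  Returns (n, 2) map
    points or (n, 3) with the axial angle appended unchanged.  Pole rows
    (abd 0/180) collapse to a single x and are deduplicated.
    """
    arr = []
    for p in poses:
        pose = getattr(p, "pose", p)
        mp = project_sine(pose)
        arr.append((mp.x, mp.y, mp.axial) if three_d else (mp.x, mp.y))
    pts = np.array(arr, dtype=float).reshape(-1, 3 if three_d else 2)
    return np.unique(pts, axis=0)


# ---------------------------------------------------------------------------
# Alpha shapes (circumradius-filtered Delaunay)
# ---------------------------------------------------------------------------


def _circumradius_simplex(pts: np.ndarray) -> np.ndarray:
    """Circumradii for a stack of d-simplices, pts shape (n, d+1, d)."""
    p0 = pts[:, 0]
    A = 2.0 * (pts[:, 1:] - p0[:, None, :])  # (n, d, d)
    b = np.einsum("nij,nij->ni", pts[:, 1:], pts[:, 1:]) - np.einsum(
        "ni,ni->n", p0, p0
    )[:, None]
    n, d = A.shape[0], A.shape[1]
    centers = np.full((n, d), np.nan)
    det = np.linalg.det(A)
    ok = np.abs(det) > 1e-12
    if ok.any():
        centers[ok] = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
    r = np.linalg.norm(centers - p0, axis=1)
    r[~ok] = np.inf  # degenerate simplex: excluded by any finite alpha
    return r


def _alpha_simplices(points: np.ndarray, alpha_radius: float):
    tri = Delaunay(points)
    simplex_pts = points[tri.simplices]
    r = _circumradius_simplex(simplex_pts)
    keep = r <= alpha_radius
    return simplex_pts[keep]


def alpha_shape_volume(points: np.ndarray, alpha_radius: float) -> float:
    """Volume of the 3D alpha shape (sum of kept tetrahedra volumes)."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 4 or np.linalg.matrix_rank(pts - pts[0], tol=1e-9) < 3:
        warnings.warn("fewer than 4 non-degenerate points: alpha volume is 0")
        return 0.0
    kept = _alpha_simplices(pts, alpha_radius)
    if len(kept) == 0:
        return 0.0
    v = kept[:, 1:] - kept[:, :1]
    vols = np.abs(np.einsum("nij,nj->n", np.cross(v[:, 0], v[:, 1])[:, None, :], v[:, 2]))
    return float(np.sum(vols) / 6.0)


def alpha_shape_area(points: np.ndarray, alpha_radius: float) -> float:
    """Area of the 2D alpha shape (sum of kept triangle areas)."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3 or np.linalg.matrix_rank(pts - pts[0], tol=1e-9) < 2:
        warnings.warn("fewer than 3 non-degenerate points: alpha area is 0")
        return 0.0
    kept = _alpha_simplices(pts, alpha_radius)
    if len(kept) == 0:
        return 0.0
    e1 = kept[:, 1] - kept[:, 0]
    e2 = kept[:, 2] - kept[:, 0]
    areas = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    return float(np.sum(areas))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def mobility(rom_poses, alpha_radius: float = 5.0) -> float:
    """Alpha-shape volume of the admissible cloud in 3D map space."""
    pts = project_poses(rom_poses, three_d=True)
    if len(pts) == 0:
        return 0.0
    return alpha_shape_volume(pts, alpha_radius)


def axial_intensity(rom_poses, increment_deg: float) -> IntensityMap:
    """Total admissible axial rotation at each (poe, abd) grid node."""
    nodes: dict[tuple[float, float], int] = {}
    for p in rom_poses:
        pose = getattr(p, "pose", p)
        key = (pose.plane_of_elevation, pose.abduction)
        nodes[key] = nodes.get(key, 0) + 1
    if not nodes:
        raise ValueError("empty ROM: no admissible poses")
    keys = sorted(nodes)
    poe = np.array([k[0] for k in keys])
    abd = np.array([k[1] for k in keys])
    inten = np.array([nodes[k] for k in keys], dtype=float) * increment_deg
    return IntensityMap(poe=poe, abd=abd, intensity=inten, increment=increment_deg)


def _geodesic_deg(poe1, abd1, poe2, abd2):
    """Great-circle distance in degrees between long-axis directions."""
    t1, t2 = np.radians(abd1), np.radians(abd2)
    dphi = np.radians(poe1 - poe2)
    cosd = np.cos(t1) * np.cos(t2) + np.sin(t1) * np.sin(t2) * np.cos(dphi)
    return np.degrees(np.arccos(np.clip(cosd, -1.0, 1.0)))


def functional_centre(
    intensity_map: IntensityMap,
    mobility_value: float,
    radius_coeff: float = 0.3,
) -> tuple[float, float]:
    """Map location maximizing mean intensity within a geodesic search circle.

    The search radius is radius_coeff * mobility^(1/3) map degrees.  The
    optimum is found by exhaustive evaluation at every map node followed by
    a local refinement on a finer sub-grid around the best node; ties break
    toward lower abduction, then lower \|plane of elevation\|.
    """
    if mobility_value <= 0:
        raise ValueError("mobility must be positive to size the search circle")
    radius = radius_coeff * mobility_value ** (1.0 / 3.0)
    poe, abd, inten = intensity_map.poe, intensity_map.abd, intensity_map.intensity
    if radius >= 180.0:
        warnings.warn("search circle covers the whole sphere; using weighted centroid")
        w = inten / inten.sum()
        return (float(np.sum(w * poe)), float(np.sum(w * abd)))

    def mean_intensity(cp, ca):
        d = _geodesic_deg(poe, abd, cp, ca)
        m = d <= radius
        if not m.any():
            return -np.inf
        return float(inten[m].mean())

    # exhaustive pass over map nodes with deterministic tie-breaking
    scores = np.array([mean_intensity(p, a) for p, a in zip(poe, abd)])
    order = np.lexsort((np.abs(poe), abd, -scores))
    best = order[0]
    cp, ca = float(poe[best]), float(abd[best])
    best_score = scores[best]
    # local continuous refinement on a shrinking sub-grid
    step = intensity_map.increment / 2.0
    for _ in range(4):
        cand_p = cp + step * np.array([-1, 0, 1])
        cand_a = np.clip(ca + step * np.array([-1, 0, 1]), 0.0, 180.0)
        improved = False
        for pp in cand_p:
            for aa in cand_a:
                s = mean_intensity(pp, aa)
                if s > best_score + 1e-12:
                    best_score, cp, ca, improved = s, float(pp), float(aa), True
        if not improved:
            step /= 2.0
    return (cp, ca)


def circumduction_envelope(rom_poses, alpha_radius: float = 5.0) -> float:
    """Alpha-shape area of the admissible cloud on the 2D joint map."""
    pts = project_poses(rom_poses, three_d=False)
    if len(pts) == 0:
        return 0.0
    return alpha_shape_area(pts, alpha_radius)


def compute_metrics(
    rom_poses,
    increment_deg: float,
    alpha_radius: float = 5.0,
    radius_coeff: float = 0.3,
) -> ROMMetrics:
    """All three ROM metrics from one admissible-pose cloud."""
    poses = list(rom_poses)
    mob = mobility(poses, alpha_radius)
    env = circumduction_envelope(poses, alpha_radius)
    if poses and mob > 0:
        imap = axial_intensity(poses, increment_deg)
        fc = functional_centre(imap, mob, radius_coeff)
    else:
        fc = (float("nan"), float("nan"))
    return ROMMetrics(
        mobility=mob,
        functional_centre=fc,
        fc_abduction=fc[1],
        circumduction_envelope=env,
        alpha_radius=alpha_radius,
        radius_coeff=radius_coeff,
        n_admissible=len(poses),
    )


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------


def regress_metrics(x_values, y_values):
    """OLS of y on x with an F-test for a non-zero slope.

    Returns a dict with slope, intercept, r_squared, p_value, n and the
    5%-level significance flag.
    """
    import statsmodels.api as sm

    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and paired")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression inputs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    p_value = float(model.f_pvalue) if np.isfinite(model.f_pvalue) else 1.0
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r_squared": float(model.rsquared),
        "p_value": p_value,
        "n": int(len(x)),
        "significant_5pct": bool(p_value < 0.05),
    }
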