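"""Landmark-based geometric morphometrics and discrete shape measures.

Scapula (22 landmarks) and proximal humerus (21 landmarks + 4
semilandmarks, treated as fixed points) are superimposed *separately* with
generalized Procrustes analysis — centering, scaling to unit centroid size
and orientation-preserving rotation to the iteratively re-estimated mean —
and the two aligned blocks are then concatenated column-wise into one joint
shape space on which PCA is run.  Regressing ROM metrics on principal
components (or on the 12 discrete morphological measures) identifies which
shape axes predict mobility and which predict the functional centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mesh_fields import TriangleMesh, fit_sphere

__all__ = [
    "LandmarkSet",
    "ShapeSpace",
    "BLOCK_SIZES",
    "centroid_size",
    "procrustes_block",
    "procrustes_distance",
    "concatenate_blocks",
    "pca",
    "discrete_measures",
    "regress_on_components",
    "load_landmarks_csv",
]

BLOCK_SIZES = {"scapula": 22, "humerus": 25}


@dataclass
class LandmarkSet:
    specimen_id: str
    block: str  # "scapula" | "humerus"
    points: np.ndarray  # (k, 3) ordered landmarks, mm
    semilandmark: np.ndarray = None  # (k,) bool flags

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.block not in BLOCK_SIZES:
            raise ValueError(f"block must be one of {sorted(BLOCK_SIZES)}")
        expected = BLOCK_SIZES[self.block]
        if self.points.shape != (expected, 3):
            raise ValueError(
                f"{self.block} block requires {expected} landmarks, got {self.points.shape}"
            )
        if self.semilandmark is None:
            self.semilandmark = np.zeros(expected, dtype=bool)


@dataclass
class ShapeSpace:
    specimen_ids: list
    aligned: dict  # block -> (n, k, 3) aligned coordinates
    matrix: np.ndarray  # (n, total columns) concatenated flattened coords
    column_map: list  # per column: (block, landmark index, axis)
    centroid_sizes: dict  # block -> (n,) original centroid sizes
    mean_shape: np.ndarray = None
    scores: np.ndarray = None
    components: np.ndarray = None
    variance_fractions: np.ndarray = None


def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared distances of landmarks to their centroid."""
    p = np.asarray(points, dtype=float)
    c = p.mean(axis=0)
    return float(np.sqrt(np.sum((p - c) ** 2)))


# ---------------------------------------------------------------------------
# Generalized Procrustes
# ---------------------------------------------------------------------------


def _align_to(shape: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rotate ``shape`` onto ``reference`` (orientation-preserving only)."""
    H = shape.T @ reference
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return shape @ R.T


def _normalize(points: np.ndarray) -> np.ndarray:
    p = points - points.mean(axis=0)
    cs = np.sqrt(np.sum(p**2))
    if cs < 1e-12:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return p / cs


def procrustes_block(landmark_sets: list) -> tuple[np.ndarray, list, np.ndarray]:
    """Generalized Procrustes superimposition of one block.

    Returns (aligned (n, k, 3), specimen ids, centroid sizes).  Iterates
    alignment to the evolving mean until the mean changes by less than
    1e-10 (Frobenius).  Reflections are excluded, so a mirrored specimen
    keeps a nonzero Procrustes distance from its original.
    """
    if len(landmark_sets) < 2:
        raise ValueError("need at least 2 specimens")
    blocks = {ls.block for ls in landmark_sets}
    if len(blocks) != 1:
        raise ValueError(f"mixed blocks in one superimposition: {sorted(blocks)}")
    ids = [ls.specimen_id for ls in landmark_sets]
    sizes = np.array([centroid_size(ls.points) for ls in landmark_sets])
    shapes = np.array([_normalize(ls.points) for ls in landmark_sets])
    mean = shapes[0]
    for _ in range(200):
        aligned = np.array([_align_to(s, mean) for s in shapes])
        new_mean = _normalize(aligned.mean(axis=0))
        if np.linalg.norm(new_mean - mean) < 1e-10:
            mean = new_mean
            break
        mean = new_mean
    # the GPA solution is unique only up to a joint rotation (it inherits the
    # first specimen's orientation); rotate everything into the mean shape's
    # principal axes so the output is independent of specimen ordering
    R = _canonical_orientation(mean)
    aligned = np.array([_align_to(s, mean) for s in shapes]) @ R
    return aligned, ids, sizes


def _canonical_orientation(mean: np.ndarray) -> np.ndarray:
    """Rotation taking a mean shape into its principal axes, deterministic
    sign convention (largest-|coordinate| landmark positive per axis)."""
    w, v = np.linalg.eigh(mean.T @ mean)
    v = v[:, ::-1]  # descending variance
    for i in range(3):
        proj = mean @ v[:, i]
        if proj[np.argmax(np.abs(proj))] < 0:
            v[:, i] = -v[:, i]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations (no reflection)."""
    sa, sb = _normalize(np.asarray(a, float)), _normalize(np.asarray(b, float))
    return float(np.linalg.norm(_align_to(sa, sb) - sb))


def concatenate_blocks(
    scapula_aligned: tuple,
    humerus_aligned: tuple,
) -> ShapeSpace:
    """Column-concatenate per-block aligned coordinates into one shape space.

    Each argument is the (aligned, ids, sizes) triple from
    :func:`procrustes_block`; the specimen rosters must match in order.
    """
    (sc, sc_ids, sc_sizes) = scapula_aligned
    (hu, hu_ids, hu_sizes) = humerus_aligned
    if sc_ids != hu_ids:
        raise ValueError("specimen rosters differ between blocks")
    n = len(sc_ids)
    matrix = np.hstack([sc.reshape(n, -1), hu.reshape(n, -1)])
    column_map = [
        (block, lm, ax)
        for block, k in (("scapula", sc.shape[1]), ("humerus", hu.shape[1]))
        for lm in range(k)
        for ax in range(3)
    ]
    return ShapeSpace(
        specimen_ids=list(sc_ids),
        aligned={"scapula": sc, "humerus": hu},
        matrix=matrix,
        column_map=column_map,
        centroid_sizes={"scapula": sc_sizes, "humerus": hu_sizes},
    )


def pca(space_or_matrix) -> ShapeSpace:
    """Centered PCA of the concatenated shape matrix via SVD.

    Sign convention: each component's largest-magnitude loading is positive,
    so scores are reproducible across runs and specimen orderings.
    """
    space = (
        space_or_matrix
        if isinstance(space_or_matrix, ShapeSpace)
        else ShapeSpace(
            specimen_ids=list(range(len(space_or_matrix))),
            aligned={},
            matrix=np.asarray(space_or_matrix, dtype=float),
            column_map=[],
            centroid_sizes={},
        )
    )
    X = space.matrix
    if X.shape[0] < 3:
        raise ValueError("need at least 3 specimens for PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(len(s)):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U * s
    var = s**2
    total = var.sum()
    space.mean_shape = mean
    space.scores = scores
    space.components = Vt
    space.variance_fractions = var / total if total > 0 else var
    return space


# ---------------------------------------------------------------------------
# Discrete measures
# ---------------------------------------------------------------------------


def _lm(df: pd.DataFrame, name: str) -> np.ndarray:
    row = df.loc[df.name == name, ["x", "y", "z"]]
    if len(row) != 1:
        raise KeyError(f"landmark {name!r} missing or duplicated")
    return row.values[0].astype(float)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def discrete_measures(
    scapula_landmarks: pd.DataFrame,
    humerus_landmarks: pd.DataFrame,
    scapula_mesh: TriangleMesh,
    humerus_mesh: TriangleMesh,
) -> dict:
    """The 12 discrete morphological parameters with shoulder-ROM relevance.

    Landmark recipes (documented defaults; angles are scale-free, linear
    measures are divided by the scapular centroid size CS and areas by CS^2
    so overall body size does not masquerade as shape):

    * cranial_angle — angle between the glenoid-plane outward normal
      (from the glenoid_rim_* ring) and the caudal direction of the medial
      border (superior_angle -> inferior_angle); a more cranially oriented
      glenoid gives a larger angle.
    * critical_shoulder_angle — at the inferior glenoid rim, angle between
      the superior-rim direction and the acromion direction.
    * glenoid_surface_area, glenoid_height (cranial-caudal rim extent),
      glenoid_width (anterior-posterior rim extent), glenoid height:width.
    * humerus_articular_surface_area, humeral_head_radius (articular sphere
      fit), articular_surface_area_ratio (humerus : glenoid).
    * inter_tuberosity_angle — angle subtended at the head centre by the two
      tubercles, projected onto the plane orthogonal to the shaft axis.
    * globularity — head radius / *humerus* centroid size.
    * sphericity — 1 - (sphere-fit rms residual / radius); 1 for a perfect
      sphere, strictly below 1 for a flattened head.

    Measures whose landmarks or labels are missing are reported as NaN with
    a warning; the rest are still computed.
    """
    out: dict[str, float] = {}
    cs = centroid_size(scapula_landmarks[["x", "y", "z"]].values)

    def attempt(name, fn):
        try:
            out[name] = float(fn())
        except Exception as exc:  # degenerate or missing inputs
            warnings.warn(f"measure {name} unavailable: {exc}")
            out[name] = float("nan")

    rim = np.array(
        [_lm(scapula_landmarks, f"glenoid_rim_{k}") for k in range(8)]
    )
    rim_c = rim.mean(axis=0)
    _, _, vt = np.linalg.svd(rim - rim_c)
    normal = vt[2]
    sup, inf = _lm(scapula_landmarks, "superior_angle"), _lm(scapula_landmarks, "inferior_angle")
    caudal = inf - sup
    if normal @ (rim_c - (sup + inf) / 2) < 0:
        normal = -normal  # outward: away from the blade

    attempt("cranial_angle", lambda: _angle_deg(normal, caudal))

    def _csa():
        rim_sup = rim[np.argmax(rim[:, 1])]
        rim_inf = rim[np.argmin(rim[:, 1])]
        acromion = _lm(scapula_landmarks, "acromion")
        return _angle_deg(rim_sup - rim_inf, acromion - rim_inf)

    attempt("critical_shoulder_angle", _csa)
    attempt(
        "glenoid_surface_area",
        lambda: scapula_mesh.face_areas(scapula_mesh.labels["glenoid_face"]).sum() / cs**2,
    )
    attempt("glenoid_height", lambda: np.ptp(rim[:, 1]) / cs)
    attempt("glenoid_width", lambda: np.ptp(rim[:, 2]) / cs)
    attempt("glenoid_height_width_ratio", lambda: np.ptp(rim[:, 1]) / np.ptp(rim[:, 2]))

    patch_pts = humerus_mesh.label_vertices("head_articular")
    attempt(
        "humerus_articular_surface_area",
        lambda: humerus_mesh.face_areas(humerus_mesh.labels["head_articular"]).sum() / cs**2,
    )

    def _ita():
        sphere = fit_sphere(patch_pts)
        shaft = _lm(humerus_landmarks, "shaft_distal_end") - sphere.center
        axis = shaft / np.linalg.norm(shaft)
        lt = _lm(humerus_landmarks, "lesser_tubercle") - sphere.center
        gt = _lm(humerus_landmarks, "greater_tubercle") - sphere.center
        lt -= (lt @ axis) * axis
        gt -= (gt @ axis) * axis
        return _angle_deg(lt, gt)

    attempt("inter_tuberosity_angle", _ita)
    attempt("humeral_head_radius", lambda: fit_sphere(patch_pts).radius / cs)
    attempt(
        "articular_surface_area_ratio",
        lambda: humerus_mesh.face_areas(humerus_mesh.labels["head_articular"]).sum()
        / scapula_mesh.face_areas(scapula_mesh.labels["glenoid_face"]).sum(),
    )
    hu_cs = centroid_size(humerus_landmarks[["x", "y", "z"]].values)
    attempt("globularity", lambda: fit_sphere(patch_pts).radius / hu_cs)

    def _sphericity():
        s = fit_sphere(patch_pts)
        return 1.0 - s.rms_residual / s.radius

    attempt("sphericity", _sphericity)
    return out


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------


def regress_on_components(
    metric_values,
    predictors: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Independent OLS of one ROM metric on each predictor column.

    One regression (with slope F-test) per predictor — deliberately not
    multiplicity-corrected, matching the independent-test convention;
    a Bonferroni column is included for callers who want it.  Zero-variance
    predictors are skipped with a warning.  The ``direction`` column uses
    the up/down arrow convention for significant slopes.
    """
    y = np.asarray(metric_values, dtype=float)
    if len(y) != len(predictors):
        raise ValueError("metric and predictor lengths differ")
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    rows = []
    for col in predictors.columns:
        x = predictors[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.ptp(x[ok]) == 0:
            warnings.warn(f"predictor {col!r} skipped (constant or too few values)")
            continue
        model = sm.OLS(y[ok], sm.add_constant(x[ok])).fit()
        p = float(model.f_pvalue) if np.isfinite(model.f_pvalue) else 1.0
        slope = float(model.params[1])
        sig = p < alpha
        rows.append(
            {
                "predictor": col,
                "slope": slope,
                "r_squared": float(model.rsquared),
                "p_value": p,
                "n": int(ok.sum()),
                "significant": sig,
                "direction": ("↑" if slope > 0 else "↓") if sig else "—",
                "p_bonferroni": min(1.0, p * len(predictors.columns)),
            }
        )
    return pd.DataFrame(rows)


def load_landmarks_csv(path, specimen_id: str, block: str) -> LandmarkSet:
    """Read a name,x,y,z[,semilandmark] CSV into a LandmarkSet."""
    df = pd.read_csv(path)
    semi = (
        df["semilandmark"].to_numpy(dtype=bool)
        if "semilandmark" in df.columns
        else None
    )
    return LandmarkSet(
        specimen_id=specimen_id,
        block=block,
        points=df[["x", "y", "z"]].to_numpy(dtype=float),
        semilandmark=semi,
    )
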