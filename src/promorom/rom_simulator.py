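"""Proximity-driven range-of-motion simulation.

For every rotational pose of the humerus relative to the scapula — plane of
elevation, abduction and axial rotation sampled on an inclusive grid — the
humeral translation is optimized so that the *joint proximity* (the mean
distance from the glenoid-face vertices to the humeral-head articular
surface) matches a target value, subject to the nonlinear constraint that
neither bone interpenetrates the other.  A pose belongs to the ROM when the
optimized proximity lies within a relative threshold (default 5%) of the
target and the clearance constraint holds.

Rotations use a sequence-independent spherical coordinate system: a
shortest-arc ("no-twist") rotation carries the humeral long axis to the
direction given by (plane of elevation, abduction), then the axial rotation
twists the humerus about the resulting long axis.  This avoids gimbal
distortion and makes the pose ↔ rotation map bijective away from the
abduction poles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mesh_fields import DistanceField, TriangleMesh

logger = logging.getLogger(__name__)

__all__ = [
    "Pose",
    "OptimizedPose",
    "ROMResult",
    "Specimen",
    "SolverConfig",
    "sample_pose_grid",
    "pose_to_transform",
    "transform_to_pose",
    "joint_proximity",
    "optimize_translation",
    "simulate_rom",
    "sweep_parameters",
]

_EY = np.array([0.0, 1.0, 0.0])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pose:
    """Rotational pose: plane of elevation, abduction, axial twist (degrees).

    plane_of_elevation in [-180, 180] (longitude about the scapular y axis,
    0 = pure lateral elevation, positive anterior), abduction in [0, 180]
    (angle of the humeral long axis from the scapular medial border), axial
    in [-180, 180].  At abduction 0 or 180 every plane of elevation denotes
    the same long-axis direction (pole degeneracy).
    """

    plane_of_elevation: float
    abduction: float
    axial: float

    def __post_init__(self):
        if not (-180.0 <= self.plane_of_elevation <= 180.0):
            raise ValueError("plane_of_elevation out of [-180, 180]")
        if not (0.0 <= self.abduction <= 180.0):
            raise ValueError("abduction out of [0, 180]")
        if not (-180.0 <= self.axial <= 180.0):
            raise ValueError("axial out of [-180, 180]")

    @property
    def at_pole(self) -> bool:
        return self.abduction in (0.0, 180.0)


@dataclass
class OptimizedPose:
    pose: Pose
    translation: np.ndarray  # (3,), mm
    achieved_proximity: float  # mm
    objective_residual: float  # |achieved - target| / target
    admissible: bool
    solver_status: str  # converged | infeasible | max_iter


@dataclass
class ROMResult:
    specimen_id: str
    target_proximity: float
    threshold: float
    increment: float
    poses: list[OptimizedPose]

    @property
    def admissible_poses(self) -> list[OptimizedPose]:
        return [p for p in self.poses if p.admissible]

    @property
    def n_admissible(self) -> int:
        return sum(p.admissible for p in self.poses)

    def admissible_count_at(self, threshold: float) -> int:
        """Re-classify stored residuals under a different proximity threshold.

        Only poses whose optimization converged and satisfied the clearance
        constraint are eligible, so relaxing the threshold can only add poses.
        """
        return sum(
            p.solver_status == "converged" and p.objective_residual <= threshold
            for p in self.poses
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "poe_deg": p.pose.plane_of_elevation,
                "abd_deg": p.pose.abduction,
                "axial_deg": p.pose.axial,
                "tx_mm": p.translation[0],
                "ty_mm": p.translation[1],
                "tz_mm": p.translation[2],
                "proximity_mm": p.achieved_proximity,
                "residual_frac": p.objective_residual,
                "admissible": p.admissible,
                "status": p.solver_status,
            }
            for p in self.poses
        ]
        return pd.DataFrame(rows)


@dataclass
class SolverConfig:
    """Optimizer settings; defaults favour determinism over raw speed."""

    max_iter: int = 30
    ftol: float = 1e-10  # on the squared-residual objective, mm^2
    clearance_tol: float = 1e-6  # mm of allowed numerical constraint violation
    warm_start: bool = True
    screen_factor: float = 2.0  # coarse-screen rejection multiple of target


@dataclass
class Specimen:
    """Everything the simulator needs, expressed in joint coordinates.

    The scapula mesh lives in the scapular anatomical frame (glenoid centroid
    at the origin, +x lateral); the humerus mesh lives in the humeral frame
    (head-sphere centre at the origin, +y along the shaft toward cranial).
    A candidate placement maps humerus points h to R h + t in scapula space.
    """

    specimen_id: str
    scapula: TriangleMesh
    humerus: TriangleMesh
    glenoid_vertices: np.ndarray  # (g, 3) glenoid-face vertices, scapula frame
    head_patch_field: DistanceField  # unsigned, humerus frame
    scapula_field: DistanceField  # signed, scapula frame
    humerus_field: DistanceField  # signed, humerus frame
    target_proximity: float  # mm
    neutral_translation: np.ndarray  # (3,) head-centre position in scapula frame
    humerus_proxy: np.ndarray = None  # subsampled humerus vertices for clearance
    scapula_proxy: np.ndarray = None  # subsampled scapula vertices for clearance
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.humerus_proxy is None:
            self.humerus_proxy = _subsample(self.humerus.vertices, 400)
        if self.scapula_proxy is None:
            self.scapula_proxy = _subsample(self.scapula.vertices, 400)


def _subsample(points: np.ndarray, n: int) -> np.ndarray:
    if len(points) <= n:
        return np.asarray(points, dtype=float)
    idx = np.linspace(0, len(points) - 1, n).astype(int)
    return np.asarray(points, dtype=float)[idx]


# ---------------------------------------------------------------------------
# Pose grid and rotations
# ---------------------------------------------------------------------------


def sample_pose_grid(increment_deg: float) -> list[Pose]:
    """Inclusive grid over the full rotational space.

    Count = (360/inc + 1) x (180/inc + 1) x (360/inc + 1); at 5 degrees this
    is 73 x 37 x 73 = 197,173 poses.
    """
    inc = float(increment_deg)
    if inc <= 0 or abs(180.0 / inc - round(180.0 / inc)) > 1e-12:
        raise ValueError("increment must divide 180 exactly")
    poe = np.linspace(-180.0, 180.0, int(round(360 / inc)) + 1)
    abd = np.linspace(0.0, 180.0, int(round(180 / inc)) + 1)
    axial = np.linspace(-180.0, 180.0, int(round(360 / inc)) + 1)
    return [
        Pose(float(p), float(a), float(x))
        for p in poe
        for a in abd
        for x in axial
    ]


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = np.asarray(axis, dtype=float)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def _long_axis_direction(poe_deg: float, abd_deg: float) -> np.ndarray:
    poe, abd = np.radians(poe_deg), np.radians(abd_deg)
    return np.array(
        [np.sin(abd) * np.cos(poe), np.cos(abd), np.sin(abd) * np.sin(poe)]
    )


def pose_to_transform(pose: Pose) -> np.ndarray:
    """Rotation matrix for a pose (acts on humerus-frame coordinates).

    Step 1 transports the humeral long axis (+y) to its target spherical
    direction along the shortest arc, which defines axial = 0 (no twist);
    step 2 rotates about the resulting long axis by the axial angle.
    """
    v = _long_axis_direction(pose.plane_of_elevation, pose.abduction)
    abd = np.radians(pose.abduction)
    if abd < 1e-12:
        S = np.eye(3)
    elif abs(abd - np.pi) < 1e-12:
        # shortest arc to the antipode is degenerate; rotate in the pose's
        # elevation plane so the map stays continuous in plane_of_elevation
        axis = np.cross(_EY, _long_axis_direction(pose.plane_of_elevation, 90.0))
        S = _rotation_about(axis / np.linalg.norm(axis), np.pi)
    else:
        axis = np.cross(_EY, v)
        S = _rotation_about(axis / np.linalg.norm(axis), abd)
    A = _rotation_about(v, np.radians(pose.axial))
    return A @ S


def transform_to_pose(R: np.ndarray) -> Pose:
    """Inverse of :func:`pose_to_transform` (up to pole degeneracy)."""
    v = R @ _EY
    abd = float(np.degrees(np.arccos(np.clip(v[1], -1.0, 1.0))))
    if abd < 1e-9 or abd > 180.0 - 1e-9:
        poe = 0.0
    else:
        poe = float(np.degrees(np.arctan2(v[2], v[0])))
    S = pose_to_transform(Pose(poe, abd, 0.0))
    w = S @ np.array([1.0, 0.0, 0.0])  # transported reference orthogonal to v
    Aw = R @ np.array([1.0, 0.0, 0.0])
    axial = float(np.degrees(np.arctan2(np.cross(w, Aw) @ v, w @ Aw)))
    return Pose(poe, abd, axial)


# ---------------------------------------------------------------------------
# Proximity and optimization
# ---------------------------------------------------------------------------


def joint_proximity(
    glenoid_vertices: np.ndarray,
    head_patch_field: DistanceField,
    rotation: np.ndarray,
    translation: np.ndarray,
) -> float:
    """Mean distance from glenoid vertices to the humeral articular patch.

    The candidate placement maps humerus points h to R h + t, so glenoid
    vertices are pulled back into the humerus frame before querying the
    patch field.  Returns +inf when any pulled-back vertex leaves the field
    prism (the pose is then infeasible, not an error).
    """
    q = (np.asarray(glenoid_vertices) - translation) @ rotation
    d = head_patch_field.query(q, out_of_bounds="nan")
    if np.isnan(d).any():
        return float("inf")
    return float(d.mean())


class _PoseProblem:
    """Objective/constraints for one fixed rotation, cached per translation."""

    def __init__(self, specimen: Specimen, rotation: np.ndarray):
        self.sp = specimen
        self.R = rotation
        self._cache_t = None
        self._cache = None

    # Out-of-prism handling during optimization: clamp the query into the
    # prism and add the clamping distance, a lower bound on the true distance
    # that grows smoothly and pushes the optimizer back inside.  The final
    # classification re-evaluates strictly (out of prism => infeasible).
    def _eval(self, t: np.ndarray):
        if self._cache_t is not None and np.array_equal(t, self._cache_t):
            return self._cache
        sp, R = self.sp, self.R
        fld = sp.head_patch_field
        q = (sp.glenoid_vertices - t) @ R
        qc = np.clip(q, fld.origin, fld.upper)
        excess = q - qc
        d, g = fld.query_with_gradient(qc)
        pen = np.linalg.norm(excess, axis=1)
        out = pen > 0
        d = d + pen
        # gradient of distance wrt humerus-frame query point
        g = g.copy()
        if out.any():
            g[out] = excess[out] / pen[out, None]
        prox = d.mean()
        # d prox / d t = mean over vertices of d d/d q * d q/d t,  q = R^T (p - t)
        grad_prox = -(R @ g.mean(axis=0))

        # clearance 1: humerus proxy vertices inside scapula signed field
        hp = sp.humerus_proxy @ R.T + t
        hpc = np.clip(hp, sp.scapula_field.origin, sp.scapula_field.upper)
        d1, g1 = sp.scapula_field.query_with_gradient(hpc)
        j1 = int(np.argmin(d1))
        c1, gc1 = float(d1[j1]), g1[j1]

        # clearance 2: scapula proxy vertices inside humerus signed field
        spv = (sp.scapula_proxy - t) @ R
        spc = np.clip(spv, sp.humerus_field.origin, sp.humerus_field.upper)
        d2, g2 = sp.humerus_field.query_with_gradient(spc)
        j2 = int(np.argmin(d2))
        c2, gc2 = float(d2[j2]), -(R @ g2[j2])

        self._cache_t = t.copy()
        self._cache = (float(prox), grad_prox, c1, gc1, c2, gc2)
        return self._cache

    def coarse_screen(self, target: float):
        """Vectorized mean proximity on a coarse translation grid.

        Returns (best feasible translation, its |mean - target|), or
        (None, inf) when no grid translation is clearance-feasible.  Serves
        both as a deterministic initial guess and as a cheap certificate
        that a pose is far from feasibility.
        """
        sp, R = self.sp, self.R
        g = target
        offs = np.array([-1.5, -0.75, 0.0, 0.75, 1.5]) * g
        T = sp.neutral_translation + np.stack(
            np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        fld = sp.head_patch_field
        q = (sp.glenoid_vertices[None, :, :] - T[:, None, :]) @ R
        flat = q.reshape(-1, 3)
        inside = fld.contains(flat).reshape(len(T), -1)
        d = np.full(flat.shape[0], np.inf)
        ok = fld.contains(flat)
        if ok.any():
            d[ok] = fld._trilinear(flat[ok])[0]
        mean = np.where(
            inside.all(axis=1), d.reshape(len(T), -1).mean(axis=1), np.inf
        )
        # clearance on the humerus-in-scapula side only (cheap pre-filter)
        hp = (sp.humerus_proxy @ R.T)[None, :, :] + T[:, None, :]
        hflat = hp.reshape(-1, 3)
        hclip = np.clip(hflat, sp.scapula_field.origin, sp.scapula_field.upper)
        c = sp.scapula_field._trilinear(hclip)[0].reshape(len(T), -1).min(axis=1)
        feas = (c >= 0) & np.isfinite(mean)
        if not feas.any():
            return None, float("inf")
        score = np.abs(mean - target)
        score[~feas] = np.inf
        j = int(np.argmin(score))
        return T[j], float(score[j])

    def proximity_strict(self, t: np.ndarray) -> float:
        return joint_proximity(self.sp.glenoid_vertices, self.sp.head_patch_field, self.R, t)

    def clearance_strict(self, t: np.ndarray) -> float:
        sp, R = self.sp, self.R
        hp = sp.humerus_proxy @ R.T + t
        hpc = np.clip(hp, sp.scapula_field.origin, sp.scapula_field.upper)
        c1 = sp.scapula_field.query(hpc).min()
        spv = (sp.scapula_proxy - t) @ R
        spc = np.clip(spv, sp.humerus_field.origin, sp.humerus_field.upper)
        c2 = sp.humerus_field.query(spc).min()
        return float(min(c1, c2))


def _projected_newton(
    prob: "_PoseProblem", target: float, t0: np.ndarray, cfg: "SolverConfig"
) -> tuple[np.ndarray, bool]:
    """Solve mean-proximity(t) = target subject to non-negative clearance.

    Each iteration takes a Newton step for the scalar proximity residual
    along the analytic gradient of the trilinear interpolant, then projects
    the step onto the boundary of any clearance constraint it would violate
    (first-order active-set correction).  Converges in a handful of
    iterations for articulating geometry; a pose where the residual stalls
    above tolerance is reported unconverged and classified by its final
    residual.
    """
    t = np.asarray(t0, dtype=float).copy()
    tol = max(1e-4, 1e-3 * target)  # mm
    max_step = 1.5 * target
    eps = 1e-12
    for _ in range(cfg.max_iter):
        prox, gp, c1, gc1, c2, gc2 = prob._eval(t)
        r = prox - target
        if abs(r) <= tol and c1 >= -cfg.clearance_tol and c2 >= -cfg.clearance_tol:
            return t, True
        step = -r * gp / max(gp @ gp, eps)
        # repair active violations, then project the step so it does not
        # (to first order) re-violate either clearance constraint
        for c, gc in ((c1, gc1), (c2, gc2)):
            if c < 0:
                step = step + (-c) * gc / max(gc @ gc, eps)
        for c, gc in ((c1, gc1), (c2, gc2)):
            pred = c + gc @ step
            if pred < 0:
                step = step + (-pred) * gc / max(gc @ gc, eps)
        norm = np.linalg.norm(step)
        if norm > max_step:
            step *= max_step / norm
        if norm < 1e-9:
            break
        t = t + step
    prox, _, c1, _, c2, _ = prob._eval(t)
    ok = abs(prox - target) <= tol and min(c1, c2) >= -cfg.clearance_tol
    return t, ok


def optimize_translation(
    pose: Pose,
    target_proximity: float,
    specimen: Specimen,
    config: SolverConfig | None = None,
    threshold: float = 0.05,
    initial_guess: np.ndarray | None = None,
) -> OptimizedPose:
    """Optimize the 3D humeral translation at a fixed rotational pose.

    Minimizes (joint proximity - target)^2 subject to non-negative signed
    clearance of each bone's vertices in the other bone's signed field.
    The pose is admissible when the relative residual is within ``threshold``
    and the clearance constraint holds at the optimum.
    """
    if target_proximity <= 0:
        raise ValueError("target_proximity must be positive")
    cfg = config or SolverConfig()
    R = pose_to_transform(pose)
    prob = _PoseProblem(specimen, R)
    if initial_guess is not None:
        t0 = np.asarray(initial_guess, dtype=float)
    else:
        # coarse screen: deterministic initial guess, and a cheap rejection
        # of poses whose best coarse placement is still far off target
        t_best, err = prob.coarse_screen(target_proximity)
        if t_best is None or err > cfg.screen_factor * target_proximity:
            t = specimen.neutral_translation if t_best is None else t_best
            prox = prob.proximity_strict(t)
            residual = (
                float("inf") if np.isinf(prox)
                else abs(prox - target_proximity) / target_proximity
            )
            return OptimizedPose(
                pose=pose, translation=np.asarray(t, dtype=float),
                achieved_proximity=prox, objective_residual=residual,
                admissible=False, solver_status="infeasible",
            )
        t0 = t_best

    t, solver_ok = _projected_newton(prob, target_proximity, t0, cfg)
    prox = prob.proximity_strict(t)
    clearance = prob.clearance_strict(t)
    if np.isinf(prox):
        residual = float("inf")
        status = "infeasible"
    else:
        residual = abs(prox - target_proximity) / target_proximity
        if clearance < -cfg.clearance_tol:
            status = "infeasible"
        elif solver_ok or residual <= threshold:
            status = "converged"
        else:
            status = "max_iter"
    admissible = status == "converged" and residual <= threshold
    return OptimizedPose(
        pose=pose,
        translation=t,
        achieved_proximity=prox,
        objective_residual=residual,
        admissible=admissible,
        solver_status=status,
    )


# ---------------------------------------------------------------------------
# Full simulation
# ---------------------------------------------------------------------------


def simulate_rom(
    specimen: Specimen,
    increment_deg: float = 5.0,
    threshold: float = 0.05,
    config: SolverConfig | None = None,
    progress: bool = False,
) -> ROMResult:
    """Run the translation optimization over the full inclusive pose grid.

    Deterministic for a fixed configuration: the initial guess at each pose
    is either the previous axial step's optimum at the same long-axis node
    (warm start) or the specimen's neutral head-centre placement.  At the
    abduction poles (0 and 180 degrees) only plane-of-elevation 0 is
    optimized; the other longitudes reuse its result, since they denote the
    same physical placement up to axial relabelling.
    """
    cfg = config or SolverConfig()
    inc = float(increment_deg)
    poses = sample_pose_grid(inc)
    n_poe = int(round(360 / inc)) + 1
    n_abd = int(round(180 / inc)) + 1
    n_ax = int(round(360 / inc)) + 1
    target = specimen.target_proximity
    results: list[OptimizedPose | None] = [None] * len(poses)

    def idx(i_poe, i_abd, i_ax):
        return (i_poe * n_abd + i_abd) * n_ax + i_ax

    zero_poe = (n_poe - 1) // 2  # index of plane_of_elevation = 0
    for i_poe in range(n_poe):
        for i_abd in range(n_abd):
            at_pole = i_abd in (0, n_abd - 1)
            if at_pole and i_poe != zero_poe:
                continue
            prev = None
            for i_ax in range(n_ax):
                pose = poses[idx(i_poe, i_abd, i_ax)]
                guess = prev if (cfg.warm_start and prev is not None) else None
                opt = optimize_translation(
                    pose, target, specimen, cfg, threshold, initial_guess=guess
                )
                if cfg.warm_start and not opt.admissible and guess is not None:
                    retry = optimize_translation(pose, target, specimen, cfg, threshold)
                    if retry.objective_residual < opt.objective_residual:
                        opt = retry
                results[idx(i_poe, i_abd, i_ax)] = opt
                prev = opt.translation if opt.solver_status == "converged" else None
        if progress:
            logger.info("simulate_rom %s: poe row %d/%d", specimen.specimen_id, i_poe + 1, n_poe)
    # propagate pole results to the redundant longitudes
    for i_abd in (0, n_abd - 1):
        for i_poe in range(n_poe):
            if i_poe == zero_poe:
                continue
            for i_ax in range(n_ax):
                src = results[idx(zero_poe, i_abd, i_ax)]
                pose = poses[idx(i_poe, i_abd, i_ax)]
                results[idx(i_poe, i_abd, i_ax)] = replace(src, pose=pose)
    rom = ROMResult(
        specimen_id=specimen.specimen_id,
        target_proximity=target,
        threshold=threshold,
        increment=inc,
        poses=results,
    )
    logger.info(
        "simulate_rom %s: %d/%d admissible at threshold %.0f%%",
        specimen.specimen_id, rom.n_admissible, len(poses), 100 * threshold,
    )
    return rom


def sweep_parameters(
    specimen: Specimen,
    thresholds=(0.02, 0.05, 0.08),
    target_scales=(1.0,),
    alpha_radii=(5.0,),
    increment_deg: float = 15.0,
    config: SolverConfig | None = None,
) -> pd.DataFrame:
    """Sensitivity sweep over threshold, target scaling and alpha radius.

    One simulation is run per target scale (thresholds reuse its stored
    residuals, alpha radii reuse its admissible cloud), which makes the
    sweep deterministic and cheap.  Returns one row per combination with the
    admissible count and all ROM metrics.
    """
    from . import rom_metrics

    thresholds = list(thresholds)
    target_scales = list(target_scales)
    alpha_radii = list(alpha_radii)
    if not thresholds or not target_scales or not alpha_radii:
        raise ValueError("parameter grid must be non-empty")
    rows = []
    for scale in target_scales:
        sp = replace(specimen, target_proximity=specimen.target_proximity * scale)
        rom = simulate_rom(sp, increment_deg=increment_deg, config=config,
                           threshold=max(thresholds))
        for thr in thresholds:
            admissible = [
                p for p in rom.poses
                if p.solver_status == "converged" and p.objective_residual <= thr
            ]
            for alpha in alpha_radii:
                metrics = rom_metrics.compute_metrics(
                    admissible, increment_deg=increment_deg, alpha_radius=alpha
                )
                rows.append(
                    {
                        "threshold": thr,
                        "target_scale": scale,
                        "alpha_radius": alpha,
                        "n_admissible": len(admissible),
                        "mobility": metrics.mobility,
                        "fc_poe": metrics.functional_centre[0],
                        "fc_abduction": metrics.fc_abduction,
                        "circumduction_envelope": metrics.circumduction_envelope,
                    }
                )
    return pd.DataFrame(rows)
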