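"""Parametric synthetic shoulder joints for offline pipeline testing.

Both bones are built as star-shaped radial surfaces over subdivided-icosphere
directions, which makes them watertight and consistently oriented by
construction:

* the humerus is a sphere of ``head_radius`` whose superior sector can be
  flattened by a planar cut (``head_flattening``), with Gaussian
  tubercle-like protuberances added radially and a capped-cylinder shaft
  extending distally; the articular patch is the angular cap of directions
  within ``head_patch_angle`` of the superior pole;
* the scapula is a blade-like flattened ellipsoid with a concave spherical
  cap (the glenoid) carved into its lateral end; the cap's centre of
  curvature sits ``glenoid_radius_of_curvature`` lateral of the dish bottom
  and can be tilted cranially.

The construction fixes the anatomical relationship that drives every
planted effect: with the humeral head centre placed at the cap's centre of
curvature, each glenoid vertex lies exactly ``glenoid_radius_of_curvature -
head_radius`` from the head sphere, so the constructed anatomical joint
proximity equals ``spec.gap`` when the radii are chosen congruent.
Flattening the superior head sector removes achievable proximity at poses
whose long axis points at the centre of the admissible cone (reducing
mobility), while cranial tilt of the glenoid shifts the whole cone toward
higher abduction (raising the functional centre) — two geometrically
independent effects that cohorts can plant and the morphometrics should
recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh

from .anatomy_frames import AnatomicalFrame
from .mesh_fields import TriangleMesh

__all__ = ["JointSpec", "SyntheticJoint", "make_joint", "make_cohort", "ideal_joint_spec"]


@dataclass(frozen=True)
class JointSpec:
    """Parameters of one synthetic ball-and-socket joint (lengths in mm)."""

    head_radius: float = 20.0
    head_flattening: float = 0.0  # 0 = sphere; 1 = deepest supported cut
    tubercle_height: float = 0.0  # radial bump height, mm
    tubercle_azimuths: tuple = (0.0, 50.0)  # degrees about +y from +x
    glenoid_radius_of_curvature: float | None = None  # default: head_radius + gap
    glenoid_cap_angle: float = 42.0  # subtended half-angle, degrees
    glenoid_cranial_tilt: float = 0.0  # degrees, toward +y
    lip_depth: float = 0.0  # radial rim ridge on the socket, mm
    gap: float = 1.8  # constructed anatomical proximity, mm
    head_patch_angle: float = 140.0  # articular cap half-angle from +y, degrees
    shaft_length: float = 32.0  # 0 disables the shaft (ideal ball)
    shaft_radius: float = 9.0
    subdivisions: int = 4  # icosphere subdivision level
    landmark_noise: float = 0.0  # sd (mm) of seeded digitization jitter
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.head_flattening <= 1.0):
            raise ValueError("head_flattening must be in [0, 1]")
        if not (10.0 < self.glenoid_cap_angle < 120.0):
            raise ValueError("glenoid_cap_angle must be in (10, 120) degrees")
        for name in ("head_radius", "gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.curvature_radius < self.head_radius:
            raise ValueError("glenoid radius of curvature must be >= head radius")

    @property
    def curvature_radius(self) -> float:
        if self.glenoid_radius_of_curvature is not None:
            return self.glenoid_radius_of_curvature
        return self.head_radius + self.gap


@dataclass
class SyntheticJoint:
    """Geometry bundle: meshes in their anatomical frames, labels, landmarks.

    The scapula mesh lives in the scapular frame (glenoid dish bottom at the
    origin, +x lateral before tilt); the humerus mesh lives in the humeral
    frame (head-sphere centre at the origin, +y cranial).  In the as-built
    (anatomical) placement the head centre sits at ``neutral_translation``
    in scapular coordinates.
    """

    spec: JointSpec
    scapula: TriangleMesh  # labels: glenoid_face
    humerus: TriangleMesh  # labels: head_articular
    scapula_frame: AnatomicalFrame
    humerus_frame: AnatomicalFrame
    neutral_translation: np.ndarray
    glenoid_normal: np.ndarray  # outward cap axis in scapula frame
    scapula_landmarks: pd.DataFrame  # name, x, y, z, semilandmark
    humerus_landmarks: pd.DataFrame
    frame_inputs: dict = field(default_factory=dict)


def _unit_dirs(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return np.asarray(ico.vertices, dtype=float), np.asarray(ico.faces, dtype=np.int64)


def _sph_dir(polar_deg: float, azim_deg: float) -> np.ndarray:
    """Direction at ``polar_deg`` from +y, azimuth about +y measured from +x toward +z."""
    t, p = np.radians(polar_deg), np.radians(azim_deg)
    return np.array([np.sin(t) * np.cos(p), np.cos(t), np.sin(t) * np.sin(p)])


# ---------------------------------------------------------------------------
# Humerus
# ---------------------------------------------------------------------------

_FLATTEN_MAX = 0.8  # fraction of the radius removable by a full (f=1) cut


def _humerus_radial(spec: JointSpec, dirs: np.ndarray) -> np.ndarray:
    r = spec.head_radius
    rho = np.full(len(dirs), r)
    uy = dirs[:, 1]
    # planar cut of the superior sector: plane y = h, h = r (1 - 0.35 f)
    if spec.head_flattening > 0:
        h = r * (1.0 - _FLATTEN_MAX * spec.head_flattening)
        with np.errstate(divide="ignore"):
            cut = np.where(uy > h / r, h / np.maximum(uy, 1e-9), np.inf)
        rho = np.minimum(rho, cut)
    # tubercle bumps: Gaussian in angular distance from each tubercle direction
    if spec.tubercle_height > 0:
        sigma = np.radians(14.0)
        for az in spec.tubercle_azimuths:
            td = _sph_dir(110.0, az)
            ang = np.arccos(np.clip(dirs @ td, -1, 1))
            rho = rho + spec.tubercle_height * np.exp(-0.5 * (ang / sigma) ** 2)
    # capped-cylinder shaft along -y
    if spec.shaft_length > 0:
        cos_down = -uy
        sin_down = np.sqrt(np.clip(1 - cos_down**2, 0, 1))
        with np.errstate(divide="ignore"):
            end = np.where(cos_down > 0, (r + spec.shaft_length) / np.maximum(cos_down, 1e-9), np.inf)
            wall = np.where(sin_down > 0, spec.shaft_radius / np.maximum(sin_down, 1e-9), np.inf)
        shaft = np.minimum(end, wall)
        in_shaft = cos_down > 0.15
        rho = np.where(in_shaft, np.maximum(rho, shaft), rho)
    return rho


def _humerus_mesh(spec: JointSpec) -> TriangleMesh:
    dirs, faces = _unit_dirs(spec.subdivisions)
    rho = _humerus_radial(spec, dirs)
    verts = dirs * rho[:, None]
    # articular patch: angular cap about +y, excluding tubercle bumps
    polar = np.degrees(np.arccos(np.clip(dirs[:, 1], -1, 1)))
    on_patch_v = polar <= spec.head_patch_angle
    if spec.tubercle_height > 0:
        base = _humerus_radial(replace(spec, tubercle_height=0.0), dirs)
        on_patch_v &= (rho - base) < 0.05 * spec.tubercle_height + 1e-9
    patch_faces = np.flatnonzero(on_patch_v[faces].all(axis=1))
    return TriangleMesh(verts, faces, {"head_articular": patch_faces})


# ---------------------------------------------------------------------------
# Scapula
# ---------------------------------------------------------------------------


def _scapula_geometry(spec: JointSpec):
    """Ellipsoid blade parameters and the (possibly tilted) cap axis/centre."""
    r = spec.head_radius
    rc = spec.curvature_radius
    tilt = np.radians(spec.glenoid_cranial_tilt)
    normal = np.array([np.cos(tilt), np.sin(tilt), 0.0])  # outward cap axis
    centre = normal * rc  # centre of curvature == anatomical head centre
    sagitta = rc * (1.0 - np.cos(np.radians(spec.glenoid_cap_angle)))
    ax = np.array([1.15 * rc, 2.2 * r, 0.45 * r])  # ellipsoid semi-axes
    c0 = np.array([sagitta + 0.15 * r - ax[0], 0.0, 0.0])  # ellipsoid centre
    return normal, centre, sagitta, ax, c0


def _scapula_mesh(spec: JointSpec) -> TriangleMesh:
    dirs, faces = _unit_dirs(spec.subdivisions)
    normal, centre, sagitta, ax, c0 = _scapula_geometry(spec)
    # ray-ellipsoid radius from c0: |(c0 + s u - c0) / ax| = 1
    scale = dirs / ax
    rho = 1.0 / np.linalg.norm(scale, axis=1)
    # carve the spherical dish: ray c0 + s u against sphere(centre, rc),
    # keeping the near intersection wherever the sphere dips inside the blade
    rc = spec.curvature_radius
    oc = c0 - centre
    b = dirs @ oc
    cterm = oc @ oc - rc * rc
    disc = b * b - cterm
    hit = disc > 0
    s_near = np.full(len(dirs), np.inf)
    s_near[hit] = -b[hit] - np.sqrt(disc[hit])
    carve = hit & (s_near > 0) & (s_near < rho)
    rho = np.where(carve, s_near, rho)
    if spec.lip_depth > 0:
        # radial ridge just outside the cap rim
        pts = c0 + dirs * rho[:, None]
        ang = np.degrees(np.arccos(np.clip((pts - centre) @ (-normal) /
                                           np.linalg.norm(pts - centre, axis=1), -1, 1)))
        ridge = spec.lip_depth * np.exp(-0.5 * ((ang - spec.glenoid_cap_angle - 6.0) / 4.0) ** 2)
        rho = np.where(~carve, rho + ridge, rho)
    verts = c0 + dirs * rho[:, None]
    # glenoid face: carved vertices within the cap half-angle of the axis
    vc = verts - centre
    ang = np.degrees(np.arccos(np.clip(vc @ (-normal) / np.linalg.norm(vc, axis=1), -1, 1)))
    on_face_v = carve & (ang <= spec.glenoid_cap_angle)
    face_ids = np.flatnonzero(on_face_v[faces].all(axis=1))
    return TriangleMesh(verts, faces, {"glenoid_face": face_ids})


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------


def _scapula_landmarks(spec: JointSpec) -> pd.DataFrame:
    normal, centre, sagitta, ax, c0 = _scapula_geometry(spec)
    rc = spec.curvature_radius
    theta = np.radians(spec.glenoid_cap_angle)
    # orthonormal basis of the cap plane
    e1 = np.array([-normal[1], normal[0], 0.0])
    if np.linalg.norm(e1) < 1e-12:
        e1 = np.array([0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    rows = []
    for k in range(8):  # glenoid rim ring
        phi = np.radians(45.0 * k)
        d = -np.cos(theta) * normal + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2)
        rows.append((f"glenoid_rim_{k}", centre + rc * d))
    rows.append(("glenoid_deep", centre - rc * normal))
    rows.append(("supraglenoid", centre + rc * (-np.cos(theta * 0.7) * normal + np.sin(theta * 0.7) * e1)))

    def ellip(u):
        u = np.asarray(u, dtype=float)
        u = u / np.linalg.norm(u)
        return c0 + u / np.linalg.norm(u / ax)

    rows += [
        ("superior_angle", ellip([-1.0, 0.9, 0.0])),
        ("inferior_angle", ellip([-1.0, -0.9, 0.0])),
        ("border_sup_quarter", ellip([-1.0, 0.45, 0.0])),
        ("border_mid", ellip([-1.0, 0.0, 0.0])),
        ("border_inf_quarter", ellip([-1.0, -0.45, 0.0])),
        ("acromion", ellip([0.55, 1.0, 0.35])),
        ("coracoid", ellip([0.55, 0.8, -0.5])),
        ("spine_root", ellip([-0.3, 0.5, 1.0])),
        ("blade_dorsal", ellip([0.0, -0.4, 1.0])),
        ("blade_ventral", ellip([0.0, -0.4, -1.0])),
        ("lateral_border_mid", ellip([0.6, -0.8, 0.0])),
        ("scapula_notch", ellip([0.4, 1.0, -0.1])),
    ]
    df = pd.DataFrame(
        [{"name": n, "x": p[0], "y": p[1], "z": p[2], "semilandmark": False} for n, p in rows]
    )
    assert len(df) == 22
    return df


def _humerus_landmarks(spec: JointSpec) -> pd.DataFrame:
    dirs_named = []

    def surf(name, polar, azim, semi=False):
        u = _sph_dir(polar, azim)
        rho = _humerus_radial(spec, u[None, :])[0]
        dirs_named.append((name, u * rho, semi))

    surf("head_apex", 0.0, 0.0)
    for k in range(8):
        surf(f"articular_margin_{k}", spec.head_patch_angle, 45.0 * k)
    for k, az in enumerate(["lesser", "greater"]):
        surf(f"{az}_tubercle", 110.0, spec.tubercle_azimuths[k])
    surf("intertubercular_groove", 112.0,
         0.5 * (spec.tubercle_azimuths[0] + spec.tubercle_azimuths[1]))
    for k in range(4):
        surf(f"anatomical_neck_{k}", 125.0, 45.0 + 90.0 * k)
    for k in range(4):
        surf(f"mid_articular_{k}", 60.0, 45.0 + 90.0 * k)
    surf("shaft_distal_end", 179.0, 0.0)
    for k in range(4):
        surf(f"shaft_mid_{k}", 160.0, 90.0 * k, semi=True)
    df = pd.DataFrame(
        [{"name": n, "x": p[0], "y": p[1], "z": p[2], "semilandmark": s}
         for n, p, s in dirs_named]
    )
    assert len(df) == 25 and int(df.semilandmark.sum()) == 4
    return df


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def make_joint(spec: JointSpec) -> SyntheticJoint:
    """Build one synthetic specimen: meshes, labels, frames and landmarks.

    Deterministic for a given spec.  The anatomical placement puts the head
    centre at the glenoid cap's centre of curvature, so the constructed
    anatomical proximity equals ``curvature_radius - head_radius`` (the
    ``gap`` when the default congruent curvature radius is used).
    """
    humerus = _humerus_mesh(spec)
    scapula = _scapula_mesh(spec)
    normal, centre, _, ax, c0 = _scapula_geometry(spec)
    sc_lm = _scapula_landmarks(spec)
    hu_lm = _humerus_landmarks(spec)
    if spec.landmark_noise > 0:
        # digitization noise: landmarks are placed from the parametrization,
        # then perturbed by seeded jitter emulating manual landmarking error
        rng = np.random.default_rng(spec.seed)
        for lm in (sc_lm, hu_lm):
            lm[["x", "y", "z"]] += rng.normal(
                0.0, spec.landmark_noise, size=(len(lm), 3)
            )
    glen_centroid = scapula.label_vertices("glenoid_face").mean(axis=0)
    frame_inputs = {
        "medial_border_points": np.array(
            [
                sc_lm.loc[sc_lm.name == "inferior_angle", ["x", "y", "z"]].values[0],
                sc_lm.loc[sc_lm.name == "border_mid", ["x", "y", "z"]].values[0],
                sc_lm.loc[sc_lm.name == "superior_angle", ["x", "y", "z"]].values[0],
            ]
        ),
        "blade_points": sc_lm.loc[
            sc_lm.name.isin(
                ["superior_angle", "inferior_angle", "border_sup_quarter",
                 "border_mid", "border_inf_quarter", "lateral_border_mid"]
            ),
            ["x", "y", "z"],
        ].values,
        "glenoid_centroid": glen_centroid,
        "shaft_axis_points": np.array(
            [hu_lm.loc[hu_lm.name == "shaft_distal_end", ["x", "y", "z"]].values[0],
             np.zeros(3)]
        ),
        "lesser_tubercle_point": hu_lm.loc[
            hu_lm.name == "lesser_tubercle", ["x", "y", "z"]
        ].values[0],
    }
    return SyntheticJoint(
        spec=spec,
        scapula=scapula,
        humerus=humerus,
        scapula_frame=AnatomicalFrame.identity(),
        humerus_frame=AnatomicalFrame.identity(),
        neutral_translation=centre.copy(),
        glenoid_normal=normal.copy(),
        scapula_landmarks=sc_lm,
        humerus_landmarks=hu_lm,
        frame_inputs=frame_inputs,
    )


def ideal_joint_spec(**overrides) -> JointSpec:
    """An ideal ball-and-socket: full-sphere articular head, no shaft.

    Every rotation of a perfect sphere inside a shallow concentric cap is
    geometrically equivalent, so every pose of the grid should be admissible
    — the reference fixture for feasibility and threshold-sensitivity checks.
    """
    base = dict(
        head_radius=20.0,
        head_patch_angle=180.0,
        shaft_length=0.0,
        tubercle_height=0.0,
        head_flattening=0.0,
        glenoid_cap_angle=30.0,
        gap=1.8,
    )
    base.update(overrides)
    return JointSpec(**base)


def make_cohort(
    base_spec: JointSpec,
    planted_effects: dict,
    n: int,
    seed: int,
) -> tuple[list[JointSpec], pd.DataFrame]:
    """Generate a cohort of joint specs with planted across-cohort gradients.

    ``planted_effects`` maps JointSpec field names to ``{"range": (lo, hi),
    "noise": sd}``.  The first effect's gradient ascends with specimen index;
    subsequent effects are assigned in an interleaved balanced order so the
    gradients are mutually near-orthogonal (each tertile of one effect spans
    the full range of the others) — required for the planted effects to be
    statistically separable.  All randomness flows from ``seed``.

    Returns the spec list and a truth manifest recording every parameter.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    for key in planted_effects:
        if not hasattr(base_spec, key):
            raise ValueError(f"unknown JointSpec field {key!r}")
    rng = np.random.default_rng(seed)
    specs = []
    values: dict[str, np.ndarray] = {}
    for j, (key, eff) in enumerate(planted_effects.items()):
        lo, hi = eff["range"]
        grad = np.linspace(lo, hi, n)
        if j > 0:
            # crossed design: draw seeded permutations until this effect's
            # ranks are nearly orthogonal to the first effect's ascent and
            # every tertile of that ascent spans most of this effect's range
            idx = np.arange(n)
            blocks = np.array_split(idx, 3)
            perm = rng.permutation(n)
            for _ in range(2000):
                r = np.corrcoef(idx, perm)[0, 1]
                spans = [np.ptp(perm[b]) for b in blocks]
                if abs(r) < 0.05 and min(spans) >= 0.7 * (n - 1):
                    break
                perm = rng.permutation(n)
            grad = grad[perm]
        noise = eff.get("noise", 0.0)
        if noise:
            grad = grad + rng.normal(0.0, noise, size=n)
        if key == "head_flattening":
            grad = np.clip(grad, 0.0, 1.0)
        values[key] = grad
    rows = []
    for i in range(n):
        overrides = {k: float(v[i]) for k, v in values.items()}
        overrides["seed"] = int(seed + i)
        sp = replace(base_spec, **overrides)
        specs.append(sp)
        row = {"specimen": f"synth_{i:03d}"}
        row.update({f.name: getattr(sp, f.name) for f in sp.__dataclass_fields__.values()
                    if f.name != "tubercle_azimuths"})
        rows.append(row)
    return specs, pd.DataFrame(rows)
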