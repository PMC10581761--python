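"""End-to-end pipeline: frames -> fields -> simulation -> metrics.

``build_specimen`` assembles the simulator's inputs (distance fields,
glenoid vertex set, interpenetration proxies) from labelled meshes already
expressed in their anatomical frames; ``specimen_from_joint`` does the same
for a synthetic joint; ``run_pipeline`` drives a full run from a
:class:`~promorom.config.RunConfig` and writes the artifacts to disk.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import RunConfig
from .mesh_fields import TriangleMesh, build_distance_field, fit_sphere
from .rom_simulator import Specimen, simulate_rom
from .synthetic_fixtures import SyntheticJoint
from . import rom_metrics, scaling_law

logger = logging.getLogger(__name__)

__all__ = ["build_specimen", "specimen_from_joint", "run_pipeline", "simulate_cohort"]


def simulate_cohort(
    specs,
    increment_deg: float = 15.0,
    resolution: int = 40,
    alpha_radius: float = 15.0,
    radius_coeff: float = 0.3,
    glenoid_max_vertices: int = 80,
    proxy_vertices: int = 160,
    progress: bool = False,
):
    """Simulate a list of synthetic joint specs end to end.

    Returns (metrics DataFrame, list of SyntheticJoint).  Desk-scale
    defaults (40-per-axis fields, 15-degree increment, alpha radius scaled
    with the increment) keep an 18-specimen cohort tractable on one CPU
    while preserving the planted morphology -> ROM orderings.
    """
    import pandas as pd

    from .synthetic_fixtures import make_joint

    rows, joints = [], []
    for i, spec in enumerate(specs):
        joint = make_joint(spec)
        joints.append(joint)
        sp = specimen_from_joint(
            joint, resolution=resolution, specimen_id=f"synth_{i:03d}",
            glenoid_max_vertices=glenoid_max_vertices,
            proxy_vertices=proxy_vertices,
        )
        rom = simulate_rom(sp, increment_deg=increment_deg)
        m = rom_metrics.compute_metrics(
            rom.admissible_poses, increment_deg=increment_deg,
            alpha_radius=alpha_radius, radius_coeff=radius_coeff,
        )
        rows.append(
            {
                "specimen": f"synth_{i:03d}",
                "head_flattening": spec.head_flattening,
                "glenoid_cranial_tilt": spec.glenoid_cranial_tilt,
                "n_admissible": rom.n_admissible,
                "mobility": m.mobility,
                "fc_abduction": m.fc_abduction,
                "circumduction_envelope": m.circumduction_envelope,
            }
        )
        if progress:
            logger.info("cohort %d/%d done", i + 1, len(specs))
    return pd.DataFrame(rows), joints


def build_specimen(
    specimen_id: str,
    scapula: TriangleMesh,
    humerus: TriangleMesh,
    neutral_translation: np.ndarray,
    target_proximity: float,
    resolution: int = 200,
    padding: float = 0.5,
    glenoid_max_vertices: int = 100,
    proxy_vertices: int = 200,
) -> Specimen:
    """Build simulator inputs from labelled meshes in anatomical frames.

    The scapula must carry a ``glenoid_face`` label and the humerus a
    ``head_articular`` label.  Three distance fields are constructed: a
    signed field per bone (interpenetration constraint) and an unsigned
    field of the articular patch (proximity objective).  The glenoid vertex
    set and the per-bone clearance proxies are deterministic subsamples.
    """
    if "glenoid_face" not in scapula.labels:
        raise ValueError("scapula mesh is missing the 'glenoid_face' label")
    if "head_articular" not in humerus.labels:
        raise ValueError("humerus mesh is missing the 'head_articular' label")
    glen = scapula.label_vertices("glenoid_face")
    if len(glen) > glenoid_max_vertices:
        idx = np.linspace(0, len(glen) - 1, glenoid_max_vertices).astype(int)
        glen = glen[idx]
    patch_field = build_distance_field(
        humerus, resolution, padding, signed=False,
        face_indices=humerus.labels["head_articular"],
    )
    scap_field = build_distance_field(scapula, resolution, padding, signed=True)
    hum_field = build_distance_field(humerus, resolution, padding, signed=True)
    sub = lambda v: v[np.linspace(0, len(v) - 1, min(len(v), proxy_vertices)).astype(int)]
    return Specimen(
        specimen_id=specimen_id,
        scapula=scapula,
        humerus=humerus,
        glenoid_vertices=glen,
        head_patch_field=patch_field,
        scapula_field=scap_field,
        humerus_field=hum_field,
        target_proximity=float(target_proximity),
        neutral_translation=np.asarray(neutral_translation, dtype=float),
        humerus_proxy=sub(humerus.vertices),
        scapula_proxy=sub(scapula.vertices),
    )


def specimen_from_joint(
    joint: SyntheticJoint,
    resolution: int = 64,
    padding: float = 0.5,
    target_proximity: float | None = None,
    specimen_id: str = "synthetic",
    **kwargs,
) -> Specimen:
    """Simulator inputs for a synthetic joint (target defaults to its gap)."""
    target = joint.spec.gap if target_proximity is None else target_proximity
    sp = build_specimen(
        specimen_id,
        joint.scapula,
        joint.humerus,
        joint.neutral_translation,
        target,
        resolution=resolution,
        padding=padding,
        **kwargs,
    )
    sp.meta["joint_spec"] = joint.spec
    return sp


def run_pipeline(
    config: RunConfig,
    scapula: TriangleMesh,
    humerus: TriangleMesh,
    neutral_translation,
    specimen_id: str = "specimen",
    law: scaling_law.ScalingLaw | None = None,
):
    """Frames -> fields -> simulate -> metrics; artifacts under config.out_dir.

    Returns (ROMResult, ROMMetrics).  Every artifact carries the config
    hash; any stage failure propagates with the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.target_mode == "scaling-law":
        if law is None:
            raise ValueError("stage target: scaling-law mode requires a fitted law")
        radius = fit_sphere(humerus.label_vertices("head_articular")).radius
        target = scaling_law.predict_target(law, radius)
    else:
        if config.target_proximity is None:
            raise ValueError("stage target: explicit mode requires target_proximity")
        target = config.target_proximity
    try:
        sp = build_specimen(
            specimen_id, scapula, humerus, neutral_translation, target,
            resolution=config.resolution, padding=config.padding,
        )
    except Exception as exc:
        raise RuntimeError(f"stage fields failed: {exc}") from exc
    try:
        rom = simulate_rom(sp, increment_deg=config.increment, threshold=config.threshold)
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc
    try:
        metrics = rom_metrics.compute_metrics(
            rom.admissible_poses,
            increment_deg=config.increment,
            alpha_radius=config.alpha_radius,
            radius_coeff=config.radius_coeff,
        )
    except Exception as exc:
        raise RuntimeError(f"stage metrics failed: {exc}") from exc
    tag = config.config_hash()
    rom.to_frame().to_csv(out / f"{specimen_id}_rom.csv", index=False)
    config.dump_sidecar(out / f"{specimen_id}_config.json")
    with open(out / f"{specimen_id}_metrics.json", "w") as fh:
        json.dump(
            {
                "config_hash": tag,
                "specimen": specimen_id,
                "target_proximity_mm": target,
                "n_admissible": metrics.n_admissible,
                "mobility": metrics.mobility,
                "fc_poe": metrics.functional_centre[0],
                "fc_abduction": metrics.fc_abduction,
                "circumduction_envelope": metrics.circumduction_envelope,
                "alpha_radius": metrics.alpha_radius,
                "radius_coeff": metrics.radius_coeff,
            },
            fh,
            indent=1,
        )
    logger.info("pipeline %s complete: %d admissible poses", specimen_id, metrics.n_admissible)
    return rom, metrics
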