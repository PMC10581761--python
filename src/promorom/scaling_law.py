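"""Joint-proximity scaling law.

Bone meshes segmented from CT exclude cartilage, so the anatomical gap
between the glenoid and the humeral head — the *joint proximity* measured
with the bones in their as-scanned pose — stands in for summed cartilage
thickness plus synovial space.  Across species this gap scales with joint
size; regressing measured proximity on the radius of a sphere fit to the
humeral head articular surface gives a law that predicts a target proximity
for any specimen from its own geometry, with no body-mass data needed.

The library never ships fitted anatomical coefficients: the law is fit from
user-supplied (head radius, proximity) pairs, or a clearly-labelled
synthetic default is used for fixtures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .rom_simulator import Specimen, joint_proximity

__all__ = [
    "ScalingLaw",
    "anatomical_proximity",
    "fit_scaling_law",
    "predict_target",
    "synthetic_default_law",
]


@dataclass
class ScalingLaw:
    slope: float  # mm proximity per mm head radius
    intercept: float  # mm
    r_squared: float
    p_value: float
    n: int
    radius_range: tuple[float, float]  # training range, mm

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "r_squared": self.r_squared,
                    "p_value": self.p_value,
                    "n": self.n,
                    "radius_range": list(self.radius_range),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ScalingLaw":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["slope"], d["intercept"], d["r_squared"], d["p_value"], d["n"],
            tuple(d["radius_range"]),
        )


def anatomical_proximity(specimen: Specimen, per_vertex: bool = False):
    """Joint proximity of a specimen in its as-scanned (identity) placement.

    The specimen's stored ``neutral_translation`` is the as-scanned relative
    placement of the humerus in scapular coordinates; the computation is the
    simulator's proximity at that placement with the identity rotation.
    With ``per_vertex=True``, also returns the per-glenoid-vertex distance
    table used for heat-map rendering.
    """
    R = np.eye(3)
    t = specimen.neutral_translation
    mean_d = joint_proximity(specimen.glenoid_vertices, specimen.head_patch_field, R, t)
    if not per_vertex:
        return mean_d
    q = (specimen.glenoid_vertices - t) @ R
    d = specimen.head_patch_field.query(q, out_of_bounds="nan")
    table = pd.DataFrame(
        {
            "x_mm": specimen.glenoid_vertices[:, 0],
            "y_mm": specimen.glenoid_vertices[:, 1],
            "z_mm": specimen.glenoid_vertices[:, 2],
            "distance_mm": d,
        }
    )
    return mean_d, table


def fit_scaling_law(head_radii_mm, proximities_mm, weights=None) -> ScalingLaw:
    """OLS of joint proximity on humeral head radius with a slope F-test.

    ``weights`` optionally down-weights over-represented groups (so one
    heavily-sampled species does not dominate the cross-species trend).
    """
    r = np.asarray(head_radii_mm, dtype=float)
    y = np.asarray(proximities_mm, dtype=float)
    if r.shape != y.shape or r.ndim != 1:
        raise ValueError("radii and proximities must be 1D and paired")
    if len(r) < 3:
        raise ValueError("need at least 3 specimens")
    if (r <= 0).any():
        raise ValueError("head radii must be strictly positive")
    if np.ptp(r) == 0:
        raise ValueError("zero variance in head radius")
    X = sm.add_constant(r)
    model = (sm.WLS(y, X, weights=np.asarray(weights, dtype=float))
             if weights is not None else sm.OLS(y, X)).fit()
    p_value = float(model.f_pvalue) if np.isfinite(model.f_pvalue) else 1.0
    rsq = float(model.rsquared)
    if not np.isfinite(rsq):
        rsq = 0.0  # zero proximity variance: a flat, uninformative law
    return ScalingLaw(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=rsq,
        p_value=p_value,
        n=int(len(r)),
        radius_range=(float(r.min()), float(r.max())),
    )


def predict_target(law: ScalingLaw, head_radius_mm: float) -> float:
    """Target proximity for a specimen from its head radius (mm).

    Warns when extrapolating beyond the training radius range; errors if the
    prediction is non-positive (a proximity target must be a distance).
    """
    if head_radius_mm <= 0:
        raise ValueError("head radius must be positive")
    lo, hi = law.radius_range
    if not (lo <= head_radius_mm <= hi):
        warnings.warn(
            f"head radius {head_radius_mm:.2f} mm outside training range "
            f"[{lo:.2f}, {hi:.2f}] mm: extrapolating"
        )
    pred = law.slope * head_radius_mm + law.intercept
    if pred <= 0:
        raise ValueError(f"scaling law predicts non-positive proximity ({pred:.3f} mm)")
    return float(pred)


def synthetic_default_law() -> ScalingLaw:
    """A synthetic, non-anatomical law for fixtures: proximity = 0.08 r + 0.2.

    The coefficients are chosen only to give fixture-scale joints plausible
    millimetre gaps; they are not estimates of any measured regression.
    """
    return ScalingLaw(
        slope=0.08, intercept=0.2, r_squared=1.0, p_value=0.0, n=0,
        radius_range=(5.0, 50.0),
    )
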