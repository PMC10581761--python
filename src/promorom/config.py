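"""Run configuration shared by the CLI and the pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass


@dataclass
class RunConfig:
    """Simulation parameters with their standard defaults.

    increment 5 degrees, 5% proximity threshold, 200 grid points per field
    axis with 50% bounding-box padding, alpha radius 5 map degrees — the
    reference configuration of the method; tests use smaller grids.
    """

    increment: float = 5.0
    threshold: float = 0.05
    resolution: int = 200
    padding: float = 0.5
    alpha_radius: float = 5.0
    radius_coeff: float = 0.3
    target_mode: str = "explicit"  # "explicit" | "scaling-law"
    target_proximity: float | None = None
    seed: int = 0
    out_dir: str = "."

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the parameters that affect results (output paths excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def dump_sidecar(self, path) -> None:
        d = self.to_dict()
        d["config_hash"] = self.config_hash()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = str(path)
        if path.endswith(".toml"):
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path) as fh:
                data = json.load(fh)
        return cls(**data)
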