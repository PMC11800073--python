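"""Run configuration: one YAML document with per-stage blocks.

Every random stage takes an explicit seed derived from the top-level seed;
defaults equal the reference settings (thresholds 20-110 keV, loss weights
1000/1000/10, TV lambda 1.0 with 18 iterations, guided filter radius 5 with
eps 1e-8 and 1000 guiding applications, Adam 1e-4).
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


def _default(block: dict) -> field:
    return field(default_factory=lambda: dict(block))


@dataclass
class RunConfig:
    seed: int = 0
    phantom: dict = _default({
        "grid_size": 256, "voxel_size_mm": 0.11, "n_ellipsoids": 5,
        "sphere_radius_mm": 12.8,
    })
    spectrum: dict = _default({"incident_counts": 400_000.0})
    detector: dict = _default({
        "crosstalk_fraction": 0.1, "dead_time_s": 1.25e-10, "exposure_s": 1.0e-3,
        "pileup_mode": "analytic",
    })
    thresholds: list = field(default_factory=lambda: [float(t) for t in range(20, 111, 10)])
    network: dict = _default({"scale": "full", "patch_size": 16})
    training: dict = _default({
        "epochs": 40, "batch_size": 64, "critic_steps": 4, "lr": 1.0e-4,
        "beta1": 0.9, "beta2": 0.999, "n_patches": 1_841_400, "train_fraction": 0.95,
        "lambda_gp": 10.0, "lambda1": 1000.0, "lambda2": 1000.0, "lambda3": 10.0,
    })
    reconstruction: dict = _default({
        "method": "fbp", "filter": "ramp", "output_size": 256, "sart_iters": 200,
        "sart_relaxation": 0.25, "count_floor": 0.5,
    })
    denoise: dict = _default({
        "tv_lambda": 1.0, "tv_iters": 18, "tv_data_term": "L1",
        "gf_radius": 5, "gf_eps": 1.0e-8, "gf_guide_iters": 1000,
    })
    paths: dict = _default({})

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        return cls(**raw)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())
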