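"""Run configuration: every pipeline parameter in one serialisable object."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .synthetic import SimulationConfig, ConfigError

__all__ = ["RunConfig", "ConfigError"]

_STAGES = ("simulate", "features", "train", "predict", "kinetics",
           "amyloid", "stats")


@dataclass
class RunConfig:
    """Parameters for an end-to-end pipeline run.

    Houses the acquisition/analysis constants (GM thresholds 0.65 / 0.90
    for target and reference regions, 4 mm FWHM smoothing, 10 folds,
    1000 permutations) alongside the simulation config and stage toggles.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    gm_thresh: float = 0.65
    ref_gm_thresh: float = 0.90
    csf_cap: float = 0.95
    fwhm_mm: float = 4.0
    folds: int = 10
    n_perm: int = 1000
    run_permutation: bool = False
    theta3_n: int = 64
    theta3_lo_per_min: float = 0.006
    theta3_hi_per_min: float = 0.6
    sd_mode: str = "cohort"
    fixed_sd: float | None = None
    seed: int = 42
    stages: tuple[str, ...] = _STAGES

    def validate(self) -> None:
        for name in ("gm_thresh", "ref_gm_thresh", "csf_cap"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.theta3_n < 2 or self.theta3_lo_per_min <= 0 \
                or self.theta3_hi_per_min <= self.theta3_lo_per_min:
            raise ConfigError("theta3 grid must be ascending with >= 2 points")
        if self.sd_mode not in ("cohort", "iterative", "fixed"):
            raise ConfigError("sd_mode must be cohort, iterative or fixed")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        self.simulation.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            for tup in ("age_range_train", "age_range_test", "grid_dims",
                        "voxel_size_mm"):
                if tup in sim and sim[tup] is not None:
                    sim[tup] = tuple(sim[tup])
            sim = SimulationConfig(**sim)
        d["stages"] = tuple(d.get("stages", _STAGES))
        return cls(simulation=sim, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        """Stable short hash stamped onto every output."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
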