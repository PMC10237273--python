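"""Schema-validated experiment configuration (JSON).

A single :class:`ExperimentConfig` drives the CLI: it names the protocol,
carries the plate geometry, subject and noise models, perturbation /
admittance specs and the protocol design, and requires a seed for any
stochastic protocol.  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .forceplate import PlateGeometry
from .impedance import PlatformDynamics
from .platform_model import AdmittanceSpec, PerturbationSpec
from .synth import ImpedanceTriple, NoiseModel, SubjectModel, SwayParams


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    a: float = 0.14
    b: float = 0.14
    c: float = 0.105
    d: float = 0.09
    inter_plate_distance_cm: float = 25.0

    def to_domain(self) -> PlateGeometry:
        return PlateGeometry(a=self.a, b=self.b, c=self.c, d=self.d)


class ImpedanceTripleConfig(_Strict):
    k: float
    b: float
    i: float

    def to_domain(self) -> ImpedanceTriple:
        return ImpedanceTriple(k=self.k, b=self.b, i=self.i)


class SwayConfig(_Strict):
    natural_freq_hz: float = 0.3
    damping_ratio: float = 0.7
    sd_ap_cm: float = 0.35
    sd_ml_cm: float = 0.25

    def to_domain(self) -> SwayParams:
        return SwayParams(**self.model_dump())


class SubjectConfig(_Strict):
    mass_kg: float = 70.0
    impedance: Optional[dict[str, dict[str, ImpedanceTripleConfig]]] = None
    sway: SwayConfig = Field(default_factory=SwayConfig)
    weight_sharing: float = 0.5
    placement_ap_bias_cm: float = 1.0
    placement_ap_jitter_cm: float = 0.8
    placement_ml_bias_cm: float = 0.0
    placement_ml_jitter_cm: float = 0.5

    def to_domain(self) -> SubjectModel:
        kwargs = dict(
            mass_kg=self.mass_kg,
            sway=self.sway.to_domain(),
            weight_sharing=self.weight_sharing,
            placement_ap_bias_cm=self.placement_ap_bias_cm,
            placement_ap_jitter_cm=self.placement_ap_jitter_cm,
            placement_ml_bias_cm=self.placement_ml_bias_cm,
            placement_ml_jitter_cm=self.placement_ml_jitter_cm,
        )
        if self.impedance is not None:
            kwargs["impedance"] = {
                side: {d: t.to_domain() for d, t in dirs.items()}
                for side, dirs in self.impedance.items()
            }
        return SubjectModel(**kwargs)


class NoiseConfig(_Strict):
    force_sd_n: float = 0.5
    angle_sd_deg: float = 0.01
    seed: int = 0

    def to_domain(self) -> NoiseModel:
        return NoiseModel(**self.model_dump())


class AdmittanceConfig(_Strict):
    k_sim: float
    b_sim: Optional[float] = None
    i_sim: float = 0.1

    def to_domain(self) -> AdmittanceSpec:
        return AdmittanceSpec(k_sim=self.k_sim, b_sim=self.b_sim, i_sim=self.i_sim)


class PerturbationConfig(_Strict):
    amplitude_deg: float = 3.0
    duration_s: float = 0.125
    direction: str = "DP"
    hold_s: float = 0.3

    def to_domain(self) -> PerturbationSpec:
        return PerturbationSpec(**self.model_dump())


class PlatformDynamicsConfig(_Strict):
    k_p: float = 0.3
    b_p: float = 0.05
    i_p: float = 0.4

    def to_domain(self) -> PlatformDynamics:
        return PlatformDynamics(k_p=self.k_p, b_p=self.b_p, i_p=self.i_p)


Protocol = Literal[
    "passive_balance",
    "active_balance",
    "standing_impedance",
    "walking_impedance",
    "validate",
]


class ExperimentConfig(_Strict):
    protocol: Protocol
    seed: Optional[int] = None
    fs: float = 2000.0
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    subject: SubjectConfig = Field(default_factory=SubjectConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    platform_dynamics: PlatformDynamicsConfig = Field(default_factory=PlatformDynamicsConfig)
    perturbation: PerturbationConfig = Field(default_factory=PerturbationConfig)
    # balance designs
    duration_s: float = 60.0
    stiffness_levels: list[float] = Field(default_factory=lambda: [10000.0, 500.0, 250.0])
    trials_per_level: int = 3
    amplitudes_deg: list[float] = Field(default_factory=lambda: [0.5, 1.0, 1.5])
    frequencies_hz: list[float] = Field(default_factory=lambda: [0.5, 1.0, 1.5])
    trials_per_cell: int = 3
    # impedance designs
    standing_trials_per_condition: int = 30
    walking_trials_per_condition: int = 80
    cadence_bpm: float = 100.0
    snr_db: Optional[float] = None

    @model_validator(mode="after")
    def _seed_required_for_stochastic(self):
        if self.protocol != "validate" and self.seed is None:
            raise ValueError(f"protocol {self.protocol!r} is stochastic; seed is required")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        return cls.model_validate_json(Path(path).read_text())
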