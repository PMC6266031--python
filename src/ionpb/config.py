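"""Run configuration: YAML-backed, schema-checked, no hidden state."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

_ALLOWED_IONS = ("proton", "carbon")
_ALLOWED_MODELS = ("rbe1.1", "lem", "mkm")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, resolved and loggable."""

    ion: str = "proton"
    model: str = "rbe1.1"
    seed: int = 0
    prescription: float = 2.0            # Gy (RBE)

    # synthetic database
    energies: list = field(default_factory=list)   # [] -> auto from target
    depth_step: float = 0.5                        # mm

    # phantom (water tank)
    phantom_size: list = field(default_factory=lambda: [100.0, 100.0, 200.0])
    ct_spacing: list = field(default_factory=lambda: [2.0, 2.0, 2.0])
    target_side: float = 30.0                      # mm
    target_depth: float = 120.0                    # mm, proximal face

    # plan / engine
    lateral_spacing: float = 4.0                   # mm spot lattice
    dose_spacing: list = field(default_factory=lambda: [2.0, 2.0, 2.0])
    n_splits: int = 1
    max_iter: int = 60
    tol: float = 0.005

    # tissue parameters
    alpha_x: float = 0.1
    beta_x: float = 0.05
    mkm_alpha0: float = 0.13
    mkm_beta0: float = 0.05

    def __post_init__(self):
        if self.ion not in _ALLOWED_IONS:
            raise ValidationError(f"ion must be one of {_ALLOWED_IONS}")
        if self.model not in _ALLOWED_MODELS:
            raise ValidationError(f"model must be one of {_ALLOWED_MODELS}")
        if self.ion == "proton" and self.model != "rbe1.1":
            raise ValidationError("proton runs use the fixed-RBE model")
        if self.prescription <= 0:
            raise ValidationError("prescription must be positive")
        if self.depth_step <= 0 or self.lateral_spacing <= 0:
            raise ValidationError("steps and spacings must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(obj, dict):
            raise ValidationError("config must be a YAML mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(obj) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
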