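"""Run configuration: one YAML-serializable object holding every
pipeline parameter, so a report can embed the exact settings it ran
with and a run can be reproduced from its config alone."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classification import ClassifierConfig
from .errors import InvalidConfigError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """End-to-end pipeline settings.

    Defaults follow the reference protocol: 70-volume windows sliding by
    one volume, all three network types, raw power spectra including the
    DC bin, the printed WLCC formula, a 0.1 simplex grid for kernel
    weights and a soft-margin SVM with C = 1.
    """

    window_length: int = 70
    window_step: int = 1
    static: bool = False
    types: list[str] = field(default_factory=lambda: ["low", "high", "associated"])
    symmetrize_associated: bool = True
    demean_edge_series: bool = False
    spectrum_kind: str = "power"  # or "amplitude"
    wlcc_variant: str = "as_printed"  # or "onnela"
    static_edge_transform: str = "abs"  # or "positive"
    tau_step: float = 0.1
    n_lambdas: int = 20
    lambda_min_ratio: float = 1e-3
    svm_c: float = 1.0
    standardize_features: bool = True
    normalize: str = "unit"
    tr_seconds: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.types:
            raise InvalidConfigError("at least one network type is required")
        unknown = set(self.types) - {"low", "high", "associated"}
        if unknown:
            raise InvalidConfigError(f"unknown network type(s): {sorted(unknown)}")

    def classifier(self) -> ClassifierConfig:
        return ClassifierConfig(
            tau_step=self.tau_step,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            svm_c=self.svm_c,
            standardize_features=self.standardize_features,
            normalize=self.normalize,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
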