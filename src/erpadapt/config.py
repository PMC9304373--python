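"""Run configuration with lossless YAML round-tripping.

All analysis constants default to the pipeline's canonical values (30-Hz
low-pass, +-150 µV marking, 12-channel rejection limit, 200 impedance
threshold, 20-epoch minimum for infants, group-specific component windows);
everything is overridable from a YAML or JSON file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .preprocessing import PreprocessingParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    group: str = "infant"
    profile: str = "validation"
    n_subjects: int | None = None  # None -> group default (49 infants, 21 adults)
    n_iterations: int = 4
    seed: int = 0
    # preprocessing
    cutoff_hz: float = 30.0
    amplitude_limit_uV: float = 150.0
    max_bad_channels: int = 12
    impedance_threshold: float = 200.0
    spline_m: int = 4
    spline_regularization: float = 1e-5
    window_ms: tuple[float, float] = (-100.0, 500.0)
    # extraction
    min_epochs: int | None = None  # None -> group default (20 infants, 0 adults)
    extraction_mode: str = "peak_then_average"
    # signal quality
    sme_score: str = "peak"
    sme_n_boot: int = 1000
    # output
    outdir: str = "erpadapt_out"

    def preprocessing_params(self) -> PreprocessingParams:
        return PreprocessingParams(
            cutoff_hz=self.cutoff_hz,
            window_ms=tuple(self.window_ms),
            impedance_threshold=self.impedance_threshold,
            amplitude_limit_uV=self.amplitude_limit_uV,
            max_bad_channels=self.max_bad_channels,
            spline_m=self.spline_m,
            spline_regularization=self.spline_regularization,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_ms"] = list(d["window_ms"])
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        if "window_ms" in d:
            d["window_ms"] = tuple(d["window_ms"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
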