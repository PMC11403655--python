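"""Pipeline configuration: defaults, YAML round-trip, seed expansion.

Precedence is CLI flags > config file > defaults; every run serializes the
resolved configuration next to its outputs so any analysis can be re-run
bit-identically.  All randomness flows from one root seed, expanded into
independent per-stage seeds, so stages can also be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .occupancy import AbandonmentCriteria
from .synthetic import GeneratorConfig
from .wham import AnalysisOptions

__all__ = ["PipelineConfig", "SurfaceSpec", "stage_seed"]

_STAGE_OFFSETS = {"simulate": 0, "bootstrap": 1, "traces": 2}


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic independent seed for a named pipeline stage."""
    if stage not in _STAGE_OFFSETS:
        raise ValueError(f"unknown stage {stage!r}")
    seq = np.random.SeedSequence([int(root_seed), _STAGE_OFFSETS[stage]])
    return int(seq.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class SurfaceSpec:
    """Parameters of the synthetic dimer surface used by `simulate`."""

    depth_contact: float = -32.0
    xi_contact: float = 0.5
    depth_solventsep: float = -4.0
    xi_solventsep: float = 1.2
    barrier: float = -1.0
    plateau_onset: float = 2.5
    support: tuple[float, float] = (0.3, 4.3)
    kind: str = "radial"


@dataclass(frozen=True)
class PipelineConfig:
    temperature: float = 310.0
    bin_width: float = 0.01
    burn_in_fraction: float = 0.1
    tol: float = 1e-5
    max_iter: int = 100_000
    plateau_region: tuple[float, float] = (3.0, 4.0)
    apply_correction: bool = True
    n_boot: int = 200
    bootstrap_unit: str = "window"
    seed: int = 0
    min_prominence: float = 1.0
    abandoned_fraction: float = 0.2
    trace_samples: int = 1000
    trace_dt_ps: float = 10.0
    surface: SurfaceSpec = field(default_factory=SurfaceSpec)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    occupancy: AbandonmentCriteria = field(default_factory=AbandonmentCriteria)

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.bootstrap_unit not in ("window", "point"):
            raise ValueError("bootstrap_unit must be 'window' or 'point'")
        lo, hi = self.plateau_region
        if not lo < hi:
            raise ValueError("plateau_region must satisfy lo < hi")

    def analysis_options(self) -> AnalysisOptions:
        return AnalysisOptions(
            temperature=self.temperature,
            bin_width=self.bin_width,
            burn_in_fraction=self.burn_in_fraction,
            tol=self.tol,
            max_iter=self.max_iter,
            apply_correction=self.apply_correction,
            plateau_region=tuple(self.plateau_region),
        )

    def generator_config(self) -> GeneratorConfig:
        """Generator settings with the simulate-stage seed injected."""
        return replace(
            self.generator,
            temperature=self.temperature,
            seed=stage_seed(self.seed, "simulate"),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_to_plain(asdict(self)), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs = {}
        if "surface" in raw:
            sub = dict(raw.pop("surface"))
            if "support" in sub:
                sub["support"] = tuple(sub["support"])
            kwargs["surface"] = SurfaceSpec(**sub)
        if "generator" in raw:
            kwargs["generator"] = GeneratorConfig(**raw.pop("generator"))
        if "occupancy" in raw:
            kwargs["occupancy"] = AbandonmentCriteria(**raw.pop("occupancy"))
        if "plateau_region" in raw:
            raw["plateau_region"] = tuple(raw["plateau_region"])
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw, **kwargs)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
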