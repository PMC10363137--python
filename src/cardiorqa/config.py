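"""Pipeline configuration: YAML round-trip, defaults, hashing.

A :class:`PipelineConfig` collects every tunable of the pipeline in nested
sections mirroring the computation stages.  All fields have defaults, so an
empty file (or ``PipelineConfig()``) is a complete, runnable configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


@dataclass
class SimSection:
    scenario: int = 2                       # 1 = paced sheet, 2 = scarred sheet
    arrhythmia_class: str = "anchored_rotor"   # scenario 2 only
    size_cm: float | None = None            # None = scenario default
    dx_mm: float | None = None
    dt_ms: float | None = None
    pacing_period_ms: float = 31.0           # scenario 1
    total_ms: float | None = None
    transient_ms: float | None = None


@dataclass
class EmbeddingSection:
    mode: str = "cao"          # "cao" (estimate per site) or "none" (m=1)
    m_max: int = 10
    tol: float = 0.05
    scope: str = "site"        # parameters estimated per "site"


@dataclass
class RQASection:
    eps_fraction: float = 0.03
    lmin: int = 2
    vmin: int = 2


@dataclass
class ComplexitySection:
    m_ent: int = 2
    r_frac: float = 0.2
    band_hz: tuple[float, float] = (0.5, 40.0)
    peak_halfwidth_hz: float = 1.0


@dataclass
class SpatialSection:
    stride_per_axis: int = 10
    min_trace_range: float = 0.1
    moran_on_smoothed: bool = False
    measures: tuple[str, ...] = ("REC", "DET", "RATIO", "Lmax", "Lmean",
                                 "DIV", "ENTR", "LAM", "Vmax", "Vmean",
                                 "OI1", "OI2", "eigen1", "eigen2",
                                 "ApEnt", "SampEnt")


@dataclass
class DetectionSection:
    thr_lmax: float = 800.0
    thr_lmean: float = 15.0


@dataclass
class PipelineConfig:
    sim: SimSection = field(default_factory=SimSection)
    embedding: EmbeddingSection = field(default_factory=EmbeddingSection)
    rqa: RQASection = field(default_factory=RQASection)
    complexity: ComplexitySection = field(default_factory=ComplexitySection)
    spatial: SpatialSection = field(default_factory=SpatialSection)
    detection: DetectionSection = field(default_factory=DetectionSection)
    seed: int = 0
    out_dir: str = "cardiorqa_out"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        sections = {
            "sim": SimSection, "embedding": EmbeddingSection,
            "rqa": RQASection, "complexity": ComplexitySection,
            "spatial": SpatialSection, "detection": DetectionSection,
        }
        kwargs = {}
        for name, typ in sections.items():
            sub = dict(d.pop(name, {}) or {})
            known = {f.name for f in dataclasses.fields(typ)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown keys in section {name}: "
                                 f"{sorted(unknown)}")
            for fld in dataclasses.fields(typ):
                if isinstance(fld.default, tuple) and fld.name in sub \
                        and isinstance(sub[fld.name], list):
                    sub[fld.name] = tuple(sub[fld.name])
            kwargs[name] = typ(**sub)
        for key in ("seed", "out_dir"):
            if key in d:
                kwargs[key] = d.pop(key)
        if d:
            raise ValueError(f"unknown top-level config keys: {sorted(d)}")
        return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    with open(path) as f:
        return PipelineConfig.from_dict(yaml.safe_load(f) or {})


def save_config(path, config: PipelineConfig) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=True)


def config_hash(config: PipelineConfig) -> str:
    canon = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
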