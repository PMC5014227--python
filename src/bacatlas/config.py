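"""Pipeline configuration: nested dataclasses, YAML round-trip, strict keys.

Unknown keys anywhere in a config file are rejected (typos should fail
loudly, not silently fall back to defaults).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .annotation import AnnotationConfig
from .arm_classifier import ClassifierConfig
from .errors import ConfigurationError
from .landscape import LandscapeConfig
from .synthetic import GenomeSpec


@dataclass
class LibraryConfig:
    n_clones: int = 500
    insert_mean: int = 100_000
    insert_sd: int = 10_000
    node_split: float = 19.7


@dataclass
class ScreeningConfig:
    n_pools: int = 30
    detect_prob: float = 0.6
    fp_rate: float = 0.001


@dataclass
class SaturationConfig:
    n_permutations: int = 10_000
    model: str = "negexp"


@dataclass
class SyntenyConfig:
    noise: float = 0.5           # mean off-target hits per clone
    evalue_cutoff: float = 1e-20
    inversion_window: int = 10
    inversion_min_run: int = 2


@dataclass
class StatsConfig:
    min_node_len: int = 200
    min_match: int = 100
    discordance_threshold: float = 33.0


@dataclass
class InputsConfig:
    """Externally provided stage inputs; a set path skips the producing stage."""

    bacs_fasta: str | None = None
    targets_fasta: str | None = None
    hits_tsv: str | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "bacatlas_out"
    log_level: str = "INFO"
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    library: LibraryConfig = field(default_factory=LibraryConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    saturation: SaturationConfig = field(default_factory=SaturationConfig)
    synteny: SyntenyConfig = field(default_factory=SyntenyConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    inputs: InputsConfig = field(default_factory=InputsConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genome"] = self.genome.to_dict()
        return d

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data, path="")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _build(dc_type, data, path: str):
    """Construct a dataclass from a dict, rejecting unknown keys recursively."""
    if not isinstance(data, dict):
        raise ConfigurationError(f"config section {path or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(dc_type)}
    unknown = set(data) - set(fields)
    if unknown:
        where = path or "<root>"
        raise ConfigurationError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        sub = _DATACLASS_FIELDS.get((dc_type, name))
        if sub is not None and value is not None:
            kwargs[name] = _build(sub, value, f"{path}.{name}".lstrip("."))
        else:
            if dc_type is GenomeSpec and name == "interior_islands" and value:
                value = [tuple(v) for v in value]
            if dc_type is GenomeSpec and name == "repeat_families" and value:
                value = tuple(value)
            kwargs[name] = value
    return dc_type(**kwargs)


_DATACLASS_FIELDS = {
    (PipelineConfig, "genome"): GenomeSpec,
    (PipelineConfig, "library"): LibraryConfig,
    (PipelineConfig, "screening"): ScreeningConfig,
    (PipelineConfig, "classifier"): ClassifierConfig,
    (PipelineConfig, "annotation"): AnnotationConfig,
    (PipelineConfig, "landscape"): LandscapeConfig,
    (PipelineConfig, "saturation"): SaturationConfig,
    (PipelineConfig, "synteny"): SyntenyConfig,
    (PipelineConfig, "stats"): StatsConfig,
    (PipelineConfig, "inputs"): InputsConfig,
}
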