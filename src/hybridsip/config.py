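"""Run configuration: every tunable threshold of the pipeline, serializable.

All thresholds printed on the pipeline's decisions live here by name: the
LBD/HBD pooling cuts (1.699 / 1.719 g/ml), the vOTU length floor (10 kb),
the per-library detection filters (>=1x mean depth, >=75% breadth), the
significance levels, and the gradient-physics constants.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields, is_dataclass

import yaml

from .community import ScenarioConfig


@dataclass
class GradientSettings:
    intercept: float = 1.660  # g/ml
    gc_slope: float = 0.098  # g/ml per GC fraction
    label_shift: float = 0.036  # g/ml at 100 atom% 13C
    natural_13c: float = 0.011
    band_sigma: float = 0.003  # g/ml diffusion broadening
    replicate_jitter_sd: float = 0.0005  # g/ml inter-gradient variation
    n_fractions: int = 24
    span_low: float = 1.66
    span_high: float = 1.78
    lbd_max: float = 1.699  # g/ml
    hbd_min: float = 1.719  # g/ml


@dataclass
class SequencingSettings:
    depth: int = 50_000  # reads per library
    read_length: int = 150  # bp
    error_rate: float = 0.001  # per-base substitution probability


@dataclass
class RecoverySettings:
    min_depth: float = 5.0  # x-fold pooled LBD depth for recoverability
    min_contig_length: int = 5_000  # bp
    min_fragments: int = 2
    max_fragments: int = 8


@dataclass
class MappingSettings:
    k: int = 21


@dataclass
class VirusSettings:
    min_orf_aa: int = 100
    score_threshold: float = 80.0  # fixed by empirical null calibration
    min_votu_length: int = 10_000  # bp
    min_coverage: float = 1.0  # x-fold
    min_breadth: float = 0.75
    gc_tolerance: float = 0.05
    guild_gc: dict = field(default_factory=lambda: {"AOA": 0.38, "AOB": 0.53, "NOB": 0.60})


@dataclass
class StatsSettings:
    alpha: float = 0.05
    variance_alpha: float = 0.05
    bh_correct: bool = False
    one_sided: bool = False
    #: which libraries feed the between-soil contrast
    soil_diff_treatment: str = "12C"
    soil_diff_pool: str = "LBD"


@dataclass
class RunConfig:
    master_seed: int = 0
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    gradient: GradientSettings = field(default_factory=GradientSettings)
    sequencing: SequencingSettings = field(default_factory=SequencingSettings)
    recovery: RecoverySettings = field(default_factory=RecoverySettings)
    mapping: MappingSettings = field(default_factory=MappingSettings)
    virus: VirusSettings = field(default_factory=VirusSettings)
    stats: StatsSettings = field(default_factory=StatsSettings)
    persist_reads: bool = False  # write per-library FASTA in run directories

    def validate(self) -> None:
        g = self.gradient
        if g.lbd_max >= g.hbd_min:
            raise ValueError("LBD threshold must be below HBD threshold")
        for name, value in (
            ("band_sigma", g.band_sigma),
            ("min_depth", self.recovery.min_depth),
            ("min_contig_length", self.recovery.min_contig_length),
            ("min_votu_length", self.virus.min_votu_length),
            ("min_coverage", self.virus.min_coverage),
            ("min_breadth", self.virus.min_breadth),
            ("k", self.mapping.k),
            ("read_length", self.sequencing.read_length),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sequencing.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 < self.stats.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.mapping.k > self.sequencing.read_length:
            raise ValueError("k must not exceed read length")


def _to_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def _from_plain(cls, data):
    if not is_dataclass(cls):
        return data
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if is_dataclass(f.type) if isinstance(f.type, type) else False:
            value = _from_plain(f.type, value)
        else:
            ftype = _resolve_field_type(cls, f.name)
            if ftype is not None and is_dataclass(ftype) and isinstance(value, dict):
                value = _from_plain(ftype, value)
            elif isinstance(value, list):
                value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


_FIELD_TYPES = {
    "scenario": ScenarioConfig,
    "gradient": GradientSettings,
    "sequencing": SequencingSettings,
    "recovery": RecoverySettings,
    "mapping": MappingSettings,
    "virus": VirusSettings,
    "stats": StatsSettings,
}


def _resolve_field_type(cls, name):
    if cls is RunConfig:
        return _FIELD_TYPES.get(name)
    return None


def config_to_dict(config: RunConfig) -> dict:
    return _to_plain(config)


def config_from_dict(data: dict) -> RunConfig:
    return _from_plain(RunConfig, data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def config_hash(config: RunConfig) -> str:
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def derive_seed(master_seed: int, label: str) -> int:
    """Stage seed derived by stable hashing of the master seed and a label."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
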