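"""Pipeline configuration: typed, range-checked, strictly validated.

Unknown keys and duplicate keys are rejected outright — the thresholds here
(significance alpha, read-count and fraction cutoffs, minimum site type)
directly shape every downstream result, so silent misconfiguration is worse
than a hard failure.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .sites import SITE_TYPES


class DuplicateKeyError(ValueError):
    pass


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys."""


def _construct_mapping(loader: _StrictLoader, node: yaml.MappingNode, deep: bool = False):
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in seen:
            raise DuplicateKeyError(f"duplicate config key {key!r}")
        seen.add(key)
    return yaml.SafeLoader.construct_mapping(loader, node, deep)


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _construct_mapping
)


@dataclass
class PipelineConfig:
    """All paths, thresholds and seeds for a pipeline run.

    Threshold defaults follow the calling conventions used throughout:
    significance at adjusted P < 0.05, 5' isomiR support at > 100 reads and
    > 5% of the miRNA's reads, target sites counted from 7mer-A1 up.
    """

    # paths (any may stay None when the corresponding stage is not run)
    hairpin_fasta: str | None = None
    mature_fasta: str | None = None
    mature_coords: str | None = None
    reads: str | None = None
    utr_fasta: str | None = None
    de_table: str | None = None
    compendium_dir: str | None = None
    target_lists: dict = field(default_factory=dict)  # set id -> one-column TSV
    host_gene: str = "WWP2"
    # thresholds
    alpha: float = 0.05
    min_reads: int = 100
    min_fraction: float = 0.05
    fraction_denominator: str = "arm_total"
    min_site_type: str = "7mer-A1"
    landscape_step: int = 100
    random_set_size: int = 500
    # randomness and output
    rng_seed: int = 0
    out_dir: str = "isomirkit_out"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if not 0 <= self.min_fraction <= 1:
            raise ValueError(f"min_fraction must be in [0, 1], got {self.min_fraction}")
        if self.fraction_denominator not in ("arm_total", "canonical_only"):
            raise ValueError(f"bad fraction_denominator {self.fraction_denominator!r}")
        if self.min_site_type not in SITE_TYPES:
            raise ValueError(f"min_site_type must be one of {SITE_TYPES}")
        if self.landscape_step < 1:
            raise ValueError("landscape_step must be >= 1")
        if self.random_set_size < 1:
            raise ValueError("random_set_size must be >= 1")
        if int(self.rng_seed) != self.rng_seed or self.rng_seed < 0:
            raise ValueError("rng_seed must be a non-negative integer")

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.load(text, Loader=_StrictLoader) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
        return cls.from_mapping(raw)

    @classmethod
    def from_yaml_path(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def validate_config(raw_text: str) -> PipelineConfig:
    """Parse and validate raw config text, filling recorded defaults."""
    return PipelineConfig.from_yaml(raw_text)
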