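"""Pipeline configuration: validated parameters with study-design defaults.

Defaults mirror the mapping design the pipeline emulates: 30-plant bulks
sequenced at ~30x, a 1 Mb / 10 kb sliding-window scan, and 10,000-replicate
null confidence intervals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything a full simulate-and-map run needs.

    Coordinates are 1-based closed throughout; converted to BED only on
    output.
    """

    seed: int = 1
    # population & genome
    n_f2: int = 430
    n_chromosomes: int = 3
    chromosome_length: int = 30_000_000
    genetic_length_morgans: float = 1.2
    snps_per_chromosome: int = 1500
    causal_chromosome: str = "Chr2"
    causal_position: int | None = None  # None -> middle SNP of the chromosome
    # bulks & sequencing
    bulk_size: int = 30
    mean_depth: float = 30.0
    depth_model: str = "poisson"
    # SNP filters
    min_total_depth: int = 7
    min_index: float = 0.3
    # window scan
    window_size: int = 1_000_000
    step: int = 10_000
    # null CI
    ci_reps: int = 10_000
    confidence: float = 0.95
    min_consecutive: int = 3
    # fine mapping: marker offsets (in SNP-grid steps) around the causal SNP
    marker_offsets: tuple[int, ...] = (-25, -12, -5, -2, 0, 2, 5, 12, 25)
    # candidate-gene fixture
    cds_length: int = 1200
    deletion_start: int = 502
    deletion_length: int = 13
    target_truncated_aa: int = 173
    # outputs
    outdir: str = "bsamap_run"

    def validate(self) -> None:
        checks = [
            (self.seed >= 0, "seed must be >= 0"),
            (self.n_f2 >= 1, "n_f2 must be >= 1"),
            (self.n_chromosomes >= 1, "n_chromosomes must be >= 1"),
            (self.chromosome_length >= 1, "chromosome_length must be >= 1"),
            (self.genetic_length_morgans >= 0, "genetic length must be >= 0"),
            (self.snps_per_chromosome >= 2, "need at least two SNPs per chromosome"),
            (self.bulk_size >= 1, "bulk_size must be >= 1"),
            (self.mean_depth > 0, "mean_depth must be > 0"),
            (self.depth_model in ("poisson", "fixed"), "depth_model must be poisson|fixed"),
            (self.min_total_depth >= 0, "min_total_depth must be >= 0"),
            (self.min_index >= 0, "min_index must be >= 0"),
            (self.window_size >= self.step > 0, "need window_size >= step > 0"),
            (self.ci_reps >= 100, "ci_reps must be >= 100"),
            (0 < self.confidence < 1, "confidence must be in (0, 1)"),
            (self.min_consecutive >= 1, "min_consecutive must be >= 1"),
            (self.cds_length % 3 == 0, "cds_length must be divisible by 3"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigurationError(message)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["marker_offsets"] = list(self.marker_offsets)
        return d

    @property
    def hash(self) -> str:
        """Short digest of the analysis parameters (output path excluded),
        embedded in every output file for provenance."""
        params = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "marker_offsets" in raw:
            raw["marker_offsets"] = tuple(raw["marker_offsets"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return Path(path)
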