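"""Run configuration: every pipeline threshold with its survey default, YAML
round-trip and a semantic content hash for reproducibility headers."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    minor_score_threshold: float = 90.0     # percentile; minor iff score > threshold
    conversion_major_max: float = 60.0      # major ceiling in conversion analyses
    local_identity: float = 0.4             # alignment-quality identity floor
    quality_window: int = 10                # residues per side for local quality
    min_intron_length: int = 30             # nt
    evalue_rbh: float = 1e-10               # similarity-search cutoff for RBHs
    evalue_snrna: float = 0.01              # snRNA covariance-model hit cutoff
    corrected_fraction_max: float = 0.25    # curation presence rule
    min_junction_reads: int = 5             # splicing-efficiency read filter
    max_boundary_shift: int = 10            # nt, boundary correction search
    seed: int = 0
    outdir: str = "minorintron_run"

    def __post_init__(self) -> None:
        if not 0 < self.minor_score_threshold <= 100:
            raise ParameterError("minor_score_threshold must be in (0, 100]")
        if not 0 < self.conversion_major_max <= 100:
            raise ParameterError("conversion_major_max must be in (0, 100]")
        if not 0 <= self.local_identity <= 1:
            raise ParameterError("local_identity must be in [0, 1]")
        if not 0 <= self.corrected_fraction_max <= 1:
            raise ParameterError("corrected_fraction_max must be in [0, 1]")
        for name in ("quality_window", "min_intron_length", "min_junction_reads",
                     "max_boundary_shift"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.evalue_rbh <= 0 or self.evalue_snrna <= 0:
            raise ParameterError("E-value cutoffs must be positive")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def config_hash(self) -> str:
        """SHA-256 over canonical JSON of all semantic fields (outdir excluded)."""
        doc = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(doc, sort_keys=True, separators=(",", ":")).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
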