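"""Analysis constants shared by every pipeline stage.

All fixed numbers of the analysis live here: the mature piRNA length
window (23-29 nt), the 22-nt miRNA length used for normalisation, the
log2 fold-change threshold that splits source loci into dependent /
independent / up-regulated classes, the ping-pong overlap window and
focus, the ChIP track pseudocounts, and the smallest p-value that is
reported numerically rather than as a floor string.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config", "save_config"]


@dataclass
class AnalysisConfig:
    """Tunable constants for the source-locus pipeline.

    Attributes
    ----------
    pirna_min_len, pirna_max_len
        Inclusive length window (nt) for mature piRNAs.
    mirna_len
        Canonical miRNA read length (nt); informational, the miRNA
        normalisation factor counts reads by locus membership, not length.
    dependency_threshold
        log2 fold-change magnitude a bin must exceed in *both* mutants to
        be called dependent (below ``-t``) or up-regulated (above ``+t``).
    overlap_max
        Largest 5'-overlap (nt) tallied in the ping-pong profile.
    pingpong_focus
        Overlap length whose enrichment over the remaining overlaps is
        summarised as the ping-pong z-score (10 nt for the ping-pong cycle).
    pseudocount_ratio
        Pseudocount added to both operands of the log2 IP (and input)
        knockdown/control ratios.
    pseudocount_subtract
        Pseudocount of the subtraction stage combining the two log2
        ratios.  Mathematically inert ((A+c) - (B+c) = A - B); kept so the
        configuration mirrors the track arithmetic it reproduces.
    p_floor
        Smallest p-value reported numerically; anything below is reported
        as the string ``"P < 2.2e-16"``.
    bin_width
        Width (bp) of the genomic bins ("source loci" are 1-kb bins).
    rng_seed
        Default seed for simulation entry points.
    """

    pirna_min_len: int = 23
    pirna_max_len: int = 29
    mirna_len: int = 22
    dependency_threshold: float = 1.5
    overlap_max: int = 30
    pingpong_focus: int = 10
    pseudocount_ratio: float = 0.1
    pseudocount_subtract: float = 0.01
    p_floor: float = 2.2e-16
    bin_width: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pirna_min_len > self.pirna_max_len:
            raise ValueError("pirna_min_len must not exceed pirna_max_len")
        if self.dependency_threshold <= 0:
            raise ValueError("dependency_threshold must be positive")
        if self.pseudocount_ratio <= 0 or self.pseudocount_subtract <= 0:
            raise ValueError("pseudocounts must be positive")
        if not (1 <= self.pingpong_focus <= self.overlap_max):
            raise ValueError("pingpong_focus must lie within [1, overlap_max]")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, used in run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML file (missing keys keep defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
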