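"""Pipeline configuration with defaults from the published analysis.

Every threshold the pipeline applies lives here so nothing is hard-coded
downstream: consensus support, fold-change and log2-ratio cutoffs, promoter
half-width, TSS downstream window, metagene flank/bin.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml


@dataclass
class PipelineConfig:
    # thresholds (published defaults)
    min_reps: int = 2
    fc_threshold: float = 3.0
    ratio_log2_threshold: float = 0.23
    promoter_halfwidth: int = 2000
    tss_window: int = 2500
    metagene_flank: int = 10000
    bin_size: int = 50
    epsilon: float = 0.25
    fc_mode: str = "mean_of_ratios"  # or "ratio_of_means"
    cgi_only_ratio: bool = True

    seed: int = 42
    output_dir: str = "results/run"

    # paths; peaks/tracks keyed by genotype -> list per replicate
    peaks: Dict[str, List[str]] = field(default_factory=dict)
    ip_tracks: Dict[str, List[str]] = field(default_factory=dict)
    input_tracks: Dict[str, str] = field(default_factory=dict)
    tss_tracks: Dict[str, List[str]] = field(default_factory=dict)
    genes: Optional[str] = None
    cgis: Optional[str] = None
    chrom_sizes: Optional[str] = None
    target: str = "KDM2A"

    def __post_init__(self) -> None:
        for name in (
            "min_reps", "fc_threshold", "ratio_log2_threshold",
            "promoter_halfwidth", "tss_window", "metagene_flank",
            "bin_size", "epsilon",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fc_mode not in ("mean_of_ratios", "ratio_of_means"):
            raise ValueError(f"unknown fc_mode {self.fc_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
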