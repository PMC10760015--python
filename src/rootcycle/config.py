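"""Validated analysis configuration and seeded random substreams.

Every stochastic stage draws its generator from :func:`substream`, keyed by the
root seed and a stage name, so stages are independently reproducible and the
whole pipeline is bit-identical under a fixed root seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, reproducible child generator of the root ``seed``."""
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


@dataclass
class AnalysisConfig:
    """Thresholds and constants for the marker/timelapse/fluorescence pipeline.

    Defaults are the study's stated constants: QC keeps cells with more than
    2000 and fewer than 10000 detected features, below 5 percent mitochondrial
    reads and below 100000 total molecules; markers must pass p < 0.01 with a
    positive log fold change; the top 50 per phase are kept; bulk phase
    patterns are clustered with k = 8; unresolved right-censored G1 durations
    are imputed at 20 h.
    """

    # cell quality control
    min_features: int = 2000
    max_features: int = 10000
    max_mito_pct: float = 5.0
    max_counts: int = 100_000
    min_r_squared: float = 0.93

    # differential expression gates
    de_p_cutoff: float = 0.01
    positive_only: bool = True
    lfc_pseudocount: float = 1e-9

    # marker selection
    top_n_markers: int = 50
    top_n_pseudotime: int = 150
    probe_min_pct: float = 0.80
    probe_min_lfc: float = 0.25
    probe_top_n: int = 5

    # bulk clustering
    kmeans_k: int = 8
    kmeans_starts: int = 25
    bulk_min_tpm: float = 1.0
    bulk_var_quantile: float = 0.5

    # module scoring
    score_n_bins: int = 25
    score_ctrl_size: int = 50

    # timelapse
    cfp_threshold: float = 50.0
    mcherry_threshold: float = 50.0
    yfp_threshold: float = 50.0
    smooth_window: int = 3
    imputed_g1_hours: float = 20.0
    frame_interval_h: float = 1.0 / 6.0  # frames every ten minutes

    # resampling
    n_permutations: int = 9999
    n_bootstrap: int = 2000

    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_features >= self.max_features:
            raise ValueError("min_features must be below max_features")
        if not (0 <= self.max_mito_pct <= 100):
            raise ValueError("max_mito_pct must be a percentage")
        if not (0 < self.de_p_cutoff <= 1):
            raise ValueError("de_p_cutoff must lie in (0, 1]")
        if self.top_n_markers < 1 or self.kmeans_k < 1:
            raise ValueError("top_n_markers and kmeans_k must be positive")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd count")
        if self.imputed_g1_hours <= 0 or self.frame_interval_h <= 0:
            raise ValueError("durations must be positive")
        if self.seed is None:
            raise ValueError("a seed is required for stochastic stages")

    def rng(self, stage: str) -> np.random.Generator:
        return substream(self.seed, stage)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
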