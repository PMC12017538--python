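"""Run configuration shared across pipeline stages.

All thresholds default to the values used throughout the analysis: a log2
family-mean expression floor of 3, lfdr < 0.05 for the transcript batch
filter, |r| > 0.5 for collinearity pruning (features explaining more than
25% of another feature's variance), |r| > 0.05 for the transcript phenotype
screen, unadjusted p < 0.05 for both SNP screens, a relative-variance
cutoff of 1, kriging weight theta = 1, and an elastic-net grid of
alpha 0.1..0.9 (step 0.1) by lambda {1, 0.1, 0.01, 0.001} tuned with
25 bootstrap resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig"]

_DEFAULT_ALPHAS = tuple(round(0.1 * k, 1) for k in range(1, 10))
_DEFAULT_LAMBDAS = (1.0, 0.1, 0.01, 0.001)


@dataclass
class RunConfig:
    """Thresholds and tuning settings for the full prediction pipeline."""

    # preprocessing / feature selection
    min_mean_log2: float = 3.0
    lfdr_cutoff: float = 0.05
    prune_r_cutoff: float = 0.5
    transcript_phen_r_cutoff: float = 0.05
    snp_batch_alpha: float = 0.05
    snp_phen_alpha: float = 0.05
    relative_variance_cutoff: float = 1.0
    multiple_testing: str = "lfdr"  # "lfdr" | "BH"

    # kriging
    theta: float = 1.0
    raw_kriging_weights: bool = False  # literal weighted average instead of centered BLUP
    standardize_similarity: bool = True

    # elastic net tuning grid
    alphas: tuple[float, ...] = _DEFAULT_ALPHAS
    lambdas: tuple[float, ...] = _DEFAULT_LAMBDAS
    n_bootstrap: int = 25

    # evaluation
    model_comparison: str = "nested_f"  # "nested_f" | "williams"

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must be in [0, 1], got {self.theta}")
        for name in ("lfdr_cutoff", "snp_batch_alpha", "snp_phen_alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 <= self.prune_r_cutoff <= 1.0:
            raise ValueError("prune_r_cutoff must be in [0, 1]")
        if not 0.0 <= self.transcript_phen_r_cutoff < 1.0:
            raise ValueError("transcript_phen_r_cutoff must be in [0, 1)")
        if self.relative_variance_cutoff < 0:
            raise ValueError("relative_variance_cutoff must be >= 0")
        if self.multiple_testing not in ("lfdr", "BH"):
            raise ValueError("multiple_testing must be 'lfdr' or 'BH'")
        if self.model_comparison not in ("nested_f", "williams"):
            raise ValueError("model_comparison must be 'nested_f' or 'williams'")
        if any(not 0.0 <= a <= 1.0 for a in self.alphas):
            raise ValueError("alphas must lie in [0, 1]")
        if any(l < 0 for l in self.lambdas):
            raise ValueError("lambdas must be >= 0")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        self.alphas = tuple(float(a) for a in self.alphas)
        self.lambdas = tuple(float(l) for l in self.lambdas)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["alphas"] = list(d["alphas"])
        d["lambdas"] = list(d["lambdas"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "alphas" in d:
            d["alphas"] = tuple(d["alphas"])
        if "lambdas" in d:
            d["lambdas"] = tuple(d["lambdas"])
        return cls(**d)
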