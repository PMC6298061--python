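"""Run configuration and seed management.

All tunable constants of the pipeline live in :class:`RunConfig`; the
defaults reproduce the method's published operating point (90th-percentile
binarization, binomial FDR 1e-4 for network aggregation, TSS FDR 0.01 with
a 0.4 cross-tissue ceiling, 30 pseudo-tissue draws, per-mille binning).

Randomness: every stochastic stage draws from a named child stream of the
single root seed, so pseudo-tissue draws, expression shuffles and synthetic
data are independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "child_rng", "child_seed"]


def child_seed(root_seed: int, name: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed derived from the root seed and a stream name."""
    return np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def child_rng(root_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(root_seed, name))


@dataclass
class RunConfig:
    """Pipeline configuration.

    Attributes
    ----------
    tan_percentile
        Per-dataset correlation percentile above which a gene pair becomes a
        binary-network link (strict ``>``).
    tan_fdr
        Binomial-null FDR used to pick the minimum cross-dataset support ``n``
        for tissue-aggregated networks.
    tan_fdr_mode
        ``planning`` uses the pure binomial tail criterion P(X>=n) <= fdr;
        ``empirical`` divides the expected false count by the observed number
        of links at each support level (suited to dense real data).
    tss_fdr
        Target FDR for the tissue-specificity score, estimated against
        pseudo-tissue nulls.
    tss_other_max
        A tissue-specific link must score below this TSS in every other tissue.
    n_pseudo
        Pseudo-tissue draws per tissue.
    n_bins
        Rank-transform granularity; 1000 gives per-mille bins.
    r2_fdr
        Benjamini-Hochberg level for calling a link's expression-model R^2
        significantly above its shuffle null.
    n_shuffles
        Expression shuffles per link for the R^2 null.
    expressed_threshold_method
        ``gmm2`` (2-component Gaussian mixture on per-gene tissue means) or
        ``fixed`` (mean > ``expressed_fixed_threshold``).
    pseudo_link_universe
        ``tan``: pseudo-tissue TSS is computed on the mirrored tissue's TAN
        links; ``all``: on all expressed pairs.
    model_response
        ``binned``: the expression model predicts the rank-binned correlation;
        ``raw``: the raw Pearson correlation.
    """

    tan_percentile: float = 0.90
    tan_fdr: float = 1e-4
    tan_fdr_mode: str = "planning"
    tss_fdr: float = 0.01
    tss_other_max: float = 0.4
    n_pseudo: int = 30
    n_bins: int = 1000
    r2_fdr: float = 0.01
    n_shuffles: int = 200
    rng_seed: int = 0
    expressed_threshold_method: str = "gmm2"
    expressed_fixed_threshold: float = 6.5
    pseudo_link_universe: str = "tan"
    model_response: str = "binned"
    input_dir: str = "."
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not 0.0 < self.tan_percentile < 1.0:
            raise ValueError("tan_percentile must be in (0, 1)")
        for name in ("tan_fdr", "tss_fdr", "r2_fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.0 <= self.tss_other_max <= 0.5:
            raise ValueError("tss_other_max must be in [0, 0.5]")
        if self.n_pseudo < 1:
            raise ValueError("n_pseudo must be positive")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.tan_fdr_mode not in ("planning", "empirical"):
            raise ValueError("tan_fdr_mode must be 'planning' or 'empirical'")
        if self.expressed_threshold_method not in ("gmm2", "fixed"):
            raise ValueError("expressed_threshold_method must be 'gmm2' or 'fixed'")
        if self.pseudo_link_universe not in ("tan", "all"):
            raise ValueError("pseudo_link_universe must be 'tan' or 'all'")
        if self.model_response not in ("binned", "raw"):
            raise ValueError("model_response must be 'binned' or 'raw'")

    def rng(self, stream: str) -> np.random.Generator:
        """Named child generator of the root seed."""
        return child_rng(self.rng_seed, stream)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls(**raw)
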