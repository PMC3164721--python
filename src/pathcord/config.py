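"""Analysis configuration: the admission-filter thresholds and set-test settings.

Defaults mirror the study design the pipeline reimplements: genes with
interquartile range below 0.5 log2 units are dropped, pathways with fewer
than 10 measured genes are dropped, and P <= 0.05 is called significant.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

SET_PVALUE_METHODS = ("normal", "permutation")


@dataclass
class AnalysisConfig:
    #: minimum interquartile range (log2 units); reporters with IQR strictly
    #: below this are excluded
    iqr_min: float = 0.5
    #: minimum number of measured member genes for a set to be tested;
    #: sets with strictly fewer are dropped
    min_set_size: int = 10
    #: significance level, inclusive (p <= alpha is significant)
    alpha: float = 0.05
    #: "normal": two-sided standard-normal tail of the set score;
    #: "permutation": sample-label permutation null (exact when enumerable)
    set_pvalue_method: str = "normal"
    n_permutations: int = 1000
    #: base of the log scale the intensities are on (fold change reporting)
    lfc_base: float = 2.0
    #: apply probe-to-gene collapse before the IQR filter instead of after
    collapse_before_filter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")
        if self.iqr_min < 0:
            raise ValueError("iqr_min must be >= 0")
        if self.set_pvalue_method not in SET_PVALUE_METHODS:
            raise ValueError(f"set_pvalue_method must be one of {SET_PVALUE_METHODS}")
        if self.set_pvalue_method == "permutation" and self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1 for the permutation method")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
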