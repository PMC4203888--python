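"""Run configuration: the thresholds every pipeline stage shares.

Defaults are the values used throughout the analysis: BLAST e-value cutoff
1e-5 for ortholog calls, Benjamini–Hochberg FDR q = 0.001 for differential
expression, top fraction 0.05 for highly-expressed-set overlap, rank window
31..500 with a Bonferroni factor of 500 for the concordance curve, a
> 100-amino-acid length filter for rate estimation, and the 5–40 µm dendrite
window for D/S summaries.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path


@dataclasses.dataclass
class RunConfig:
    evalue_max: float = 1e-5
    fdr_q: float = 0.001
    top_fraction: float = 0.05
    k_min: int = 31
    k_max: int = 500
    bonferroni_factor: int = 500
    min_aa: int = 100
    ds_window: tuple[float, float] = (5.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.evalue_max:
            raise ValueError("evalue_max must be positive")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.bonferroni_factor < 1:
            raise ValueError("bonferroni_factor must be >= 1")
        if self.min_aa < 0:
            raise ValueError("min_aa must be non-negative")
        lo, hi = self.ds_window
        if not 0 <= lo < hi:
            raise ValueError("ds_window must satisfy 0 <= low < high")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides take precedence over the file."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ds_window" in data:
            data["ds_window"] = tuple(data["ds_window"])
        data.update(overrides)
        return cls(**data)

    def describe(self) -> str:
        return " ".join(
            f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)
        )
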