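"""Flat pipeline configuration with the published defaults, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end analysis in one flat document.

    Thresholds default to the published analysis values: state threshold
    20, demethylation fold changes 0.5/0.66, DE fold change 2 with FPKM
    floor 4, promoter flank 3 kb, rank-plot window 1000 genes.
    """

    # inputs (unused when simulate=True)
    genome: str | None = None
    genes: str | None = None
    k4_minus: str | None = None
    k27_minus: str | None = None
    k27_plus: str | None = None
    expression: str | None = None
    truth: str | None = None
    # output
    outdir: str = "chromcouple_out"
    # simulation
    simulate: bool = False
    seed: int = 0
    n_genes: int = 400
    # coverage handling
    bin_width: int = 50
    flank: int = 3000
    # state / demethylation thresholds
    state_threshold: float = 20.0
    pseudocount: float = 0.1
    fc_strict: float = 0.5
    fc_relaxed: float = 0.66
    # expression thresholds
    de_fc_threshold: float = 2.0
    min_fpkm: float = 4.0
    expr_pseudocount: float = 0.1
    # coupling
    window_size: int = 1000
    step: int = 1
    alternative: str = "two-sided"
    # condition column names in the expression table
    cond_minus: str = "minus_dox"
    cond_plus: str = "plus_dox"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
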