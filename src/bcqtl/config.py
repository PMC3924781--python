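"""Run configuration: every tunable of the mapping workflow, with defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    line_type: str = "DH"            # "DH" | "RI"
    step_1d: float = 1.0             # 1D scan grid (cM)
    step_2d: float = 5.0             # 2D pair grid (cM)
    refine_span_cm: float = 5.0      # 1 cM refinement half-window around 2D peaks
    window_cm: float = 10.0          # cofactor exclusion window
    min_separation_cm: float = 20.0  # peak merging distance
    alpha: float = 0.05              # genome-wide threshold level
    n_perm: int = 200                # permutations per threshold
    mps_alpha: float = 0.01          # MPS entry threshold (marker intervals)
    mps_pair_alpha: float = 0.001    # MPS entry threshold (interval pairs)
    max_cofactors: int = 10
    max_cofactor_pairs: int = 5
    select_alpha: float = 0.05       # backward-elimination retention level
    include_epistasis: bool = True
    scan_2d_scope: str = "candidates"  # "candidates" | "genome"
    estimation: str = "gibbs"        # "gibbs" | "em"
    gibbs_burn: int = 2000
    gibbs_iter: int = 10000
    cache_thresholds: bool = True    # reuse thresholds across MC replicates
    match_window_cm: float = 10.0    # detection window for power
    false_window_cm: float = 20.0    # no-true-QTL window for false positives

    def __post_init__(self):
        self.line_type = str(self.line_type).upper()
        if self.line_type not in ("DH", "RI"):
            raise ValueError("line_type must be 'DH' or 'RI'")
        if self.estimation not in ("gibbs", "em"):
            raise ValueError("estimation must be 'gibbs' or 'em'")
        if self.scan_2d_scope not in ("candidates", "genome"):
            raise ValueError("scan_2d_scope must be 'candidates' or 'genome'")
        for name in ("step_1d", "step_2d", "window_cm", "min_separation_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.mps_alpha < 1.0:
            raise ValueError("mps_alpha must be in (0, 1)")
        if not 0.0 < self.mps_pair_alpha < 1.0:
            raise ValueError("mps_pair_alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown configuration keys: {sorted(unknown)}; "
                f"valid keys are {sorted(known)}"
            )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError("configuration file must contain a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)
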