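"""Run configuration: every tunable and every seed of the pipeline.

All stochastic stages (sample split, permutation null, bootstrap) take
explicit seeds so a run is exactly reproducible from its config; report
files embed the config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # network construction / module detection
    beta: int = 6
    signed: bool = False
    cut_height: float | None = None
    min_size: int = 3
    edge_threshold: float | None = None
    # preservation (topology-based validation)
    n_perm: int = 200
    preservation_mode: str = "correlation"
    zsummary_moderate: float = 2.0
    zsummary_strong: float = 10.0
    # multiscale bootstrap (statistics-based validation)
    scales: tuple = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))
    n_boot: int = 1000
    au_threshold: float = 0.95
    # experiment driver
    split_mode: str = "first_half"
    perturbation_levels: tuple = (0.1, 0.5, 0.9, 1.1, 1.5, 2.0)
    min_size_sweep: tuple = (4, 5, 6, 7, 8, 9, 10)
    # seeds, one per stochastic stage
    split_seed: int = 0
    permutation_seed: int = 0
    bootstrap_seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("scales", "perturbation_levels", "min_size_sweep"):
            d[k] = list(d[k])
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(raw)
        for k in ("scales", "perturbation_levels", "min_size_sweep"):
            if k in cfg and cfg[k] is not None:
                cfg[k] = tuple(cfg[k])
        return cls(**cfg)
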