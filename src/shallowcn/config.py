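"""Run configuration: the tunable parameters of the pipeline, with the
defaults the method was characterized at, serialized as a plain key=value
file so a run can be reproduced exactly."""

from __future__ import annotations

import os
from dataclasses import dataclass, fields

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    bin_size: int = 15000          # bp per bin
    mapq_min: int = 37             # highest MAPQ emitted by BWA
    span: float = 0.65             # LOESS neighborhood fraction
    family: str = "symmetric"      # robust LOESS reweighting
    degree: int = 2
    robustness_iters: int = 4
    mappability_min: float | None = None   # e.g. 50 to drop repeat-heavy bins
    cutoff_sd: float = 4.0         # blacklist residual threshold
    trim: float = 0.001            # first-order estimator trim fraction
    seed: int = 0
    autosomes_only: bool = True
    log2_export: bool = False

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if not (0 < self.span):
            raise ValueError("span must be positive")
        if not (0 <= self.trim < 0.5):
            raise ValueError("trim must be in [0, 0.5)")
        if self.cutoff_sd <= 0:
            raise ValueError("cutoff_sd must be positive")
        if self.mapq_min < 0:
            raise ValueError("mapq_min must be >= 0")

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def read(cls, path: str | os.PathLike) -> "RunConfig":
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                kv[key.strip()] = value.strip()
        kwargs = {}
        for f in fields(cls):
            if f.name not in kv:
                continue
            raw = kv[f.name]
            if raw == "None":
                kwargs[f.name] = None
            elif f.name in ("bin_size", "mapq_min", "degree", "robustness_iters", "seed"):
                kwargs[f.name] = int(raw)
            elif f.name in ("span", "cutoff_sd", "trim", "mappability_min"):
                kwargs[f.name] = float(raw)
            elif f.name in ("autosomes_only", "log2_export"):
                kwargs[f.name] = raw == "True"
            else:
                kwargs[f.name] = raw
        return cls(**kwargs)
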