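"""Pipeline configuration.

One plain-text (YAML) config file drives every stage; unknown keys are
rejected so typos fail loudly.  All randomness flows from the single
``seed`` through per-stage derived streams (stage name hashed into the
seed), so any stage re-run in isolation reproduces its artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    model: str = "full"              # "full", "reduced", or a definition-file path
    data: str | None = None          # observation table (TSV); None -> synthesize
    out: str = "artifacts"
    seed: int = 0
    log_level: str = "INFO"
    # solver
    rtol: float = 1e-8
    atol: float = 1e-10
    fit_rtol: float = 1e-6
    fit_atol: float = 1e-9
    # protocol
    low_glucose: float = 2.8
    high_glucose: float = 16.7
    pre_minutes: float = 120.0
    pool_ratio: float = 3.0          # cytosol : mitochondria relative volume
    # synthetic study
    noise_cv: float = 0.15
    replicates: int = 3
    truth_spread: float = 0.3
    # fitting
    free_parameters: list[str] = field(default_factory=list)
    bound_factor: float = 100.0
    iterations: int = 2000
    runs: int = 100
    keep_best: int = 8
    swarm_size: int = 50
    # sensitivity
    efast_samples: int = 65
    efast_M: int = 4
    efast_resamples: int = 1
    efast_threshold: float = 0.85
    range_decades: float = 2.0
    # plsr
    n_components: int = 3
    train_times: list[float] = field(default_factory=lambda: [3.0, 15.0, 60.0])
    # perturbation
    scan_factor: float = 2.0
    insulin_window: float = 60.0
    steady_horizon: float = 4320.0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)
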