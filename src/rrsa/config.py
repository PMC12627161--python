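"""Run configuration: a validated, hashable record of one analysis.

YAML in, YAML/JSON out; every report carries the configuration hash and
seed so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Paths and analysis parameters for :func:`rrsa.pipeline.run_pipeline`.

    Statistical defaults are the conventional ones for this analysis
    family: cluster-forming threshold t = 2.04 (two-tailed alpha 0.05 at
    df = 30), 100,000 permutations, alpha 0.05, cross-temporal target
    rate 300 Hz.
    """

    # paths
    lexicon: str | None = None
    taxonomy_edges: str | None = None
    taxonomy_wordmap: str | None = None
    similarity_matrix: str | None = None  # precomputed word-by-word TSV
    epochs_dir: str | None = None
    out_dir: str = "rrsa_out"

    # analysis parameters
    windows: list[list[float]] = field(default_factory=list)  # explicit [start, end] ms
    threshold_t: float = 2.04
    n_perm: int = 100_000
    alpha: float = 0.05
    direction: str = "greater"
    chance_override: float | None = None
    target_rate: float = 300.0
    run_cts: bool = False
    fisher_z: bool = False  # arctanh the similarities before regression
    seed: int = 0
    channels: list[str] | None = None  # scalp-channel selection; None = all
    resume: bool = True

    MIN_PERMUTATIONS = 100

    def validate(self, require_inputs: bool = True) -> None:
        if self.n_perm < self.MIN_PERMUTATIONS:
            raise ValueError(f"n_perm below the floor of {self.MIN_PERMUTATIONS}")
        if self.threshold_t <= 0:
            raise ValueError("threshold_t must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.target_rate <= 0:
            raise ValueError("target_rate must be positive")
        if self.direction not in ("greater", "less", "two-sided"):
            raise ValueError("direction must be greater, less or two-sided")
        for w in self.windows:
            if len(w) != 2 or w[0] >= w[1]:
                raise ValueError(f"malformed analysis window {w}")
        if require_inputs:
            if self.lexicon is None or self.epochs_dir is None:
                raise ValueError("lexicon and epochs_dir are required")
            if self.taxonomy_edges is None and self.similarity_matrix is None:
                raise ValueError("need a taxonomy or a precomputed similarity matrix")
            for name in ("lexicon", "taxonomy_edges", "taxonomy_wordmap",
                         "similarity_matrix", "epochs_dir"):
                value = getattr(self, name)
                if value is not None and not Path(value).exists():
                    raise FileNotFoundError(f"{name} path does not exist: {value}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
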