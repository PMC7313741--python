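"""Pipeline configuration: a YAML-backed record of every knob and seed."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run (config + seed ⇒ results).

    With ``spikes_path``/``trials_path`` unset the pipeline simulates its
    inputs with the synthetic generator; otherwise it ingests the CSVs.
    """

    out_dir: str = "spikespace_out"
    spikes_path: str | None = None
    trials_path: str | None = None
    seed: int = 0
    n_trials: int = 160
    n_units: int = 6
    bin_ms: float = 80.0
    corr_bin_ms: float = 40.0
    window_s: float = 1.6  # analysis window after the central poke
    bandwidth_ms: float | None = 8.0  # None -> per-unit MISE optimization
    thetas: tuple[int, ...] = (1, 2, 3)
    block_size: int = 40
    lambda_grid_size: int = 11
    fixed_lambda: float | None = None
    n_permutations: int = 0  # 0 disables the permutation stage
    balance_tolerance: float = 0.10
    zscore: bool = True
    merge_premature_threshold: float = 0.5  # merge PC+PL when the smaller
    # premature category falls below this fraction of the mean category size

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in (self.spikes_path, self.trials_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if (self.spikes_path is None) != (self.trials_path is None):
            raise ValueError("provide both spikes_path and trials_path, or neither")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "thetas" in raw:
        raw["thetas"] = tuple(raw["thetas"])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
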