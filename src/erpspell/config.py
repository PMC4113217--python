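"""Run configuration: every tunable hyperparameter with its default.

Defaults reproduce the study settings: K=6 stimuli, J=15 iterations per
trial, SOA 175 ms, 30 trials per block, 5 classifier pairs, 5 EM iterations
per trial, lambda initialized to 1, beta to 100 and capped at 200, the 12
feature intervals, the [-200, 700] ms epoch window and the calibration
outlier rule (variance > 2.5 x the 90th-percentile threshold).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

from .preprocessing import DEFAULT_INTERVALS_MS, DEFAULT_WINDOW_S
from .synthetic import DEFAULT_DIFFERENCE_AMPLITUDE

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # paradigm
    n_stimuli: int = 6
    n_iterations: int = 15
    soa_s: float = 0.175
    trials_per_block: int = 30
    n_blocks: int = 7  # 1 calibration + 6 evaluation
    # generator
    sampling_rate: float = 100.0
    n_channels: int = 31
    difference_amplitude: float = DEFAULT_DIFFERENCE_AMPLITUDE
    noise_std: float = 1.0
    ar_coefficient: float = 0.8
    # preprocessing
    epoch_window_s: tuple[float, float] = DEFAULT_WINDOW_S
    baseline_s: tuple[float, float] = (-0.2, 0.0)
    lowpass_hz: float = 40.0
    feature_intervals_ms: tuple = DEFAULT_INTERVALS_MS
    outlier_factor: float = 2.5
    outlier_percentile: float = 90.0
    # unsupervised decoder
    n_pairs: int = 5
    em_iterations: int = 5
    lambda_init: float = 1.0
    beta_init: float = 100.0
    beta_cap: float = 200.0
    mu_target: float = 1.0
    mu_nontarget: float = -1.0
    selection: str = "loglik"
    loglik_mode: str = "exact"

    def __post_init__(self):
        if self.n_stimuli < 2 or self.n_iterations < 1:
            raise ValueError("need >= 2 stimuli and >= 1 iteration")
        if self.lambda_init <= 0 or self.beta_init <= 0 or self.beta_cap <= 0:
            raise ValueError("precisions must be positive")
        if self.lowpass_hz >= self.sampling_rate / 2:
            raise ValueError("low-pass edge must be below Nyquist")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Short content hash, logged with every run for reproducibility."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config; unknown keys are rejected with a clear error."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
    data.update(overrides)
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("epoch_window_s", "baseline_s"):
        if key in data:
            data[key] = tuple(data[key])
    if "feature_intervals_ms" in data:
        data["feature_intervals_ms"] = tuple(
            tuple(iv) for iv in data["feature_intervals_ms"]
        )
    return RunConfig(**data)
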