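"""Pipeline configuration: every tunable with its default, validated strictly.

Unknown keys and out-of-range values are rejected at load time so that a
typo in a config file can never silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # fNIRS
    nirs_band_hz: Tuple[float, float] = (0.03, 0.5)
    nirs_filter_order: int = Field(6, ge=1)
    z_threshold: float = Field(4.0, gt=0)
    z_signed: bool = False
    block_window_s: Tuple[float, float] = (-5.0, 25.0)
    baseline_window_s: Tuple[float, float] = (-5.0, 0.0)
    auc_window_s: Tuple[float, float] = (0.0, 10.0)
    auc_window_full_s: Tuple[float, float] = (0.0, 20.0)
    dpf: float = Field(4.99, gt=0)
    separation_mm: float = Field(15.0, gt=0)
    adjacency_radius_mm: float = Field(20.0, gt=0)
    analyze_in: Literal["uM", "z"] = "uM"  # scale carried past block rejection

    # EEG
    eeg_band_hz: Tuple[float, float] = (1.0, 20.0)
    eeg_target_rate_hz: float = Field(512.0, gt=0)
    epoch_window_s: Tuple[float, float] = (-0.5, 3.5)
    erp_baseline_s: Tuple[float, float] = (-0.2, 0.0)
    abs_thresh_uV: float = Field(50.0, gt=0)
    jump_thresh_uV: float = Field(30.0, gt=0)
    jump_span: int = Field(10, ge=2)
    chan_frac: float = Field(0.70, gt=0, le=1)
    trial_frac: float = Field(0.15, gt=0, le=1)
    peak_latencies_ms: Tuple[float, ...] = (84.0, 244.0, 378.0, 576.0)
    gfp_peak_window_ms: float = Field(40.0, gt=0)
    proj_peak_window_ms: float = Field(100.0, gt=0)
    n_repetitions: int = Field(4, ge=2, le=4)

    # statistics
    forming_alpha: float = Field(0.05, gt=0, lt=1)
    n_permutations: int = Field(1000, ge=10)
    seed: int = Field(0, ge=0)

    # cohort
    n_healthy: int = Field(12, ge=0)
    n_ivh: int = Field(7, ge=0)
    n_blocks: int = Field(12, ge=1)

    @field_validator(
        "nirs_band_hz", "eeg_band_hz", "block_window_s", "epoch_window_s",
        "auc_window_s", "auc_window_full_s", "baseline_window_s", "erp_baseline_s",
    )
    @classmethod
    def _ordered(cls, v):
        if v[0] >= v[1]:
            raise ValueError(f"interval must be increasing, got {v}")
        return v

    def digest(self) -> str:
        """Stable hash of the configuration for provenance stamps."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config, merging file values and overrides onto defaults.

    Raises a validation error naming the key for unknown or out-of-range
    entries.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded:
            if not isinstance(loaded, dict):
                raise ValueError("config file must hold a mapping")
            data.update(loaded)
    if overrides:
        data.update(overrides)
    return PipelineConfig(**data)
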