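"""Run configuration: every tunable of the pipeline in one validated object.

Defaults follow the published operating point for PPG at 300 Hz: endpoint
search window fractions alpha = 0.7 and beta = 1.3 of the average cycle
length, morphology scale gamma = 5000, 1-minute analysis batches, and a
4th-order Butterworth band-pass of [0.5, 5] Hz.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # endpoint search (fractions of the average cycle length l_X)
    alpha: float = 0.7
    beta: float = 1.3
    gamma: float = 5000.0
    batch_seconds: float = 60.0
    hr_band: tuple[float, float] = (0.5, 3.0)  # Hz band searched for the dominant frequency
    normalization: str = "minmax"  # none | minmax | zscore, applied per batch before DTW
    reset_policy: str = "score_gated"  # score_gated | literal
    window: int | None = None  # optional Sakoe-Chiba band (samples)
    # preprocessing
    bandpass_low: float = 0.5
    bandpass_high: float = 5.0
    filter_order: int = 4
    # evaluation
    tolerance_ms: float = 30.0
    ibi_lo_ms: float = 300.0
    ibi_hi_ms: float = 1500.0
    # dynamic template ensemble
    k: int = 3
    region_seconds: float = 30.0
    reanalysis: bool = True
    dba_max_iter: int = 30
    dba_tol: float = 1e-6
    # SPRING baseline
    spring_tau: float | None = None  # None -> 25th percentile of first-batch end distances

    def __post_init__(self) -> None:
        self.hr_band = tuple(self.hr_band)  # type: ignore[assignment]
        if not (0 < self.alpha < 1 < self.beta):
            raise ValueError(f"need 0 < alpha < 1 < beta, got alpha={self.alpha}, beta={self.beta}")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if not self.batch_seconds > 0:
            raise ValueError("batch_seconds must be positive")
        if not (0 < self.hr_band[0] < self.hr_band[1]):
            raise ValueError(f"invalid hr_band {self.hr_band}")
        if self.normalization not in ("none", "minmax", "zscore"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.reset_policy not in ("score_gated", "literal"):
            raise ValueError(f"unknown reset_policy {self.reset_policy!r}")
        if not (0 < self.bandpass_low < self.bandpass_high):
            raise ValueError("need 0 < bandpass_low < bandpass_high")
        if self.k < 1:
            raise ValueError("ensemble size k must be >= 1")
        if not self.region_seconds > 0:
            raise ValueError("region_seconds must be positive")
        if not (0 <= self.ibi_lo_ms < self.ibi_hi_ms):
            raise ValueError("need 0 <= ibi_lo_ms < ibi_hi_ms")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(d, dict):
            raise ValueError(f"{path}: config file must hold a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hr_band"] = list(self.hr_band)
        return d

    def hash(self) -> str:
        """Short digest of the configuration, for provenance blocks."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
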