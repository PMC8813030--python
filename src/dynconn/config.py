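"""Run configuration: a flat YAML-serializable parameter record.

Defaults reproduce the analysis design the pipeline implements: discard 10
initial volumes, window 22 TR with Gaussian sigma 3 TR sliding in steps of
1 TR, sparsity sweep 0.08-0.48 in 0.01 increments, k-means over k = 2..8
with 500 iterations and 150 replicates, BH-FDR at q = 0.05.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # paths
    output_dir: str = "dynconn_out"
    input_timecourses: str = ""   # directory of *.tsv (empty -> use simulate stage)
    input_metadata: str = ""

    # cohort simulation (used by the simulate stage)
    n_hc: int = 37
    n_ltle: int = 22
    n_rtle: int = 31
    n_components: int = 43
    n_timepoints_raw: int = 225   # collected volumes, before discard
    tr_seconds: float = 2.0
    noise_sd: float = 0.3

    # conditioning / QC
    discard_volumes: int = 10
    despike_robust_z: float = 4.0
    lowpass_cutoff_hz: float = 0.15
    mean_fd_max: float = 0.2
    max_disp_mm: float = 3.0
    max_rot_deg: float = 3.0

    # dynamic connectivity
    window_length: int = 22
    window_sigma: float = 3.0
    window_step: int = 1

    # state clustering
    k_min: int = 2
    k_max: int = 8
    kmeans_max_iter: int = 500
    kmeans_replicates: int = 150

    # graph analysis
    sparsity_min: float = 0.08
    sparsity_max: float = 0.48
    sparsity_step: float = 0.01
    n_rand_static: int = 100
    n_rand_dynamic: int = 20

    # statistics
    q_fdr: float = 0.05

    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.discard_volumes < 0:
            raise ValueError("discard_volumes must be >= 0")
        if self.window_length < 3 or self.window_sigma <= 0 or self.window_step < 1:
            raise ValueError("invalid window parameters")
        if not (0 < self.sparsity_min < self.sparsity_max < 1):
            raise ValueError("invalid sparsity range")
        if self.sparsity_step <= 0:
            raise ValueError("sparsity_step must be positive")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("invalid k range")
        if not 0 < self.q_fdr < 1:
            raise ValueError("q_fdr must be in (0, 1)")
        if self.n_timepoints_raw - self.discard_volumes <= self.window_length:
            raise ValueError("too few retained volumes for the window length")

    @property
    def n_timepoints(self) -> int:
        """Retained TRs after the initial-volume discard."""
        return self.n_timepoints_raw - self.discard_volumes

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def out_path(self, *parts) -> Path:
        p = Path(self.output_dir).joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p
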