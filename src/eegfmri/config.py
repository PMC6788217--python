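"""Run configuration: one validated schema for every pipeline parameter."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator


class SimulationConfig(BaseModel):
    n_sensors: int = 32
    grid_shape: tuple[int, int, int] = (8, 8, 6)
    spacing_mm: float = 6.0
    n_networks: int = 1
    band_assignment: tuple[str, ...] = ("alpha",)
    duration_s: float = 300.0
    fs: float = 250.0
    envelope_cutoff_hz: float = 0.1
    background_amp: float = 0.5
    network_amp: float = 1.0
    sensor_noise_frac: float = 0.05      # white sensor noise, fraction of clean RMS
    tr_s: float = 2.0
    slices_per_tr: int = 10
    cardiac_bpm: float = 60.0
    jitter_ms: float = 40.0
    artifact_amplitudes: dict[str, float] = Field(
        default_factory=lambda: {"gradient": 50.0, "bcg": 5.0, "eog": 3.0, "emg": 2.0}
    )
    bold_noise_sd: float = 0.5
    bold_drift_amp: float = 0.3

    @field_validator("duration_s")
    @classmethod
    def _min_duration(cls, v):
        if v < 60:
            raise ValueError("duration must be at least 60 s")
        return v


class PreprocessConfig(BaseModel):
    n_avg_epochs: int = 20
    gradient_obs_pcs: int = 3
    bcg_obs_pcs: int = 3
    bcg_window: tuple[float, float] = (-0.2, 0.6)
    filter_lo: float = 1.0
    filter_hi: float = 80.0
    ica_order: Optional[int] = None      # None -> MDL
    ic_thresholds: dict[str, float] = Field(
        default_factory=lambda: {"eog_corr": 0.3, "emg_corr": 0.3,
                                 "kurtosis": 10.0, "spec_1f_sim": 0.5}
    )


class SourceConfig(BaseModel):
    alpha_reg: float = 0.05
    tol: float = 1e-6
    max_iter: int = 100


class NetworkConfig(BaseModel):
    tica_order: Optional[int] = None     # None -> MDL
    sica_order: Optional[int] = None
    max_auto_order: int = 20             # ceiling on the MDL-chosen order


class HemoConfig(BaseModel):
    hrf_dt: float = 1.0
    burn_in_s: float = 32.0
    occipital_band: str = "alpha"


class GroupConfig(BaseModel):
    q: float = 0.05
    binarize_rule: str = "by_fdr"        # {'by_fdr', 'z_1.96'}
    z_thresh: float = 1.96


class RunConfig(BaseModel):
    """Full study configuration; serialized into every output directory."""

    seed: int = 0
    n_subjects: int = 10
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    source: SourceConfig = Field(default_factory=SourceConfig)
    networks: NetworkConfig = Field(default_factory=NetworkConfig)
    hemo: HemoConfig = Field(default_factory=HemoConfig)
    group: GroupConfig = Field(default_factory=GroupConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=False)
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:12]

    def subject_seed(self, subject_index: int) -> int:
        """Deterministic per-subject seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{subject_index}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31 - 1)


def desk_scale_config(seed: int = 0, n_subjects: int = 10) -> RunConfig:
    """Reduced-size study preset used for fast end-to-end validation runs.

    Same generative structure as the defaults, scaled to stay well inside
    a single-CPU desk budget: 24 sensors, a 6×6×5 grid (≈100 gray-matter
    voxels), 160 s at 200 Hz, 80 BOLD volumes at TR 2 s. The sensor-space
    ICA is reduced to 15 dimensions (artifact subspaces plus the network
    leave the rest to noise at this channel count).
    """
    return RunConfig(
        seed=seed,
        n_subjects=n_subjects,
        simulation=SimulationConfig(
            n_sensors=24,
            grid_shape=(6, 6, 5),
            duration_s=160.0,
            fs=200.0,
        ),
        preprocess=PreprocessConfig(n_avg_epochs=10, ica_order=15),
        # ~100 voxels x 160 frames cannot support many components; a low
        # ceiling keeps the slow network fluctuation in one component
        # instead of splitting it from its own frame-to-frame power noise
        networks=NetworkConfig(max_auto_order=3),
    )
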