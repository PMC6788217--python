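"""Shared data containers for the EEG–fMRI coupling pipeline.

All containers are thin dataclasses around numpy arrays with the invariants
that the downstream algorithms rely on checked at construction time (cheap
checks only; anything O(data) beyond a finiteness scan is left to the
producing code).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


def _as_float(a) -> np.ndarray:
    return np.asarray(a, dtype=np.float64)


@dataclass
class SourceGrid:
    """Regular voxel grid defining the source space.

    ``coords`` are voxel centers in mm for every voxel of the rectangular
    box (C order over ``shape``); ``gm_mask`` marks the gray-matter subset
    on which power/network analyses run.
    """

    coords: np.ndarray          # (n_voxels, 3) mm
    spacing: float              # mm
    gm_mask: np.ndarray         # (n_voxels,) bool
    shape: tuple                # (nx, ny, nz)

    def __post_init__(self):
        self.coords = _as_float(self.coords)
        self.gm_mask = np.asarray(self.gm_mask, dtype=bool)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_voxels, 3)")
        if len(self.gm_mask) != self.n_voxels:
            raise ValueError("gm_mask length must equal n_voxels")
        uniq = np.unique(self.coords.round(9), axis=0)
        if len(uniq) != self.n_voxels:
            raise ValueError("voxel coordinates must be unique")

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    def affine(self) -> np.ndarray:
        """NIfTI affine mapping voxel indices to the mm coordinates."""
        aff = np.diag([self.spacing] * 3 + [1.0])
        aff[:3, 3] = self.coords[0]
        return aff

    def volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Reshape a flat per-voxel vector to the 3-D box (C order)."""
        values = np.asarray(values)
        if values.shape[0] != self.n_voxels:
            raise ValueError("values length must equal n_voxels")
        return values.reshape(self.shape + values.shape[1:])


@dataclass
class LeadField:
    """Forward operator: scalp potential per unit dipole moment.

    ``matrix`` is sensors × (n_voxels·3); columns come in x/y/z triples per
    voxel. When ``reference == 'average'`` every column sums to zero.
    """

    matrix: np.ndarray
    sensor_positions: np.ndarray      # (n_sensors, 3) mm
    reference: str = "average"        # {'average', 'original'}

    def __post_init__(self):
        self.matrix = _as_float(self.matrix)
        self.sensor_positions = _as_float(self.sensor_positions)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("leadfield entries must be finite")
        if self.matrix.shape[1] % 3 != 0:
            raise ValueError("leadfield must have 3 columns per voxel")
        norms = np.linalg.norm(self.matrix, axis=0)
        if np.any(norms == 0):
            raise ValueError("leadfield column norms must be positive")
        if self.reference == "average":
            if np.max(np.abs(self.matrix.sum(axis=0))) > 1e-9 * norms.max():
                raise ValueError("average-referenced leadfield columns must sum to 0")

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1] // 3

    def voxel_block(self, v: int) -> np.ndarray:
        """Sensors × 3 leadfield block of voxel ``v``."""
        return self.matrix[:, 3 * v:3 * v + 3]


@dataclass
class SensorRecording:
    """Multichannel EEG in µV with acquisition markers."""

    data: np.ndarray               # (n_channels, n_samples) µV
    fs: float                      # Hz
    labels: Sequence[str]
    positions: np.ndarray          # (n_channels, 3) mm
    tr_markers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    cardiac_markers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    bad_flags: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = _as_float(self.data)
        self.positions = _as_float(self.positions)
        self.tr_markers = np.asarray(self.tr_markers, dtype=np.int64)
        self.cardiac_markers = np.asarray(self.cardiac_markers, dtype=np.int64)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording data must be finite")
        if self.bad_flags is None:
            self.bad_flags = np.zeros(self.n_channels, dtype=bool)
        self.bad_flags = np.asarray(self.bad_flags, dtype=bool)
        self.labels = list(self.labels)
        if len(self.labels) != self.n_channels:
            raise ValueError("one label per channel required")
        for name, m in (("tr", self.tr_markers), ("cardiac", self.cardiac_markers)):
            if m.size:
                if np.any(np.diff(m) <= 0):
                    raise ValueError(f"{name} markers must be strictly increasing")
                if m[0] < 0 or m[-1] >= self.n_samples:
                    raise ValueError(f"{name} markers must lie within the record")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "SensorRecording":
        """Copy of the recording with replaced samples (markers preserved)."""
        return dataclasses.replace(self, data=np.array(data, dtype=np.float64))


@dataclass
class SourceActivity:
    """Scalar activity per voxel with a fixed orientation per voxel.

    The dense n_voxels × 3 × n_samples moment array is ``activity`` expanded
    along ``orientations``; it is materialised only on request.
    """

    activity: np.ndarray        # (n_voxels, n_samples)
    orientations: np.ndarray    # (n_voxels, 3) unit vectors
    fs: float

    def __post_init__(self):
        self.orientations = _as_float(self.orientations)

    @property
    def n_voxels(self) -> int:
        return self.activity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.activity.shape[1]

    def dense(self) -> np.ndarray:
        """Expand to the (n_voxels, 3, n_samples) dipole-moment array."""
        return self.orientations[:, :, None] * self.activity[:, None, :]


@dataclass
class GroundTruth:
    """Generative ground truth of one synthetic subject."""

    network_maps: np.ndarray        # (n_voxels, K) nonnegative loadings
    envelopes: np.ndarray           # (K, T_seconds) slow power envelopes, 1 Hz
    carrier_bands: Sequence[str]
    artifact_signals: dict = field(default_factory=dict)
    coupling: str = "BOLD = HRF ⊗ envelope, weighted by network_maps"

    def __post_init__(self):
        self.network_maps = _as_float(self.network_maps)
        self.envelopes = _as_float(self.envelopes)
        if self.K < 1:
            raise ValueError("at least one network required")
        if np.any(self.envelopes < 0):
            raise ValueError("envelopes must be nonnegative")
        if np.any((self.network_maps != 0).sum(axis=0) == 0):
            raise ValueError("each network map needs at least one nonzero voxel")

    @property
    def K(self) -> int:
        return self.network_maps.shape[1]


@dataclass
class VolumeSeries:
    """BOLD (or BOLD-like) voxel × volume series on a SourceGrid."""

    values: np.ndarray      # (n_voxels, n_volumes)
    tr: float               # seconds
    grid_ref: str = ""

    def __post_init__(self):
        self.values = _as_float(self.values)
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass
class CleaningReport:
    """Record of one EEG cleaning step."""

    step: str
    residual_variance: dict = field(default_factory=dict)  # channel -> variance after step
    bad_channels: list = field(default_factory=list)       # (label, criterion)
    removed_ic_ids: list = field(default_factory=list)
    ic_scores: dict = field(default_factory=dict)          # name -> per-IC array
    reference: str = "original"
    notes: list = field(default_factory=list)


@dataclass
class ICDecomposition:
    """FastICA result in the whitened k-dimensional subspace."""

    k: int
    whitening: np.ndarray       # (k, dim)
    mixing: np.ndarray          # (dim, k)
    sources: np.ndarray         # (k, n_obs), unit variance rows
    mean: np.ndarray            # (dim,) removed before whitening
    convergence: list           # iterations used per component
    seed: Optional[int] = None

    @property
    def dim(self) -> int:
        return self.mixing.shape[0]

    @property
    def n_obs(self) -> int:
        return self.sources.shape[1]

    @property
    def unmixing(self) -> np.ndarray:
        """k × dim matrix mapping centered data to sources."""
        return np.linalg.pinv(self.mixing)


@dataclass
class InverseOperator:
    """eLORETA linear inverse."""

    weights: np.ndarray      # (n_voxels, 3, 3) symmetric blocks
    operator: np.ndarray     # (n_voxels*3, n_sensors)
    alpha_reg: float
    n_iter: int
    converged: bool

    def __post_init__(self):
        if self.alpha_reg <= 0:
            raise ValueError("regularization fraction must be positive")
        if not np.all(np.isfinite(self.operator)):
            raise ValueError("inverse operator must be finite")
        if not self.converged:
            raise ValueError("inverse operator did not converge")

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]


@dataclass
class BandPowerSeries:
    """Per-voxel band-limited power at one frame per second.

    Frames come from a 2 s Hamming short-time Fourier transform with 50%
    overlap, so a record of ``duration`` seconds yields ``floor(duration)-1``
    frames, the first centered at t = 1 s.
    """

    values: np.ndarray      # (n_voxels, T_power) >= 0
    band: str
    f_lo: float
    f_hi: float
    rate: float = 1.0       # frames per second
    window: str = "hamming-2s-50%"

    def __post_init__(self):
        self.values = _as_float(self.values)
        if np.any(self.values < -1e-12):
            raise ValueError("power values must be nonnegative")
        if not (1.0 <= self.f_lo < self.f_hi <= 80.0):
            raise ValueError("band must lie within 1-80 Hz")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class NetworkResult:
    """One ICA network-detection run (tICA on power or sICA on BOLD)."""

    band: str
    decomposition: ICDecomposition
    spatial_zmaps: np.ndarray      # (n_voxels, k)
    timecourses: np.ndarray        # (k, T)
    rate: float                    # Hz of the timecourses
    template_r: Optional[np.ndarray] = None
    selected_ic: Optional[int] = None
    selected_r: Optional[float] = None

    @property
    def selected_zmap(self) -> np.ndarray:
        return self.spatial_zmaps[:, self.selected_ic]

    @property
    def selected_timecourse(self) -> np.ndarray:
        return self.timecourses[self.selected_ic]


@dataclass
class HRFKernel:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1."""

    samples: np.ndarray
    dt: float
    params: dict

    @property
    def duration(self) -> float:
        return (len(self.samples) - 1) * self.dt


@dataclass
class ZMap:
    """Subject-level Fisher-z correlation map."""

    z: np.ndarray
    subject_id: str = ""
    band: str = ""
    regressor_kind: str = "network_ic"   # {'occipital_sensor', 'network_ic'}

    def __post_init__(self):
        self.z = _as_float(self.z)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z map must be finite")


@dataclass
class GroupMap:
    """Mass-univariate group result with BY-FDR masks."""

    t: np.ndarray
    p_pos: np.ndarray
    p_neg: np.ndarray
    q: float
    mask_pos: np.ndarray
    mask_neg: np.ndarray
    n_subjects: int
    scope: str = "voxels"    # {'voxels', 'voxels_x_bands'}
    band: str = ""


@dataclass
class OverlapResult:
    """Spatial correspondence of two maps."""

    cc: float
    dc: float
    band: str = ""

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.cc <= 1.0 + 1e-12:
            raise ValueError("CC must lie in [-1, 1]")
        if not 0.0 <= self.dc <= 1.0:
            raise ValueError("DC must lie in [0, 1]")
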