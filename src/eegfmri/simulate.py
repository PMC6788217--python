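"""Ground-truth-known synthetic EEG + BOLD generator.

The generator embodies the coupling model the analysis assumes: K spatial
network patterns whose voxels carry band-limited oscillations
(e.g. an 8–13 Hz alpha carrier) amplitude-modulated by slow (<0.1 Hz)
envelopes. Sources are projected to sensors through a closed-form
leadfield; the recording is then contaminated with the artifact families
characteristic of the MR environment (gradient, ballistocardiogram, EOG,
EMG). BOLD per voxel is the canonical-HRF-convolved neural power envelope
weighted by the network map, plus polynomial drift and white noise,
sampled at the TR.

The head model is deliberately simple: sensors on an upper-hemisphere
shell and the current-dipole potential of an infinite homogeneous
conductor stand in for a FEM forward solution. This is a documented
stand-in — it is closed-form, exactly linear, and sufficient to exercise
the inverse solution, but it carries no tissue geometry.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre
from scipy import signal

from .containers import (
    GroundTruth,
    LeadField,
    SensorRecording,
    SourceActivity,
    SourceGrid,
    VolumeSeries,
)
from .hemo import canonical_hrf, hrf_convolve
from .source import BANDS

__all__ = [
    "make_head_model",
    "make_network_maps",
    "simulate_sources",
    "project_to_sensors",
    "add_mr_artifacts",
    "simulate_bold",
    "montage_roles",
    "DEFAULT_ARTIFACT_AMPLITUDES",
]

_CONDUCTIVITY = 0.33  # S/m, brain-like homogeneous medium

#: Artifact amplitudes as multiples of the clean recording's RMS. The
#: gradient artifact dwarfs neural signal by orders of magnitude; BCG is a
#: few times larger than EEG; ocular and myogenic activity are of the same
#: order as the neural signal.
DEFAULT_ARTIFACT_AMPLITUDES = {
    "gradient": 50.0,
    "bcg": 5.0,
    "eog": 3.0,
    "emg": 2.0,
}


# ---------------------------------------------------------------------------
# Head model
# ---------------------------------------------------------------------------

def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the upper hemisphere (z > 0.1)."""
    i = np.arange(n)
    z = 0.12 + 0.88 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _dipole_potentials(sensors: np.ndarray, voxels: np.ndarray) -> np.ndarray:
    """Infinite-homogeneous-conductor potentials, sensors × (n_voxels·3).

    V(r_s) = (1 / 4πσ) · q · (r_s − r_v) / |r_s − r_v|³ for a unit dipole
    moment q along each Cartesian axis.
    """
    diff = sensors[:, None, :] - voxels[None, :, :]          # (m, V, 3)
    dist = np.linalg.norm(diff, axis=2)
    lf = diff / dist[:, :, None] ** 3 / (4.0 * np.pi * _CONDUCTIVITY)
    return lf.reshape(sensors.shape[0], -1)


def make_head_model(
    n_sensors: int = 32,
    grid_shape: tuple[int, int, int] = (8, 8, 6),
    spacing_mm: float = 6.0,
    seed: int | None = None,
) -> tuple[SourceGrid, LeadField]:
    """Source grid plus average-referenced closed-form leadfield.

    Voxels fill a rectangular box centered at the origin; the gray-matter
    mask is the inscribed ellipsoid. Sensors sit on an upper-hemisphere
    shell around the grid with a small seeded jitter; geometry degenerate
    enough to place a sensor on top of a voxel is re-jittered, up to 100
    times, before giving up.
    """
    if n_sensors < 8:
        raise ValueError("need at least 8 sensors")
    shape = tuple(int(s) for s in grid_shape)
    if int(np.prod(shape)) < 27:
        raise ValueError("grid must contain at least 27 voxels")
    rng = np.random.default_rng(seed)

    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    idx = idx.reshape(-1, 3).astype(float)
    center = (np.array(shape, dtype=float) - 1.0) / 2.0
    coords = (idx - center) * spacing_mm
    half = np.maximum(np.array(shape, dtype=float) / 2.0 * spacing_mm, spacing_mm)
    gm = (np.sum((coords / half) ** 2, axis=1) <= 1.0 + 1e-9)
    grid = SourceGrid(coords=coords, spacing=spacing_mm, gm_mask=gm, shape=shape)

    radius = 1.8 * float(np.max(np.abs(coords))) + 2.0 * spacing_mm
    base = _fibonacci_hemisphere(n_sensors) * radius
    for _ in range(100):
        sensors = base + rng.normal(scale=0.02 * spacing_mm, size=base.shape)
        dmin = np.min(np.linalg.norm(sensors[:, None, :] - coords[None, :, :], axis=2))
        if dmin > spacing_mm:
            break
    else:
        raise RuntimeError("could not place sensors away from the source grid")

    lf = _dipole_potentials(sensors, coords)
    lf = lf - lf.mean(axis=0, keepdims=True)    # average reference
    return grid, LeadField(matrix=lf, sensor_positions=sensors, reference="average")


def montage_roles(positions: np.ndarray, n_each: int = 4) -> dict[str, np.ndarray]:
    """Index sets for the synthetic montage by sensor position.

    ``frontal`` = most anterior (+y), ``occipital`` = most posterior (−y),
    ``rim`` = lowest on the shell (smallest z) — the channels most exposed
    to ocular and myogenic contamination respectively.
    """
    y, z = positions[:, 1], positions[:, 2]
    return {
        "frontal": np.argsort(y)[::-1][:n_each],
        "occipital": np.argsort(y)[:n_each],
        "rim": np.argsort(z)[:n_each],
    }


# ---------------------------------------------------------------------------
# Neural sources
# ---------------------------------------------------------------------------

def _lowpass_envelope(n: int, fs: float, cutoff: float, rng) -> np.ndarray:
    """Rectified low-pass Gaussian noise, normalised to unit mean.

    The low-pass is applied in the frequency domain (all bins above
    ``cutoff`` zeroed): at resting-state cutoffs (~0.1 Hz) a recursive
    filter at EEG sampling rates is numerically fragile and its edge
    transients can dominate a whole run, whereas spectral synthesis is
    stationary by construction.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(rng.standard_normal(n))
    spec[freqs > cutoff] = 0.0
    env = np.abs(np.fft.irfft(spec, n=n))
    mean = env.mean()
    return env / mean if mean > 0 else env


def _bandpass_noise(n: int, fs: float, lo: float, hi: float, rng) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to [lo, hi] Hz."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _carrier_noise(n: int, fs: float, lo: float, hi: float, rng,
                   margin_hz: float = 0.5) -> np.ndarray:
    """Exactly band-limited unit-variance carrier (spectral synthesis).

    Gaussian noise whose spectrum is zeroed outside
    [lo + margin, hi − margin]: the margin keeps the carrier clear of the
    shared band edges so that, like a physiological rhythm, it does not
    bleed into the adjacent analysis bands through the edge bins.
    """
    lo_eff = lo + margin_hz
    hi_eff = hi - margin_hz
    if hi_eff <= lo_eff:
        lo_eff, hi_eff = lo, hi
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(rng.standard_normal(n))
    spec[(freqs < lo_eff) | (freqs > hi_eff)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _one_over_f_noise(shape: tuple[int, int], fs: float, rng) -> np.ndarray:
    """Rows of 1/f-power background noise, unit variance per row."""
    n = shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** -0.5                      # amplitude ∝ f^-1/2 → power 1/f
    spec = np.fft.rfft(rng.standard_normal(shape), axis=1) * gain
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def make_network_maps(
    grid: SourceGrid,
    K: int = 1,
    blob_sigma_factor: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """K smooth nonnegative spatial blobs inside the gray-matter mask."""
    rng = np.random.default_rng(seed)
    gm_idx = np.nonzero(grid.gm_mask)[0]
    maps = np.zeros((grid.n_voxels, K))
    sigma = blob_sigma_factor * grid.spacing
    centers = rng.choice(gm_idx, size=K, replace=False)
    for k, c in enumerate(centers):
        d2 = np.sum((grid.coords - grid.coords[c]) ** 2, axis=1)
        blob = np.exp(-d2 / (2.0 * sigma**2))
        blob[~grid.gm_mask] = 0.0
        blob[blob < 0.1] = 0.0
        maps[:, k] = blob
    return maps


def simulate_sources(
    grid: SourceGrid,
    K: int = 1,
    band_assignment: tuple[str, ...] = ("alpha",),
    duration_s: float = 300.0,
    fs: float = 250.0,
    envelope_cutoff_hz: float = 0.1,
    background_amp: float = 0.5,
    network_amp: float = 1.0,
    blob_sigma_factor: float = 1.0,
    maps: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[SourceActivity, GroundTruth]:
    """Voxelwise neural activity with K envelope-modulated network carriers.

    Each network is a smooth spatial blob inside the gray-matter mask; its
    voxels carry band-passed Gaussian noise in the assigned band, amplitude
    modulated by a rectified low-pass (< ``envelope_cutoff_hz``) envelope.
    Every voxel additionally receives 1/f background noise scaled by
    ``background_amp``. Orientations are fixed unit vectors per voxel.
    """
    if duration_s < 60:
        raise ValueError("duration must be at least 60 s")
    if len(band_assignment) != K:
        raise ValueError("one carrier band per network required")
    for b in band_assignment:
        lo, hi = BANDS[b] if isinstance(b, str) else b
        if lo < 1.0 or hi > 80.0:
            raise ValueError(f"carrier band {b!r} outside 1-80 Hz")
        if envelope_cutoff_hz >= lo:
            raise ValueError("envelope cutoff must lie below the carrier band")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    V = grid.n_voxels

    if maps is None:
        maps = make_network_maps(grid, K, blob_sigma_factor, seed=seed)
    maps = np.asarray(maps, dtype=np.float64)
    if maps.shape != (V, K):
        raise ValueError("maps must be (n_voxels, K)")

    env_fs = np.empty((K, n))
    carriers = np.empty((K, n))
    for k in range(K):
        env_fs[k] = _lowpass_envelope(n, fs, envelope_cutoff_hz, rng)
        lo, hi = BANDS[band_assignment[k]] if isinstance(band_assignment[k], str) \
            else band_assignment[k]
        carriers[k] = _carrier_noise(n, fs, lo, hi, rng)

    net_signals = env_fs * carriers
    activity = (maps * network_amp) @ net_signals
    if background_amp > 0:
        activity += background_amp * _one_over_f_noise((V, n), fs, rng)

    orientations = rng.standard_normal((V, 3))
    orientations /= np.linalg.norm(orientations, axis=1, keepdims=True)

    # 1 Hz ground-truth power envelopes: the realized band power of each
    # network per second (slow modulator² × carrier power). This is the
    # quantity the hemodynamic coupling acts on — the power a perfect
    # band-power analysis of the neural signal would see — whose slow
    # structure comes from the sub-`envelope_cutoff_hz` modulator.
    T = int(np.floor(duration_s))
    fs_i = int(round(fs))
    env_1hz = (net_signals[:, : T * fs_i] ** 2).reshape(K, T, fs_i).mean(axis=2)

    truth = GroundTruth(
        network_maps=maps,
        envelopes=env_1hz,
        carrier_bands=[b if isinstance(b, str) else str(b) for b in band_assignment],
    )
    return SourceActivity(activity=activity, orientations=orientations, fs=fs), truth


def project_to_sensors(
    leadfield: LeadField,
    source_activity: SourceActivity | np.ndarray,
    sensor_noise_sd: float = 0.0,
    seed: int | None = None,
    fs: float | None = None,
) -> SensorRecording:
    """Forward-project sources and add white sensor noise.

    Accepts either a :class:`SourceActivity` (scalar activity with fixed
    orientations) or the dense (n_voxels, 3, n_samples) moment array.
    """
    m, cols = leadfield.matrix.shape
    V = cols // 3
    if isinstance(source_activity, SourceActivity):
        if source_activity.n_voxels != V:
            raise ValueError("source count does not match leadfield")
        # effective gain of each voxel's fixed orientation
        Leff = np.einsum("mvi,vi->mv", leadfield.matrix.reshape(m, V, 3),
                         source_activity.orientations)
        data = Leff @ source_activity.activity
        fs = source_activity.fs
    else:
        src = np.asarray(source_activity)
        if src.ndim != 3 or src.shape[0] != V or src.shape[1] != 3:
            raise ValueError("dense sources must be (n_voxels, 3, n_samples)")
        data = leadfield.matrix @ src.reshape(V * 3, -1)
        if fs is None:
            raise ValueError("fs required when passing a dense source array")
    if sensor_noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(scale=sensor_noise_sd, size=data.shape)
    labels = [f"E{i+1:03d}" for i in range(m)]
    return SensorRecording(data=data, fs=fs, labels=labels,
                           positions=leadfield.sensor_positions)


# ---------------------------------------------------------------------------
# MR-environment artifacts
# ---------------------------------------------------------------------------

def _gradient_epoch(tr_samples: int, slices_per_tr: int) -> np.ndarray:
    """One TR of gradient waveform: a sharp shape repeated at the slice rate."""
    slice_len = tr_samples // slices_per_tr
    t = np.arange(slice_len) / slice_len
    shape = (signal.sawtooth(2 * np.pi * 3 * t, width=0.2)
             + 0.6 * np.sin(2 * np.pi * 7 * t + 1.0)
             + 0.4 * np.sin(2 * np.pi * 11 * t))
    epoch = np.tile(shape, slices_per_tr)
    if len(epoch) < tr_samples:
        epoch = np.concatenate([epoch, epoch[: tr_samples - len(epoch)]])
    return epoch / np.sqrt(np.mean(epoch**2))


def _bcg_shape(fs: float, window: tuple[float, float] = (-0.2, 0.6)) -> np.ndarray:
    """Pulse-artifact waveform on the R-peak-locked window."""
    t = np.arange(int(round((window[1] - window[0]) * fs))) / fs + window[0]
    w = (np.exp(-((t - 0.15) / 0.05) ** 2)
         - 0.6 * np.exp(-((t - 0.30) / 0.08) ** 2)
         + 0.3 * np.exp(-((t - 0.45) / 0.10) ** 2))
    return w / np.sqrt(np.mean(w**2))


def add_mr_artifacts(
    rec: SensorRecording,
    tr_s: float = 2.0,
    slices_per_tr: int = 10,
    cardiac_bpm: float = 60.0,
    jitter_ms: float = 40.0,
    amp_cfg: dict[str, float] | None = None,
    seed: int | None = None,
    ground_truth: GroundTruth | None = None,
) -> SensorRecording:
    """Contaminate a clean recording with MR-environment artifacts.

    Adds (i) a gradient artifact exactly periodic at the slice rate with
    onsets stored in ``tr_markers``; (ii) a ballistocardiogram locked to
    ``cardiac_markers`` with per-beat timing jitter and slow amplitude
    drift; (iii) blink transients weighted to frontal sensors; and (iv)
    band-limited myogenic bursts weighted to rim sensors. Amplitudes are
    multiples of the clean recording RMS; an amplitude of 0 disables that
    artifact, a negative amplitude is an error.
    """
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    if not 40.0 <= cardiac_bpm <= 120.0:
        raise ValueError("cardiac rate must lie in [40, 120] bpm")
    amps = {**DEFAULT_ARTIFACT_AMPLITUDES, **(amp_cfg or {})}
    if any(a < 0 for a in amps.values()):
        raise ValueError("artifact amplitudes must be nonnegative")

    rng = np.random.default_rng(seed)
    fs = rec.fs
    n_ch, n = rec.n_channels, rec.n_samples
    rms = float(np.sqrt(np.mean(rec.data**2)))
    if rms == 0:
        rms = 1.0
    data = rec.data.copy()
    artifacts: dict[str, np.ndarray] = {}

    # (i) gradient: exactly epoch-periodic, onsets at TR markers
    tr_samples = int(round(tr_s * fs))
    tr_markers = np.arange(0, n - tr_samples + 1, tr_samples)
    if amps["gradient"] > 0:
        epoch = _gradient_epoch(tr_samples, slices_per_tr)
        gains = amps["gradient"] * rms * (0.8 + 0.4 * rng.random(n_ch))
        art = np.zeros_like(data)
        for m0 in tr_markers:
            art[:, m0:m0 + tr_samples] = gains[:, None] * epoch
        data += art
        artifacts["gradient"] = art

    # (ii) BCG: marker-locked with jitter and amplitude drift
    beat = 60.0 / cardiac_bpm
    nominal = np.arange(beat, n / fs - 0.8, beat)
    jitter = rng.normal(scale=jitter_ms / 1000.0, size=nominal.shape)
    times = np.sort(nominal + jitter)
    cardiac_markers = np.unique((times * fs).round().astype(int))
    cardiac_markers = cardiac_markers[(cardiac_markers >= 0) & (cardiac_markers < n)]
    if amps["bcg"] > 0:
        shape = _bcg_shape(fs)
        L = len(shape)
        start_off = int(round(-0.2 * fs))
        gains = amps["bcg"] * rms * (0.7 + 0.6 * rng.random(n_ch))
        art = np.zeros_like(data)
        for i, mk in enumerate(cardiac_markers):
            lag = int(round(rng.uniform(-jitter_ms / 2, jitter_ms / 2) / 1000.0 * fs))
            drift = 1.0 + 0.3 * np.sin(2 * np.pi * mk / fs / 60.0) + 0.1 * rng.standard_normal()
            s = mk + start_off + lag
            e = s + L
            if s < 0 or e > n:
                continue
            art[:, s:e] += gains[:, None] * drift * shape
        data += art
        artifacts["bcg"] = art

    roles = montage_roles(rec.positions)

    # (iii) EOG blinks on frontal sensors
    if amps["eog"] > 0:
        w_ch = np.zeros(n_ch)
        w_ch[roles["frontal"]] = 1.0
        y = rec.positions[:, 1]
        w_ch *= 0.5 + 0.5 * (y - y.min()) / (np.ptp(y) + 1e-12)
        blink = np.hanning(int(round(0.4 * fs)))
        n_blinks = max(1, rng.poisson(0.25 * n / fs))
        starts = rng.integers(0, n - len(blink), size=n_blinks)
        trace = np.zeros(n)
        for s in starts:
            trace[s:s + len(blink)] += blink
        art = amps["eog"] * rms * np.outer(w_ch, trace)
        data += art
        artifacts["eog"] = art

    # (iv) EMG bursts on rim sensors
    if amps["emg"] > 0:
        w_ch = np.zeros(n_ch)
        w_ch[roles["rim"]] = 1.0
        burst_len = int(round(1.0 * fs))
        n_bursts = max(1, rng.poisson(0.1 * n / fs))
        trace = np.zeros(n)
        hi = min(80.0, 0.45 * fs)
        for s in rng.integers(0, n - burst_len, size=n_bursts):
            trace[s:s + burst_len] += (_bandpass_noise(burst_len, fs, 30.0, hi, rng)
                                       * np.hanning(burst_len))
        art = amps["emg"] * rms * np.outer(w_ch, trace)
        data += art
        artifacts["emg"] = art

    if ground_truth is not None:
        ground_truth.artifact_signals.update(artifacts)

    out = rec.with_data(data)
    out.tr_markers = tr_markers
    out.cardiac_markers = cardiac_markers
    return out


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def simulate_bold(
    ground_truth: GroundTruth,
    grid: SourceGrid,
    tr_s: float = 2.0,
    n_volumes: int | None = None,
    noise_sd: float = 0.5,
    drift_amp: float = 0.3,
    seed: int | None = None,
    grid_ref: str = "",
) -> VolumeSeries:
    """BOLD = network-weighted HRF-convolved envelope + drift + noise.

    The 1 Hz ground-truth envelope of each network is convolved with the
    canonical HRF, standardised to unit variance, weighted by the network
    map and sampled at t_j = j·tr. Drift is a random 2nd-order Legendre
    polynomial per voxel scaled by ``drift_amp``; noise is white with
    ``noise_sd``. Both are in units of the (unit-variance) neural signal.
    """
    K, T = ground_truth.envelopes.shape
    if n_volumes is None:
        n_volumes = int(np.floor(T / tr_s))
    if n_volumes * tr_s > T + 1e-9:
        raise ValueError("requested volumes exceed the envelope duration")
    rng = np.random.default_rng(seed)

    kernel = canonical_hrf(dt=1.0)
    t_j = np.arange(n_volumes) * tr_s
    sec = np.arange(T, dtype=float)
    conv_tr = np.empty((K, n_volumes))
    for k in range(K):
        conv = hrf_convolve(ground_truth.envelopes[k], kernel)
        sd = conv.std()
        if sd > 0:
            conv = (conv - conv.mean()) / sd
        conv_tr[k] = np.interp(t_j, sec, conv)

    values = ground_truth.network_maps @ conv_tr
    if drift_amp > 0:
        basis = np.stack([
            legendre.legval(np.linspace(-1, 1, n_volumes), [0] * d + [1])
            for d in range(3)
        ])
        # heavy-tailed spatial distribution of drift amplitude (scanner
        # drift concentrates near edges/susceptibility regions rather than
        # spreading Gaussian-like over the volume)
        coef = rng.laplace(scale=drift_amp / np.sqrt(2.0),
                           size=(grid.n_voxels, 3))
        values = values + coef @ basis
    if noise_sd > 0:
        values = values + rng.normal(scale=noise_sd, size=values.shape)
    return VolumeSeries(values=values, tr=tr_s, grid_ref=grid_ref)
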