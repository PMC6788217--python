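"""eLORETA source reconstruction and band-limited power time-courses.

The inverse is the exact low-resolution electromagnetic tomography
operator: a weighted minimum-norm solution whose per-voxel 3×3 weight
blocks are refined by a fixed-point iteration until self-consistent, which
gives the estimator its zero-localization-error property for point
sources. Power is computed with a short-time Fourier transform (2 s
Hamming window, 50% overlap, i.e. one frame per second) and aggregated
into the canonical EEG bands; the three orientation powers of each voxel
are summed.
"""

from __future__ import annotations

import numpy as np

from .containers import BandPowerSeries, InverseOperator, LeadField, SensorRecording, SourceActivity

__all__ = [
    "BANDS",
    "compute_eloreta_operator",
    "apply_inverse",
    "compute_band_power",
    "band_power_from_recording",
    "resolution_smeared_map",
    "stft_power",
    "band_bin_mask",
]

#: Canonical band edges in Hz. Bands are half-open [lo, hi) so that a shared
#: printed edge belongs to the higher band (13 Hz is beta, 8 Hz is alpha);
#: the upper edge 80 Hz closes the gamma and full bands inclusively.
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
    "full": (1.0, 80.0),
}

#: Column order used in report tables.
BAND_ORDER = ["full", "delta", "theta", "alpha", "beta", "gamma"]


def band_bin_mask(freqs: np.ndarray, f_lo: float, f_hi: float) -> np.ndarray:
    """Frequency-bin selector: [lo, hi), inclusive of hi at the 80 Hz edge."""
    sel = (freqs >= f_lo) & (freqs < f_hi)
    if f_hi >= 80.0:
        sel |= np.isclose(freqs, f_hi)
    return sel


# ---------------------------------------------------------------------------
# eLORETA
# ---------------------------------------------------------------------------

def _sqrtm_psd(blocks: np.ndarray) -> np.ndarray:
    """Symmetric square roots of a stack of symmetric PSD 3×3 matrices."""
    lam, vec = np.linalg.eigh(blocks)
    lam = np.clip(lam, 0.0, None)
    return np.einsum("vij,vj,vkj->vik", vec, np.sqrt(lam), vec)


def compute_eloreta_operator(
    leadfield: LeadField,
    alpha_reg: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> InverseOperator:
    """Iterate the eLORETA weight fixed point and assemble the inverse.

    At each iteration the sensor-space matrix ``C = Σ_v K_v W_v⁻¹ K_vᵀ`` is
    regularized by ``alpha_reg`` times its mean eigenvalue (on the
    average-reference subspace) and pseudo-inverted; each voxel weight is
    then replaced by the symmetric square root of ``K_vᵀ M K_v``. Iteration
    stops when the largest relative Frobenius change of any weight block
    falls below ``tol``.
    """
    K = leadfield.matrix
    if leadfield.reference != "average":
        raise ValueError("eLORETA requires an average-referenced leadfield")
    m = leadfield.n_sensors
    V = leadfield.n_voxels
    Kv = K.reshape(m, V, 3).transpose(1, 0, 2)          # (V, m, 3)
    H = np.eye(m) - np.full((m, m), 1.0 / m)            # average-reference projector

    W = np.tile(np.eye(3), (V, 1, 1))
    n_iter = 0
    converged = False
    trace = []
    for n_iter in range(1, max_iter + 1):
        Winv = np.linalg.inv(W)
        C = np.einsum("vmi,vij,vnj->mn", Kv, Winv, Kv, optimize=True)
        alpha = alpha_reg * np.trace(C) / m
        M = np.linalg.pinv(C + alpha * H, hermitian=True)
        A = np.einsum("vmi,mn,vnj->vij", Kv, M, Kv, optimize=True)
        W_new = _sqrtm_psd(A)
        num = np.linalg.norm(W_new - W, axis=(1, 2))
        den = np.linalg.norm(W, axis=(1, 2))
        delta = float(np.max(num / den))
        trace.append(delta)
        W = W_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"eLORETA weights did not converge in {max_iter} iterations; "
            f"relative-change trace tail: {trace[-5:]}"
        )

    Winv = np.linalg.inv(W)
    KtM = np.einsum("vmi,mn->vin", Kv, M, optimize=True)     # (V, 3, m)
    T = np.einsum("vij,vjm->vim", Winv, KtM, optimize=True)  # (V, 3, m)
    return InverseOperator(
        weights=W,
        operator=T.reshape(V * 3, m),
        alpha_reg=alpha_reg,
        n_iter=n_iter,
        converged=True,
    )


def apply_inverse(op: InverseOperator, rec: SensorRecording) -> np.ndarray:
    """Project sensor data to source space: (n_voxels, 3, n_samples)."""
    if rec.n_channels != op.operator.shape[1]:
        raise ValueError("channel count does not match the inverse operator")
    s = op.operator @ rec.data
    return s.reshape(op.n_voxels, 3, rec.n_samples)


def resolution_smeared_map(op: InverseOperator, leadfield: LeadField,
                           source_map: np.ndarray) -> np.ndarray:
    """Expected source-power profile of a network map as the inverse sees it.

    A linear inverse has a finite point-spread: power generated at voxel u
    appears at voxel v with gain ``||T_v K_u||²`` (averaged over dipole
    orientation). Smearing a source-space network map through this
    resolution kernel yields the template appropriate for matching maps
    obtained *through* the inverse — the analogue of using a template
    derived from the same imaging modality rather than from anatomy.
    """
    V = op.n_voxels
    T = op.operator.reshape(V, 3, -1)                  # (V, 3, m)
    K = leadfield.matrix.reshape(-1, V, 3)             # (m, V, 3)
    # R[v, u] = ||T_v K_u||_F^2 / 3 (orientation-averaged power gain)
    G = np.einsum("vim,muj->vuij", T, K, optimize=True)
    R = (G**2).sum(axis=(2, 3)) / 3.0
    m2 = np.asarray(source_map, dtype=np.float64) ** 2
    return R @ m2


# ---------------------------------------------------------------------------
# STFT band power
# ---------------------------------------------------------------------------

def _stft_params(fs: float):
    nperseg = int(round(2.0 * fs))
    hop = int(round(fs))
    window = np.hamming(nperseg)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return nperseg, hop, window, freqs


def stft_coefficients(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Complex STFT frames of the trailing axis (2 s Hamming, 50% overlap).

    Returns ``(coeffs, freqs)`` where coeffs has shape
    ``x.shape[:-1] + (n_bins, n_frames)`` and frame ``t`` is centered at
    ``t + 1`` seconds.
    """
    x = np.asarray(x)
    nperseg, hop, window, freqs = _stft_params(fs)
    n = x.shape[-1]
    if n < nperseg:
        raise ValueError("need at least 2 s of data for the 2 s analysis window")
    n_frames = (n - nperseg) // hop + 1
    idx = hop * np.arange(n_frames)[:, None] + np.arange(nperseg)[None, :]
    frames = x[..., idx] * window                  # (..., n_frames, nperseg)
    coeffs = np.fft.rfft(frames, axis=-1)          # (..., n_frames, n_bins)
    return np.moveaxis(coeffs, -1, -2), freqs      # (..., n_bins, n_frames)


def stft_power(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Periodogram power of each STFT frame; shape (..., n_bins, n_frames)."""
    coeffs, freqs = stft_coefficients(x, fs)
    return np.abs(coeffs) ** 2, freqs


def compute_band_power(
    sources: np.ndarray | SourceActivity,
    fs: float,
    bands: dict[str, tuple[float, float]] | None = None,
    chunk: int = 48,
) -> list[BandPowerSeries]:
    """Band-limited power per voxel, orientation powers summed.

    ``sources`` is the (n_voxels, 3, n_samples) moment array from
    :func:`apply_inverse` (a :class:`SourceActivity` is densified first).
    Band power of a frame is the mean periodogram power over the bins whose
    center frequency falls in the band.
    """
    if isinstance(sources, SourceActivity):
        sources = sources.dense()
    sources = np.asarray(sources)
    if sources.ndim != 3 or sources.shape[1] != 3:
        raise ValueError("sources must be (n_voxels, 3, n_samples)")
    bands = dict(bands or BANDS)
    for name, (lo, hi) in bands.items():
        if hi > fs / 2:
            raise ValueError(f"band {name!r} upper edge {hi} Hz exceeds Nyquist")

    V = sources.shape[0]
    _, _, _, freqs = _stft_params(fs)
    sels = {name: band_bin_mask(freqs, lo, hi) for name, (lo, hi) in bands.items()}
    out = {name: [] for name in bands}
    for start in range(0, V, chunk):
        block = sources[start:start + chunk]
        power, _ = stft_power(block, fs)              # (v, 3, bins, frames)
        total = power.sum(axis=1)                     # orientation sum
        for name, sel in sels.items():
            out[name].append(total[:, sel, :].mean(axis=1))
    return [
        BandPowerSeries(
            values=np.concatenate(out[name], axis=0),
            band=name,
            f_lo=bands[name][0],
            f_hi=bands[name][1],
        )
        for name in bands
    ]


def band_power_from_recording(
    op: InverseOperator,
    rec: SensorRecording,
    bands: dict[str, tuple[float, float]] | None = None,
    voxels: np.ndarray | None = None,
    chunk: int = 32,
) -> list[BandPowerSeries]:
    """Source band power straight from sensor STFT coefficients.

    The STFT is linear in the signal, so the source-space coefficients are
    the inverse operator applied to the sensor coefficients; this equals
    the explicit :func:`apply_inverse` → :func:`compute_band_power` route
    without materialising the source time series. ``voxels`` restricts the
    output to a subset (e.g. the gray-matter mask).
    """
    bands = dict(bands or BANDS)
    for name, (lo, hi) in bands.items():
        if hi > rec.fs / 2:
            raise ValueError(f"band {name!r} upper edge {hi} Hz exceeds Nyquist")
    coeffs, freqs = stft_coefficients(rec.data, rec.fs)   # (m, bins, frames)
    sels = {name: band_bin_mask(freqs, lo, hi) for name, (lo, hi) in bands.items()}
    V = op.n_voxels
    idx = np.arange(V) if voxels is None else np.asarray(voxels)
    T3 = op.operator.reshape(V, 3, -1)
    out = {name: [] for name in bands}
    for start in range(0, len(idx), chunk):
        sub = idx[start:start + chunk]
        src = np.tensordot(T3[sub], coeffs, axes=([2], [0]))  # (v, 3, bins, frames)
        total = (np.abs(src) ** 2).sum(axis=1)
        for name, sel in sels.items():
            out[name].append(total[:, sel, :].mean(axis=1))
    return [
        BandPowerSeries(
            values=np.concatenate(out[name], axis=0),
            band=name,
            f_lo=bands[name][0],
            f_hi=bands[name][1],
        )
        for name in bands
    ]
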