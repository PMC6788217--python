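"""EEG-derived hemodynamic regressors and voxelwise BOLD correlation.

A neural power time-course (occipital sensor alpha power, or the
time-course of an ICA-derived network) is convolved with the canonical
double-gamma hemodynamic response function and correlated voxel by voxel
with the BOLD series, previously upsampled to the 1 Hz resolution of the
power frames. Correlations are Fisher r-to-z transformed.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

from .containers import HRFKernel, SensorRecording, VolumeSeries, ZMap
from .source import BANDS, band_bin_mask, stft_power
from .stats import fisher_z

__all__ = [
    "canonical_hrf",
    "occipital_power_regressor",
    "hrf_convolve",
    "upsample_bold",
    "correlate_voxelwise",
]

#: Canonical HRF parameters: response/undershoot gamma delays (s),
#: dispersions (s), peak:undershoot ratio, kernel length (s).
HRF_PARAMS = {
    "delay_response": 6.0,
    "delay_undershoot": 16.0,
    "dispersion_response": 1.0,
    "dispersion_undershoot": 1.0,
    "ratio": 6.0,
    "length": 32.0,
}


def canonical_hrf(dt: float, params: dict | None = None) -> HRFKernel:
    """Difference-of-gammas canonical HRF on [0, length], peak-normalized.

    With unit dispersion the response gamma has shape 6 and mode
    (shape−1)·scale = 5 s, which fixes the kernel peak at t = 5 s.
    """
    if not 0 < dt <= 1:
        raise ValueError("dt must lie in (0, 1]")
    p = {**HRF_PARAMS, **(params or {})}
    t = np.arange(0.0, p["length"] + dt / 2, dt)
    main = sps.gamma.pdf(t, a=p["delay_response"] / p["dispersion_response"],
                         scale=p["dispersion_response"])
    under = sps.gamma.pdf(t, a=p["delay_undershoot"] / p["dispersion_undershoot"],
                          scale=p["dispersion_undershoot"])
    h = main - under / p["ratio"]
    h = h / h.max()
    return HRFKernel(samples=h, dt=dt, params=p)


def occipital_power_regressor(
    clean_rec: SensorRecording,
    channel_names: list[str],
    band: str = "alpha",
) -> np.ndarray:
    """Band power (1 Hz frames) of the average of the named channels.

    Mirrors the sensor-level analysis: the selected channels are averaged
    into a single trace, then passed through the same 2 s Hamming / 50%
    overlap short-time Fourier engine used for source power.
    """
    if not channel_names:
        raise ValueError("at least one channel name required")
    index = {lab: i for i, lab in enumerate(clean_rec.labels)}
    missing = [c for c in channel_names if c not in index]
    if missing:
        raise ValueError(f"channels not found in recording: {missing}")
    trace = clean_rec.data[[index[c] for c in channel_names]].mean(axis=0)
    power, freqs = stft_power(trace, clean_rec.fs)
    lo, hi = BANDS[band] if isinstance(band, str) else band
    sel = band_bin_mask(freqs, lo, hi)
    return power[sel, :].mean(axis=0)


def hrf_convolve(timecourse: np.ndarray, kernel: HRFKernel) -> np.ndarray:
    """Causal convolution with the HRF, truncated to the input length.

    The first ``kernel.duration`` seconds of the output are convolution
    burn-in and should be excluded from correlation (see
    :func:`correlate_voxelwise`).
    """
    timecourse = np.asarray(timecourse, dtype=np.float64)
    return np.convolve(timecourse, kernel.samples)[: len(timecourse)]


def upsample_bold(vol: VolumeSeries, to_rate: float = 1.0) -> VolumeSeries:
    """Per-voxel linear interpolation onto the ``to_rate`` grid.

    The output grid spans the original extent: samples at
    t = 0, 1/rate, …, (n_volumes−1)·tr, giving
    ``floor((n_volumes−1)·tr·rate) + 1`` points.
    """
    t_orig = np.arange(vol.n_volumes) * vol.tr
    t_new = np.arange(0.0, t_orig[-1] + 0.5 / to_rate, 1.0 / to_rate)
    out = np.empty((vol.n_voxels, len(t_new)))
    for v in range(vol.n_voxels):
        out[v] = np.interp(t_new, t_orig, vol.values[v])
    return VolumeSeries(values=out, tr=1.0 / to_rate, grid_ref=vol.grid_ref)


def correlate_voxelwise(
    regressor: np.ndarray,
    bold_1hz: VolumeSeries,
    burn_in_s: float = 32.0,
    subject_id: str = "",
    band: str = "",
    regressor_kind: str = "network_ic",
) -> ZMap:
    """Pearson correlation of the regressor with every voxel, Fisher z.

    Series are aligned by truncation to the common length; the first
    ``burn_in_s`` seconds (the HRF convolution transient) are dropped.
    """
    regressor = np.asarray(regressor, dtype=np.float64)
    rate = 1.0 / bold_1hz.tr
    n = min(len(regressor), bold_1hz.n_volumes)
    skip = int(round(burn_in_s * rate))
    if n - skip < 30:
        raise ValueError("need at least 30 overlapping samples after burn-in")
    x = regressor[skip:n]
    Y = bold_1hz.values[:, skip:n]
    if x.std() == 0:
        raise ValueError("degenerate regressor (zero variance)")
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    y_sd = np.sqrt((Yc**2).sum(axis=1))
    r = np.zeros(bold_1hz.n_voxels)
    ok = y_sd > 0
    r[ok] = (Yc[ok] @ xc) / (y_sd[ok] * np.sqrt((xc**2).sum()))
    if np.any(~ok):
        warnings.warn("constant BOLD voxel(s); correlation set to 0")
    return ZMap(z=fisher_z(r), subject_id=subject_id, band=band,
                regressor_kind=regressor_kind)
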