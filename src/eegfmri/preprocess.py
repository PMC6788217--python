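"""MR-environment EEG cleaning.

Order of operations mirrors standard simultaneous-EEG–fMRI practice:
gradient-artifact removal (average artifact subtraction plus an
optimal-basis-set residual fit), ballistocardiogram removal (R-peak-locked
optimal basis set), bad-channel detection and interpolation, 1–80 Hz
band-pass filtering, ICA-based rejection of ocular/myogenic components,
and average re-referencing.

The template-subtraction operators here are the non-adaptive AAS+OBS
variants: epoch the data on the artifact markers, subtract a sliding
average of neighboring epochs (gradient) and a per-epoch least-squares fit
of the leading principal components of the epoch matrix (both). They are
reproducible, marker-driven, and leave samples outside the epochs
untouched.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal, stats as sps

from .containers import CleaningReport, ICDecomposition, SensorRecording

__all__ = [
    "remove_gradient_artifact",
    "remove_bcg_artifact",
    "detect_r_peaks",
    "detect_bad_channels",
    "interpolate_channels",
    "bandpass_filter",
    "classify_artifact_ics",
    "remove_ics_and_rereference",
    "IC_THRESHOLDS",
]

#: Default artifact-IC classifier thresholds: absolute correlation with the
#: EOG/EMG references, excess kurtosis of the IC time-course, and the
#: minimum similarity of the IC spectrum to a fitted 1/f^β line below which
#: the component is considered artifactual.
IC_THRESHOLDS = {"eog_corr": 0.3, "emg_corr": 0.3, "kurtosis": 10.0, "spec_1f_sim": 0.5}


def _epoch_matrix(x: np.ndarray, starts: np.ndarray, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack epochs of ``length`` samples from channel-major data.

    Returns (epochs, starts_kept) with epochs shaped
    (n_channels, n_epochs, length); epochs extending past the record are
    dropped.
    """
    n = x.shape[1]
    keep = starts[(starts >= 0) & (starts + length <= n)]
    idx = keep[:, None] + np.arange(length)[None, :]
    return x[:, idx], keep


def _obs_fit(epochs: np.ndarray, n_pcs: int, center: bool) -> np.ndarray:
    """Per-epoch least-squares fit of the top PCs of an epoch matrix.

    ``epochs`` is (n_epochs, length) for one channel. With ``center`` the
    basis comes from the epoch matrix after removing the mean epoch
    (residual PCA, gradient case); without, the leading singular vectors of
    the raw matrix absorb the mean artifact shape as well (BCG case).
    """
    if n_pcs <= 0:
        return np.zeros_like(epochs)
    E = epochs - epochs.mean(axis=0) if center else epochs
    n_pcs = min(n_pcs, min(E.shape))
    _, _, vt = np.linalg.svd(E, full_matrices=False)
    basis = vt[:n_pcs]                        # (n_pcs, length), orthonormal
    return (epochs @ basis.T) @ basis


def remove_gradient_artifact(
    rec: SensorRecording,
    n_avg_epochs: int = 20,
    n_obs_pcs: int = 3,
) -> tuple[SensorRecording, CleaningReport]:
    """Average-artifact subtraction + OBS on TR-marker epochs.

    Each channel is epoched on ``tr_markers``; every epoch has the average
    of its ``n_avg_epochs`` nearest neighboring epochs (itself excluded)
    subtracted, after which the top ``n_obs_pcs`` principal components of
    the residual epoch matrix are fitted and removed per epoch. Samples
    outside the epochs are untouched.
    """
    if rec.tr_markers.size == 0:
        raise ValueError("gradient markers required")
    length = int(np.min(np.diff(rec.tr_markers))) if rec.tr_markers.size > 1 \
        else rec.n_samples - rec.tr_markers[0]
    epochs, starts = _epoch_matrix(rec.data, rec.tr_markers, length)
    n_ch, n_ep, _ = epochs.shape
    if n_avg_epochs > n_ep - 1:
        warnings.warn("n_avg_epochs exceeds available neighbors; using all")
        n_avg_epochs = n_ep - 1
    if n_ep < 2 * min(n_avg_epochs, n_ep - 1) and n_ep < 4:
        raise ValueError("too few TR epochs for sliding-average subtraction")

    # sliding-average templates: nearest n_avg epochs excluding the current
    templates = np.empty_like(epochs)
    half = n_avg_epochs // 2
    for j in range(n_ep):
        lo = max(0, min(j - half, n_ep - n_avg_epochs - 1))
        neigh = [i for i in range(lo, min(n_ep, lo + n_avg_epochs + 1)) if i != j]
        neigh = neigh[:n_avg_epochs] if n_avg_epochs < len(neigh) else neigh
        templates[:, j, :] = epochs[:, neigh, :].mean(axis=1)

    residual = epochs - templates
    cleaned = np.empty_like(residual)
    for c in range(n_ch):
        cleaned[c] = residual[c] - _obs_fit(residual[c], n_obs_pcs, center=True)

    data = rec.data.copy()
    idx = starts[:, None] + np.arange(length)[None, :]
    for c in range(n_ch):
        data[c, idx] = cleaned[c]
    out = rec.with_data(data)
    report = CleaningReport(
        step="gradient_aas_obs",
        residual_variance={lab: float(v) for lab, v in zip(rec.labels, data.var(axis=1))},
    )
    return out, report


def remove_bcg_artifact(
    rec: SensorRecording,
    n_obs_pcs: int = 3,
    window: tuple[float, float] = (-0.2, 0.6),
) -> tuple[SensorRecording, CleaningReport]:
    """Optimal-basis-set removal of the pulse artifact.

    Epochs run from ``window[0]`` to ``window[1]`` seconds around each
    cardiac marker (R peak). Per channel, the leading ``n_obs_pcs``
    singular vectors of the raw epoch matrix (which absorb the mean pulse
    shape plus its amplitude/lag variation) are fitted per epoch and
    subtracted. With 0 PCs the recording is returned unchanged.
    """
    if rec.cardiac_markers.size == 0:
        raise ValueError("cardiac markers required; run detect_r_peaks first")
    fs = rec.fs
    length = int(round((window[1] - window[0]) * fs))
    starts = rec.cardiac_markers + int(round(window[0] * fs))
    epochs, kept = _epoch_matrix(rec.data, starts, length)
    if epochs.shape[1] < 10:
        raise ValueError("need at least 10 cardiac epochs")
    data = rec.data.copy()
    idx = kept[:, None] + np.arange(length)[None, :]
    for c in range(rec.n_channels):
        fit = _obs_fit(epochs[c], n_obs_pcs, center=False)
        data[c, idx] = epochs[c] - fit
    out = rec.with_data(data)
    report = CleaningReport(
        step="bcg_obs",
        residual_variance={lab: float(v) for lab, v in zip(rec.labels, data.var(axis=1))},
    )
    return out, report


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """R-peak indices from a single-channel ECG trace.

    Band-pass 5–20 Hz, square, then peak detection with a 0.5 s refractory
    period and an amplitude floor relative to the largest deflection. A
    flat trace yields no peaks.
    """
    ecg = np.asarray(ecg, dtype=np.float64)
    if len(ecg) < 10 * fs:
        raise ValueError("need at least 10 s of ECG")
    sos = signal.butter(4, [5.0, min(20.0, 0.45 * fs)], btype="bandpass",
                        fs=fs, output="sos")
    sq = signal.sosfiltfilt(sos, ecg) ** 2
    peak = sq.max()
    if peak <= 0:
        return np.empty(0, dtype=int)
    locs, _ = signal.find_peaks(sq, height=0.2 * peak, distance=int(round(0.5 * fs)))
    return locs.astype(int)


def detect_bad_channels(rec: SensorRecording) -> tuple[np.ndarray, CleaningReport]:
    """Flag channels whose correlation or noise-band variance is an outlier.

    Criterion A: mean Pearson correlation of each channel (1–80 Hz
    filtered) with all other channels. Criterion B: variance in the
    200–250 Hz band, where neural contribution is negligible; when the
    sampling rate puts that band above Nyquist the fallback band is
    0.4–0.5 of Nyquist (with a logged warning). A channel is bad if either
    statistic falls outside median ± 3·1.4826·MAD of its cross-channel
    distribution.
    """
    if rec.n_channels < 8:
        raise ValueError("need at least 8 channels")
    fs = rec.fs
    hi = min(80.0, 0.45 * fs)
    sos = signal.butter(4, [1.0, hi], btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, rec.data, axis=1)
    cmat = np.corrcoef(filt)
    np.fill_diagonal(cmat, np.nan)
    mean_corr = np.nanmean(cmat, axis=1)

    notes = []
    if fs >= 500.0:
        noise_band = (200.0, 250.0)
    else:
        nyq = fs / 2.0
        noise_band = (0.4 * nyq, 0.5 * nyq)
        notes.append(
            f"sampling rate {fs} Hz puts 200-250 Hz above Nyquist; "
            f"noise-variance band moved to {noise_band[0]:.1f}-{noise_band[1]:.1f} Hz"
        )
        warnings.warn(notes[-1])
    sos_n = signal.butter(4, noise_band, btype="bandpass", fs=fs, output="sos")
    noise_var = np.log10(signal.sosfiltfilt(sos_n, rec.data, axis=1).var(axis=1) + 1e-300)

    def _outliers(x):
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        return np.abs(x - med) > 3.0 * 1.4826 * mad

    bad_corr = _outliers(mean_corr)
    bad_var = _outliers(noise_var)
    flags = bad_corr | bad_var
    report = CleaningReport(
        step="bad_channels",
        residual_variance={lab: float(v) for lab, v in zip(rec.labels, rec.data.var(axis=1))},
        bad_channels=[
            (rec.labels[i],
             "correlation" if bad_corr[i] else "noise_variance")
            for i in np.nonzero(flags)[0]
        ],
        notes=notes,
    )
    return flags, report


def interpolate_channels(rec: SensorRecording, bad_flags: np.ndarray) -> SensorRecording:
    """Replace bad channels by inverse-distance-weighted good neighbors (k=4)."""
    bad_flags = np.asarray(bad_flags, dtype=bool)
    if bad_flags.sum() == 0:
        return rec.with_data(rec.data)
    if bad_flags.sum() >= 0.25 * rec.n_channels:
        raise ValueError("too many bad channels")
    data = rec.data.copy()
    good = np.nonzero(~bad_flags)[0]
    for b in np.nonzero(bad_flags)[0]:
        d = np.linalg.norm(rec.positions[good] - rec.positions[b], axis=1)
        order = np.argsort(d)[:4]
        w = 1.0 / np.maximum(d[order], 1e-9)
        w /= w.sum()
        data[b] = w @ rec.data[good[order]]
    out = rec.with_data(data)
    out.bad_flags = bad_flags.copy()
    return out


def bandpass_filter(rec: SensorRecording, lo: float = 1.0, hi: float = 80.0) -> SensorRecording:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward)."""
    if hi >= rec.fs / 2:
        raise ValueError("upper edge must lie below Nyquist")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=1))


def _one_over_f_similarity(x: np.ndarray, fs: float) -> float:
    """Correlation of the log-spectrum with its fitted 1/f^β line (2–40 Hz)."""
    nper = int(min(len(x), 4 * fs))
    freqs, pxx = signal.welch(x, fs=fs, nperseg=nper)
    sel = (freqs >= 2.0) & (freqs <= 40.0) & (pxx > 0)
    if sel.sum() < 4:
        return 0.0
    lf, lp = np.log10(freqs[sel]), np.log10(pxx[sel])
    if lp.std() == 0:
        return 0.0
    r = np.corrcoef(lf, lp)[0, 1]
    # fitted line = a + b·lf with sign(b) = sign(r); corr(fit, spectrum) = |r|
    return float(abs(r))


def classify_artifact_ics(
    decomp: ICDecomposition,
    eog_ref: np.ndarray,
    emg_ref: np.ndarray,
    fs: float,
    thresholds: dict | None = None,
) -> tuple[list[int], dict, CleaningReport]:
    """Score each IC against the four artifact criteria.

    An IC is flagged when |corr with the EOG reference| or |corr with the
    EMG reference| exceeds its threshold, when its power spectrum is a poor
    match to a 1/f^β line, or when its time-course has excess kurtosis
    beyond threshold. All scores are reported for every component.
    """
    thr = {**IC_THRESHOLDS, **(thresholds or {})}
    k, n = decomp.sources.shape
    for name, ref in (("EOG", eog_ref), ("EMG", emg_ref)):
        if len(ref) != n:
            raise ValueError(f"{name} reference length must match IC time-courses")

    def _abs_corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(abs(np.corrcoef(a, b)[0, 1]))

    scores = {
        "eog_corr": np.array([_abs_corr(s, eog_ref) for s in decomp.sources]),
        "emg_corr": np.array([_abs_corr(s, emg_ref) for s in decomp.sources]),
        "spec_1f_sim": np.array([_one_over_f_similarity(s, fs) for s in decomp.sources]),
        "kurtosis": np.array([float(sps.kurtosis(s)) for s in decomp.sources]),
    }
    flagged = [
        i for i in range(k)
        if scores["eog_corr"][i] > thr["eog_corr"]
        or scores["emg_corr"][i] > thr["emg_corr"]
        or scores["spec_1f_sim"][i] < thr["spec_1f_sim"]
        or scores["kurtosis"][i] > thr["kurtosis"]
    ]
    report = CleaningReport(step="ic_classification", removed_ic_ids=list(flagged),
                            ic_scores={k_: v.copy() for k_, v in scores.items()})
    return flagged, scores, report


def remove_ics_and_rereference(
    rec: SensorRecording,
    decomp: ICDecomposition,
    artifact_ids: list[int],
) -> SensorRecording:
    """Subtract artifact-IC contributions, then average-reference.

    The cleaned data are the recording minus the mixing-weighted artifact
    sources, re-referenced by removing the across-channel mean at every
    sample (so every output sample has zero channel mean).
    """
    artifact_ids = list(artifact_ids)
    if any(i < 0 or i >= decomp.k for i in artifact_ids):
        raise ValueError("artifact ids out of range")
    data = rec.data.copy()
    if artifact_ids:
        data -= decomp.mixing[:, artifact_ids] @ decomp.sources[artifact_ids]
    data -= data.mean(axis=0, keepdims=True)
    return rec.with_data(data)
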