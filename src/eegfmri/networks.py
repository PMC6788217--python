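"""Network detection: temporal ICA of band power, spatial ICA of BOLD.

The EEG route runs temporal ICA on a voxels × frames band-power matrix;
each component's spatial map is the per-voxel Pearson correlation of the
component time-course with that voxel's power series, Fisher r-to-z
transformed. The fMRI route runs spatial ICA on the volumes × voxels
matrix (voxels as observations, so the maps are the independent sources)
and z-scores each map across voxels. In both routes the network of
interest is the component whose map correlates best with a template.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

from .containers import BandPowerSeries, NetworkResult, VolumeSeries
from .ica import estimate_order_mdl, estimate_order_mp, fastica_deflation
from .stats import fisher_z

__all__ = ["detect_networks_tica", "detect_networks_sica", "match_template"]


def match_template(
    maps: np.ndarray,
    template_map: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[int, np.ndarray]:
    """Pearson correlation of each candidate map with the template.

    ``maps`` is (n_voxels, k). Correlations are computed within ``mask``;
    the selected component is the argmax, ties broken toward the lower
    index (with a warning).
    """
    maps = np.asarray(maps, dtype=np.float64)
    template_map = np.asarray(template_map, dtype=np.float64)
    if maps.shape[0] != template_map.shape[0]:
        raise ValueError("maps and template must live on the same grid")
    if mask is None:
        mask = np.ones(maps.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    t = template_map[mask]
    if t.std() == 0:
        raise ValueError("template has zero variance within the mask")
    r = np.empty(maps.shape[1])
    for i in range(maps.shape[1]):
        m = maps[mask, i]
        r[i] = 0.0 if m.std() == 0 else np.corrcoef(m, t)[0, 1]
    best = int(np.argmax(r))
    if np.sum(np.isclose(r, r[best])) > 1:
        warnings.warn("template-match tie; selecting the lowest component index")
    return best, r


def _corr_with_rows(timecourse: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Pearson r of one time-course against each row; 0 for constant rows."""
    x = timecourse - timecourse.mean()
    Y = rows - rows.mean(axis=1, keepdims=True)
    y_norm = np.sqrt((Y**2).sum(axis=1))
    r = np.zeros(rows.shape[0])
    ok = y_norm > 0
    if np.any(~ok):
        warnings.warn("constant series; correlation set to 0")
    denom = np.sqrt((x**2).sum())
    if denom == 0:
        return r
    r[ok] = (Y[ok] @ x) / (y_norm[ok] * denom)
    return r


def _auto_order(X: np.ndarray, k: int | None, cap: int, max_auto: int) -> int:
    """Automatic model order for the network decompositions.

    The MDL estimate is taken jointly with the Marchenko–Pastur
    signal-eigenvalue count: on short series (dimension comparable to the
    number of observations) the MDL asymptotics saturate at full order,
    while the random-matrix bound still separates signal from the noise
    bulk. The result is additionally capped at ``max_auto`` so the late
    deflation components stay well-conditioned. An explicit ``k`` bypasses
    all of this.
    """
    if k is not None:
        return int(k)
    k_est = min(estimate_order_mdl(X), estimate_order_mp(X))
    if k_est < 1:
        warnings.warn("estimated order 0; using a single component")
        k_est = 1
    return min(k_est, cap, max_auto)


def _fix_spatial_sign(zmaps: np.ndarray, timecourses: np.ndarray) -> None:
    """Flip components so each spatial map has positive skewness.

    Deterministic default orientation for decompositions run without a
    template (network blobs are right-skewed); falls back to making the
    largest-magnitude map value positive when skewness is numerically 0.
    """
    for i in range(zmaps.shape[1]):
        s = sps.skew(zmaps[:, i])
        flip = np.sign(s) if abs(s) > 1e-8 else \
            np.sign(zmaps[np.argmax(np.abs(zmaps[:, i])), i])
        if flip < 0:
            zmaps[:, i] *= -1
            timecourses[i] *= -1


def detect_networks_tica(
    power: BandPowerSeries,
    template: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    k: int | None = None,
    seed: int | None = 0,
    max_auto_order: int = 20,
    orient_template: np.ndarray | None = None,
) -> NetworkResult:
    """Temporal ICA on a band-power matrix with Fisher-z correlation maps.

    The model order defaults to the MDL estimate on the power matrix. Each
    IC time-course is correlated with every voxel's power series; the
    resulting map is Fisher-z transformed. When a template is supplied the
    best-matching component is selected.
    """
    X = power.values                           # (V, T)
    V, T = X.shape
    k_use = _auto_order(X, k, cap=min(V, T - 1), max_auto=max_auto_order)
    dec = fastica_deflation(X, k_use, seed=seed)
    # sign already fixed in the engine: mixing columns (voxel power
    # loadings) have positive skewness, so the correlation maps inherit a
    # deterministic orientation
    timecourses = dec.sources.copy()           # (k, T) temporally independent
    zmaps = np.empty((V, k_use))
    for i in range(k_use):
        zmaps[:, i] = fisher_z(_corr_with_rows(timecourses[i], X))
    result = NetworkResult(
        band=power.band,
        decomposition=dec,
        spatial_zmaps=zmaps,
        timecourses=timecourses,
        rate=power.rate,
    )
    _attach_template_match(result, template, mask, orient_template)
    return result


def _attach_template_match(result: NetworkResult, template, mask,
                           orient_template=None) -> None:
    """Orient components toward the template, then select the best match.

    ICA leaves a sign ambiguity per component that the loading-skewness
    convention cannot always resolve on small grids; each component is
    therefore flipped so its correlation with ``orient_template`` (the
    match template by default) is nonnegative before the argmax selection.
    Passing a sharper orientation template than the match template anchors
    the sign to the network core while the match may use a
    resolution-degraded map.
    """
    if template is None:
        return
    if orient_template is None:
        orient_template = template
    orient_template = np.asarray(orient_template, dtype=np.float64)
    core = orient_template >= 0.5 * orient_template.max()
    core_mean = result.spatial_zmaps[core].mean(axis=0)
    for i in np.nonzero(core_mean < 0)[0]:
        result.spatial_zmaps[:, i] *= -1
        result.timecourses[i] *= -1
    best, r = match_template(result.spatial_zmaps, template, mask)
    result.template_r = r
    result.selected_ic = best
    result.selected_r = float(r[best])


def detect_networks_sica(
    bold: VolumeSeries,
    template: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    k: int | None = None,
    seed: int | None = 0,
    max_auto_order: int = 20,
) -> NetworkResult:
    """Spatial ICA of a BOLD series with z-scored component maps.

    The data matrix is volumes × voxels, so the independent sources are
    spatial maps and the mixing columns are the associated TR-rate time
    courses. Each map is converted to z-scores by subtracting its mean
    across voxels and dividing by the standard deviation across voxels.
    """
    if bold.n_volumes < 30:
        raise ValueError("need at least 30 volumes")
    X = bold.values.T                          # (n_volumes, n_voxels)
    if np.allclose(bold.values.std(axis=1), 0):
        raise ValueError("degenerate data: BOLD is constant in time")
    k_use = _auto_order(X, k, cap=min(X.shape[0], X.shape[1]) - 1,
                        max_auto=max_auto_order)
    dec = fastica_deflation(X, k_use, seed=seed)
    maps = dec.sources.T.copy()                # (n_voxels, k) independent maps
    timecourses = dec.mixing.T.copy()          # (k, n_volumes)
    zmaps = (maps - maps.mean(axis=0)) / maps.std(axis=0)
    _fix_spatial_sign(zmaps, timecourses)
    result = NetworkResult(
        band="bold",
        decomposition=dec,
        spatial_zmaps=zmaps,
        timecourses=timecourses,
        rate=1.0 / bold.tr,
    )
    _attach_template_match(result, template, mask)
    return result
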