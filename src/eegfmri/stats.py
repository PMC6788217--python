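"""Group-level mass-univariate inference and spatial-overlap metrics.

One-sample one-sided t-tests over stacked subject Fisher-z maps, the
Benjamini–Yekutieli step-up procedure (valid under arbitrary dependence),
and the Pearson/Dice correspondence measures used to quantify how well two
network maps agree.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

from .containers import GroupMap, OverlapResult

__all__ = ["group_ttest", "by_fdr", "group_map", "overlap_metrics", "fisher_z"]


def fisher_z(r: np.ndarray | float, cap: float = 1.0 - 1e-12) -> np.ndarray | float:
    """Variance-stabilising transform z = atanh(r), with |r| clipped below 1."""
    return np.arctanh(np.clip(r, -cap, cap))


def group_ttest(zmaps: np.ndarray, side: str = "pos"):
    """One-sample t-test of stacked subject maps against zero, per voxel.

    Parameters
    ----------
    zmaps : ndarray, shape (n_subjects, n_voxels)
    side : {'pos', 'neg'}
        Direction of the one-sided alternative (mean > 0 or mean < 0).

    Returns
    -------
    t, p : ndarray
        t statistic (n-1 df) and one-sided p for the requested direction.
        Voxels with zero sample variance get the degenerate limit:
        p = 0 when the mean lies strictly in the tested direction, p = 1
        when it lies strictly against it, p = 0.5 when the mean is 0.
    """
    zmaps = np.asarray(zmaps, dtype=np.float64)
    if zmaps.ndim != 2 or zmaps.shape[0] < 3:
        raise ValueError("need at least 3 subjects stacked in rows")
    if side not in ("pos", "neg"):
        raise ValueError("side must be 'pos' or 'neg'")
    n = zmaps.shape[0]
    mean = zmaps.mean(axis=0)
    sd = zmaps.std(axis=0, ddof=1)
    sgn = 1.0 if side == "pos" else -1.0

    t = np.zeros_like(mean)
    p = np.full_like(mean, 0.5)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = sps.t.sf(sgn * t[ok], df=n - 1)
    degen = ~ok
    if np.any(degen):
        t[degen & (mean > 0)] = np.inf
        t[degen & (mean < 0)] = -np.inf
        p[degen & (sgn * mean > 0)] = 0.0
        p[degen & (sgn * mean < 0)] = 1.0
    return t, p


def by_fdr(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Yekutieli step-up rejection mask at FDR level ``q``.

    Sorts the m p-values ascending and rejects the k smallest where
    k = max{i : p(i) <= i·q / (m·c(m))} with c(m) = sum_{j=1..m} 1/j,
    the harmonic correction that makes the procedure valid under any
    dependence structure.
    """
    p = np.asarray(pvals, dtype=np.float64).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    thresholds = np.arange(1, m + 1) * q / (m * c_m)
    below = p[order] <= thresholds
    mask = np.zeros(m, dtype=bool)
    if np.any(below):
        k = np.max(np.nonzero(below)[0])
        mask[order[: k + 1]] = True
    return mask.reshape(np.shape(pvals))


def group_map(
    zmaps: np.ndarray,
    q: float = 0.05,
    scope: str = "voxels",
    band: str = "",
    joint_p_pos: np.ndarray | None = None,
    joint_p_neg: np.ndarray | None = None,
) -> GroupMap:
    """Full group result: two-sided t machinery run in both directions.

    When the multiple-comparison scope spans more than this map (e.g.
    voxels × bands), pass the jointly pooled p-value vectors via
    ``joint_p_pos``/``joint_p_neg``; the BY threshold is then derived from
    the pooled family and applied to this map's p-values.
    """
    t, p_pos = group_ttest(zmaps, side="pos")
    _, p_neg = group_ttest(zmaps, side="neg")

    def _mask(p_here, p_family):
        if p_family is None:
            return by_fdr(p_here, q)
        fam = np.asarray(p_family, dtype=np.float64).ravel()
        fam_mask = by_fdr(fam, q)
        if not np.any(fam_mask):
            return np.zeros_like(p_here, dtype=bool)
        thr = fam[fam_mask].max()
        return p_here <= thr

    return GroupMap(
        t=t,
        p_pos=p_pos,
        p_neg=p_neg,
        q=q,
        mask_pos=_mask(p_pos, joint_p_pos),
        mask_neg=_mask(p_neg, joint_p_neg),
        n_subjects=zmaps.shape[0],
        scope=scope,
        band=band,
    )


def overlap_metrics(
    map_a: np.ndarray,
    map_b: np.ndarray,
    mask: np.ndarray,
    bin_a: np.ndarray | None = None,
    bin_b: np.ndarray | None = None,
    z_thresh: float = 1.96,
    band: str = "",
) -> OverlapResult:
    """Pearson CC of unthresholded maps and Dice DC of binarized maps.

    CC is computed within ``mask`` on the raw values. DC uses the supplied
    binary masks when given (the default pipeline passes BY-FDR-significant
    positive masks), otherwise both maps are binarized at ``z_thresh``.
    If both binary sets are empty DC is defined as 0 with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty analysis mask")
    a = np.asarray(map_a, dtype=np.float64)[mask]
    b = np.asarray(map_b, dtype=np.float64)[mask]
    if a.std() == 0 or b.std() == 0:
        cc = 0.0
    else:
        cc = float(np.corrcoef(a, b)[0, 1])

    if bin_a is None:
        bin_a = np.asarray(map_a) > z_thresh
    if bin_b is None:
        bin_b = np.asarray(map_b) > z_thresh
    A = np.asarray(bin_a, dtype=bool) & mask
    B = np.asarray(bin_b, dtype=bool) & mask
    denom = A.sum() + B.sum()
    if denom == 0:
        warnings.warn("both binary maps are empty; Dice defined as 0")
        dc = 0.0
    else:
        dc = float(2.0 * np.sum(A & B) / denom)
    return OverlapResult(cc=cc, dc=dc, band=band)
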