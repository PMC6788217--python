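"""Shared ICA engine: MDL order selection and FastICA by deflation.

This is the numerical core used three times in the pipeline: rejection of
biological artifacts from sensor EEG, temporal ICA of band-power series,
and spatial ICA of BOLD volumes. The implementation is the classic
fixed-point algorithm with a hyperbolic-tangent contrast, one component at
a time with Gram–Schmidt decorrelation against the components already
found, preceded by PCA whitening to the requested order.

Conventions
-----------
Data matrices are ``dim × n_obs`` (variables in rows, observations in
columns). Sources have unit sample variance (1/n normalisation). The sign
of each component is fixed so that its mixing (loading) vector has positive
skewness, falling back to making the largest-magnitude loading positive
when the skewness is numerically zero; this makes downstream template
matching deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .containers import ICDecomposition

__all__ = ["estimate_order_mdl", "estimate_order_mp", "fastica_deflation",
           "amari_index"]


def _covariance_eigenvalues(data: np.ndarray) -> tuple[np.ndarray, int]:
    """Descending eigenvalues of the sample covariance and its numerical rank."""
    x = data - data.mean(axis=1, keepdims=True)
    cov = (x @ x.T) / x.shape[1]
    lam = np.linalg.eigvalsh(cov)[::-1]
    lam = np.clip(lam, 0.0, None)
    if lam[0] <= 0:
        return lam, 0
    rank = int(np.sum(lam > lam[0] * 1e-12))
    return lam, rank


def estimate_order_mdl(data_matrix: np.ndarray) -> int:
    """Wax–Kailath minimum-description-length model order.

    Evaluates ``MDL(k) = n (p-k) log(AM/GM of the p-k smallest eigenvalues)
    + k (2p - k)/2 · log n`` on the covariance eigenvalues and returns the
    minimising ``k``. For a rank-deficient covariance only ``k < rank`` is
    evaluated (with ``p`` replaced by the rank).

    Parameters
    ----------
    data_matrix : ndarray, shape (dim, n_obs)
        Observations in columns; requires ``n_obs > dim``.
    """
    data_matrix = np.asarray(data_matrix, dtype=np.float64)
    p, n = data_matrix.shape
    if n <= p:
        raise ValueError("MDL requires more observations than dimensions")
    lam, rank = _covariance_eigenvalues(data_matrix)
    if rank == 0:
        return 0
    lam = lam[:rank]
    p_eff = rank
    mdl = np.empty(p_eff)
    for k in range(p_eff):
        tail = lam[k:]
        m = p_eff - k
        log_gm = np.mean(np.log(tail))
        log_am = np.log(np.mean(tail))
        mdl[k] = n * m * (log_am - log_gm) + 0.5 * k * (2 * p_eff - k) * np.log(n)
    return int(np.argmin(mdl))


def estimate_order_mp(data_matrix: np.ndarray) -> int:
    """Signal count above the Marchenko–Pastur upper edge.

    Rows are standardized, and the number of correlation-matrix
    eigenvalues exceeding the pure-noise upper edge ``(1 + sqrt(p/n))²``
    is returned. This random-matrix bound stays meaningful in the short
    series regime (``p`` comparable to ``n``) where the MDL asymptotics
    saturate at full order; signal eigenvalues absorbing variance only
    shrink the noise bulk, so the count errs on the conservative side.
    """
    data_matrix = np.asarray(data_matrix, dtype=np.float64)
    p, n = data_matrix.shape
    if n <= 1:
        raise ValueError("need more than one observation")
    x = data_matrix - data_matrix.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    x = x / sd
    lam = np.linalg.eigvalsh((x @ x.T) / n)
    edge = (1.0 + np.sqrt(p / n)) ** 2
    return int(np.sum(lam > edge))


def _whiten(data: np.ndarray, k: int):
    """PCA-whiten rows of ``data`` down to ``k`` dimensions (1/n variance)."""
    mean = data.mean(axis=1, keepdims=True)
    x = data - mean
    n = x.shape[1]
    cov = (x @ x.T) / n
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1][:k]
    lam, vec = lam[order], vec[:, order]
    if np.any(lam <= 0) or lam[-1] < lam[0] * 1e-14:
        raise ValueError("requested order exceeds the numerical rank of the data")
    # fix eigenvector signs for reproducibility across LAPACK builds
    flip = np.sign(vec[np.argmax(np.abs(vec), axis=0), np.arange(k)])
    vec = vec * flip
    whitening = (vec / np.sqrt(lam)).T          # (k, dim)
    z = whitening @ x                            # cov(z) = I exactly
    return z, whitening, mean.ravel(), vec, lam


def fastica_deflation(
    data_matrix: np.ndarray,
    k: int,
    seed: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
    n_restarts: int = 10,
) -> ICDecomposition:
    """Deflationary FastICA with tanh nonlinearity on whitened data.

    Components are extracted one by one; a component that has not converged
    after ``max_iter`` fixed-point updates is restarted from a fresh random
    vector, up to ``n_restarts`` times, after which a ``RuntimeError`` naming
    the component index is raised. Restart attempts after the first use a
    damped update (the new direction averaged with the old one), which
    suppresses the two-cycle oscillation the plain iteration can fall into
    on nearly Gaussian directions. Deterministic given ``seed``.
    """
    data_matrix = np.asarray(data_matrix, dtype=np.float64)
    if not np.all(np.isfinite(data_matrix)):
        raise ValueError("data must be finite")
    dim, n = data_matrix.shape
    if not 1 <= k <= dim:
        raise ValueError("k must be in [1, dim]")
    rng = np.random.default_rng(seed)
    z, whitening, mean, vec, lam = _whiten(data_matrix, k)

    B = np.zeros((k, k))
    iterations = []
    for comp in range(k):
        converged = False
        for attempt in range(n_restarts + 1):
            w = rng.standard_normal(k)
            w -= B[:, :comp] @ (B[:, :comp].T @ w)
            nw = np.linalg.norm(w)
            if nw < 1e-12:
                continue
            w /= nw
            damping = 0.5 if attempt > 0 else 0.0
            for it in range(1, max_iter + 1):
                wx = w @ z
                g = np.tanh(wx)
                g_prime = 1.0 - g * g
                w_new = (z @ g) / n - g_prime.mean() * w
                w_new -= B[:, :comp] @ (B[:, :comp].T @ w_new)
                nw = np.linalg.norm(w_new)
                if nw < 1e-12:
                    break
                w_new /= nw
                if abs(abs(w_new @ w) - 1.0) < tol:
                    w = w_new
                    converged = True
                    break
                if damping:
                    # sign-align before averaging so the damped step is a
                    # contraction toward the fixed point, not the origin
                    w_new = (1 - damping) * w_new * np.sign(w_new @ w) + damping * w
                    w_new /= np.linalg.norm(w_new)
                w = w_new
            if converged:
                iterations.append(it)
                break
        if not converged:
            raise RuntimeError(
                f"FastICA component {comp} failed to converge after "
                f"{n_restarts} restarts"
            )
        B[:, comp] = w

    sources = B.T @ z                            # (k, n), unit variance rows
    mixing = (vec * np.sqrt(lam)) @ B            # (dim, k)

    # sign convention: positive skewness of the loading vector
    for i in range(k):
        s = stats.skew(mixing[:, i])
        if abs(s) > 1e-8:
            flip = np.sign(s)
        else:
            flip = np.sign(mixing[np.argmax(np.abs(mixing[:, i])), i])
        if flip < 0:
            mixing[:, i] *= -1
            B[:, i] *= -1
            sources[i] *= -1

    return ICDecomposition(
        k=k,
        whitening=whitening,
        mixing=mixing,
        sources=sources,
        mean=mean,
        convergence=iterations,
        seed=seed,
    )


def amari_index(W: np.ndarray, A: np.ndarray) -> float:
    """Amari separation index of unmixing ``W`` against true mixing ``A``.

    Zero iff ``W @ A`` is a scaled permutation; normalised to [0, 1].
    """
    P = np.abs(np.asarray(W) @ np.asarray(A))
    m = P.shape[0]
    row = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * m * (m - 1)))
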