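"""Genomic kinship and single-marker mixed-model association.

The scan follows the standard efficient mixed-model (EMMA-style)
factorization: the realized relationship matrix K is eigendecomposed
once, the variance ratio delta = sigma2_e / sigma2_g is estimated by
REML on the rotated null model, and each marker is then tested by
generalized least squares in the rotated space with a Wald t test on
its coefficient.  PVE and GVE report the marker variance as a fraction
of the clone-mean phenotypic and genetic variance respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

__all__ = [
    "KinshipMatrix",
    "EmmaNullFit",
    "vanraden_kinship",
    "emma_null_fit",
    "gwas_scan",
    "bonferroni_threshold",
    "marker_pve_gve",
    "marker_variance",
]


@dataclass
class KinshipMatrix:
    """n x n symmetric realized genomic relationship matrix."""

    values: np.ndarray
    individuals: list[str]

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        self.values = 0.5 * (V + V.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def vanraden_kinship(G) -> KinshipMatrix:
    """VanRaden realized relationship matrix.

    K = Z Z' / (2 * sum_j p_j (1 - p_j)) with Z the column-centered
    dosage matrix (G - 2p) and allele frequencies p estimated from the
    data.  Missing dosages are mean-imputed per marker.
    """
    from .simpop import GenotypeMatrix

    if isinstance(G, GenotypeMatrix):
        M, ids = G.dosages, G.individuals
    else:
        M = np.asarray(G, dtype=float)
        ids = [f"ind{i:04d}" for i in range(M.shape[0])]
    M = M.astype(float).copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(M, axis=0) / 2.0
    nan_mask = np.isnan(M)
    if nan_mask.any():
        M[nan_mask] = np.take(2.0 * p, np.where(nan_mask)[1])
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic; kinship undefined")
    Z = M[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = Z @ Z.T / denom
    return KinshipMatrix(K, list(ids))


@dataclass
class EmmaNullFit:
    """Null mixed model y = X b + g + e, g ~ (0, sigma2_g K).

    Caches the spectral rotation so a marker scan (or BLUP) reuses it.
    """

    delta: float                 # sigma2_e / sigma2_g
    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray
    loglik: float
    eigenvalues: np.ndarray
    U: np.ndarray                # eigenvectors of K (columns)
    y_rot: np.ndarray
    X_rot: np.ndarray
    boundary: bool

    @property
    def weights(self) -> np.ndarray:
        return self.eigenvalues + self.delta


def _restricted_ll(log10_delta, s, y_rot, X_rot, n, p, logdet_XtX):
    delta = 10.0 ** log10_delta
    w = s + delta
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        bad = int(np.argmin(w))
        raise FloatingPointError(
            f"non-finite restricted likelihood at eigenvalue "
            f"{s[bad]:.3e} (index {bad}) with delta={delta:.3e}"
        )
    Xw = X_rot / w[:, None]
    XtWX = X_rot.T @ Xw
    XtWy = Xw.T @ y_rot
    beta = np.linalg.solve(XtWX, XtWy)
    resid = y_rot - X_rot @ beta
    rss = np.sum(resid * resid / w)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    ll = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * rss / (n - p)) + 1.0)
        + np.sum(np.log(w)) + logdet_XtWX - logdet_XtX
    )
    return ll, beta, rss


def emma_null_fit(y, K, X=None, n_grid: int = 101) -> EmmaNullFit:
    """REML fit of the kinship-only model by spectral profiling.

    The restricted likelihood is profiled over delta on a log10 grid
    spanning [1e-5, 1e5] and polished by bounded Brent search in the
    best bracket.
    """
    Kmat = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 individuals")
    if Kmat.shape != (n, n):
        raise ValueError("kinship does not match phenotype length")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]

    s, U = np.linalg.eigh(Kmat)
    s = np.clip(s, 0.0, None)  # PSD up to round-off
    y_rot = U.T @ y
    X_rot = U.T @ X
    _, logdet_XtX = np.linalg.slogdet(X.T @ X)

    grid = np.linspace(-5.0, 5.0, n_grid)
    lls = np.array([
        _restricted_ll(g, s, y_rot, X_rot, n, p, logdet_XtX)[0] for g in grid
    ])
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    res = scipy.optimize.minimize_scalar(
        lambda g: -_restricted_ll(g, s, y_rot, X_rot, n, p, logdet_XtX)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    best = res.x if -res.fun >= lls[k] else grid[k]
    ll, beta, rss = _restricted_ll(best, s, y_rot, X_rot, n, p, logdet_XtX)
    delta = 10.0 ** best
    sigma2_g = rss / (n - p)
    return EmmaNullFit(
        delta=float(delta),
        sigma2_g=float(sigma2_g),
        sigma2_e=float(delta * sigma2_g),
        beta=beta,
        loglik=float(ll),
        eigenvalues=s,
        U=U,
        y_rot=y_rot,
        X_rot=X_rot,
        boundary=bool(k in (0, n_grid - 1)),
    )


def gwas_scan(y, G, K=None, X=None, null: EmmaNullFit | None = None
              ) -> pd.DataFrame:
    """Single-marker mixed-model scan with Wald t tests.

    With the variance ratio fixed at the null estimate, each marker is
    added to the rotated GLS regression; the residual variance is
    re-estimated per marker, so with K = I the test reduces exactly to
    the ordinary-least-squares t test.  Monomorphic markers get p = 1
    and a flag rather than being dropped.
    """
    from .simpop import GenotypeMatrix

    if isinstance(G, GenotypeMatrix):
        M = G.dosages
        marker_ids, chrom, pos = G.marker_ids, G.chrom, G.pos
    else:
        M = np.asarray(G, dtype=float)
        marker_ids = [f"mk{j:05d}" for j in range(M.shape[1])]
        chrom = np.array(["."] * M.shape[1])
        pos = np.zeros(M.shape[1], dtype=int)

    y = np.asarray(y, dtype=float)
    n = y.size
    if null is None:
        if K is None:
            raise ValueError("provide either K or a null fit")
        null = emma_null_fit(y, K, X)
    w = null.weights
    sw = 1.0 / np.sqrt(w)

    # mean-impute missing dosages, as for the kinship
    M = M.astype(float).copy()
    nan_mask = np.isnan(M)
    if nan_mask.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_mean = np.nanmean(M, axis=0)
        M[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])

    Xs = null.X_rot * sw[:, None]        # whitened covariates
    ys = null.y_rot * sw
    Ms = (null.U.T @ M) * sw[:, None]    # whitened markers
    p_cov = Xs.shape[1]

    # project covariates out of y and every marker (Frisch-Waugh under GLS)
    Q, _ = np.linalg.qr(Xs)
    y_t = ys - Q @ (Q.T @ ys)
    M_t = Ms - Q @ (Q.T @ Ms)

    sxx = np.einsum("ij,ij->j", M_t, M_t)
    sxy = M_t.T @ y_t
    syy = float(y_t @ y_t)
    df = n - p_cov - 1

    mono = sxx <= 1e-12 * max(np.max(sxx), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, 0.0, sxy / sxx)
        rss = syy - beta * sxy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
    pvals = 2.0 * scipy.stats.t.sf(np.abs(tstat), df)
    pvals = np.where(mono, 1.0, pvals)
    beta = np.where(mono, np.nan, beta)
    se = np.where(mono, np.nan, se)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(np.clip(pvals, 1e-300, None))
    return pd.DataFrame({
        "marker": marker_ids,
        "chrom": chrom,
        "pos": pos,
        "beta": beta,
        "se": se,
        "p_wald": pvals,
        "neglog10_p": neglog,
        "monomorphic": mono,
    })


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide -log10(p) threshold, -log10(alpha / n_tests)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.log10(alpha / n_tests))


def marker_variance(values, dosage) -> float:
    """Variance across individuals of the fitted genotype-class means.

    Approximates the marker-associated variance sigma2_M used in the
    PVE/GVE ratios: each individual is assigned its dosage-class mean
    and the sample variance of those fitted values is returned.
    """
    values = np.asarray(values, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    ok = ~(np.isnan(values) | np.isnan(dosage))
    values, dosage = values[ok], dosage[ok]
    fitted = np.empty_like(values)
    for cls in np.unique(dosage):
        m = dosage == cls
        fitted[m] = values[m].mean()
    return float(np.var(fitted, ddof=1))


def marker_pve_gve(sigma2_M: float, sigma2_P: float, sigma2_G: float
                   ) -> tuple[float, float]:
    """PVE = sigma2_M / sigma2_P and GVE = sigma2_M / sigma2_G,
    clamped to [0, 1] with a warning when the marker variance exceeds
    its denominator."""
    if sigma2_G <= 0 or sigma2_P <= 0:
        raise ValueError("variance denominators must be > 0")
    if sigma2_P < sigma2_G:
        raise ValueError("sigma2_P must be >= sigma2_G")
    pve, gve = sigma2_M / sigma2_P, sigma2_M / sigma2_G
    if gve > 1.0 or pve > 1.0:
        warnings.warn(
            "marker variance exceeds denominator; PVE/GVE clamped to 1",
            RuntimeWarning, stacklevel=2,
        )
    return float(min(pve, 1.0)), float(min(gve, 1.0))
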