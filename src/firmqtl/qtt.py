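"""Transcript normalization and the quantitative-trait-transcript scan.

Counts are normalized by trimmed-mean-of-M-values (TMM) scaling factors
and converted to log2 counts-per-million with a library-size-scaled
prior count.  The phenotype (individual firmness means) is adjusted for
polygenic background by taking the environmental residuals of a
kinship-based mixed model, and each gene's profile is then correlated
with the adjusted phenotype (Pearson r, two-sided t-transform p).
Significant genes can be grouped into co-expression modules by average-
linkage hierarchical clustering on correlation distance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats

from .assoc import EmmaNullFit, emma_null_fit

__all__ = [
    "tmm_norm_factors",
    "filter_by_expression",
    "log2_cpm",
    "polygenic_adjust",
    "qtt_scan",
    "coexpression_modules",
]


def _counts_and_libs(counts, lib_sizes):
    from .simpop import CountsMatrix

    if isinstance(counts, CountsMatrix):
        return counts.counts.astype(float), counts.lib_sizes.astype(float)
    counts = np.asarray(counts, dtype=float)
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    return counts, np.asarray(lib_sizes, dtype=float)


def _tmm_pair(obs, ref, lib_obs, lib_ref, logratio_trim=0.30,
              sum_trim=0.05, do_weighting=True) -> float:
    """TMM scaling factor of one sample against the reference sample.

    Genes with a zero count in either sample are excluded; the log
    ratios (M) are trimmed by 30% on each side and the average absolute
    intensities (A) by 5%, and the surviving M values are averaged with
    inverse asymptotic-variance weights.
    """
    keep = (obs > 0) & (ref > 0)
    obs_p = obs[keep] / lib_obs
    ref_p = ref[keep] / lib_ref
    if obs_p.size == 0:
        return 1.0
    logR = np.log2(obs_p / ref_p)
    absE = 0.5 * np.log2(obs_p * ref_p)
    v = ((lib_obs - obs[keep]) / (lib_obs * obs[keep])
         + (lib_ref - ref[keep]) / (lib_ref * ref[keep]))
    fin = np.isfinite(logR) & np.isfinite(absE)
    logR, absE, v = logR[fin], absE[fin], v[fin]
    if logR.size == 0 or np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = logR.size
    loL = np.floor(n * logratio_trim) + 1
    hiL = n + 1 - loL
    loS = np.floor(n * sum_trim) + 1
    hiS = n + 1 - loS
    rank_m = scipy.stats.rankdata(logR)
    rank_a = scipy.stats.rankdata(absE)
    keep2 = ((rank_m >= loL) & (rank_m <= hiL)
             & (rank_a >= loS) & (rank_a <= hiS))
    if not keep2.any():
        return 1.0
    if do_weighting:
        w = 1.0 / v[keep2]
        f = np.sum(w * logR[keep2]) / np.sum(w)
    else:
        f = np.mean(logR[keep2])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_norm_factors(counts, lib_sizes=None, ref_column: int | None = None,
                     logratio_trim: float = 0.30, sum_trim: float = 0.05,
                     do_weighting: bool = True) -> np.ndarray:
    """Per-sample TMM scaling factors, normalized to geometric mean 1.

    When no reference column is given, the sample whose upper-quartile
    count proportion is closest to the mean upper quartile is used.
    """
    C, lib = _counts_and_libs(counts, lib_sizes)
    n_samples = C.shape[1]
    if n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    zero = np.where(C.sum(axis=0) == 0)[0]
    if zero.size:
        raise ValueError(f"sample column {zero[0]} has all-zero counts")
    if ref_column is None:
        f75 = np.array([
            np.quantile(C[:, j] / lib[j], 0.75) for j in range(n_samples)
        ])
        ref_column = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array([
        _tmm_pair(C[:, j], C[:, ref_column], lib[j], lib[ref_column],
                  logratio_trim, sum_trim, do_weighting)
        for j in range(n_samples)
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def filter_by_expression(counts, lib_sizes=None, min_cpm: float = 1.0,
                         min_samples: int | None = None) -> np.ndarray:
    """Keep a gene iff its (unnormalized) CPM is >= min_cpm in at least
    min_samples samples (default: 10% of samples, at least 1)."""
    C, lib = _counts_and_libs(counts, lib_sizes)
    n_samples = C.shape[1]
    if min_samples is None:
        min_samples = max(1, int(round(0.1 * n_samples)))
    if min_samples > n_samples:
        raise ValueError("min_samples exceeds the number of samples")
    cpm = C / lib[None, :] * 1e6
    return (cpm >= min_cpm).sum(axis=1) >= min_samples


def log2_cpm(counts, lib_sizes=None, factors=None,
             prior: float = 0.5) -> np.ndarray:
    """log2 counts-per-million with library-size-scaled prior count:

        log2( (count + prior*s_j) / (L_j + 2*prior*s_j) * 1e6 ),

    where L_j = libsize_j * factor_j and s_j = L_j / mean(L)."""
    if prior <= 0:
        raise ValueError("prior must be > 0")
    C, lib = _counts_and_libs(counts, lib_sizes)
    if factors is None:
        factors = np.ones(C.shape[1])
    eff = lib * np.asarray(factors, dtype=float)
    if np.any(eff <= 0):
        raise ValueError("zero effective library size")
    s = eff / eff.mean()
    return np.log2((C + prior * s[None, :])
                   / (eff + 2.0 * prior * s)[None, :] * 1e6)


def polygenic_adjust(y, K, null: EmmaNullFit | None = None) -> np.ndarray:
    """Environmental residuals of the kinship-based polygenic model.

    Fits y = mu + g + e with g ~ (0, sigma2_g K), then returns
    e_hat = y - mu_hat - BLUP(g); in the spectral basis these are
    delta/(s_i + delta) times the rotated fixed-effect residuals.
    """
    y = np.asarray(y, dtype=float)
    if np.var(y) == 0.0:
        return np.zeros_like(y)
    if null is None:
        null = emma_null_fit(y, K)
    r_rot = null.y_rot - null.X_rot @ null.beta
    shrink = null.delta / (null.eigenvalues + null.delta)
    return null.U @ (shrink * r_rot)


def qtt_scan(expr, y_adj, p_threshold: float = 0.005,
             gene_ids=None) -> pd.DataFrame:
    """Per-gene Pearson correlation with the adjusted phenotype.

    p-values come from the t transform with n-2 degrees of freedom;
    genes with zero variance are flagged and excluded from significance.
    """
    E = np.asarray(expr, dtype=float)
    y = np.asarray(y_adj, dtype=float)
    n = y.size
    if E.shape[1] != n:
        raise ValueError("expression columns must match phenotype length")
    if n < 4:
        raise ValueError("need at least 4 samples")
    if gene_ids is None:
        gene_ids = [f"gene{j:05d}" for j in range(E.shape[0])]

    Ec = E - E.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom_y = np.sqrt(np.sum(yc * yc))
    gene_ss = np.sqrt(np.einsum("ij,ij->i", Ec, Ec))
    degenerate = gene_ss <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ec @ yc) / (gene_ss * denom_y)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r * r, 1e-300, None))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), n - 2)
    r = np.where(degenerate, np.nan, r)
    p = np.where(degenerate, np.nan, p)
    sig = np.where(degenerate, False, p <= p_threshold)
    return pd.DataFrame({
        "gene": gene_ids,
        "r": r,
        "p": p,
        "significant": sig.astype(bool),
        "degenerate": degenerate,
    })


def coexpression_modules(expr_subset, n_modules: int = 3, gene_ids=None
                         ) -> tuple[pd.Series, np.ndarray]:
    """Average-linkage hierarchical modules on correlation distance.

    Distance between gene profiles is 1 - Pearson r; the tree is cut to
    ``n_modules`` clusters.  Returns (labels, linkage matrix).
    """
    E = np.asarray(expr_subset, dtype=float)
    if gene_ids is None:
        gene_ids = [f"gene{j:05d}" for j in range(E.shape[0])]
    if E.shape[0] < n_modules:
        raise ValueError("fewer genes than requested modules")
    sd = E.std(axis=1)
    flat = [gene_ids[j] for j in np.where(sd == 0)[0]]
    if flat:
        raise ValueError(f"constant gene profiles: {flat[:10]}")
    R = np.corrcoef(E)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    condensed = scipy.spatial.distance.squareform(
        np.clip(0.5 * (D + D.T), 0.0, None), checks=False
    )
    Z = scipy.cluster.hierarchy.linkage(condensed, method="average")
    labels = scipy.cluster.hierarchy.fcluster(
        Z, t=n_modules, criterion="maxclust"
    )
    return pd.Series(labels, index=gene_ids, name="module"), Z
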