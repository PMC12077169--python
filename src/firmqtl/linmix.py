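"""REML variance components, estimated marginal means, and heritability.

The phenotype models are Gaussian linear mixed models with crossed,
independent random factors, e.g. for the multi-environment trial

    value ~ location (fixed) + genotype + year + location:year
            + genotype:year + location:year:block (random) + residual.

Variance components are estimated by direct maximization of the
restricted log-likelihood over the variance ratios gamma_k =
sigma2_k / sigma2_e (bounded quasi-Newton on log(gamma), Nelder--Mead
fallback), with the residual variance profiled out.  The restricted
likelihood is evaluated through the Woodbury identity on the q x q
random-level cross-product matrix, so fits stay fast on desk-scale
crossed designs without sparse machinery.

Broad-sense heritability on a clone-mean basis is

    H^2 = sigma2_G / (sigma2_G + sigma2_GxY / y + sigma2_e / (r y)),

with y years and r the harmonic mean number of replications per
genotype within a year; narrow-sense h^2 divides the additive variance
from a kinship-based (RR-BLUP-equivalent) fit by the clone-mean
phenotypic variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "VarComp",
    "reml_fit",
    "estimate_emms",
    "harmonic_mean_reps",
    "broad_sense_h2",
    "narrow_sense_h2",
    "FIRMNESS_VC_MODEL",
    "FIRMNESS_EMM_MODEL",
]


@dataclass(frozen=True)
class ModelSpec:
    """Names the response, fixed terms and independent random terms.

    A term is a column name or a colon-joined interaction of column
    names ("location:year"); interactions are encoded through the
    concatenated level labels of their parent factors.  The residual
    component is implicit.
    """

    response: str
    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random", tuple(self.random))
        if len(set(self.random)) != len(self.random):
            raise ValueError("random terms must be pairwise distinct")

    def validate(self, df: pd.DataFrame) -> None:
        needed = {self.response}
        for term in (*self.fixed, *self.random):
            needed.update(term.split(":"))
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"columns missing from data: {sorted(missing)}")


def _term_labels(df: pd.DataFrame, term: str) -> pd.Series:
    parts = term.split(":")
    lab = df[parts[0]].astype(str)
    for p in parts[1:]:
        lab = lab + ":" + df[p].astype(str)
    return lab


class _FixedDesign:
    """Treatment-coded fixed-effect design, pruned to full column rank.

    The pruned basis is remembered so design rows for new data (EMM
    prediction) use exactly the columns the model was fitted with.
    """

    def __init__(self, df: pd.DataFrame, terms: tuple[str, ...]):
        self.terms = terms
        self.levels = {
            t: sorted(_term_labels(df, t).unique()) for t in terms
        }
        self.colspec = [("__intercept__", None)]
        for t in terms:
            self.colspec.extend((t, lev) for lev in self.levels[t][1:])
        X = self._raw(df)
        if X.shape[1] > 1:
            _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
            diag = np.abs(np.diag(R))
            tol = diag.max() * max(X.shape) * np.finfo(float).eps
            rank = int((diag > tol).sum())
            self.keep = np.sort(piv[:rank])
        else:
            self.keep = np.array([0])
        self.names = [
            "(Intercept)" if t == "__intercept__" else f"{t}[{lev}]"
            for k, (t, lev) in enumerate(self.colspec) if k in set(self.keep)
        ]

    def _raw(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        X = np.zeros((n, len(self.colspec)))
        X[:, 0] = 1.0
        labels = {t: _term_labels(df, t).to_numpy() for t in self.terms}
        for k, (t, lev) in enumerate(self.colspec):
            if t == "__intercept__":
                continue
            X[:, k] = labels[t] == lev
        return X

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        return self._raw(df)[:, self.keep]


def _random_design(df: pd.DataFrame, terms: tuple[str, ...]):
    """Indicator matrices per random term, concatenated; returns
    (Z, block_slices, level_names)."""
    blocks, slices, names = [], [], []
    start = 0
    for t in terms:
        lab = _term_labels(df, t)
        levels = sorted(lab.unique())
        if len(levels) < 2:
            raise ValueError(f"random term '{t}' has < 2 levels")
        idx = pd.Categorical(lab, categories=levels).codes
        Zk = np.zeros((len(df), len(levels)))
        Zk[np.arange(len(df)), idx] = 1.0
        blocks.append(Zk)
        slices.append(slice(start, start + len(levels)))
        names.append(levels)
        start += len(levels)
    Z = np.hstack(blocks) if blocks else np.zeros((len(df), 0))
    return Z, slices, names


@dataclass
class VarComp:
    """REML fit: variance components, fixed solutions and bookkeeping."""

    variances: dict[str, float]
    beta: pd.Series
    cov_beta: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    spec: ModelSpec
    design: _FixedDesign | None = None
    message: str = ""

    def __getitem__(self, key: str) -> float:
        return self.variances[key]


class RemlError(RuntimeError):
    """Non-convergence diagnostic carrying the last iterate."""

    def __init__(self, message: str, last_gamma: np.ndarray):
        super().__init__(message)
        self.last_gamma = last_gamma


def _profiled_neg2_restricted_ll(theta, ZtZ, ZtX, Zty, XtX, Xty, yty,
                                 slices, n, p, want_grad=False):
    """-2 * restricted log-likelihood with sigma2_e profiled out, as a
    function of log variance ratios theta_k = log gamma_k; optionally
    also its analytic gradient."""
    gamma = np.exp(theta)
    w = np.empty(ZtZ.shape[0])
    for g, sl in zip(gamma, slices):
        w[sl] = np.sqrt(g)
    A = np.eye(len(w)) + (w[:, None] * ZtZ) * w[None, :]
    cA = scipy.linalg.cho_factor(A, lower=True, check_finite=False)
    logdetA = 2.0 * np.sum(np.log(np.diag(cA[0])))

    WZtX = w[:, None] * ZtX
    WZty = w * Zty
    SX = scipy.linalg.cho_solve(cA, WZtX, check_finite=False)
    Sy = scipy.linalg.cho_solve(cA, WZty, check_finite=False)
    XtOX = XtX - WZtX.T @ SX
    XtOy = Xty - WZtX.T @ Sy
    ytOy = yty - WZty @ Sy

    cXX = scipy.linalg.cho_factor(XtOX, lower=True, check_finite=False)
    beta = scipy.linalg.cho_solve(cXX, XtOy, check_finite=False)
    rss = max(ytOy - XtOy @ beta, 1e-300)
    sigma2 = rss / (n - p)
    logdet_XtOX = 2.0 * np.sum(np.log(np.diag(cXX[0])))
    sign, logdet_XtX = np.linalg.slogdet(XtX)
    neg2 = ((n - p) * np.log(2.0 * np.pi * sigma2) + logdetA
            + logdet_XtOX - logdet_XtX + (n - p))
    if not want_grad:
        return neg2, beta, sigma2, XtOX

    # score of -2 lR: for each component k with dOmega/dgamma_k = Zk Zk',
    #   d log|Omega|        =  tr(Zk' Oi Zk)
    #   d log|X' Oi X|      = -tr((X'OiX)^-1 X'Oi Zk Zk'Oi X)
    #   d rss               = -|| Zk' P y ||^2
    # with Oi = Omega^-1 and P the REML projection.
    WZtZ = w[:, None] * ZtZ
    S = scipy.linalg.cho_solve(cA, WZtZ, check_finite=False)
    ZOiZ = ZtZ - WZtZ.T @ S                  # Z' Omega^-1 Z
    ZOiX = ZtX - WZtZ.T @ SX                 # Z' Omega^-1 X
    ZOiy = Zty - WZtZ.T @ Sy
    ZPy = ZOiy - ZOiX @ beta                 # Z' P y (block rows)
    XtOXinv = scipy.linalg.cho_solve(cXX, np.eye(p), check_finite=False)
    grad = np.empty(len(slices))
    for k, sl in enumerate(slices):
        t1 = np.trace(ZOiZ[sl, sl])
        Bk = ZOiX[sl]
        t2 = float(np.sum((Bk @ XtOXinv) * Bk))
        t3 = float(ZPy[sl] @ ZPy[sl])
        grad[k] = (t1 - t2 - (n - p) * t3 / rss) * gamma[k]
    return neg2, beta, sigma2, XtOX, grad


def reml_fit(pheno: pd.DataFrame, spec: ModelSpec,
             max_starts: int = 1) -> VarComp:
    """Estimate variance components by REML for the given model.

    Variances are constrained non-negative; boundary estimates are
    returned as (numerically) zero.  Deterministic given the data.
    """
    spec.validate(pheno)
    df = pheno.dropna(subset=[spec.response]).reset_index(drop=True)
    y = df[spec.response].to_numpy(dtype=float)
    n = len(y)
    design = _FixedDesign(df, spec.fixed)
    X = design.matrix(df)
    p = X.shape[1]
    if n <= p:
        raise ValueError("not enough observations for the fixed effects")

    comp_names = list(spec.random)
    if np.var(y) == 0.0:
        # degenerate: a constant response carries no variance to split
        variances = {name: 0.0 for name in comp_names}
        variances["residual"] = 0.0
        beta = np.zeros(p)
        beta[0] = y[0] if p else 0.0
        return VarComp(variances, pd.Series(beta, index=design.names),
                       np.zeros((p, p)), 0.0, True, n, spec, design,
                       "degenerate: constant response")

    if not spec.random:
        # no random terms: REML reduces to ordinary least squares
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = float(resid @ resid / (n - p))
        XtX = X.T @ X
        cov_beta = sigma2 * np.linalg.pinv(XtX)
        ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0))
        return VarComp({"residual": sigma2},
                       pd.Series(beta, index=design.names), cov_beta,
                       float(ll), True, n, spec, design, "OLS (no random terms)")

    Z, slices, _ = _random_design(df, spec.random)
    ZtZ = Z.T @ Z
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = y @ y
    K = len(comp_names)

    def objective(theta):
        try:
            out = _profiled_neg2_restricted_ll(
                theta, ZtZ, ZtX, Zty, XtX, Xty, yty, slices, n, p,
                want_grad=True)
            return out[0], out[4]
        except np.linalg.LinAlgError:
            return 1e12, np.zeros(K)

    def objective_nog(theta):
        try:
            return _profiled_neg2_restricted_ll(
                theta, ZtZ, ZtX, Zty, XtX, Xty, yty, slices, n, p)[0]
        except np.linalg.LinAlgError:
            return 1e12

    bounds = [(-13.8, 13.8)] * K  # gamma in ~[1e-6, 1e6]
    starts = [np.zeros(K), np.full(K, -4.0), np.full(K, 2.0)]
    best = None
    for i, x0 in enumerate(starts):
        res = scipy.optimize.minimize(
            objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        # extra starts only guard against failed convergence
        if best.success and i + 1 >= max_starts:
            break
    if not best.success:
        # a fresh restart usually escapes line-search stalls
        res = scipy.optimize.minimize(
            objective, best.x, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        if res.fun <= best.fun:
            best = res
    if not best.success:
        # derivative-free fallback for awkward likelihood surfaces
        res = scipy.optimize.minimize(
            objective_nog, best.x, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400},
        )
        if res.fun <= best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RemlError("REML did not reach a finite likelihood",
                        np.exp(best.x))

    neg2, beta, sigma2, XtOX = _profiled_neg2_restricted_ll(
        best.x, ZtZ, ZtX, Zty, XtX, Xty, yty, slices, n, p)
    gamma = np.exp(best.x)
    variances = {}
    for name, g in zip(comp_names, gamma):
        v = g * sigma2
        variances[name] = 0.0 if v < 1e-10 * sigma2 else float(v)
    variances["residual"] = float(sigma2)
    cov_beta = sigma2 * np.linalg.inv(XtOX)
    return VarComp(
        variances=variances,
        beta=pd.Series(beta, index=design.names),
        cov_beta=cov_beta,
        loglik=-0.5 * neg2,
        converged=bool(best.success or best.fun < 1e12),
        n_obs=n,
        spec=spec,
        design=design,
        message=str(best.message),
    )


def estimate_emms(fit: VarComp, pheno: pd.DataFrame,
                  genotype: str = "individual") -> pd.DataFrame:
    """Estimated marginal mean per individual.

    Averages model-predicted cell values (random effects at zero) with
    equal weight over the combinations of non-genotype fixed factors the
    individual was observed in; cells empty for an individual are
    dropped from its average.  Requires genotype among the fixed terms.
    """
    if genotype not in [t for term in fit.spec.fixed for t in term.split(":")]:
        raise ValueError(f"'{genotype}' is not a fixed factor in the model")
    df = pheno.dropna(subset=[fit.spec.response]).reset_index(drop=True)
    base_factors = sorted(
        {f for term in fit.spec.fixed for f in term.split(":")} - {genotype}
    )
    beta = fit.beta.to_numpy()
    out = []
    for g, sub in df.groupby(genotype, sort=True):
        if base_factors:
            cells = sub.drop_duplicates(subset=base_factors)
        else:
            cells = sub.iloc[:1]
        rows = fit.design.matrix(cells)
        cbar = rows.mean(axis=0)
        emm = float(cbar @ beta)
        se = float(np.sqrt(max(cbar @ fit.cov_beta @ cbar, 0.0)))
        out.append((g, emm, se, len(cells)))
    return pd.DataFrame(out, columns=[genotype, "emm", "se", "n_cells"])


def harmonic_mean_reps(rep_counts) -> float:
    """Harmonic mean of per-genotype replication counts."""
    c = np.asarray(rep_counts, dtype=float)
    if c.size == 0 or np.any(c <= 0):
        raise ValueError("replication counts must all be > 0")
    return float(c.size / np.sum(1.0 / c))


def _clamp01(x: float, what: str) -> float:
    if x < 0.0 or x > 1.0:
        logger.info("clamping %s=%.4g into [0, 1]", what, x)
    return float(min(max(x, 0.0), 1.0))


def broad_sense_h2(vc, n_years: int, r: float,
                   g_component: str = "individual",
                   gy_component: str = "individual:year") -> float:
    """Clone-mean broad-sense heritability
    H^2 = sG / (sG + sGY/y + se/(r*y))."""
    variances = vc.variances if isinstance(vc, VarComp) else dict(vc)
    if n_years < 1 or r <= 0:
        raise ValueError("need n_years >= 1 and r > 0")
    s_g = variances[g_component]
    s_gy = variances.get(gy_component, 0.0)
    s_e = variances["residual"]
    denom = s_g + s_gy / n_years + s_e / (r * n_years)
    if denom <= 0:
        raise ValueError("clone-mean phenotypic variance is zero")
    return _clamp01(s_g / denom, "H2")


def narrow_sense_h2(emms, K, vc_P: float) -> float:
    """Narrow-sense heritability h^2 = sigma2_A / sigma2_Pbar.

    The additive variance comes from a kinship-based REML fit of the
    individual means, y = mu + g + e with g ~ (0, sigma2_A * K)
    (equivalent to RR-BLUP when K is the realized genomic relationship
    matrix); vc_P is the clone-mean phenotypic variance.
    """
    from .assoc import KinshipMatrix, emma_null_fit

    if isinstance(emms, pd.DataFrame):
        emm_map = emms.set_index(emms.columns[0])["emm"]
    else:
        emm_map = pd.Series(emms)
    if isinstance(K, KinshipMatrix):
        ids, Kmat = K.individuals, K.values
    else:
        ids, Kmat = list(emm_map.index), np.asarray(K)
    missing = [i for i in ids if i not in emm_map.index]
    if missing:
        raise ValueError(f"EMMs missing for individuals: {missing[:5]}")
    y = emm_map.loc[ids].to_numpy(dtype=float)
    if vc_P <= 0:
        raise ValueError("vc_P must be > 0")
    fit = emma_null_fit(y, Kmat)
    return _clamp01(fit.sigma2_g / vc_P, "h2")


# canonical model specifications for the replicated firmness trial:
# variance components need genotype random, EMMs need genotype fixed
FIRMNESS_VC_MODEL = ModelSpec(
    response="value",
    fixed=("location",),
    random=("individual", "year", "location:year", "individual:year",
            "location:year:block"),
)
FIRMNESS_EMM_MODEL = ModelSpec(
    response="value",
    fixed=("individual", "location"),
    random=("year", "location:year", "individual:year",
            "location:year:block"),
)
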