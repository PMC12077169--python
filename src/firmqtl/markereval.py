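"""Single-marker effect characterization and validation statistics.

Genotype classes are keyed by favorable-allele dosage (0 = -/-,
1 = +/-, 2 = +/+).  The additive effect is half the difference between
homozygote class means, a_hat = (ybar_{+/+} - ybar_{-/-}) / 2, and the
dominance deviation is the heterozygote mean minus the homozygote
midpoint, d_hat = ybar_{+/-} - (ybar_{+/+} + ybar_{-/-}) / 2, so a_hat
is positive for the favorable allele.  The degree of dominance is
|d/a| (0 = additive, 1 = complete dominance).  Validation statistics
cover segregation chi-square against an expected ratio, call-set
concordance (accuracy and call rate), favorable-allele frequency and
fold-change reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ClassMeans",
    "SegregationTest",
    "ConcordanceResult",
    "MarkerEffectRecord",
    "class_means",
    "additive_dominance",
    "degree_of_dominance",
    "marker_corr",
    "segregation_chisq",
    "concordance",
    "allele_freq",
    "fold_change",
    "evaluate_marker",
]


@dataclass
class ClassMeans:
    """Per-dosage-class means, variances and counts (index 0, 1, 2)."""

    means: np.ndarray
    variances: np.ndarray
    counts: np.ndarray

    @property
    def n_genotyped(self) -> int:
        return int(self.counts.sum())


def class_means(values, dosage) -> ClassMeans:
    """Arithmetic mean of individual values per dosage class.

    Missing dosages are excluded from every class and from n; empty
    classes are reported as NaN.
    """
    values = np.asarray(values, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    ok = ~(np.isnan(values) | np.isnan(dosage))
    values, dosage = values[ok], dosage[ok]
    means = np.full(3, np.nan)
    variances = np.full(3, np.nan)
    counts = np.zeros(3, dtype=int)
    for cls in (0, 1, 2):
        m = dosage == cls
        counts[cls] = int(m.sum())
        if counts[cls] > 0:
            means[cls] = values[m].mean()
        if counts[cls] > 1:
            variances[cls] = values[m].var(ddof=1)
    if counts.sum() == 0:
        raise ValueError("no genotyped individuals")
    return ClassMeans(means, variances, counts)


def _contrast_test(c, means, variances, counts):
    """t test of a linear contrast among class means with pooled
    within-class variance; Welch-Satterthwaite fallback when class
    variances differ more than 4-fold."""
    used = np.nonzero(c)[0]
    v = variances[used]
    n = counts[used]
    est = float(np.sum(c[used] * means[used]))
    if np.any(n < 2) or np.all(np.isnan(v)):
        return est, np.nan
    finite_v = v[~np.isnan(v)]
    pooled = (np.nansum((n - 1) * v) / np.nansum(n - 1))
    if finite_v.size > 1 and finite_v.min() > 0 and \
            finite_v.max() / finite_v.min() > 4.0:
        se2 = float(np.nansum(c[used] ** 2 * v / n))
        df = se2 ** 2 / float(
            np.nansum((c[used] ** 2 * v / n) ** 2 / (n - 1))
        )
    else:
        se2 = pooled * float(np.sum(c[used] ** 2 / n))
        df = float(np.nansum(n - 1))
    if se2 <= 0 or df <= 0:
        return est, np.nan
    t = est / np.sqrt(se2)
    return est, float(2.0 * scipy.stats.t.sf(abs(t), df))


def additive_dominance(cm: ClassMeans) -> tuple[float, float, float, float]:
    """(a_hat, d_hat, p_a, p_d) from genotype-class means.

    a_hat needs both homozygote classes; d_hat additionally needs the
    heterozygote class (NaN and a warning otherwise).
    """
    if cm.counts[0] == 0 or cm.counts[2] == 0:
        raise ValueError(
            "both homozygote classes must be observed to estimate a_hat"
        )
    ca = np.array([-0.5, 0.0, 0.5])
    a_hat, p_a = _contrast_test(ca, cm.means, cm.variances, cm.counts)
    if cm.counts[1] == 0:
        warnings.warn("heterozygote class empty; d_hat undefined",
                      RuntimeWarning, stacklevel=2)
        return a_hat, np.nan, p_a, np.nan
    cd = np.array([-0.5, 1.0, -0.5])
    d_hat, p_d = _contrast_test(cd, cm.means, cm.variances, cm.counts)
    return a_hat, d_hat, p_a, p_d


def degree_of_dominance(a: float, d: float) -> float:
    """|d/a|; NaN with a warning when a == 0 (undefined)."""
    if a == 0:
        warnings.warn("additive effect is zero; |d/a| undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return abs(d / a)


def marker_corr(values, dosage) -> tuple[float, float]:
    """Pearson correlation of a value vector against dosage 0/1/2,
    with a two-sided t-based p-value."""
    values = np.asarray(values, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    ok = ~(np.isnan(values) | np.isnan(dosage))
    values, dosage = values[ok], dosage[ok]
    if values.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.var(values) == 0 or np.var(dosage) == 0:
        raise ValueError("zero variance in values or dosage")
    res = scipy.stats.pearsonr(values, dosage)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SegregationTest:
    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    chisq: float
    df: int
    p: float


def segregation_chisq(counts, ratio=(1, 2, 1)) -> SegregationTest:
    """Pearson chi-square of observed class counts against an expected
    ratio (default 1 +/+ : 2 +/- : 1 -/-)."""
    obs = np.asarray(counts, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if obs.sum() <= 0:
        raise ValueError("total count must be > 0")
    exp = obs.sum() * ratio / ratio.sum()
    if np.any(exp <= 0):
        raise ValueError("expected count of zero in some class")
    chisq = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    p = float(scipy.stats.chi2.sf(chisq, df))
    return SegregationTest(tuple(int(c) for c in counts),
                           tuple(ratio), chisq, df, p)


@dataclass
class ConcordanceResult:
    n_compared: int
    n_called: int
    n_both_called: int
    n_concordant: int
    accuracy_pct: float
    call_rate_pct: float


def _is_missing(x) -> bool:
    if x is None:
        return True
    try:
        return bool(np.isnan(x))
    except TypeError:
        return False


def concordance(reference_calls, test_calls) -> ConcordanceResult:
    """Genotype-call concordance between a reference and a test assay.

    Call rate = called / total in the test set (x100); accuracy =
    concordant / both-called (x100), so reference-missing samples drop
    out of the accuracy denominator only.
    """
    ref = list(reference_calls)
    test = list(test_calls)
    if len(ref) != len(test):
        raise ValueError("call sets must be aligned")
    if len(ref) == 0:
        raise ValueError("empty overlap between call sets")
    n = len(ref)
    called = [t for t in test if not _is_missing(t)]
    both = [(r, t) for r, t in zip(ref, test)
            if not _is_missing(r) and not _is_missing(t)]
    if not both:
        raise ValueError("no samples called in both sets")
    concordant = sum(1 for r, t in both if r == t)
    return ConcordanceResult(
        n_compared=n,
        n_called=len(called),
        n_both_called=len(both),
        n_concordant=concordant,
        accuracy_pct=100.0 * concordant / len(both),
        call_rate_pct=100.0 * len(called) / n,
    )


def allele_freq(dosage) -> float:
    """Favorable-allele frequency: mean(dosage)/2 over non-missing."""
    d = np.asarray(dosage, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("all genotype calls missing")
    return float(d.mean() / 2.0)


def fold_change(numerator: float, denominator: float) -> float:
    """Expression ratio rounded half-away-from-zero to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    ratio = numerator / denominator
    return float(np.floor(abs(ratio) * 10.0 + 0.5) / 10.0 * np.sign(ratio))


@dataclass
class MarkerEffectRecord:
    """One marker's effect and validation summary (one table row)."""

    marker: str
    class_means: ClassMeans
    faf: float
    r_y_M: float
    p_r_y_M: float
    r_RE_M: float | None
    p_r_RE_M: float | None
    pve: float | None
    gve: float | None
    a_hat: float
    p_a: float
    d_hat: float
    p_d: float
    deg_dominance: float

    def as_row(self) -> dict:
        return {
            "marker": self.marker,
            "n": self.class_means.n_genotyped,
            "FAF": self.faf,
            "r_y_M": self.r_y_M,
            "r_RE_M": self.r_RE_M,
            "PVE": self.pve,
            "GVE": self.gve,
            "a_hat": self.a_hat,
            "p_a": self.p_a,
            "d_hat": self.d_hat,
            "p_d": self.p_d,
            "abs_d_over_a": self.deg_dominance,
        }


def evaluate_marker(marker_id: str, emms, dosage, expression=None,
                    sigma2_P: float | None = None,
                    sigma2_G: float | None = None) -> MarkerEffectRecord:
    """Assemble the full effect record for one marker.

    ``emms`` are per-individual phenotype means aligned with ``dosage``;
    ``expression`` optionally holds the focal transcript's abundances
    for the genotype-expression correlation.  PVE/GVE are filled when
    the clone-mean phenotypic and genetic variances are supplied.
    """
    from .assoc import marker_pve_gve, marker_variance

    emms = np.asarray(emms, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    cm = class_means(emms, dosage)
    a_hat, d_hat, p_a, p_d = additive_dominance(cm)
    r_y, p_y = marker_corr(emms, dosage)
    if expression is not None:
        r_e, p_e = marker_corr(np.asarray(expression, float), dosage)
    else:
        r_e = p_e = None
    if sigma2_P is not None and sigma2_G is not None:
        s2m = marker_variance(emms, dosage)
        pve, gve = marker_pve_gve(s2m, sigma2_P, sigma2_G)
    else:
        pve = gve = None
    return MarkerEffectRecord(
        marker=marker_id,
        class_means=cm,
        faf=allele_freq(dosage),
        r_y_M=r_y, p_r_y_M=p_y,
        r_RE_M=r_e, p_r_RE_M=p_e,
        pve=pve, gve=gve,
        a_hat=a_hat, p_a=p_a, d_hat=d_hat, p_d=p_d,
        deg_dominance=degree_of_dominance(a_hat, d_hat),
    )
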