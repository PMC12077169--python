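"""Matrix-formulated marker-to-transcript (eQTL) association scan.

Each (marker, gene) pair is a simple linear regression of expression on
additive dosage, evaluated through the correlation identity
t = r * sqrt(n-2) / sqrt(1 - r^2) on one product of standardized
matrices, which reproduces per-pair ordinary regression exactly.  Pairs
are labelled cis when the marker lies within a window of the gene
midpoint on the same chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["eqtl_scan", "top_cis_eqtl", "EqtlScanLog"]

DEFAULT_CIS_WINDOW = 1_000_000  # bp


@dataclass
class EqtlScanLog:
    n_pairs_tested: int
    n_skipped_constant_marker: int
    n_skipped_constant_gene: int


def _standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Mc = M - M.mean(axis=1, keepdims=True)
    ss = np.sqrt(np.einsum("ij,ij->i", Mc, Mc))
    ok = ss > 0
    out = np.zeros_like(Mc)
    out[ok] = Mc[ok] / ss[ok, None]
    return out, ok


def eqtl_scan(G, expr, p_threshold: float | None = 0.005,
              gene_ids=None, gene_chrom=None, gene_midpoint=None,
              cis_window: int = DEFAULT_CIS_WINDOW
              ) -> tuple[pd.DataFrame, EqtlScanLog]:
    """Scan all marker x gene pairs; keep those with p <= p_threshold
    (all pairs when the threshold is None).

    ``G`` is individuals x markers (samples must align with the columns
    of ``expr``, genes x samples).  Zero-variance markers or genes are
    skipped and counted in the returned log.
    """
    from .simpop import GenotypeMatrix

    if isinstance(G, GenotypeMatrix):
        M = G.dosages.T                       # markers x samples
        marker_ids, m_chrom, m_pos = G.marker_ids, G.chrom, G.pos
    else:
        M = np.asarray(G, dtype=float).T
        marker_ids = [f"mk{j:05d}" for j in range(M.shape[0])]
        m_chrom = np.array(["."] * M.shape[0])
        m_pos = np.zeros(M.shape[0], dtype=int)
    E = np.asarray(expr, dtype=float)
    n = E.shape[1]
    if M.shape[1] != n:
        raise ValueError("samples of G and expr are not aligned")
    if n < 4:
        raise ValueError("need at least 4 samples")
    if gene_ids is None:
        gene_ids = [f"gene{j:05d}" for j in range(E.shape[0])]

    Mz, m_ok = _standardize(M)
    Ez, g_ok = _standardize(E)
    R = Mz @ Ez.T                              # markers x genes Pearson r
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = R * np.sqrt((n - 2) / np.clip(1.0 - R * R, 1e-300, None))
    P = 2.0 * scipy.stats.t.sf(np.abs(T), n - 2)

    valid = np.outer(m_ok, g_ok)
    if p_threshold is None:
        sel = valid
    else:
        sel = valid & (P <= p_threshold)
    mi, gi = np.nonzero(sel)
    table = pd.DataFrame({
        "marker": np.asarray(marker_ids, dtype=object)[mi],
        "marker_chrom": np.asarray(m_chrom)[mi],
        "marker_pos": np.asarray(m_pos)[mi],
        "gene": np.asarray(gene_ids, dtype=object)[gi],
        "t": T[mi, gi],
        "p": P[mi, gi],
        "sign": np.sign(R[mi, gi]).astype(int),
        "r": R[mi, gi],
    })
    if gene_chrom is not None and gene_midpoint is not None:
        gc = np.asarray(gene_chrom)[gi]
        gm = np.asarray(gene_midpoint)[gi].astype(int)
        table["gene_chrom"] = gc
        table["gene_midpoint"] = gm
        table["distance"] = np.abs(table["marker_pos"] - gm)
        table["cis"] = ((table["marker_chrom"] == gc)
                        & (table["distance"] <= cis_window))
    log = EqtlScanLog(
        n_pairs_tested=int(valid.sum()),
        n_skipped_constant_marker=int((~m_ok).sum()) * E.shape[0],
        n_skipped_constant_gene=int(m_ok.sum()) * int((~g_ok).sum()),
    )
    return table, log


def top_cis_eqtl(table: pd.DataFrame, gene: str,
                 window: int = DEFAULT_CIS_WINDOW) -> pd.Series | None:
    """Most significant cis record for one gene.

    Ties on p are broken by smaller marker-gene distance, then lower
    marker position.  Returns None when no cis marker falls in the
    window.
    """
    if "gene_midpoint" not in table.columns:
        raise ValueError("table lacks gene positions; rerun the scan "
                         "with gene_chrom/gene_midpoint")
    sub = table[table["gene"] == gene]
    if sub.empty:
        raise KeyError(f"gene {gene!r} not present in the table")
    cis = sub[(sub["marker_chrom"] == sub["gene_chrom"])
              & (sub["distance"] <= window)]
    if cis.empty:
        return None
    cis = cis.sort_values(["p", "distance", "marker_pos"],
                          kind="mergesort")
    return cis.iloc[0]
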