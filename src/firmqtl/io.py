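"""Plain-text readers and writers for the pipeline's file formats.

Genotypes travel as VCF v4.2 (GT field, dosage of the ALT = favorable
allele); phenotypes as a long tab-separated table; counts as a
genes x samples TSV with a library-size row.  Every table written here
carries '#'-prefixed metadata lines (seed, package version) before the
single header row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simpop import CountsMatrix, GenotypeMatrix

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(G: GenotypeMatrix, path: str, meta: dict | None = None) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=firmqtl\n")
        for k, v in (meta or {}).items():
            fh.write(f"##firmqtl_{k}={v}\n")
        for contig in dict.fromkeys(G.chrom):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.individuals) + "\n")
        for j in range(G.n_markers):
            gts = []
            for x in G.dosages[:, j]:
                gts.append("./." if np.isnan(x) else _GT_STRINGS[int(x)])
            fh.write(
                f"{G.chrom[j]}\t{G.pos[j]}\t{G.marker_ids[j]}\tA\tT\t.\tPASS"
                f"\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic GT calls into a favorable-allele dosage matrix."""
    vcf = VCF(path)
    individuals = list(vcf.samples)
    rows, ids, chroms, poss = [], [], [], []
    for var in vcf:
        dos = np.empty(len(individuals))
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            dos[i] = sum(alleles) if len(alleles) == 2 else np.nan
        rows.append(dos)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    vcf.close()
    if not rows:
        raise ValueError(f"no variants in {path}")
    return GenotypeMatrix(
        dosages=np.vstack(rows).T,
        individuals=individuals,
        marker_ids=ids,
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=int),
    )


def _write_tsv(df: pd.DataFrame, path: str, meta: dict | None,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_pheno_tsv(pheno: pd.DataFrame, path: str,
                    meta: dict | None = None) -> None:
    cols = ["individual", "location", "year", "block", "harvest", "value"]
    _write_tsv(pheno[cols], path, meta)


def read_pheno_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"individual": str, "location": str,
                              "year": str, "block": str, "harvest": str})


def write_counts_tsv(cm: CountsMatrix, path: str,
                     meta: dict | None = None) -> None:
    """Genes x samples counts with a leading library-size row and optional
    gene-position columns."""
    df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids)
    lib_row = pd.DataFrame(
        [cm.lib_sizes], index=["__lib_size__"], columns=cm.sample_ids
    )
    out = pd.concat([lib_row, df])
    out.index.name = "gene"
    if cm.gene_chrom is not None:
        out.insert(0, "chrom", np.concatenate([["."], cm.gene_chrom]))
        out.insert(1, "midpoint",
                   np.concatenate([[0], cm.gene_midpoint]).astype(int))
    _write_tsv(out, path, meta, index=True)


def read_counts_tsv(path: str) -> CountsMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    has_pos = "chrom" in df.columns
    if has_pos:
        chrom = df["chrom"].to_numpy()[1:]
        midpoint = df["midpoint"].to_numpy()[1:].astype(int)
        df = df.drop(columns=["chrom", "midpoint"])
    else:
        chrom = midpoint = None
    lib = df.loc["__lib_size__"].to_numpy(dtype=float)
    body = df.drop(index="__lib_size__")
    return CountsMatrix(
        counts=body.to_numpy(dtype=np.int64),
        gene_ids=[str(g) for g in body.index],
        sample_ids=[str(s) for s in body.columns],
        lib_sizes=lib,
        gene_chrom=chrom,
        gene_midpoint=midpoint,
    )


def write_table(df: pd.DataFrame, path: str, meta: dict | None = None,
                index: bool = False) -> None:
    """Generic metadata-bearing TSV writer used by every stage."""
    _write_tsv(df, path, meta, index=index)


def read_table(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
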