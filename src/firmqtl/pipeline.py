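"""End-to-end orchestration of the firmness-locus analysis stages.

Stages communicate only through declared files in the output directory,
so deleting intermediates and rerunning with the same configuration
reproduces them bit-identically:

    simulate    -> genotypes.vcf, phenotypes.tsv, counts.tsv, truth.tsv
    heritability-> varcomp.tsv, emms.tsv, heritability.tsv
    gwas        -> kinship.tsv, gwas.tsv
    qtt         -> log2cpm.tsv, qtt.tsv, modules.tsv
    eqtl        -> eqtl.tsv
    marker-eval -> marker_effects.tsv, segregation.tsv

A JSON manifest lists each stage's status, inputs, outputs, seed,
package version and wall time.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, assoc, eqtl as eqtl_mod, io, linmix, markereval, qtt, simpop

STAGES = ("simulate", "heritability", "gwas", "qtt", "eqtl", "marker-eval")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Flat run configuration; any SimConfig field may be overridden
    through ``sim`` keys of the config file."""

    out_dir: str = "firmqtl_run"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    alpha: float = 0.05
    qtt_p_threshold: float = 0.005
    eqtl_p_threshold: float = 0.005
    cis_window: int = 1_000_000
    n_modules: int = 3
    filter_min_cpm: float = 1.0
    cpm_prior: float = 0.5
    sim: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise simpop.ConfigurationError(f"unknown stages: {unknown}")
        for name, lo in (("alpha", 0.0), ("qtt_p_threshold", 0.0),
                         ("eqtl_p_threshold", 0.0)):
            v = getattr(self, name)
            if not lo < v < 1.0:
                raise simpop.ConfigurationError(
                    f"{name} must be in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise simpop.ConfigurationError("config must be a mapping")
        sim = {}
        known = {f.name for f in dataclasses.fields(cls)}
        sim_known = {f.name for f in dataclasses.fields(simpop.SimConfig)}
        top = {}
        for k, v in raw.items():
            if k in known and k != "sim":
                top[k] = tuple(v) if k == "stages" else v
            elif k in sim_known:
                sim[k] = tuple(v) if isinstance(v, list) else v
            else:
                raise simpop.ConfigurationError(f"unknown config key: {k}")
        top["sim"] = sim
        return cls(**top)

    def sim_config(self) -> simpop.SimConfig:
        return simpop.SimConfig(seed=self.seed, **self.sim)


def _meta(config: RunConfig) -> dict:
    return {"seed": config.seed, "version": __version__}


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(stage, "missing-input", f"required file {path}")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns (and
    writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    runners = {
        "simulate": _stage_simulate,
        "heritability": _stage_heritability,
        "gwas": _stage_gwas,
        "qtt": _stage_qtt,
        "eqtl": _stage_eqtl,
        "marker-eval": _stage_markereval,
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            files = runners[stage](config, out)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-tag with stage context
            raise StageError(stage, "stage-failure", str(exc)) from exc
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": [str(f) for f in files],
            "wall_time_s": round(time.time() - t0, 3),
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _stage_simulate(config: RunConfig, out: Path) -> list[Path]:
    cfg = config.sim_config()
    G = simpop.simulate_genotypes(cfg)
    pheno, truth = simpop.simulate_phenotypes(cfg, G)
    counts = simpop.simulate_expression(cfg, G)
    meta = _meta(config)
    io.write_vcf(G, out / "genotypes.vcf", meta)
    io.write_pheno_tsv(pheno, out / "phenotypes.tsv", meta)
    io.write_counts_tsv(counts, out / "counts.tsv", meta)
    truth_df = pd.DataFrame({
        "key": ["a", "d", "H2", "h2", "sigma2_G_total",
                "major_locus_index", "focal_gene_index"],
        "value": [truth.a, truth.d, truth.H2, truth.h2,
                  truth.sigma2_G_total, truth.major_locus_index,
                  truth.focal_gene_index],
    })
    io.write_table(truth_df, out / "truth.tsv", meta)
    bv = pd.DataFrame({"individual": G.individuals,
                       "breeding_value": truth.breeding_values})
    io.write_table(bv, out / "breeding_values.tsv", meta)
    return [out / f for f in ("genotypes.vcf", "phenotypes.tsv",
                              "counts.tsv", "truth.tsv",
                              "breeding_values.tsv")]


def _stage_heritability(config: RunConfig, out: Path) -> list[Path]:
    stage = "heritability"
    pheno = io.read_pheno_tsv(_require(out / "phenotypes.tsv", stage))
    vc = linmix.reml_fit(pheno, linmix.FIRMNESS_VC_MODEL)
    emm_fit = linmix.reml_fit(pheno, linmix.FIRMNESS_EMM_MODEL)
    emms = linmix.estimate_emms(emm_fit, pheno)
    n_years = pheno["year"].nunique()
    reps = pheno.groupby(["individual", "year"]).size()
    r_harm = linmix.harmonic_mean_reps(
        reps.groupby(level="individual").mean()
    )
    H2 = linmix.broad_sense_h2(vc, n_years, r_harm)
    sigma2_P = (vc["individual"] + vc.variances.get("individual:year", 0.0)
                / n_years + vc["residual"] / (r_harm * n_years))
    G = io.read_vcf(_require(out / "genotypes.vcf", stage))
    K = assoc.vanraden_kinship(G)
    h2 = linmix.narrow_sense_h2(emms, K, sigma2_P)
    meta = _meta(config)
    io.write_table(
        pd.DataFrame(
            {"component": list(vc.variances), "variance": list(vc.variances.values())}
        ), out / "varcomp.tsv", meta)
    io.write_table(emms, out / "emms.tsv", meta)
    io.write_table(
        pd.DataFrame({
            "statistic": ["H2", "h2", "r_harmonic", "n_years", "sigma2_Pbar"],
            "value": [H2, h2, r_harm, n_years, sigma2_P],
        }), out / "heritability.tsv", meta)
    return [out / f for f in ("varcomp.tsv", "emms.tsv", "heritability.tsv")]


def _stage_gwas(config: RunConfig, out: Path) -> list[Path]:
    stage = "gwas"
    G = io.read_vcf(_require(out / "genotypes.vcf", stage))
    emms = io.read_table(_require(out / "emms.tsv", stage))
    emm_map = emms.set_index("individual")["emm"]
    y = emm_map.loc[G.individuals].to_numpy(dtype=float)
    K = assoc.vanraden_kinship(G)
    scan = assoc.gwas_scan(y, G, K=K)
    thr = assoc.bonferroni_threshold(
        int((~scan["monomorphic"]).sum()), config.alpha)
    meta = dict(_meta(config), bonferroni_neglog10p=round(thr, 4))
    kin = pd.DataFrame(K.values, index=K.individuals, columns=K.individuals)
    kin.index.name = "individual"
    io.write_table(kin, out / "kinship.tsv", _meta(config), index=True)
    io.write_table(scan, out / "gwas.tsv", meta)
    return [out / "kinship.tsv", out / "gwas.tsv"]


def _stage_qtt(config: RunConfig, out: Path) -> list[Path]:
    stage = "qtt"
    cm = io.read_counts_tsv(_require(out / "counts.tsv", stage))
    emms = io.read_table(_require(out / "emms.tsv", stage))
    kin = io.read_table(_require(out / "kinship.tsv", stage), index_col=0)
    keep = qtt.filter_by_expression(cm, min_cpm=config.filter_min_cpm)
    factors = qtt.tmm_norm_factors(cm.counts[keep], cm.lib_sizes)
    expr = qtt.log2_cpm(cm.counts[keep], cm.lib_sizes, factors,
                        prior=config.cpm_prior)
    gene_ids = [g for g, k in zip(cm.gene_ids, keep) if k]
    emm_map = emms.set_index("individual")["emm"]
    y = emm_map.loc[cm.sample_ids].to_numpy(dtype=float)
    K = assoc.KinshipMatrix(
        kin.loc[cm.sample_ids, cm.sample_ids].to_numpy(), cm.sample_ids)
    y_adj = qtt.polygenic_adjust(y, K)
    table = qtt.qtt_scan(expr, y_adj, config.qtt_p_threshold, gene_ids)
    meta = _meta(config)
    expr_df = pd.DataFrame(expr, index=gene_ids, columns=cm.sample_ids)
    expr_df.index.name = "gene"
    io.write_table(expr_df, out / "log2cpm.tsv", meta, index=True)
    io.write_table(table, out / "qtt.tsv",
                   dict(meta, p_threshold=config.qtt_p_threshold))
    sig = table[table["significant"]]["gene"].tolist()
    if len(sig) >= config.n_modules:
        sub = expr_df.loc[sig].to_numpy()
        labels, _ = qtt.coexpression_modules(sub, config.n_modules, sig)
        mod_df = labels.rename_axis("gene").reset_index()
    else:
        mod_df = pd.DataFrame(columns=["gene", "module"])
    io.write_table(mod_df, out / "modules.tsv", meta)
    return [out / f for f in ("log2cpm.tsv", "qtt.tsv", "modules.tsv")]


def _stage_eqtl(config: RunConfig, out: Path) -> list[Path]:
    stage = "eqtl"
    G = io.read_vcf(_require(out / "genotypes.vcf", stage))
    cm = io.read_counts_tsv(_require(out / "counts.tsv", stage))
    expr_df = io.read_table(_require(out / "log2cpm.tsv", stage),
                            index_col=0)
    expr_df = expr_df[G.individuals]
    gene_pos = dict(zip(cm.gene_ids, zip(cm.gene_chrom, cm.gene_midpoint)))
    chroms = np.array([gene_pos[g][0] for g in expr_df.index])
    mids = np.array([gene_pos[g][1] for g in expr_df.index])
    table, log = eqtl_mod.eqtl_scan(
        G, expr_df.to_numpy(), config.eqtl_p_threshold,
        gene_ids=list(expr_df.index), gene_chrom=chroms,
        gene_midpoint=mids, cis_window=config.cis_window)
    meta = dict(_meta(config), p_threshold=config.eqtl_p_threshold,
                n_pairs_tested=log.n_pairs_tested)
    io.write_table(table, out / "eqtl.tsv", meta)
    return [out / "eqtl.tsv"]


def _stage_markereval(config: RunConfig, out: Path) -> list[Path]:
    stage = "marker-eval"
    G = io.read_vcf(_require(out / "genotypes.vcf", stage))
    emms = io.read_table(_require(out / "emms.tsv", stage))
    scan = io.read_table(_require(out / "gwas.tsv", stage))
    herit = io.read_table(_require(out / "heritability.tsv", stage))
    qtt_table = io.read_table(_require(out / "qtt.tsv", stage))
    expr_df = io.read_table(_require(out / "log2cpm.tsv", stage),
                            index_col=0)

    stats = herit.set_index("statistic")["value"]
    sigma2_P = float(stats["sigma2_Pbar"])
    sigma2_G = float(stats["H2"]) * sigma2_P
    emm_map = emms.set_index("individual")["emm"]
    y = emm_map.loc[G.individuals].to_numpy(dtype=float)

    top = scan.loc[scan["p_wald"].idxmin()]
    j = G.marker_ids.index(top["marker"])
    dosage = G.dosages[:, j]

    # focal transcript: the gene with the strongest association at the
    # evaluated marker (mirroring "most significant cis-eQTL"), falling
    # back to the strongest QTT gene if the marker has no eQTL record
    focal_gene = None
    eqtl_path = out / "eqtl.tsv"
    if eqtl_path.exists():
        etab = io.read_table(eqtl_path)
        at_marker = etab[etab["marker"] == top["marker"]]
        if not at_marker.empty:
            focal_gene = at_marker.loc[at_marker["p"].idxmin(), "gene"]
    if focal_gene is None:
        qtt_ok = qtt_table.dropna(subset=["p"])
        focal_gene = qtt_ok.loc[qtt_ok["p"].idxmin(), "gene"]
    expression = expr_df.loc[focal_gene, G.individuals].to_numpy(dtype=float)

    record = markereval.evaluate_marker(
        str(top["marker"]), y, dosage, expression=expression,
        sigma2_P=sigma2_P, sigma2_G=sigma2_G)
    meta = dict(_meta(config), focal_gene=focal_gene)
    io.write_table(pd.DataFrame([record.as_row()]),
                   out / "marker_effects.tsv", meta)

    # segregation of a het x het full-sib family at the top marker
    fam = simpop.simulate_fullsib(1, 1, 152,
                                  seed=np.random.default_rng(
                                      [config.seed, 9]))
    n2, n1, n0 = (int((fam == 2).sum()), int((fam == 1).sum()),
                  int((fam == 0).sum()))
    seg = markereval.segregation_chisq((n2, n1, n0))
    io.write_table(
        pd.DataFrame([{
            "n_favorable_hom": n2, "n_het": n1, "n_unfavorable_hom": n0,
            "chisq": seg.chisq, "df": seg.df, "p": seg.p,
        }]), out / "segregation.tsv", meta)
    return [out / "marker_effects.tsv", out / "segregation.tsv"]
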