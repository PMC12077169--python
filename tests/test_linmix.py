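"""REML variance components, marginal means and heritability formulas."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from firmqtl.linmix import (
    FIRMNESS_VC_MODEL,
    ModelSpec,
    broad_sense_h2,
    estimate_emms,
    harmonic_mean_reps,
    narrow_sense_h2,
    reml_fit,
)


@pytest.fixture(scope="module")
def oneway_balanced():
    """5 groups x 4 replicates with positive between-group variance."""
    rng = np.random.default_rng(0)
    groups = np.repeat([f"g{i}" for i in range(5)], 4)
    eff = dict(zip(sorted(set(groups)), rng.normal(0, 2, 5)))
    y = np.array([eff[g] for g in groups]) + rng.normal(0, 1, 20)
    return pd.DataFrame({"grp": groups, "value": y})


@pytest.fixture(scope="module")
def crossed_data():
    """Two crossed random factors, 6 x 8 complete layout."""
    rng = np.random.default_rng(5)
    df = pd.DataFrame({
        "A": np.repeat([f"a{i}" for i in range(6)], 8),
        "B": np.tile([f"b{i}" for i in range(8)], 6),
    })
    df["value"] = (rng.normal(0, 1, 48)
                   + np.repeat(rng.normal(0, 1, 6), 8)
                   + np.tile(rng.normal(0, 0.7, 8), 6))
    return df


class TestRemlFit:
    def test_constant_response_gives_zero_variances(self):
        df = pd.DataFrame({"grp": list("aabb"), "value": [3.0] * 4})
        fit = reml_fit(df, ModelSpec("value", random=("grp",)))
        assert all(v == 0.0 for v in fit.variances.values())

    def test_matches_balanced_anova_estimators(self, oneway_balanced):
        df = oneway_balanced
        fit = reml_fit(df, ModelSpec("value", random=("grp",)))
        r = 4
        msb = r * df.groupby("grp")["value"].mean().var(ddof=1)
        msw = df.groupby("grp")["value"].var(ddof=1).mean()
        assert fit.variances["grp"] == pytest.approx((msb - msw) / r,
                                                     abs=1e-6)
        assert fit.variances["residual"] == pytest.approx(msw, abs=1e-6)

    def test_matches_lme4_on_crossed_design(self, crossed_data, tmp_path):
        """Independent cross-check of the crossed-random-effects REML
        against lme4."""
        df = crossed_data
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(value ~ 1 + (1|A) + (1|B), data=d, REML=TRUE,
                      control=lmerControl(optCtrl=list(xtol_abs=1e-12,
                                                       ftol_abs=1e-12)))
            vc <- as.data.frame(VarCorr(m))
            write.csv(vc[, c("grp", "vcov")],
                      "{tmp_path / 'vc.csv'}", row.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        vc = pd.read_csv(tmp_path / "vc.csv").set_index("grp")["vcov"]
        fit = reml_fit(df, ModelSpec("value", random=("A", "B")))
        assert fit.variances["A"] == pytest.approx(vc["A"], rel=1e-3,
                                                   abs=1e-6)
        assert fit.variances["B"] == pytest.approx(vc["B"], rel=1e-3,
                                                   abs=1e-6)
        assert fit.variances["residual"] == pytest.approx(vc["Residual"],
                                                          rel=1e-3)

    def test_shift_invariance_of_variances(self, crossed_data):
        spec = ModelSpec("value", random=("A", "B"))
        fit0 = reml_fit(crossed_data, spec)
        shifted = crossed_data.assign(value=crossed_data["value"] + 100.0)
        fit1 = reml_fit(shifted, spec)
        for k in fit0.variances:
            assert fit0.variances[k] == pytest.approx(
                fit1.variances[k], rel=1e-4, abs=1e-8)

    def test_recovers_genetic_variance_on_simulated_trial(self):
        """Mean REML genetic variance over 20 simulated trials is within
        10% of the simulated truth."""
        from firmqtl.simpop import SimConfig, simulate_genotypes, \
            simulate_phenotypes

        est = []
        for seed in range(20):
            cfg = SimConfig(n_individuals=85, seed=300 + seed)
            G = simulate_genotypes(cfg)
            pheno, truth = simulate_phenotypes(cfg, G)
            fit = reml_fit(pheno, FIRMNESS_VC_MODEL)
            est.append(fit.variances["individual"])
        assert np.mean(est) == pytest.approx(0.010, rel=0.10)


class TestEmms:
    def test_single_factor_emm_equals_group_mean(self, oneway_balanced):
        df = oneway_balanced.rename(columns={"grp": "individual"})
        fit = reml_fit(df, ModelSpec("value", fixed=("individual",)))
        emms = estimate_emms(fit, df)
        raw = df.groupby("individual")["value"].mean()
        np.testing.assert_allclose(
            emms.set_index("individual")["emm"], raw[emms["individual"]],
            atol=1e-8)

    def test_balanced_two_factor_emm_equals_group_mean(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "individual": np.repeat(["i1", "i2", "i3"], 4),
            "harvest": np.tile(["h1", "h2"], 6),
        })
        df["value"] = rng.normal(0, 1, 12)
        fit = reml_fit(df, ModelSpec(
            "value", fixed=("individual", "harvest")))
        emms = estimate_emms(fit, df)
        raw = df.groupby("individual")["value"].mean()
        np.testing.assert_allclose(
            emms.set_index("individual")["emm"], raw[emms["individual"]],
            atol=1e-8)

    def test_unbalanced_emm_averages_observed_cell_means(self):
        """With a saturated genotype x harvest model and one empty cell,
        the EMM is the equally weighted average of the genotype's
        observed cell means."""
        rows = []
        vals = {("i1", "h1"): [1.0, 1.2], ("i1", "h2"): [2.0],
                ("i1", "h3"): [3.0, 3.4],
                ("i2", "h1"): [0.5], ("i2", "h2"): [1.5, 1.7]}
        for (ind, h), vs in vals.items():
            rows.extend({"individual": ind, "harvest": h, "value": v}
                        for v in vs)
        df = pd.DataFrame(rows)
        fit = reml_fit(df, ModelSpec(
            "value",
            fixed=("individual", "harvest", "individual:harvest")))
        emms = estimate_emms(fit, df).set_index("individual")["emm"]
        cell = df.groupby(["individual", "harvest"])["value"].mean()
        assert emms["i1"] == pytest.approx(
            cell.loc["i1"].mean(), abs=1e-8)  # (1.1 + 2.0 + 3.2)/3
        assert emms["i2"] == pytest.approx(cell.loc["i2"].mean(), abs=1e-8)

    def test_requires_genotype_fixed(self, oneway_balanced):
        df = oneway_balanced.rename(columns={"grp": "individual"})
        fit = reml_fit(df, ModelSpec("value", random=("individual",)))
        with pytest.raises(ValueError):
            estimate_emms(fit, df)


class TestHeritability:
    def test_harmonic_mean_examples(self):
        assert harmonic_mean_reps([4, 4, 4]) == pytest.approx(4.0)
        assert harmonic_mean_reps([2, 4, 8]) == pytest.approx(
            3 / (0.5 + 0.25 + 0.125))
        assert harmonic_mean_reps([7]) == pytest.approx(7.0)
        with pytest.raises(ValueError):
            harmonic_mean_reps([4, 0])

    def test_broad_sense_formula(self):
        vc = {"individual": 2.0, "individual:year": 1.0, "residual": 4.0}
        assert broad_sense_h2(vc, 2, 4.0) == pytest.approx(2 / 3)
        vc0 = {"individual": 0.0, "individual:year": 1.0, "residual": 4.0}
        assert broad_sense_h2(vc0, 2, 4.0) == 0.0
        vc1 = {"individual": 2.0, "individual:year": 0.0, "residual": 0.0}
        assert broad_sense_h2(vc1, 2, 4.0) == 1.0

    def test_narrow_sense_near_zero_without_genetic_signal(self):
        from firmqtl.assoc import vanraden_kinship
        from firmqtl.simpop import SimConfig, simulate_genotypes

        cfg = SimConfig(seed=8)
        G = simulate_genotypes(cfg)
        K = vanraden_kinship(G)
        rng = np.random.default_rng(9)
        y = rng.normal(0.3, 0.1, cfg.n_individuals)
        emms = pd.DataFrame({"individual": G.individuals, "emm": y})
        h2 = narrow_sense_h2(emms, K, float(np.var(y, ddof=1)))
        assert h2 <= 0.15

    def test_narrow_sense_recovers_additive_h2(self):
        """Purely additive simulations: kinship-based h2 within 0.1 of
        the simulated clone-mean heritability, and never much above the
        broad-sense value when dominance is present."""
        from firmqtl.assoc import vanraden_kinship
        from firmqtl.simpop import SimConfig, simulate_genotypes, \
            simulate_phenotypes

        h2_add, h2_dom = [], []
        for seed in range(20):
            for d, sink in ((0.0, h2_add), (0.08, h2_dom)):
                cfg = SimConfig(n_individuals=200, d=d, seed=500 + seed)
                G = simulate_genotypes(cfg)
                pheno, truth = simulate_phenotypes(cfg, G)
                y = (pheno.groupby("individual")["value"].mean()
                     .loc[G.individuals])
                emms = pd.DataFrame({"individual": G.individuals,
                                     "emm": y.to_numpy()})
                K = vanraden_kinship(G)
                vc_P = float(y.var(ddof=1))
                sink.append(narrow_sense_h2(emms, K, vc_P))
        assert np.mean(h2_add) == pytest.approx(0.5, abs=0.1)
        assert np.mean(h2_dom) <= 0.5 + 0.05
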