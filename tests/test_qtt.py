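"""TMM normalization, log2 CPM, polygenic adjustment, QTT scan and
co-expression modules."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from firmqtl.assoc import vanraden_kinship
from firmqtl.qtt import (
    coexpression_modules,
    filter_by_expression,
    log2_cpm,
    polygenic_adjust,
    qtt_scan,
    tmm_norm_factors,
)


def brute_force_tmm(counts, lib, ref):
    """Independent re-derivation of the TMM factor: explicit sort-based
    double trim and inverse-variance weighting, per sample vs ref."""
    n_samp = counts.shape[1]
    out = np.ones(n_samp)
    for j in range(n_samp):
        fs = []
        keep = (counts[:, j] > 0) & (counts[:, ref] > 0)
        o = counts[keep, j] / lib[j]
        r = counts[keep, ref] / lib[ref]
        M = np.log2(o / r)
        A = 0.5 * np.log2(o * r)
        w = 1.0 / ((lib[j] - counts[keep, j]) / (lib[j] * counts[keep, j])
                   + (lib[ref] - counts[keep, ref])
                   / (lib[ref] * counts[keep, ref]))
        if M.size == 0 or np.max(np.abs(M)) < 1e-6:
            out[j] = 1.0
            continue
        n = M.size
        # indices surviving a 30% trim on M and a 5% trim on A
        loM, hiM = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        loA, hiA = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        rm = scipy.stats.rankdata(M)
        ra = scipy.stats.rankdata(A)
        sel = (rm >= loM) & (rm <= hiM) & (ra >= loA) & (ra <= hiA)
        out[j] = 2.0 ** (np.sum(w[sel] * M[sel]) / np.sum(w[sel]))
    return out / np.exp(np.mean(np.log(out)))


@pytest.fixture(scope="module")
def spiked_counts():
    """4 samples, 60 genes, one strongly spiked gene in sample 2."""
    rng = np.random.default_rng(10)
    base = rng.poisson(200, size=(60, 1)).astype(float)
    counts = np.tile(base, (1, 4)) + rng.poisson(20, size=(60, 4))
    counts[5, 2] += 20_000  # composition outlier
    lib = counts.sum(axis=0)
    return counts, lib


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile(np.arange(1, 51)[:, None], (1, 3)).astype(float)
        f = tmm_norm_factors(counts)
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_pure_depth_difference_gives_unit_factors(self):
        c1 = np.arange(1, 51).astype(float)
        counts = np.column_stack([c1, 2 * c1])
        f = tmm_norm_factors(counts)
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_matches_independent_brute_force(self, spiked_counts):
        counts, lib = spiked_counts
        f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                        for j in range(4)])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        ours = tmm_norm_factors(counts, lib)
        oracle = brute_force_tmm(counts, lib, ref)
        np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_matches_edger_calcnormfactors(self, spiked_counts, tmp_path):
        counts, lib = spiked_counts
        df = pd.DataFrame(counts.astype(int))
        csv = tmp_path / "counts.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.csv("{csv}"))
            f <- calcNormFactors(x, lib.size=c({",".join(map(str, lib))}),
                                 method="TMM")
            write.csv(data.frame(f=f), "{tmp_path / 'f.csv'}",
                      row.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "f.csv")["f"].to_numpy()
        ours = tmm_norm_factors(counts, lib)
        np.testing.assert_allclose(ours, ref, atol=1e-6)

    def test_all_zero_sample_rejected(self):
        counts = np.ones((10, 3))
        counts[:, 1] = 0
        with pytest.raises(ValueError, match="1"):
            tmm_norm_factors(counts)


class TestFilterAndCpm:
    def test_all_zero_gene_dropped(self):
        counts = np.vstack([np.zeros(6), np.full(6, 50.0)])
        mask = filter_by_expression(counts, min_cpm=1.0, min_samples=1)
        assert not mask[0] and mask[1]

    def test_boundary_gene_kept(self):
        # gene at exactly min_cpm in exactly min_samples samples
        lib = np.full(6, 1e6)
        counts = np.zeros((1, 6))
        counts[0, :3] = 5.0  # CPM exactly 5
        mask = filter_by_expression(counts, lib_sizes=lib, min_cpm=5.0,
                                    min_samples=3)
        assert mask[0]

    def test_hand_evaluated_fixture(self):
        lib = np.full(6, 1e6)
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 30, size=(10, 6)).astype(float)
        mask = filter_by_expression(counts, lib, min_cpm=10.0,
                                    min_samples=4)
        expected = ((counts / 1e6 * 1e6 >= 10).sum(axis=1) >= 4)
        np.testing.assert_array_equal(mask, expected)

    def test_log2_cpm_zero_count_formula(self):
        out = log2_cpm(np.array([[0.0]]), np.array([1e6]), prior=0.5)
        assert out[0, 0] == pytest.approx(
            np.log2(0.5 / 1_000_001 * 1e6), abs=1e-3)
        assert out[0, 0] == pytest.approx(-1.0, abs=1e-3)

    def test_log2_cpm_doubling_large_count_adds_one(self):
        lib = np.array([1e6, 1e6])
        out = log2_cpm(np.array([[2000.0, 4000.0]]), lib)
        assert out[0, 1] - out[0, 0] == pytest.approx(1.0, abs=0.01)

    def test_equal_columns_identical(self):
        counts = np.tile(np.arange(1, 11)[:, None], (1, 2)).astype(float)
        out = log2_cpm(counts, np.array([1e5, 1e5]))
        np.testing.assert_allclose(out[:, 0], out[:, 1])

    def test_library_scaling_shifts_by_constant(self):
        """Scaling every library size by c shifts log2 CPM by -log2(c)
        uniformly, so all between-sample contrasts and correlations are
        invariant."""
        rng = np.random.default_rng(12)
        counts = rng.poisson(5000, size=(20, 5)).astype(float)
        lib = counts.sum(axis=0)
        a = log2_cpm(counts, lib)
        b = log2_cpm(counts, 4.0 * lib)
        np.testing.assert_allclose(b - a, -2.0, atol=1e-4)


class TestPolygenicAdjust:
    def test_identity_kinship_recovers_centered_phenotype(self):
        rng = np.random.default_rng(13)
        y = rng.normal(0, 1, 30)
        adj = polygenic_adjust(y, np.eye(30))
        r = np.corrcoef(adj, y - y.mean())[0, 1]
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_constant_phenotype_gives_zero_residuals(self):
        adj = polygenic_adjust(np.full(20, 3.0), np.eye(20))
        np.testing.assert_allclose(adj, 0.0)

    def test_adjustment_strips_polygenic_signal(self):
        """The environmental residuals carry far less of the true
        polygenic signal than the raw phenotype, and are mean-zero."""
        from firmqtl.assoc import emma_null_fit
        from firmqtl.simpop import SimConfig, simulate_genotypes

        rng = np.random.default_rng(14)
        G = simulate_genotypes(SimConfig(n_individuals=150, seed=14))
        K = vanraden_kinship(G)
        s, U = np.linalg.eigh(K.values)
        g = U @ (np.sqrt(np.clip(s, 0, None)) * rng.normal(size=150))
        y = 0.3 + g + rng.normal(0, 0.7, 150)
        null = emma_null_fit(y, K)
        adj = polygenic_adjust(y, K, null=null)
        assert abs(np.mean(adj)) < 0.05 * np.std(y)
        assert abs(np.corrcoef(adj, g)[0, 1]) < abs(
            np.corrcoef(y, g)[0, 1])


class TestQttScan:
    def test_gene_identical_to_phenotype(self):
        rng = np.random.default_rng(15)
        y = rng.normal(0, 1, 20)
        expr = np.vstack([y, rng.normal(0, 1, 20)])
        tab = qtt_scan(expr, y, 0.005, ["g1", "g2"])
        assert tab["r"][0] == pytest.approx(1.0)
        assert tab["p"][0] < 1e-12
        assert tab["significant"][0]

    def test_t_pvalue_agrees_with_permutation(self):
        """Analytic t-transform p matches a 10 000-rep permutation p
        within 0.01 for a moderately correlated fixture gene."""
        rng = np.random.default_rng(16)
        n = 40
        y = rng.normal(0, 1, n)
        g = 0.45 * y + rng.normal(0, 1, n)
        robs = np.corrcoef(g, y)[0, 1]
        perm_r = np.empty(10_000)
        for i in range(10_000):
            perm_r[i] = np.corrcoef(g, rng.permutation(y))[0, 1]
        p_perm = (np.sum(np.abs(perm_r) >= abs(robs)) + 1) / 10_001
        tab = qtt_scan(g[None, :], y, 0.005, ["g"])
        assert tab["p"][0] == pytest.approx(p_perm, abs=0.01)

    def test_zero_variance_gene_flagged(self):
        rng = np.random.default_rng(17)
        y = rng.normal(0, 1, 10)
        expr = np.vstack([np.full(10, 2.0), y])
        tab = qtt_scan(expr, y, 0.005)
        assert tab["degenerate"][0]
        assert not tab["significant"][0]
        assert np.isnan(tab["r"][0])


class TestModules:
    def test_two_anticorrelated_groups_recovered(self):
        t = np.linspace(0, 4 * np.pi, 30)
        up = np.sin(t)
        rng = np.random.default_rng(18)
        expr = np.vstack([up + rng.normal(0, 0.05, 30) for _ in range(5)]
                         + [-up + rng.normal(0, 0.05, 30)
                            for _ in range(5)])
        labels, _ = coexpression_modules(expr, 2)
        arr = labels.to_numpy()
        assert len(set(arr[:5])) == 1
        assert len(set(arr[5:])) == 1
        assert arr[0] != arr[5]

    def test_linkage_heights_monotone(self):
        rng = np.random.default_rng(19)
        expr = rng.normal(0, 1, size=(25, 40))
        _, Z = coexpression_modules(expr, 3)
        heights = Z[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_constant_gene_rejected_by_name(self):
        expr = np.vstack([np.ones(10), np.random.default_rng(20).normal(
            0, 1, (3, 10))])
        with pytest.raises(ValueError, match="gene00000"):
            coexpression_modules(expr, 2)
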