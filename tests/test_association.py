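"""Kinship, mixed-model likelihoods, the LRT scan, and SNP→gene reduction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netprio.association import (
    AssociationResult,
    GenotypeMatrix,
    KinshipMatrix,
    assign_snps_to_genes,
    bonferroni_threshold,
    compute_kinship,
    lmm_ml_loglik,
    load_genotypes,
    load_phenotype,
    load_snp_pvalues,
    snp_lrt_scan,
)
from netprio.network_io import GeneAnnotation


def make_genotypes(calls, positions=None, chrom="chr1"):
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    snps = pd.DataFrame(
        {"snp_id": [f"s{j}" for j in range(m)], "chrom": chrom, "pos": positions}
    )
    return GenotypeMatrix([f"S{i}" for i in range(n)], snps, calls)


def ols_ml_loglik(y, X):
    """Closed-form Gaussian ML log-likelihood at the OLS fit."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    n = len(y)
    s2 = rss / n
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1)


class TestKinship:
    def test_identical_strains_entry_one(self):
        g = make_genotypes([[0, 1, 1, 0], [0, 1, 1, 0]])
        k = compute_kinship(g)
        assert k.values[0, 1] == 1.0

    def test_opposite_strains_entry_zero(self):
        g = make_genotypes([[0, 1, 0, 1], [1, 0, 1, 0]])
        assert compute_kinship(g).values[0, 1] == 0.0

    def test_excluded_region_has_no_influence(self, rng):
        calls = rng.integers(0, 2, (6, 50)).astype(float)
        g = make_genotypes(calls)
        region = ("chr1", 1, 20_000)  # first 20 SNPs
        k1 = compute_kinship(g, exclude_region=region)
        perturbed = calls.copy()
        perturbed[:, :20] = rng.integers(0, 2, (6, 20))
        k2 = compute_kinship(make_genotypes(perturbed), exclude_region=region)
        assert np.allclose(k1.values, k2.values)

    def test_column_order_invariance(self, rng):
        calls = rng.integers(0, 2, (5, 30)).astype(float)
        k1 = compute_kinship(make_genotypes(calls))
        k2 = compute_kinship(make_genotypes(calls[:, ::-1]))
        assert np.allclose(k1.values, k2.values)

    def test_pairwise_complete_with_missing(self):
        calls = np.array([[0, 1, np.nan, 1], [0, 1, 0, 0]])
        k = compute_kinship(make_genotypes(calls))
        assert k.values[0, 1] == pytest.approx(2 / 3)  # NaN column skipped

    def test_all_excluded_is_error(self):
        g = make_genotypes([[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="excluded"):
            compute_kinship(g, exclude_region=("chr1", 0, 10**9))

    def test_all_missing_strain_is_error(self):
        calls = np.array([[0.0, 1.0], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="all-missing"):
            compute_kinship(make_genotypes(calls))


class TestMixedModelLoglik:
    def test_identity_kinship_equals_ols(self, rng):
        n = 30
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        K = KinshipMatrix([f"S{i}" for i in range(n)], np.eye(n))
        ll, _ = lmm_ml_loglik(y, X, K)
        assert ll == pytest.approx(ols_ml_loglik(y, X), abs=1e-8)

    def test_constant_phenotype_finite(self):
        n = 12
        y = np.ones(n)
        K = KinshipMatrix([f"S{i}" for i in range(n)], np.eye(n))
        ll, _ = lmm_ml_loglik(y, np.ones((n, 1)), K)
        assert np.isfinite(ll)

    def test_singular_design_rejected(self, rng):
        n = 15
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), np.ones(n)])
        K = KinshipMatrix([f"S{i}" for i in range(n)], np.eye(n))
        with pytest.raises(ValueError, match="singular"):
            lmm_ml_loglik(y, X, K)

    def test_nonfinite_phenotype_rejected(self):
        K = KinshipMatrix(["a", "b"], np.eye(2))
        with pytest.raises(ValueError):
            lmm_ml_loglik(np.array([1.0, np.nan]), np.ones((2, 1)), K)

    def test_variance_ratio_recovery_block_kinship(self):
        # sg2 = se2 = 1 (delta = 1): median estimate within [0.5, 2]
        rng = np.random.default_rng(12)
        n, n_blocks = 200, 10
        groups = np.repeat(np.arange(n_blocks), n // n_blocks)
        K = 0.5 * np.eye(n)
        K += 0.5 * (groups[:, None] == groups[None, :])
        L = np.linalg.cholesky(K + 1e-9 * np.eye(n))
        strains = [f"S{i}" for i in range(n)]
        deltas = []
        for _ in range(100):
            u = L @ rng.normal(size=n)
            y = u + rng.normal(size=n)
            _, delta = lmm_ml_loglik(y, np.ones((n, 1)), KinshipMatrix(strains, K))
            deltas.append(delta)
        assert 0.5 <= np.median(deltas) <= 2.0


class TestScan:
    def test_strong_effect_with_identity_kinship(self, rng):
        n = 20
        x = np.array([0.0] * (n // 2) + [1.0] * (n // 2))
        y = x * 3 + rng.normal(scale=0.5, size=n)
        g = make_genotypes(x[:, None])
        K = KinshipMatrix(g.strains, np.eye(n))
        res = snp_lrt_scan(y, g, K)
        assert res.per_snp["p_value"].iloc[0] < 0.001

    def test_identity_kinship_matches_ols_lrt(self, rng):
        n, m = 25, 40
        calls = rng.integers(0, 2, (n, m)).astype(float)
        y = rng.normal(size=n)
        g = make_genotypes(calls)
        res = snp_lrt_scan(y, g, KinshipMatrix(g.strains, np.eye(n)))
        rss0 = float(np.sum((y - y.mean()) ** 2))
        for j, p in enumerate(res.per_snp["p_value"]):
            x = calls[:, j]
            if len(np.unique(x)) < 2:
                continue
            X = np.column_stack([np.ones(n), x])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = float(np.sum((y - X @ beta) ** 2))
            expected = stats.chi2.sf(n * np.log(rss0 / rss1), 1)
            assert p == pytest.approx(expected, abs=1e-6)

    def test_monomorphic_flagged(self, rng):
        calls = np.column_stack([np.zeros(10), rng.integers(0, 2, 10)])
        g = make_genotypes(calls)
        res = snp_lrt_scan(rng.normal(size=10), g, KinshipMatrix(g.strains, np.eye(10)))
        row = res.per_snp.iloc[0]
        assert row["p_value"] == 1.0 and row["flag"] == "monomorphic"

    def test_missing_call_snp_dropped(self, rng):
        calls = rng.integers(0, 2, (8, 3)).astype(float)
        calls[2, 1] = np.nan
        g = make_genotypes(calls)
        res = snp_lrt_scan(rng.normal(size=8), g, KinshipMatrix(g.strains, np.eye(8)))
        assert list(res.per_snp["snp_id"]) == ["s0", "s2"]

    def test_phenotype_series_alignment(self, rng):
        calls = rng.integers(0, 2, (6, 5)).astype(float)
        g = make_genotypes(calls)
        y = pd.Series(rng.normal(size=6), index=g.strains[::-1])  # shuffled index
        res = snp_lrt_scan(y, g, KinshipMatrix(g.strains, np.eye(6)))
        y2 = y.loc[g.strains].to_numpy()
        res2 = snp_lrt_scan(y2, g, KinshipMatrix(g.strains, np.eye(6)))
        assert np.allclose(res.per_snp["p_value"], res2.per_snp["p_value"])


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 13598, 3.68e-6), (0.05, 1, 0.05), (0.05, 15302, 3.27e-6)],
    )
    def test_threshold_values(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=5e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestAssignSnps:
    def _result(self, rows):
        return AssociationResult(
            per_snp=pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "p_value", "flag"])
        )

    def test_snp_inside_gene_body(self):
        genes = [GeneAnnotation("A", "chr1", 100, 200)]
        res = assign_snps_to_genes(self._result([("s1", "chr1", 150, 0.01, "")]), genes)
        assert res.per_snp["assigned_gene"].iloc[0] == "A"
        assert res.per_gene["A"] == pytest.approx(2.0)

    def test_snp_beyond_one_megabase_unassigned(self):
        genes = [GeneAnnotation("A", "chr1", 100, 200)]
        res = assign_snps_to_genes(
            self._result([("s1", "chr1", 1_500_300, 0.01, "")]), genes
        )
        assert res.per_snp["assigned_gene"].iloc[0] == ""
        assert res.n_unassigned == 1
        assert res.per_gene["A"] == 0.0

    def test_max_neglog10_over_snps(self):
        genes = [GeneAnnotation("A", "chr1", 100, 200)]
        res = assign_snps_to_genes(
            self._result(
                [("s1", "chr1", 150, 1e-4, ""), ("s2", "chr1", 160, 1e-6, "")]
            ),
            genes,
        )
        assert res.per_gene["A"] == pytest.approx(6.0)
        detail = res.gene_detail.set_index("gene_id")
        assert detail.loc["A", "best_snp"] == "s2"
        assert detail.loc["A", "n_snps"] == 2

    def test_equidistant_tie_goes_to_smaller_start(self):
        genes = [
            GeneAnnotation("B", "chr1", 300, 400),
            GeneAnnotation("A", "chr1", 100, 200),
        ]
        res = assign_snps_to_genes(self._result([("s1", "chr1", 250, 0.5, "")]), genes)
        assert res.per_snp["assigned_gene"].iloc[0] == "A"

    def test_chromosome_mismatch_unassigned(self):
        genes = [GeneAnnotation("A", "chr1", 100, 200)]
        res = assign_snps_to_genes(self._result([("s1", "chr2", 150, 0.5, "")]), genes)
        assert res.n_unassigned == 1


class TestFileFormats:
    def test_genotype_phenotype_round_trip(self, tmp_path, rng):
        calls = rng.integers(0, 2, (4, 6)).astype(float)
        g = make_genotypes(calls)
        df = g.snps.copy()
        for k, s in enumerate(g.strains):
            df[s] = g.calls[k]
        path = tmp_path / "geno.tsv"
        df.to_csv(path, sep="\t", index=False)
        g2 = load_genotypes(path)
        assert g2.strains == g.strains
        assert np.allclose(g2.calls, g.calls)

        ppath = tmp_path / "pheno.tsv"
        ppath.write_text("strain\tvalue\n" + "\n".join(f"{s}\t1" for s in g.strains))
        y = load_phenotype(ppath)
        assert list(y.index) == g.strains

    def test_precomputed_pvalues(self, tmp_path):
        path = tmp_path / "pv.tsv"
        path.write_text("snp_id\tchrom\tpos\tp\ns1\tchr1\t100\t0.01\n")
        res = load_snp_pvalues(path)
        assert res.per_snp["p_value"].iloc[0] == 0.01
        bad = tmp_path / "bad.tsv"
        bad.write_text("snp_id\tchrom\tpos\tp\ns1\tchr1\t100\t1.5\n")
        with pytest.raises(ValueError):
            load_snp_pvalues(bad)
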