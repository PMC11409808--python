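"""QC filtering, association scans, locus clumping, heritability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dietmr import gwas
from dietmr import synthcohort as sc


class TestHwe:
    def test_perfect_equilibrium(self):
        assert gwas.hwe_test(250, 500, 250) == 1.0

    def test_gross_deviation_fails_filter(self):
        # expected counts under HWE are (250, 500, 250): chi-square 360
        p = gwas.hwe_test(400, 200, 400)
        assert p < 1e-6

    def test_monomorphic_convention(self):
        assert gwas.hwe_test(100, 0, 0) == 1.0
        assert gwas.hwe_test(0, 0, 50) == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            gwas.hwe_test(-1, 2, 3)
        with pytest.raises(ValueError):
            gwas.hwe_test(0, 0, 0)


def _toy_panel():
    """12 variants: 2 INFO-fails, 3 missingness-fails, 2 MAF-fails, 1 HWE-fail."""
    rng = np.random.default_rng(42)
    n = 600
    maf = np.full(12, 0.3)
    maf[5:7] = 1e-5  # MAF failures
    dos = rng.binomial(2, 0.3, size=(n, 12)).astype(np.int8)
    dos[:, 7] = np.where(rng.random(n) < 0.5, 0, 2)  # no hets: HWE failure
    variants = pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(12)],
            "chrom": 1,
            "pos": np.arange(1, 13) * 1000,
            "effect_allele": "A",
            "other_allele": "G",
            "maf": maf,
            "info": [0.2, 0.1] + [0.9] * 10,  # first two: INFO failures
            "missingness": [0.0] * 2 + [0.10, 0.07, 0.06] + [0.0] * 7,  # 3 failures
        }
    )
    return sc.GenotypeMatrix(dos, variants, [f"S{i}" for i in range(n)])


class TestQcFilter:
    def test_toy_panel_counts(self):
        retained, report = gwas.qc_filter(_toy_panel())
        assert report["removed"] == {"info": 2, "missingness": 3, "maf": 2, "hwe": 1}
        assert report["n_retained"] == 4 == retained.n_variants
        assert sum(report["removed"].values()) + report["n_retained"] == 12

    def test_first_failing_filter_wins(self):
        # variant 0 fails INFO; give it a failing MAF too -> still counted under info
        panel = _toy_panel()
        panel.variants.loc[0, "maf"] = 1e-6
        _, report = gwas.qc_filter(panel)
        assert report["removed"]["info"] == 2
        # the double-failing variant is NOT double counted under maf
        assert report["removed"]["maf"] == 2
        assert sum(report["removed"].values()) + report["n_retained"] == 12

    def test_idempotent(self):
        retained, _ = gwas.qc_filter(_toy_panel())
        retained2, report2 = gwas.qc_filter(retained)
        assert retained2.n_variants == retained.n_variants
        assert sum(report2["removed"].values()) == 0

    def test_all_passing_variant_retained(self):
        retained, report = gwas.qc_filter(_toy_panel())
        assert "v3" not in set(retained.variants["id"])  # missingness 0.07
        assert "v11" in set(retained.variants["id"])


class TestPca:
    def test_separates_subpopulations(self):
        rng = np.random.default_rng(0)
        n, M = 400, 100
        group = np.repeat([0, 1], n // 2)
        p = np.where(group[:, None] == 0, 0.15, 0.45)
        dos = rng.binomial(2, np.broadcast_to(p, (n, M)))
        variants = pd.DataFrame(
            {
                "id": [f"v{i}" for i in range(M)],
                "chrom": 1,
                "pos": np.arange(M) + 1,
                "effect_allele": "A",
                "other_allele": "G",
                "maf": 0.3,
                "info": 1.0,
                "missingness": 0.0,
            }
        )
        g = sc.GenotypeMatrix(dos, variants, [f"S{i}" for i in range(n)])
        pc = gwas.pca_covariates(g, 2)
        r = np.corrcoef(pc[:, 0], group)[0, 1]
        assert abs(r) > 0.9

    def test_no_dominant_pc_in_unstructured_panel(self, small_geno):
        Z = gwas._standardize_dosages(small_geno.dosages)
        s = np.linalg.svd(Z, compute_uv=False)
        evals = s**2 / Z.shape[0]
        # leading eigenvalue close to the Marchenko-Pastur bulk edge
        edge = (1 + np.sqrt(Z.shape[1] / Z.shape[0])) ** 2
        assert evals[0] < 1.5 * edge

    def test_k_zero_and_bounds(self, small_geno):
        assert gwas.pca_covariates(small_geno, 0).shape == (1000, 0)
        with pytest.raises(ValueError):
            gwas.pca_covariates(small_geno, 50)

    def test_deterministic_sign(self, small_geno):
        a = gwas.pca_covariates(small_geno, 3)
        b = gwas.pca_covariates(small_geno, 3)
        np.testing.assert_allclose(a, b)


class TestAssociationScan:
    def test_matches_explicit_ols_oracle(self, small_geno):
        """Per-variant scan equals a normal-equations OLS solve to 1e-8."""
        rng = np.random.default_rng(3)
        n = small_geno.n_samples
        covars = pd.DataFrame({"age": rng.normal(55, 8, n), "sex": rng.binomial(1, 0.5, n)})
        y = rng.normal(0, 1, n) + 0.2 * small_geno.dosages[:, 0]
        res = gwas.association_scan(y, small_geno, covars)
        for j in [0, 7, 23]:
            X = np.column_stack(
                [np.ones(n), small_geno.dosages[:, j], covars["age"], covars["sex"]]
            )
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            sigma2 = resid @ resid / (n - X.shape[1])
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            assert res.loc[j, "beta"] == pytest.approx(beta[1], abs=1e-8)
            assert res.loc[j, "se"] == pytest.approx(se, abs=1e-8)

    def test_null_calibration(self):
        geno = sc.simulate_genotypes(5000, 500, (0.05, 0.5), seed=31)
        rng = np.random.default_rng(32)
        y = rng.normal(0, 1, 5000)
        res = gwas.association_scan(y, geno, None)
        frac = (res["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_causal_beta_recovery(self, small_geno):
        rng = np.random.default_rng(33)
        y = 0.3 * small_geno.dosages[:, 5] + rng.normal(0, 1, 1000)
        res = gwas.association_scan(y, small_geno, None)
        lo = res.loc[5, "beta"] - 1.96 * res.loc[5, "se"]
        hi = res.loc[5, "beta"] + 1.96 * res.loc[5, "se"]
        assert lo < 0.3 < hi

    def test_family_adjustment_reduces_relatedness_inflation(self):
        n, M = 4000, 300
        geno = sc.simulate_genotypes(n, M, (0.1, 0.5), seed=35)
        kin = sc.make_families(n, block_size=4, icc=0.4)
        arch = sc.TrueArchitecture(traits={"t": sc.TraitArchitecture([], [], h2=0.0)})
        traits, covars, _ = sc.simulate_traits(geno, arch, kin, seed=36)
        plain = gwas.association_scan(traits["t"], geno, None)
        adj = gwas.association_scan(traits["t"], geno, None, kin=kin)
        # family effect is noise w.r.t. genotype, so both are calibrated;
        # the adjusted scan must not be anticonservative
        assert (adj["p"] < 0.05).mean() < 0.08

    def test_degenerate_inputs(self, small_geno):
        with pytest.raises(ValueError, match="constant"):
            gwas.association_scan(np.ones(1000), small_geno, None)
        covars = pd.DataFrame({"a": np.ones(1000), "b": np.ones(1000)})
        with pytest.raises(ValueError, match="singular"):
            gwas.association_scan(np.random.default_rng(0).normal(size=1000), small_geno, covars)


class TestOutcomeScan:
    def test_injected_loghr_recovered(self):
        n = 20000
        geno = sc.simulate_genotypes(n, 3, (0.3, 0.3), seed=41)
        arch = sc.TrueArchitecture(traits={"d": sc.TraitArchitecture([], [], h2=0.0)})
        traits, covars, _ = sc.simulate_traits(geno, arch, None, seed=42)
        lp = 0.3 * (geno.dosages[:, 1] - geno.dosages[:, 1].mean())
        rate = sc.calibrate_baseline_rate(lp, np.full(n, 12.4), 0.075)
        rng = np.random.default_rng(43)
        t = rng.exponential(1 / (rate * np.exp(lp)))
        event = t <= 12.4
        out = pd.DataFrame(
            {
                "entry_age": covars["age"],
                "exit_age": covars["age"] + np.minimum(t, 12.4),
                "event": event.astype(int),
                "sex": covars["sex"],
            }
        )
        res = gwas.outcome_scan(out, geno, covars[["sex"]])
        assert 0.1 < res.loc[1, "beta"] < 0.5
        assert res.loc[1, "p"] < 1e-4

    def test_null_p_values_uniform(self, study):
        sub = study["geno"].subset_variants(np.arange(150))
        res = gwas.outcome_scan(study["outcome"], sub, None)
        ks = stats.kstest(res["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_zero_events_rejected(self, study):
        out = study["outcome"].copy()
        out["event"] = 0
        with pytest.raises(ValueError, match="events"):
            gwas.outcome_scan(out, study["geno"].subset_variants(np.arange(2)), None)


def _stats_frame(rows):
    df = pd.DataFrame(rows, columns=["id", "chrom", "pos", "p"])
    df["beta"] = 0.1
    df["se"] = 0.02
    return df


class TestSelectLoci:
    def test_no_significant_variants(self):
        df = _stats_frame([("a", 1, 100, 1.0), ("b", 1, 200, 0.5)])
        assert gwas.select_loci(df).empty

    def test_single_variant_forms_own_locus(self):
        df = _stats_frame([("a", 1, 100, 1e-9)])
        loci = gwas.select_loci(df)
        assert len(loci) == 1 and loci.loc[0, "lead_id"] == "a" and loci.loc[0, "n_members"] == 1

    def test_greedy_clumping_hand_trace(self):
        # 5 significant variants within 250 kb of the best one, 1 beyond -> 2 loci
        rows = [
            ("v1", 1, 100_000, 1e-10),
            ("v2", 1, 150_000, 1e-9),
            ("v3", 1, 200_000, 1e-8 / 2),
            ("v4", 1, 300_000, 1e-9),
            ("v5", 1, 340_000, 1e-8 / 3),
            ("far", 1, 900_000, 1e-9),
        ]
        loci = gwas.select_loci(_stats_frame(rows))
        assert len(loci) == 2
        assert set(loci["lead_id"]) == {"v1", "far"}
        assert loci.set_index("lead_id").loc["v1", "n_members"] == 5

    def test_row_order_invariance_and_lead_separation(self):
        rows = [
            ("a", 1, 100_000, 1e-9),
            ("b", 1, 360_000, 1e-12),
            ("c", 2, 100_000, 1e-9),
            ("d", 1, 120_000, 1e-8 / 5),
        ]
        df = _stats_frame(rows)
        l1 = gwas.select_loci(df)
        l2 = gwas.select_loci(df.sample(frac=1, random_state=0).reset_index(drop=True))
        pd.testing.assert_frame_equal(l1, l2)
        leads = l1[l1["chrom"] == 1]
        assert np.abs(np.diff(sorted(leads["pos"]))).min() > 250_000


class TestHeritability:
    def test_pure_genetic_trait_near_one(self):
        geno = sc.simulate_genotypes(2000, 400, (0.1, 0.5), seed=51)
        rng = np.random.default_rng(52)
        ids = list(rng.choice(geno.variants["id"], 50, replace=False))
        g = geno.columns_for(ids) @ rng.normal(0, 1, 50)
        est = gwas.estimate_h2(geno, (g - g.mean()) / g.std())
        assert est.h2 >= 0.9

    def test_null_trait_near_zero(self):
        geno = sc.simulate_genotypes(4000, 600, (0.05, 0.5), seed=53)
        y = np.random.default_rng(54).normal(0, 1, 4000)
        est = gwas.estimate_h2(geno, y)
        assert abs(est.h2) < 0.05 or (est.clipped and est.h2 == 0.0)

    def test_small_sample_rejected(self):
        tiny = sc.simulate_genotypes(400, 20, (0.1, 0.5), seed=55)
        with pytest.raises(ValueError, match="500"):
            gwas.estimate_h2(tiny, np.random.default_rng(0).normal(size=400))


class TestGeneticCorrelation:
    def test_identical_traits_give_unity(self, study):
        geno = study["geno"].subset_variants(np.arange(300))
        y = study["traits"]["total_fruit"]
        res = gwas.genetic_correlation(geno, y, y)
        assert res.rg == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_architectures_near_zero(self):
        geno = sc.simulate_genotypes(6000, 400, (0.1, 0.5), seed=61)
        rng = np.random.default_rng(62)
        ids = rng.choice(geno.variants["id"], 40, replace=False)
        arch = sc.TrueArchitecture(
            traits={
                "a": sc.TraitArchitecture(list(ids[:20]), rng.normal(0, 1, 20), h2=0.3),
                "b": sc.TraitArchitecture(list(ids[20:]), rng.normal(0, 1, 20), h2=0.3),
            }
        )
        traits, _, _ = sc.simulate_traits(geno, arch, None, seed=63)
        res = gwas.genetic_correlation(geno, traits["a"], traits["b"])
        assert abs(res.rg) < 0.25

    def test_half_shared_architecture(self):
        hits = []
        for seed in range(5):
            geno = sc.simulate_genotypes(5000, 300, (0.1, 0.5), seed=70 + seed)
            rng = np.random.default_rng(80 + seed)
            ids = rng.choice(geno.variants["id"], 30, replace=False)
            shared, only_a, only_b = list(ids[:10]), list(ids[10:20]), list(ids[20:])
            arch = sc.TrueArchitecture(
                traits={
                    "a": sc.TraitArchitecture(shared + only_a, np.ones(20), h2=0.3),
                    "b": sc.TraitArchitecture(shared + only_b, np.ones(20), h2=0.3),
                }
            )
            traits, _, _ = sc.simulate_traits(geno, arch, None, seed=90 + seed)
            hits.append(gwas.genetic_correlation(geno, traits["a"], traits["b"]).rg)
        assert 0.3 < np.mean(hits) < 0.7
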