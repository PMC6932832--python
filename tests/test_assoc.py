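"""Association: logistic scans, TDT, PCA, inflation factor, Li-Ji Meff."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ndj21 import assoc
from ndj21 import simulate as sim
from ndj21.cohort import MISSING


@pytest.fixture(scope="module")
def null_panel():
    pop = sim.PopulationModel()
    fs = sim.sample_founder_haplotypes(pop, 400, 800, 100)
    y = np.concatenate([np.ones(200), np.zeros(200)])
    return fs.dosages, y


class TestLogisticScan:
    def test_matches_statsmodels(self, null_panel):
        import statsmodels.api as sm

        G, y = null_panel
        rng = np.random.default_rng(1)
        cov = rng.normal(size=(len(y), 3))
        res = assoc.logistic_scan_matrix(G[:, :20], y, cov)
        for j in range(20):
            X = np.column_stack([np.ones(len(y)), cov, G[:, j]])
            fit = sm.Logit(y, X).fit(disp=0, method="newton")
            assert res["beta"][j] == pytest.approx(fit.params[-1], abs=1e-6)
            assert res["p"][j] == pytest.approx(fit.pvalues[-1], rel=1e-4)

    def test_collapsible_beta_equals_log_contingency_or(self):
        """With binary dosage and no covariates the logistic slope is the log
        of the sample odds ratio from the 2x2 table."""
        rng = np.random.default_rng(2)
        g = rng.integers(0, 2, size=500).astype(float)
        y = (rng.random(500) < np.where(g == 1, 0.6, 0.4)).astype(float)
        res = assoc.logistic_scan_matrix(g[:, None], y)
        a = ((y == 1) & (g == 1)).sum()
        b = ((y == 0) & (g == 1)).sum()
        c = ((y == 1) & (g == 0)).sum()
        d = ((y == 0) & (g == 0)).sum()
        assert res["beta"][0] == pytest.approx(np.log(a * d / (b * c)), abs=1e-8)

    def test_monomorphic_snp_flagged(self, null_panel):
        G, y = null_panel
        g = np.zeros((len(y), 1))
        res = assoc.logistic_scan_matrix(g, y)
        assert res["flag"][0] == "monomorphic"
        assert np.isnan(res["p"][0])

    def test_missing_dosages_complete_case(self, null_panel):
        G, y = null_panel
        g = G[:, 0].astype(float).copy()
        g[:50] = MISSING
        res = assoc.logistic_scan_matrix(g[:, None], y)
        assert res["n_case"][0] + res["n_control"][0] == len(y) - 50

    def test_contrast_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            assoc.ContrastSpec("mi_vs_mii", ("s1", "s2"), ("s2", "s3"))

    def test_risk_snp_or_recovered(self):
        pop = sim.PopulationModel(beta_a=3.0, beta_b=7.0)
        risk = sim.RiskModel(effects=(("bg_000000", np.log(1.5)),), baseline_logit=-3.0)
        gmap = sim.default_genetic_map(n_markers=30)
        ors = []
        for seed in range(8):
            cfg = sim.SimConfig(n_families=700, n_background=30, seed=400 + seed,
                                pop=pop, risk=risk, genetic_map=gmap,
                                parent_pattern_probs=(1.0, 0, 0))
            s = sim.simulate_cohort(cfg)
            mothers = s.cohort.sample_ids("mother")
            fathers = s.cohort.sample_ids("father")[:650]
            G = s.cohort.genotype_matrix(mothers + fathers)
            j = list(s.cohort.variants["id"]).index("bg_000000")
            y = np.concatenate([np.ones(len(mothers)), np.zeros(len(fathers))])
            ors.append(assoc.logistic_scan_matrix(G[:, [j]], y)["OR"][0])
        assert np.mean(ors) == pytest.approx(1.5, abs=0.12)


class TestTdt:
    def _one_variant_cohort(self, child_dosages):
        """Complete trios, mother het / father hom-A at a single background
        SNP, so each trio contributes exactly one scored transmission."""
        from ndj21.cohort import Cohort, TrioRecord, default_genetic_map
        from ndj21.simulate import build_panel

        gmap = default_genetic_map(n_markers=2)
        variants = build_panel(gmap, 1)
        V = len(variants)
        trios = []
        for i, c in enumerate(child_dosages):
            m = np.array([0, 0, 1], dtype=np.int8)
            f = np.array([0, 0, 0], dtype=np.int8)
            ch = np.array([MISSING, MISSING, c], dtype=np.int8)
            trios.append(TrioRecord(
                family_id=f"f{i}", child_id=f"f{i}_c", mother_id=f"f{i}_m",
                father_id=f"f{i}_f", availability="complete",
                mother_geno=m, father_geno=f, child_geno=ch,
                child_tris=np.zeros(2, dtype=np.int8)))
        return Cohort(variants=variants, trios=trios, genetic_map=gmap)

    def test_counts_and_statistic_b20_c10(self):
        cohort = self._one_variant_cohort([1] * 20 + [0] * 10)
        res = assoc.tdt_scan(cohort)
        row = res.iloc[0]
        assert (row["b"], row["c"]) == (20, 10)
        assert row["stat"] == pytest.approx(100 / 30, rel=1e-6)
        assert row["p"] == pytest.approx(stats.chi2.sf(100 / 30, 1), rel=1e-6)
        assert row["p"] == pytest.approx(0.0679, abs=2e-4)

    def test_balanced_transmissions_give_p_one(self):
        cohort = self._one_variant_cohort([1] * 10 + [0] * 10)
        row = assoc.tdt_scan(cohort).iloc[0]
        assert row["stat"] == 0 and row["p"] == 1.0

    def test_allele_swap_invariance(self, complete_cohort):
        cohort = complete_cohort.cohort
        res = assoc.tdt_scan(cohort)
        flipped = cohort.copy()
        for t in flipped.trios:
            for g in (t.mother_geno, t.father_geno, t.child_geno):
                present = g != MISSING
                g[present] = 2 - g[present]
        res2 = assoc.tdt_scan(flipped)
        np.testing.assert_allclose(res["stat"], res2["stat"], rtol=1e-10)
        assert (res["b"] == res2["c"]).all()

    def test_chr21_excluded(self, complete_cohort):
        res = assoc.tdt_scan(complete_cohort.cohort)
        assert not (res["chrom"] == "21").any()


class TestGenomicLambda:
    def test_uniform_null(self):
        rng = np.random.default_rng(3)
        lam = assoc.genomic_lambda(rng.random(100_000))
        assert 0.98 < lam < 1.02

    def test_constant_half(self):
        assert assoc.genomic_lambda(np.full(200, 0.5)) == pytest.approx(1.0)

    def test_inflation_scaling(self):
        rng = np.random.default_rng(4)
        chi = stats.chi2.rvs(1, size=50_000, random_state=rng) * 1.2
        lam = assoc.genomic_lambda(stats.chi2.sf(chi, 1))
        assert lam == pytest.approx(1.2, abs=0.03)


class TestLiJiMeff:
    def test_identity_gives_m(self):
        assert assoc.li_ji_meff(np.eye(7)) == pytest.approx(7.0)

    def test_duplicated_pair_plus_independent(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 1.0
        assert assoc.li_ji_meff(r) == pytest.approx(2.0)

    def test_all_identical_gives_one(self):
        assert assoc.li_ji_meff(np.ones((5, 5))) == pytest.approx(1.0)

    def test_monotone_under_adding_independent_snp(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 6))
        X[:, 1] = X[:, 0] * 0.9 + rng.normal(size=200) * 0.1
        r = np.corrcoef(X, rowvar=False)
        m1 = assoc.li_ji_meff(r)
        r2 = np.eye(7)
        r2[:6, :6] = r
        assert assoc.li_ji_meff(r2) == pytest.approx(m1 + 1, abs=1e-8)
        assert 1 <= m1 <= 6

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            assoc.li_ji_meff(np.array([[1.0, 0.2], [0.3, 1.0]]))
        with pytest.raises(ValueError):
            assoc.li_ji_meff(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestPcaAndSelection:
    def test_independent_snps_mostly_retained(self, mixed_cohort):
        snps = assoc.select_pca_snps(mixed_cohort.cohort, ld_r2_max=0.1)
        v = mixed_cohort.cohort.variants
        parents = (mixed_cohort.cohort.sample_ids("mother")
                   + mixed_cohort.cohort.sample_ids("father"))
        G = mixed_cohort.cohort.genotype_matrix(parents).astype(float)
        p = G.mean(axis=0) / 2
        maf = np.minimum(p, 1 - p)
        screened = ((v["chrom"] != "21") & (maf > 0.05)).sum()
        assert len(snps) >= 0.9 * screened

    def test_duplicated_snp_pruned_and_exclusion_respected(self, mixed_cohort):
        cohort = mixed_cohort.cohort.copy()
        # duplicate variant 1's genotypes into variant 2
        for t in cohort.trios:
            for g in (t.mother_geno, t.father_geno, t.child_geno):
                if g is not None:
                    g[2] = g[1]
        v = cohort.variants
        dup_ids = {v["id"].iloc[1], v["id"].iloc[2]}
        region = [(v["chrom"].iloc[5], v["pos_bp"].iloc[5] - 1, v["pos_bp"].iloc[5] + 1)]
        snps = set(assoc.select_pca_snps(cohort, exclusion_regions=region))
        assert len(snps & dup_ids) <= 1
        assert v["id"].iloc[5] not in snps

    def test_two_subpops_separated_on_pc1(self):
        pop = sim.PopulationModel(n_subpops=2, subpop_weights=(0.5, 0.5), fst=0.1)
        fs = sim.sample_founder_haplotypes(pop, 500, 5000, 200)
        coords, vals = assoc.pca_patterson(fs.dosages)
        side = coords[:, 0] > 0
        acc = max((side == (fs.subpop == 0)).mean(), (side == (fs.subpop == 1)).mean())
        assert acc >= 0.99

    def test_homogeneous_population_shows_no_separation(self):
        pop = sim.PopulationModel()
        fs = sim.sample_founder_haplotypes(pop, 300, 3000, 201)
        labels = np.arange(300) % 2  # arbitrary split
        coords, vals = assoc.pca_patterson(fs.dosages)
        side = coords[:, 0] > 0
        acc = max((side == (labels == 0)).mean(), (side == (labels == 1)).mean())
        assert acc < 0.65

    def test_duplicated_samples_get_identical_coordinates(self):
        pop = sim.PopulationModel()
        fs = sim.sample_founder_haplotypes(pop, 50, 500, 202)
        G = np.vstack([fs.dosages, fs.dosages])
        coords, _ = assoc.pca_patterson(G)
        np.testing.assert_allclose(coords[:50], coords[50:], atol=1e-8)

    def test_zero_variance_panel_rejected(self):
        with pytest.raises(ValueError):
            assoc.pca_patterson(np.ones((10, 5)))


class TestCandidateAndTopHits:
    def _results(self, variants, p_by_analysis):
        out = {}
        for name, p in p_by_analysis.items():
            out[name] = pd.DataFrame(
                {
                    "variant_id": variants["id"],
                    "chrom": variants["chrom"],
                    "pos_bp": variants["pos_bp"],
                    "p": p,
                    "analysis": name,
                }
            )
        return out

    def test_single_snp_window_threshold(self, mixed_cohort):
        cohort = mixed_cohort.cohort
        v = cohort.variants
        j = int(np.flatnonzero(~cohort.chr21_mask)[0])
        rng = np.random.default_rng(7)
        res = self._results(v, {"mi_vs_fathers": rng.random(len(v))})
        loci = pd.DataFrame(
            [{"name": "locus1", "chrom": v["chrom"].iloc[j],
              "start_bp": v["pos_bp"].iloc[j], "end_bp": v["pos_bp"].iloc[j]}]
        )
        fathers = cohort.sample_ids("father")
        tab = assoc.candidate_gene_analysis(res, loci, cohort, fathers, window_bp=10)
        assert tab["m_snps"].iloc[0] == 1
        assert tab["threshold"].iloc[0] == pytest.approx(0.05)
        assert tab["min_p"].iloc[0] == pytest.approx(res["mi_vs_fathers"]["p"].iloc[j])

    def test_empty_window_rejected(self, mixed_cohort):
        cohort = mixed_cohort.cohort
        loci = pd.DataFrame([{"name": "void", "chrom": "1",
                              "start_bp": 10 ** 9, "end_bp": 10 ** 9}])
        res = self._results(cohort.variants,
                            {"mi_vs_fathers": np.ones(cohort.n_variants)})
        with pytest.raises(ValueError, match="no SNPs"):
            assoc.candidate_gene_analysis(res, loci, cohort,
                                          cohort.sample_ids("father"), window_bp=10)

    def test_cross_lookup_reports_na_out_of_range(self, mixed_cohort):
        v = mixed_cohort.cohort.variants
        p1 = np.ones(len(v))
        p1[10] = 1e-6
        p2 = np.ones(len(v))
        res = self._results(v, {"mi_vs_fathers": p1, "mii_vs_fathers": p2})
        # remove every variant within 20 kb in the other analysis
        near = (res["mii_vs_fathers"]["chrom"] == v["chrom"].iloc[10]) & (
            np.abs(res["mii_vs_fathers"]["pos_bp"] - v["pos_bp"].iloc[10]) <= 20_000
        )
        res["mii_vs_fathers"] = res["mii_vs_fathers"][~near]
        out = assoc.top_hits_cross_lookup(res)
        tab = out["mi_vs_fathers"]
        assert len(tab) == 1
        assert np.isnan(tab["p_mii_vs_fathers"].iloc[0])
        assert len(out["mii_vs_fathers"]) == 0

    def test_no_suggestive_hits_gives_empty_tables(self, mixed_cohort):
        v = mixed_cohort.cohort.variants
        res = self._results(v, {"mi_vs_fathers": np.full(len(v), 0.5)})
        out = assoc.top_hits_cross_lookup(res)
        assert len(out["mi_vs_fathers"]) == 0


class TestNegativeControl:
    def test_sex_null_scan_calibrated(self):
        pop = sim.PopulationModel()
        fs = sim.sample_founder_haplotypes(pop, 400, 2000, 300)
        rng = np.random.default_rng(301)
        sex = rng.integers(0, 2, 400)
        res, lam = assoc.negative_control_scan(fs.dosages, sex)
        assert 0.9 < lam < 1.1
        assert not (res["p"].dropna() < 5e-8).any()

    def test_identical_genotypes_rejected(self):
        with pytest.raises(ValueError):
            assoc.negative_control_scan(np.ones((20, 10)), np.arange(20) % 2)
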