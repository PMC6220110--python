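"""Association statistics, genomic control, clumping and gene annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mbherit import mbgwas as M
from mbherit import simdata, io_qc
from mbherit.taxa import PrevalenceClass, TraitVector, prepare_trait


class TestScoreTest:
    def test_hand_example(self):
        b, chi2, p = M.score_test_quantitative(np.array([1., 2, 3, 4]),
                                               np.array([0., 1, 1, 2]))
        assert chi2 == pytest.approx(3.6)
        assert b == pytest.approx(1.5)

    def test_perfect_correlation_chi2_equals_n(self):
        g = np.array([0., 1, 2, 1, 0, 2])
        _, chi2, _ = M.score_test_quantitative(2 * g - 1, g)
        assert chi2 == pytest.approx(len(g))

    def test_constant_genotype_rejected(self):
        with pytest.raises(ValueError):
            M.score_test_quantitative(np.array([1., 2, 3]), np.ones(3))

    def test_vectorized_scan_matches_scalar(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(40)
        G = rng.integers(0, 3, size=(40, 12)).astype(float)
        beta, chi2, p = M.quantitative_scan(y, G)
        for j in range(12):
            b1, c1, p1 = M.score_test_quantitative(y, G[:, j])
            assert chi2[j] == pytest.approx(c1)
            assert beta[j] == pytest.approx(b1)

    def test_matches_ols_lrt_asymptotically(self):
        rng = np.random.default_rng(1)
        n = 1000
        y = rng.standard_normal(n)
        g = rng.binomial(2, 0.3, n).astype(float)
        _, chi2, _ = M.score_test_quantitative(y, g)
        r2 = np.corrcoef(y, g)[0, 1] ** 2
        lrt = -n * np.log1p(-r2)
        assert chi2 == pytest.approx(lrt, rel=0.05)


class TestLogistic:
    def test_uninformative_snp_chi2_near_zero(self):
        rng = np.random.default_rng(2)
        pres = np.repeat([True, False], 50)
        g = np.tile([0., 1], 50)  # identical distribution in both classes
        st = M.logistic_assoc(pres, g)
        assert st.chi2 < 1e-6

    def test_matches_statsmodels_lrt(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        n = 200
        g = rng.binomial(2, 0.4, n).astype(float)
        cov = rng.standard_normal((n, 2))
        eta = -0.5 + 0.6 * g + 0.3 * cov[:, 0]
        pres = rng.random(n) < 1 / (1 + np.exp(-eta))
        st = M.logistic_assoc(pres, g, cov)
        X0 = sm.add_constant(cov)
        X1 = np.column_stack([X0, g])
        ll0 = sm.Logit(pres.astype(float), X0).fit(disp=0).llf
        ll1 = sm.Logit(pres.astype(float), X1).fit(disp=0).llf
        assert st.chi2 == pytest.approx(2 * (ll1 - ll0), abs=1e-5)

    def test_complete_separation_flagged(self):
        pres = np.repeat([True, False], 10)
        g = np.repeat([2., 0], 10)
        st = M.logistic_assoc(pres, g)
        assert not st.testable

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            M.logistic_assoc(np.array([True] * 20 + [False] * 3),
                             np.zeros(23))

    def test_planted_liability_snp_recovered(self, family_cohort):
        _, G, K = family_cohort
        snp = G.snps.snp_id.iloc[50]
        truth = simdata.SimTruth(0.0, 0, zero_inflation_rate=0.4,
                                 binary_effect_snp=snp, seed=5)
        st = simdata.simulate_traits(G, K, truth)
        res = M.logistic_assoc(st.presence, G.dosage[:, 50])
        assert res.testable and res.p < 1e-4


class TestGenomicControl:
    def test_lambda_definition(self):
        chi2 = np.full(200, M.CHI2_1_MEDIAN)
        lam, _, _ = M.genomic_control(chi2)
        assert lam == pytest.approx(1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        chi2 = stats.chi2.rvs(1, size=500, random_state=rng)
        lam1, _, _ = M.genomic_control(chi2)
        lam2, _, _ = M.genomic_control(2 * chi2)
        assert lam2 == pytest.approx(2 * lam1)

    def test_no_deflation_by_default_but_optional(self):
        chi2 = np.full(100, 0.2)  # lambda < 1
        lam, gc_default, _ = M.genomic_control(chi2)
        assert lam < 1 and np.allclose(gc_default, chi2)
        _, gc_uncond, _ = M.genomic_control(chi2, unconditional=True)
        assert np.all(gc_uncond > chi2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            M.genomic_control(np.array([np.nan]))

    @pytest.mark.parametrize("lam,kept", [(1.00, True), (0.99, True), (1.06, True),
                                          (0.98, False), (1.07, False)])
    def test_lambda_filter_boundaries(self, lam, kept):
        s = M.ScanSummary("t", "quantitative", lam, True, 100, 1e-6, 1e-5)
        assert M.lambda_filter(s) is kept


class TestThresholdsAndQQ:
    def test_single_snp(self):
        assert M.bonferroni_thresholds(1) == (0.05, 1.0)

    def test_qq_single_point_raw_scale(self):
        e, o = M.qq_data(np.array([0.5]))
        assert e[0] == 0.5 and o[0] == 0.5

    def test_qq_monotone(self):
        rng = np.random.default_rng(5)
        e, o = M.qq_data(rng.uniform(size=100))
        assert (np.diff(e) > 0).all() and (np.diff(o) >= 0).all()

    def test_qq_null_near_diagonal(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=2000)
        e, o = M.qq_data(p)
        ks_band = 1.63 / np.sqrt(2000)  # ~1% KS critical value
        assert np.abs(e - o).max() < ks_band

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            M.qq_data(np.array([0.0, 0.5]))


class TestLD:
    def test_identity_and_allele_flip(self):
        g = np.array([0., 0, 1, 1, 2, 2])
        assert M.ld_r2(g, g) == pytest.approx(1.0)
        assert M.ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_hand_pearson(self):
        g1 = np.array([0., 0, 1, 1, 2, 2])
        g2 = np.array([0., 1, 0, 1, 1, 2])
        r = np.corrcoef(g1, g2)[0, 1]
        assert M.ld_r2(g1, g2) == pytest.approx(r * r)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            M.ld_r2(np.ones(5), np.arange(5.0))


def _geno_from(dosage, chrom="1", pos=None):
    dosage = np.asarray(dosage, dtype=float)
    n, p = dosage.shape
    pos = pos if pos is not None else np.arange(1, p + 1) * 100
    snps = pd.DataFrame({"snp_id": [f"m{j}" for j in range(p)], "chrom": chrom,
                         "pos": pos, "ref": "A", "alt": "G"})
    return io_qc.GenotypeMatrix([f"s{i}" for i in range(n)], snps, dosage)


class TestLoci:
    def test_single_isolated_snp_zero_width(self):
        rng = np.random.default_rng(7)
        D = rng.binomial(2, 0.4, size=(50, 5)).astype(float)
        G = _geno_from(D)
        res = pd.DataFrame({
            "taxon_id": "t", "snp_id": [f"m{j}" for j in range(5)],
            "chrom": "1", "pos": np.arange(1, 6) * 100, "part": "quantitative",
            "p_gc": [0.5, 0.5, 1e-9, 0.5, 0.5]})
        loci = M.define_locus(res, G, 1e-6)
        assert len(loci) == 1
        assert loci[0].interval_start == loci[0].interval_end == 300
        assert loci[0].top_snp == "m2"

    def test_ld_block_merges_into_one_locus(self):
        rng = np.random.default_rng(8)
        base = rng.binomial(2, 0.5, 80).astype(float)
        # m0,m1 near-duplicates (high LD); m3 independent
        D = np.column_stack([base, base, rng.binomial(2, 0.5, 80),
                             rng.binomial(2, 0.5, 80)]).astype(float)
        G = _geno_from(D)
        res = pd.DataFrame({
            "taxon_id": "t", "snp_id": [f"m{j}" for j in range(4)],
            "chrom": "1", "pos": [100, 200, 300, 400], "part": "quantitative",
            "p_gc": [1e-8, 1e-7, 0.3, 1e-7]})
        loci = M.define_locus(res, G, 1e-6)
        assert len(loci) == 2
        first = loci[0]
        assert first.top_snp == "m0"
        assert first.interval_start == 100 and first.interval_end == 200
        assert first.n_sig_snps == 2

    def test_interval_contains_top_and_claims_disjoint(self):
        rng = np.random.default_rng(9)
        D = rng.binomial(2, 0.4, size=(60, 10)).astype(float)
        G = _geno_from(D)
        res = pd.DataFrame({
            "taxon_id": "t", "snp_id": [f"m{j}" for j in range(10)],
            "chrom": "1", "pos": np.arange(1, 11) * 50, "part": "quantitative",
            "p_gc": rng.uniform(1e-10, 1e-7, 10)})
        loci = M.define_locus(res, G, 1e-6)
        seen = set()
        for loc in loci:
            assert loc.interval_start <= loc.top_pos <= loc.interval_end
            assert loc.top_snp not in seen
            seen.add(loc.top_snp)

    def test_no_significant_snp_rejected(self):
        G = _geno_from(np.random.default_rng(0).binomial(2, .4, (20, 3)).astype(float))
        res = pd.DataFrame({"taxon_id": "t", "snp_id": ["m0", "m1", "m2"],
                            "chrom": "1", "pos": [100, 200, 300],
                            "part": "quantitative", "p_gc": [0.5, 0.2, 0.9]})
        with pytest.raises(ValueError):
            M.define_locus(res, G, 1e-6)


class TestNearestGene:
    def _locus(self, pos):
        return M.Locus("t", "quantitative", "1", pos, pos, "m0", pos, 1e-9, 1)

    def test_inside_gene_distance_zero(self):
        genes = pd.DataFrame({"chrom": "1", "start": [100], "end": [200],
                              "name": ["gA"]})
        g, d = M.nearest_gene(self._locus(150), genes)
        assert g == "gA" and d == 0

    def test_between_genes_bed_arithmetic(self):
        genes = pd.DataFrame({"chrom": ["1", "1"], "start": [0, 200],
                              "end": [100, 300], "name": ["gA", "gB"]})
        g, d = M.nearest_gene(self._locus(140), genes)
        assert g == "gA" and d == 40

    def test_equidistant_tie_lower_start(self):
        genes = pd.DataFrame({"chrom": ["1", "1"], "start": [0, 180],
                              "end": [100, 280], "name": ["gA", "gB"]})
        # top at 1-based 141 -> pos0 140: distances 41 and 40... pick exact tie
        g, d = M.nearest_gene(self._locus(140), genes)  # pos0=139: 40 vs 41
        assert g == "gA"
        genes2 = pd.DataFrame({"chrom": ["1", "1"], "start": [0, 178],
                               "end": [100, 278], "name": ["gA", "gB"]})
        g2, d2 = M.nearest_gene(self._locus(140), genes2)  # 40 vs 39 -> gB
        assert g2 == "gB" and d2 == 39

    def test_no_gene_on_chromosome(self):
        genes = pd.DataFrame({"chrom": ["2"], "start": [0], "end": [10],
                              "name": ["gX"]})
        assert M.nearest_gene(self._locus(5), genes) == (None, None)


class TestTwoPartScan:
    def _setup(self, family_cohort, zero_inflation):
        ped, G, K = family_cohort
        truth = simdata.SimTruth(0.3, 2, zero_inflation_rate=zero_inflation, seed=17)
        st = simdata.simulate_traits(G, K, truth)
        abund = st.abundance / max(st.abundance.max(), 1.0)
        off = ped.offspring
        tv = prepare_trait(abund, off.sex.to_numpy(), off.batch.to_numpy(), "t")
        return G, tv

    def test_core_taxon_quantitative_only(self, family_cohort):
        G, tv = self._setup(family_cohort, 0.0)
        pclass = PrevalenceClass("t", 1.0, "core")
        table, summaries = M.two_part_scan(tv, G, None, pclass)
        assert len(table) == G.n_snps
        assert (table.part == "quantitative").all()
        assert len(summaries) == 1

    def test_random_taxon_has_both_parts(self, family_cohort):
        G, tv = self._setup(family_cohort, 0.4)
        pclass = PrevalenceClass("t", 0.6, "random")
        table, summaries = M.two_part_scan(tv, G, None, pclass)
        assert set(table.part) == {"quantitative", "binary"}
        assert len(table) <= 2 * G.n_snps
        assert {s.part for s in summaries} == {"quantitative", "binary"}

    def test_discarded_taxon_rejected(self, family_cohort):
        G, tv = self._setup(family_cohort, 0.0)
        with pytest.raises(ValueError):
            M.two_part_scan(tv, G, None, PrevalenceClass("t", 0.1, "discarded"))

    def test_planted_quantitative_snp_power(self):
        """SNP explaining 10% of trait variance at n=250 is found at the
        genome-wide threshold in most replicates."""
        rng = np.random.default_rng(10)
        n, p = 250, 400
        gw, _ = M.bonferroni_thresholds(p)
        hits = 0
        reps = 30
        for _ in range(reps):
            G = rng.binomial(2, rng.uniform(0.1, 0.5, p), size=(n, p)).astype(float)
            j = int(rng.integers(p))
            g = G[:, j] - G[:, j].mean()
            g = g / g.std()
            y = np.sqrt(0.10) * g + np.sqrt(0.90) * rng.standard_normal(n)
            _, chi2, pvals = M.quantitative_scan(y, G)
            if pvals[j] < gw:
                hits += 1
        assert hits / reps > 0.8
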