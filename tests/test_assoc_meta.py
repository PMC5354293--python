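"""Regression engines, genomic control, meta-analysis and lookups.

statsmodels serves as the independent oracle for the OLS and IRLS fits;
the meta-analysis is checked against its closed forms and a brute-force
weighted mean.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

from cohortgwas import assoc_meta as am


rng_global = np.random.default_rng(2024)


def _random_instance(seed, n=200, p_cov=3, binary=False):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.3, size=n).astype(float)
    cov = rng.normal(size=(n, p_cov))
    eta = 0.3 * g + cov @ rng.normal(scale=0.2, size=p_cov)
    if binary:
        y = rng.binomial(1, 1 / (1 + np.exp(-(eta - 1.0)))).astype(float)
    else:
        y = eta + rng.normal(size=n)
    return g, cov, y


class TestLinearAssoc:
    def test_noiseless_fit(self):
        g = np.array([0, 1, 2, 0, 1, 2, 1], dtype=float)
        res = am.linear_assoc(g, 0.5 * g)
        assert res.beta == pytest.approx(0.5, abs=1e-12)
        assert res.se < 1e-8

    def test_constant_dosage_rejected(self):
        with pytest.raises(am.CollinearityError):
            am.linear_assoc(np.ones(10), np.arange(10.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_ols(self, seed):
        g, cov, y = _random_instance(seed)
        res = am.linear_assoc(g, y, cov)
        x = sm.add_constant(np.column_stack([cov, g]))
        fit = sm.OLS(y, x).fit()
        assert res.beta == pytest.approx(fit.params[-1], abs=1e-10)
        assert res.se == pytest.approx(fit.bse[-1], abs=1e-10)

    def test_missing_y_rejected(self):
        y = np.array([1.0, np.nan, 2.0])
        with pytest.raises(ValueError, match="missing"):
            am.linear_assoc(np.array([0.0, 1.0, 2.0]), y)


class TestLinearScan:
    def test_matches_single_marker_fits(self):
        rng = np.random.default_rng(3)
        n, m = 300, 25
        G = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        cov = rng.normal(size=(n, 2))
        y = G[:, 0] * 0.2 + rng.normal(size=n)
        design = np.column_stack([np.ones(n), cov])
        scan = am.linear_scan(G, y, design)
        for j in range(m):
            single = am.linear_assoc(G[:, j], y, cov)
            assert scan["beta"][j] == pytest.approx(single.beta, abs=1e-10)
            assert scan["se"][j] == pytest.approx(single.se, abs=1e-10)
            assert scan["p"][j] == pytest.approx(single.p, abs=1e-10)

    def test_monomorphic_marker_nan(self):
        rng = np.random.default_rng(4)
        G = np.column_stack([np.full(100, 1.0), rng.binomial(2, 0.5, 100)])
        y = rng.normal(size=100)
        scan = am.linear_scan(G, y, np.ones((100, 1)))
        assert np.isnan(scan["beta"][0])
        assert np.isfinite(scan["beta"][1])


class TestLogisticAssoc:
    def test_or_equals_2x2_table_odds_ratio(self):
        # hard-call genotypes with an allele-level 2x2 structure: exp(beta)
        # from the genotype-dose model equals the sample allele odds ratio
        g = np.repeat([0, 2], [60, 40]).astype(float)
        y = np.concatenate([np.repeat([0, 1], [45, 15]),
                            np.repeat([0, 1], [20, 20])])
        res = am.logistic_assoc(g, y)
        # per-dose OR; with only 0/2 genotypes the 2-dose OR is table OR
        table_or = (20 / 20) / (15 / 45)
        assert np.exp(2 * res.beta) == pytest.approx(table_or, rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_logit(self, seed):
        g, cov, y = _random_instance(seed, binary=True)
        res = am.logistic_assoc(g, y, cov)
        x = sm.add_constant(np.column_stack([cov, g]))
        fit = sm.Logit(y, x).fit(disp=0)
        assert res.beta == pytest.approx(fit.params[-1], abs=1e-6)
        assert res.se == pytest.approx(fit.bse[-1], abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            am.logistic_assoc(np.array([0.0, 1.0, 2.0]), np.zeros(3))

    def test_separation_flagged_not_raised(self):
        g = np.repeat([0.0, 2.0], 20)
        y = np.repeat([0.0, 1.0], 20)
        res = am.logistic_assoc(g, y)
        assert not res.converged

    def test_permutation_null_uniform_p(self):
        # continuous imputed dosages keep the permutation distribution of
        # the Wald p continuous, so the KS comparison to Uniform(0,1) is
        # well calibrated
        rng = np.random.default_rng(7)
        n = 500
        g = np.clip(rng.normal(0.6, 0.45, size=n), 0, 2)
        y0 = rng.binomial(1, 0.3, size=n).astype(float)
        pvals = []
        for _ in range(500):
            y = rng.permutation(y0)
            pvals.append(am.logistic_assoc(g, y).p)
        stat, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_effect_recovery_rare_binary(self):
        # planted log-OR ln(2.17) at realistic prevalence recovered in mean
        log_or = np.log(2.17)
        betas = []
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = 4000
            g = rng.binomial(2, 0.2, size=n).astype(float)
            alpha = np.log(0.072 / 0.928) - log_or * g.mean()
            y = rng.binomial(1, 1 / (1 + np.exp(-(alpha + log_or * g))))
            betas.append(am.logistic_assoc(g, y.astype(float)).beta)
        assert np.mean(betas) == pytest.approx(log_or, abs=0.05)


class TestBatchLogisticScan:
    def test_matches_per_marker_irls(self):
        rng = np.random.default_rng(9)
        n, m = 400, 12
        G = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        G[rng.random((n, m)) < 0.02] = -1
        y = rng.binomial(1, 0.4, size=n).astype(float)
        scan = am.logistic_scan_2param(G, y)
        for j in range(m):
            ok = G[:, j] != -1
            single = am.logistic_assoc(G[ok, j].astype(float), y[ok])
            assert scan["beta"][j] == pytest.approx(single.beta, abs=1e-6)
            assert scan["se"][j] == pytest.approx(single.se, abs=1e-6)

    def test_dosage_input_rejected(self):
        with pytest.raises(ValueError, match="hard-call"):
            am.logistic_scan_2param(np.zeros((10, 2)), np.zeros(10))


class TestMinCaseScreen:
    def test_published_boundary(self):
        # 200 cases at MAF 0.05 -> expected count 10 -> passes
        assert am.min_case_screen(200, 0.05, 10)

    def test_below_boundary_fails(self):
        assert not am.min_case_screen(100, 0.05, 10)

    def test_above_boundary_passes(self):
        assert am.min_case_screen(400, 0.05, 10)

    def test_diploid_convention_option(self):
        assert am.min_case_screen(100, 0.05, 10, diploid=True)

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError):
            am.min_case_screen(100, 0.7, 10)


class TestGenomicLambda:
    def test_unit_lambda_at_null_median(self):
        z = np.full(200, np.sqrt(am.CHI2_1_MEDIAN))
        assert am.genomic_lambda(z).lam == pytest.approx(1.0, abs=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=1000)
        lam1 = am.genomic_lambda(z).lam
        lam2 = am.genomic_lambda(z * np.sqrt(2)).lam
        assert lam2 == pytest.approx(2 * lam1, rel=1e-9)

    def test_null_simulation_near_one(self):
        rng = np.random.default_rng(11)
        lams = [am.genomic_lambda(rng.normal(size=100_000)).lam
                for _ in range(20)]
        inside = np.mean([0.98 <= l <= 1.02 for l in lams])
        assert inside >= 0.95

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError):
            am.genomic_lambda(np.ones(50))


class TestMeta:
    def test_two_identical_studies_closed_form(self):
        res = [am.AssocResult("m", 0.4, 0.1, 4.0, 1e-4, 100),
               am.AssocResult("m", 0.4, 0.1, 4.0, 1e-4, 100)]
        meta = am.fixed_effects_meta(res)
        assert meta.beta == pytest.approx(0.4, abs=1e-12)
        assert meta.se == pytest.approx(0.1 / np.sqrt(2), abs=1e-12)
        assert meta.direction == "++"

    def test_single_study_identity(self):
        res = [am.AssocResult("m", -0.2, 0.05, -4.0, 1e-4, 100)]
        meta = am.fixed_effects_meta(res)
        assert meta.beta == pytest.approx(-0.2)
        assert meta.se == pytest.approx(0.05)
        assert meta.q == 0.0 and meta.df == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_weighted_mean_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        betas = rng.normal(size=k)
        ses = rng.uniform(0.05, 0.5, size=k)
        res = [am.AssocResult("m", b, s, b / s, 0.5, 100)
               for b, s in zip(betas, ses)]
        meta = am.fixed_effects_meta(res)
        w = 1 / ses**2
        assert meta.beta == pytest.approx(np.sum(w * betas) / np.sum(w),
                                          abs=1e-12)
        assert meta.se == pytest.approx(np.sum(w) ** -0.5, abs=1e-12)
        assert min(betas) - 1e-12 <= meta.beta <= max(betas) + 1e-12

    def test_cochran_hand_computed(self):
        res = [am.AssocResult("m", 0.0, 1.0, 0.0, 1.0, 10),
               am.AssocResult("m", 1.0, 1.0, 1.0, 0.3, 10)]
        q, df, p = am.cochran_q(res)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert df == 1

    def test_cochran_identical_betas(self):
        res = [am.AssocResult("m", 0.3, 0.1, 3.0, 0.01, 10)] * 3
        q, df, p = am.cochran_q(res)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_cochran_requires_two(self):
        with pytest.raises(ValueError):
            am.cochran_q([am.AssocResult("m", 0.3, 0.1, 3.0, 0.01, 10)])

    def test_cochran_null_distribution(self):
        rng = np.random.default_rng(12)
        k = 4
        qs = []
        for _ in range(1000):
            betas = rng.normal(0, 1.0, size=k)   # common effect 0, se = 1
            res_q, _, _ = am.cochran_q_from_arrays(betas, np.ones(k))
            qs.append(res_q)
        assert np.mean(qs) == pytest.approx(k - 1, rel=0.1)

    def test_meta_table_matches_rowwise(self):
        rng = np.random.default_rng(13)
        scans = []
        ids = [f"rs{j}" for j in range(30)]
        for _ in range(3):
            scans.append(pd.DataFrame({
                "marker_id": ids,
                "beta": rng.normal(size=30),
                "se": rng.uniform(0.05, 0.2, size=30)}))
        table = am.meta_analyze_scans(scans).set_index("marker_id")
        for j in [0, 7, 29]:
            res = [am.AssocResult(ids[j], s["beta"][j], s["se"][j], 0, 0.5,
                                  10) for s in scans]
            meta = am.fixed_effects_meta(res)
            assert table.loc[ids[j], "beta"] == pytest.approx(meta.beta,
                                                              abs=1e-12)
            assert table.loc[ids[j], "q"] == pytest.approx(meta.q, abs=1e-9)


class TestReplicationLookup:
    def test_empty_known_table(self):
        meta = pd.DataFrame({"marker_id": ["a"], "beta": [0.1], "p": [0.01]})
        known = pd.DataFrame(columns=["marker_id", "published_direction"])
        out = am.replication_lookup(meta, known)
        assert len(out) == 0

    def test_concordance_and_counts(self):
        meta = pd.DataFrame({"marker_id": ["a", "b", "c"],
                             "beta": [0.5, -0.2, 0.1],
                             "p": [0.001, 0.2, 0.03]})
        known = pd.DataFrame({"marker_id": ["a", "b", "d"],
                              "published_direction": ["+", "+", "-"]})
        out = am.replication_lookup(meta, known, alpha=0.05)
        summary = am.replication_summary(out)
        assert summary == {"n_known": 3, "n_found": 2, "n_significant": 1,
                           "n_concordant": 1}
        assert not out[out["marker_id"] == "d"]["found"].iloc[0]

    def test_matches_brute_force_on_planted_loci(self):
        rng = np.random.default_rng(14)
        ids = [f"rs{j}" for j in range(32)]
        meta = pd.DataFrame({"marker_id": ids,
                             "beta": rng.normal(size=32),
                             "p": rng.uniform(size=32)})
        known = pd.DataFrame({"marker_id": ids,
                              "published_direction":
                                  rng.choice(["+", "-"], size=32)})
        out = am.replication_lookup(meta, known, alpha=0.05)
        expect_sig = int((meta["p"] < 0.05).sum())
        assert am.replication_summary(out)["n_significant"] == expect_sig
        for _, row in out.iterrows():
            b = meta.set_index("marker_id").loc[row["marker_id"], "beta"]
            d = known.set_index("marker_id").loc[row["marker_id"],
                                                 "published_direction"]
            assert row["direction_concordant"] == ((b > 0) == (d == "+"))


class TestCovariateBuilder:
    def test_stratum_indicators_and_reference_level(self):
        pheno = pd.DataFrame({
            "cohort": ["CohortA", "CohortA", "CohortC", "CohortC"],
            "primary_outcome": ["t2d", "gout", "t2d", "t2d"],
            "age": [50.0, 60.0, 55.0, 65.0]})
        x = am.build_covariates(pheno, include_age=True)
        # intercept + 2 non-reference strata + age
        assert x.shape == (4, 4)
        assert np.allclose(x[:, 0], 1.0)

    def test_rank_check_names_column(self):
        n = 30
        rng = np.random.default_rng(15)
        g = rng.binomial(2, 0.5, size=n).astype(float)
        cov = np.column_stack([g])  # perfectly collinear with dosage
        with pytest.raises(am.CollinearityError):
            am.linear_assoc(g, rng.normal(size=n), cov)
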