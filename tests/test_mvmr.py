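"""mvmr: joint instrument assembly, multivariable IVW, multivariable PRESSO."""

import numpy as np
import pytest

from mrscreen.gwas_data import GwasTable, VariantAssociation, harmonize_pair
from mrscreen.instruments import LdMatrix
from mrscreen.mr_estimators import ivw
from mrscreen.mvmr import (
    CollinearityError,
    InsufficientInstrumentsError,
    MvmrInputs,
    build_mvmr_inputs,
    mvmr_ivw,
    mvmr_presso,
)
from mrscreen.synthetic_data import simulate_universe


def make_inputs(j=30, thetas=(0.4, -0.3), seed=28, noise=1.0, outlier=None):
    """Direct MvmrInputs from a known multivariable generative law."""
    rng = np.random.default_rng(seed)
    m = len(thetas)
    gamma = rng.uniform(0.05, 0.3, (j, m)) * rng.choice([-1, 1], (j, m))
    sx = np.full((j, m), 0.01)
    bx = gamma + sx * rng.standard_normal((j, m))
    sy = rng.uniform(0.01, 0.03, j)
    by = gamma @ np.array(thetas) + noise * sy * rng.standard_normal(j)
    if outlier is not None:
        by[outlier] += 10 * sy[outlier]
    return MvmrInputs(snp_ids=[f"rs{i + 1}" for i in range(j)],
                      exposure_ids=[f"exp{k + 1}" for k in range(m)],
                      bx=bx, sx=sx, by=by, sy=sy)


class TestMvmrIvw:
    def test_matches_wls_oracle(self):
        import statsmodels.api as sm
        inp = make_inputs(j=15, noise=3.0)  # heterogeneous → scale > 1
        res = sm.WLS(inp.by, inp.bx, weights=1.0 / inp.sy**2).fit()
        est = mvmr_ivw(inp)
        assert np.allclose(est.table["b_direct"], res.params, atol=1e-10)
        assert np.allclose(est.table["se"], res.bse, atol=1e-10)

    def test_recovery_of_direct_effects(self):
        inp = make_inputs(j=200, thetas=(0.4, -0.3, 0.0), seed=29)
        est = mvmr_ivw(inp)
        for b, se, truth in zip(est.table["b_direct"], est.table["se"],
                                (0.4, -0.3, 0.0)):
            assert abs(b - truth) < 3 * se

    def test_perfect_collinearity_raises(self):
        inp = make_inputs(j=10)
        inp2 = MvmrInputs(snp_ids=inp.snp_ids, exposure_ids=inp.exposure_ids,
                          bx=np.column_stack([inp.bx[:, 0], 2 * inp.bx[:, 0]]),
                          sx=inp.sx, by=inp.by, sy=inp.sy)
        with pytest.raises(CollinearityError):
            mvmr_ivw(inp2)

    def test_independent_null_column_leaves_univariable(self):
        # exposure 2 contributes nothing: direct effect of exposure 1 ≈ its
        # univariable IVW estimate
        rng = np.random.default_rng(30)
        j = 200
        g1 = rng.uniform(0.05, 0.3, j)
        sx = np.full((j, 2), 0.01)
        bx = np.column_stack([g1, np.zeros(j)]) + sx * rng.standard_normal((j, 2))
        sy = np.full(j, 0.02)
        by = 0.5 * g1 + sy * rng.standard_normal(j)
        inp = MvmrInputs([f"rs{i}" for i in range(j)], ["e1", "e2"],
                         bx, sx, by, sy)
        est = mvmr_ivw(inp)
        from conftest import make_harmonized
        uni = ivw(make_harmonized(bx[:, 0], sx[:, 0], by, sy))
        row = est.table.set_index("exposure").loc["e1"]
        assert abs(row["b_direct"] - uni.beta) < 3 * row["se"]

    def test_needs_more_snps_than_exposures(self):
        inp = make_inputs(j=10)
        with pytest.raises(InsufficientInstrumentsError):
            mvmr_ivw(inp.subset(np.arange(2)))


class TestBuildInputs:
    def test_union_of_disjoint_sets(self):
        # two exposures with disjoint 5-SNP instruments, complete tables
        rng = np.random.default_rng(31)

        def var(snp, beta, p, chrom, pos):
            return VariantAssociation(snp_id=snp, effect_allele="A",
                                      other_allele="G", beta=beta, se=0.01,
                                      pvalue=p, n=10_000, chrom=chrom, pos=pos,
                                      eaf=0.3)

        snps1 = [f"a{i}" for i in range(5)]
        snps2 = [f"b{i}" for i in range(5)]
        exp1 = GwasTable("e1", "quantitative",
                         [var(s, 0.2, 1e-8, "1", i * 10**6)
                          for i, s in enumerate(snps1)]
                         + [var(s, 0.001, 0.5, "2", i * 10**6)
                            for i, s in enumerate(snps2)])
        exp2 = GwasTable("e2", "quantitative",
                         [var(s, 0.001, 0.5, "1", i * 10**6)
                          for i, s in enumerate(snps1)]
                         + [var(s, 0.2, 1e-8, "2", i * 10**6)
                            for i, s in enumerate(snps2)])
        out = GwasTable("o", "binary",
                        [var(s, 0.01, 0.5, c, i * 10**6)
                         for c, group in (("1", snps1), ("2", snps2))
                         for i, s in enumerate(group)],
                        n_total=30_000, n_cases=12_000)
        ld = LdMatrix(snps1 + snps2, np.eye(10))
        inp = build_mvmr_inputs({"e1": exp1, "e2": exp2}, out, ld)
        assert inp.bx.shape == (10, 2)
        assert set(inp.snp_ids) == set(snps1 + snps2)

    def test_incomplete_snp_dropped_and_audited(self):
        def var(snp, beta, p, pos):
            return VariantAssociation(snp_id=snp, effect_allele="A",
                                      other_allele="G", beta=beta, se=0.01,
                                      pvalue=p, n=10_000, chrom="1",
                                      pos=pos, eaf=0.3)

        snps = [f"rs{i}" for i in range(8)]
        exp1 = GwasTable("e1", "quantitative",
                         [var(s, 0.2, 1e-8, i * 10**6) for i, s in enumerate(snps)])
        # exposure 2 is missing rs0 entirely
        exp2 = GwasTable("e2", "quantitative",
                         [var(s, 0.2, 1e-8, i * 10**6)
                          for i, s in enumerate(snps) if s != "rs0"])
        out = GwasTable("o", "binary",
                        [var(s, 0.01, 0.5, i * 10**6) for i, s in enumerate(snps)],
                        n_total=30_000, n_cases=12_000)
        ld = LdMatrix(snps, np.eye(8))
        inp = build_mvmr_inputs({"e1": exp1, "e2": exp2}, out, ld)
        assert "rs0" not in inp.snp_ids
        assert "rs0" in inp.audit["incomplete"]

    def test_insufficient_raises(self):
        def var(snp, pos):
            return VariantAssociation(snp_id=snp, effect_allele="A",
                                      other_allele="G", beta=0.2, se=0.01,
                                      pvalue=1e-8, n=10_000, chrom="1",
                                      pos=pos, eaf=0.3)

        snps = ["rs0", "rs1", "rs2"]
        t = GwasTable("e1", "quantitative", [var(s, i * 10**6)
                                             for i, s in enumerate(snps)])
        t2 = GwasTable("e2", "quantitative", [var(s, i * 10**6)
                                              for i, s in enumerate(snps)])
        out = GwasTable("o", "binary",
                        [VariantAssociation(snp_id=s, effect_allele="A",
                                            other_allele="G", beta=0.01, se=0.01,
                                            pvalue=0.5, n=30_000, chrom="1",
                                            pos=i * 10**6, eaf=0.3)
                         for i, s in enumerate(snps)],
                        n_total=30_000, n_cases=12_000)
        ld = LdMatrix(snps, np.eye(3))
        with pytest.raises(InsufficientInstrumentsError):
            build_mvmr_inputs({"e1": t, "e2": t2}, out, ld)

    def test_universe_complete_cases(self):
        uni = simulate_universe(n_exposures=6, n_causal=2, seed=32)
        ids = uni["truth"].causal_ids
        inp = build_mvmr_inputs({e: uni["exposures"][e] for e in ids},
                                uni["outcome_primary"], uni["ld"])
        assert inp.n_exposures == 2 and inp.n_snp >= 4


class TestMvmrPresso:
    def test_global_p_lower_bound_and_seed(self):
        inp = make_inputs(j=12)
        with pytest.raises(ValueError):
            mvmr_presso(inp)
        res = mvmr_presso(inp, n_sim=100, seed=4)
        assert res.global_p >= 1.0 / 101
        res2 = mvmr_presso(inp, n_sim=100, seed=4)
        assert res.global_p == res2.global_p

    def test_planted_outlier_flagged_and_removed(self):
        inp = make_inputs(j=20, seed=33, outlier=5)
        res = mvmr_presso(inp, n_sim=1000, seed=5)
        assert "rs6" in res.outliers
        assert res.estimate_outlier_corrected is not None
        assert res.estimate_outlier_corrected.n_snp == 20 - len(res.outliers)
        # after removal the direct effects are consistent with truth and the
        # heterogeneity the outlier injected collapses
        corr = res.estimate_outlier_corrected.table
        truth = np.array([0.4, -0.3])
        assert np.all(np.abs(corr["b_direct"].to_numpy() - truth)
                      <= 3 * corr["se"].to_numpy())
        assert res.estimate_outlier_corrected.q < res.estimate_raw.q

    def test_null_rejection_rate(self):
        from scipy.stats import binom
        n_rep = 100
        rej = 0
        for r in range(n_rep):
            inp = make_inputs(j=12, seed=900_000 + r)
            rej += mvmr_presso(inp, n_sim=200, seed=910_000 + r).global_p < 0.05
        lo, hi = binom.ppf([0.005, 0.995], n_rep, 0.05)
        assert lo <= rej <= hi

    def test_too_few_snps(self):
        inp = make_inputs(j=4)
        with pytest.raises(InsufficientInstrumentsError):
            mvmr_presso(inp, seed=0)
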