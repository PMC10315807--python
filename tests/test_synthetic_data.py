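"""synthetic_data: generators and their ground-truth guarantees."""

import numpy as np
import pytest
from scipy import stats

from mrscreen.gwas_data import harmonize_pair
from mrscreen.mr_estimators import ivw, mr_egger
from mrscreen.synthetic_data import (
    SimConfig,
    simulate_confounder_table,
    simulate_ld_region,
    simulate_ldsc_panel,
    simulate_two_sample,
    simulate_universe,
)
from mrscreen.coloc import coloc_abf


class TestTwoSample:
    def test_fixed_seed_reproducible(self):
        cfg = SimConfig(n_snps=10, theta=0.3, seed=35)
        e1, o1, t1 = simulate_two_sample(cfg)
        e2, o2, t2 = simulate_two_sample(cfg)
        assert e1.to_frame().equals(e2.to_frame())
        assert o1.to_frame().equals(o2.to_frame())
        assert np.array_equal(t1.gamma, t2.gamma)

    def test_tables_satisfy_invariants_and_harmonize_cleanly(self):
        exp, out, truth = simulate_two_sample(SimConfig(n_snps=25, seed=36))
        # GwasTable construction already enforces record invariants
        h = harmonize_pair(exp, out)
        assert h.n_snp == 25 and h.dropped == []
        assert exp.trait_type == "quantitative" and out.trait_type == "binary"

    def test_moments(self):
        # mean(bx − γ) ≈ 0 and sd(bx − γ) ≈ se_x over a large SNP panel
        exp, _, truth = simulate_two_sample(SimConfig(n_snps=20_000, seed=37))
        bx = np.array([r.beta for r in exp.records])
        se = np.array([r.se for r in exp.records])
        resid = (bx - truth.gamma) / se
        assert abs(resid.mean()) < 3 / np.sqrt(len(resid))
        assert resid.std() == pytest.approx(1.0, abs=0.02)

    def test_gamma_truncation_and_orientation(self):
        _, _, truth = simulate_two_sample(SimConfig(n_snps=500, seed=38))
        assert np.all(truth.gamma >= truth.config.gamma_min)

    def test_pleiotropy_modes(self):
        for mode, frac in (("balanced", 1.0), ("directional", 0.4),
                           ("inside_violating", 1.0)):
            _, _, truth = simulate_two_sample(SimConfig(
                n_snps=1000, pleiotropy=mode, pleiotropy_frac=frac, seed=39))
            assert len(truth.invalid_idx) == int(round(frac * 1000))
            alpha = truth.alpha[truth.invalid_idx]
            if mode == "balanced":
                assert abs(alpha.mean()) < 3 * alpha.std() / np.sqrt(len(alpha))
            elif mode == "directional":
                assert alpha.mean() > 0.03
            else:
                r = np.corrcoef(alpha, truth.gamma[truth.invalid_idx])[0, 1]
                assert r > 0.4  # InSIDE violated by construction

    def test_none_mode_has_no_invalid(self):
        _, _, truth = simulate_two_sample(SimConfig(n_snps=50, seed=40))
        assert len(truth.invalid_idx) == 0 and np.all(truth.alpha == 0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(pleiotropy="bogus")
        with pytest.raises(ValueError):
            SimConfig(case_fraction=0.0)
        with pytest.raises(ValueError):
            SimConfig(pleiotropy_frac=1.5)

    def test_inside_violation_biases_egger_but_balanced_does_not(self):
        # positive control for the diagnostics: with InSIDE violated the Egger
        # slope is biased by more than 3 of its sampling SDs; with balanced
        # pleiotropy (InSIDE satisfied) it is not
        theta = 0.3
        est = {"balanced": [], "inside_violating": []}
        for mode in est:
            for r in range(500):
                exp, out, _ = simulate_two_sample(SimConfig(
                    n_snps=100, theta=theta, pleiotropy=mode,
                    pleiotropy_scale=0.05, seed=410_000 + r))
                est[mode].append(mr_egger(harmonize_pair(exp, out)).beta)
        bal = np.array(est["balanced"])
        ins = np.array(est["inside_violating"])
        assert abs(bal.mean() - theta) <= 3 * bal.std()
        assert abs(ins.mean() - theta) > 3 * ins.std()


class TestLdRegion:
    def test_null_mode_marginally_standard_normal(self):
        # z's within a region are LD-correlated, so take one SNP per region
        # to get iid draws for the KS test
        zs = []
        for r in range(300):
            t1, _, _ = simulate_ld_region(m_snps=100, causal_mode="null",
                                          seed=420_000 + r)
            zs.append(t1.beta[50] / t1.se[50])
        assert stats.kstest(np.array(zs), "norm").pvalue > 0.01

    def test_shared_mode_truth(self):
        t1, t2, truth = simulate_ld_region(causal_mode="shared", seed=41)
        assert truth.shared and truth.causal_idx_t1 == truth.causal_idx_t2

    def test_distinct_mode_modal_h3(self):
        modal = 0
        for r in range(20):
            t1, t2, _ = simulate_ld_region(m_snps=100, rho=0.2,
                                           causal_mode="distinct",
                                           effect_r2=0.01, seed=430_000 + r)
            modal += int(np.argmax(coloc_abf(t1, t2).pp)) == 3
        assert modal >= 18

    def test_trait1_only(self):
        _, _, truth = simulate_ld_region(causal_mode="trait1_only", seed=42)
        assert truth.causal_idx_t1 is not None and truth.causal_idx_t2 is None

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_ld_region(m_snps=1)
        with pytest.raises(ValueError):
            simulate_ld_region(rho=1.0)
        with pytest.raises(ValueError):
            simulate_ld_region(causal_mode="bogus")


class TestLdscPanel:
    def test_null_h2_mean_chi2(self):
        panel, _ = simulate_ldsc_panel(m_snps=20_000, h2_1=0.0, h2_2=0.0,
                                       rg=0.0, seed=43)
        chi2 = panel.z1**2
        assert abs(chi2.mean() - 1.0) < 3 * chi2.std() / np.sqrt(len(chi2))

    def test_generative_slope_identity(self):
        panel, _ = simulate_ldsc_panel(m_snps=50_000, h2_1=0.3, h2_2=0.3,
                                       rg=0.5, seed=44)
        # E[χ²] = 1 + N·h²·ℓ/M: check by binned means against the line
        expected = 1.0 + panel.n1 * 0.3 * panel.l2 / panel.m_ref
        resid = panel.z1**2 - expected
        assert abs(resid.mean()) < 3 * resid.std() / np.sqrt(len(resid))

    def test_reproducible(self):
        p1, _ = simulate_ldsc_panel(m_snps=100, seed=45)
        p2, _ = simulate_ldsc_panel(m_snps=100, seed=45)
        assert np.array_equal(p1.z1, p2.z1) and np.array_equal(p1.l2, p2.l2)

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_ldsc_panel(h2_1=1.0)
        with pytest.raises(ValueError):
            simulate_ldsc_panel(rg=1.5)


class TestConfounderTable:
    def test_planted_below_threshold(self):
        t = simulate_confounder_table(["rs1", "rs2", "rs3"],
                                      [("rs1", "bmi")], seed=46, n_benign=2)
        planted = t[t["trait"] == "bmi"]
        assert (planted["pvalue"] < 1e-5).all()
        benign = t[t["trait"] == "benign_trait"]
        assert (benign["pvalue"] >= 1e-4).all()

    def test_unknown_planted_snp_raises(self):
        with pytest.raises(ValueError):
            simulate_confounder_table(["rs1"], [("rs9", "bmi")])


class TestUniverse:
    def test_structure_and_truth(self):
        uni = simulate_universe(n_exposures=5, n_causal=2, seed=47)
        assert len(uni["exposures"]) == 5
        assert len(uni["truth"].causal_ids) == 2
        for eid, theta in uni["truth"].thetas.items():
            assert (theta != 0) == (eid in uni["truth"].causal_ids)
        # replication shares the SNP panel with the primary outcome
        prim = {r.snp_id for r in uni["outcome_primary"].records}
        repl = {r.snp_id for r in uni["outcome_replication"].records}
        assert prim == repl
        # every exposure table reports the full panel (complete rows for MVMR)
        for t in uni["exposures"].values():
            assert {r.snp_id for r in t.records} == prim

    def test_reproducible(self):
        u1 = simulate_universe(n_exposures=4, n_causal=1, seed=48)
        u2 = simulate_universe(n_exposures=4, n_causal=1, seed=48)
        for eid in u1["exposures"]:
            assert u1["exposures"][eid].to_frame().equals(
                u2["exposures"][eid].to_frame())
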