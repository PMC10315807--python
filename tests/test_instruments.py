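"""instruments: R²/F formulas, clumping, selection pipeline, confounder filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrscreen.gwas_data import GwasTable, VariantAssociation
from mrscreen.instruments import (
    LdMatrix,
    MissingLdError,
    SelectionConfig,
    clump,
    f_statistic,
    filter_confounders,
    select_instruments,
    variance_explained,
)
from mrscreen.synthetic_data import simulate_confounder_table


def rec(snp, p=1e-8, pos=None, chrom="1", beta=0.1, se=0.01, n=10_000, eaf=0.3):
    return VariantAssociation(snp_id=snp, effect_allele="A", other_allele="G",
                              beta=beta, se=se, pvalue=p, n=n, chrom=chrom,
                              pos=pos, eaf=eaf)


class TestVarianceExplained:
    def test_null_effect(self):
        assert variance_explained(0.0, 0.01, 1000) == 0.0

    def test_hand_value(self):
        # z = 10: r2 = z²/(z² + N) = 100/1100
        assert variance_explained(0.1, 0.01, 1000) == pytest.approx(100 / 1100)

    def test_eaf_symmetry(self):
        for p in (0.05, 0.2, 0.5, 0.8):
            assert variance_explained(0.1, 0.01, 1000, eaf=p) == pytest.approx(
                variance_explained(0.1, 0.01, 1000, eaf=1 - p))

    @given(beta=st.floats(-0.5, 0.5), se=st.floats(1e-3, 0.1),
           n=st.floats(10, 1e6), eaf=st.floats(1e-3, 1 - 1e-3))
    @settings(max_examples=100, deadline=None)
    def test_weighted_form_equals_reduced_form(self, beta, se, n, eaf):
        full = variance_explained(beta, se, n, eaf=eaf)
        reduced = beta**2 / (beta**2 + n * se**2)
        assert full == pytest.approx(reduced, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            variance_explained(0.1, 0.0, 1000)
        with pytest.raises(ValueError):
            variance_explained(0.1, 0.01, 1000, eaf=1.0)

    def test_vectorized(self):
        out = variance_explained(np.array([0.0, 0.1]), np.array([0.01, 0.01]),
                                 np.array([1000, 1000]))
        assert np.allclose(out, [0.0, 100 / 1100])


class TestFStatistic:
    def test_zero(self):
        assert f_statistic(0.0, 1000) == 0.0

    def test_hand_value(self):
        # (1000-2)/1 × (100/1100)/(1000/1100) = 998 × 0.1
        assert f_statistic(100 / 1100, 1000, k=1) == pytest.approx(99.8)

    def test_filter_boundary_study_scale(self):
        # at the study's exposure n, F = 10 exactly at r² = 10/7832
        assert f_statistic(10 / 7832, 7824, k=1) == pytest.approx(10.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 1000)
        with pytest.raises(ValueError):
            f_statistic(0.1, 2, k=1)
        with pytest.raises(ValueError):
            f_statistic(0.1, 1000, k=0)


class TestLdMatrix:
    def test_validation(self):
        with pytest.raises(ValueError):
            LdMatrix(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]))  # asymmetric
        with pytest.raises(ValueError):
            LdMatrix(["a", "b"], np.array([[0.9, 0.5], [0.5, 1.0]]))  # diagonal
        with pytest.raises(ValueError):
            LdMatrix(["a", "b"], np.array([[1.0, -0.5], [-0.5, 1.0]]))  # range

    def test_missing_pair_raises(self):
        ld = LdMatrix(["a", "b"], np.eye(2))
        with pytest.raises(MissingLdError):
            ld.r2("a", "zzz")

    def test_tsv_round_trip(self, tmp_path):
        m = np.array([[1.0, 0.2], [0.2, 1.0]])
        LdMatrix(["rs1", "rs2"], m).to_tsv(tmp_path / "ld.tsv")
        ld2 = LdMatrix.from_tsv(tmp_path / "ld.tsv")
        assert ld2.r2("rs1", "rs2") == pytest.approx(0.2)


class TestClump:
    def test_independent_all_retained(self):
        cands = [rec(f"rs{i}", p=10.0**-(8 - i), pos=i * 1000) for i in range(5)]
        ld = LdMatrix([c.snp_id for c in cands], np.eye(5))
        assert set(clump(cands, ld)) == {c.snp_id for c in cands}

    def test_pairwise_rule(self):
        a, b = rec("rsA", 1e-8, pos=0), rec("rsB", 1e-6, pos=100_000)
        ld = LdMatrix(["rsA", "rsB"],
                      np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert clump([a, b], ld) == ["rsA"]

    def test_chain_oracle(self):
        # A–B r²=0.2, B–C r²=0.2, A–C r²=0, pA<pB<pC → greedy keeps {A, C}
        a, b, c = rec("rsA", 1e-9, 0), rec("rsB", 1e-8, 1000), rec("rsC", 1e-7, 2000)
        m = np.array([[1.0, 0.2, 0.0],
                      [0.2, 1.0, 0.2],
                      [0.0, 0.2, 1.0]])
        ld = LdMatrix(["rsA", "rsB", "rsC"], m)
        assert set(clump([a, b, c], ld)) == {"rsA", "rsC"}

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        cands = [rec(f"rs{i}", p=float(rng.uniform(1e-9, 1e-5)), pos=i * 50_000)
                 for i in range(8)]
        m = np.eye(8)
        for i in range(8):
            for j in range(i + 1, 8):
                m[i, j] = m[j, i] = rng.uniform(0, 0.4)
        ld = LdMatrix([c.snp_id for c in cands], m)
        ref = clump(cands, ld)
        for s in (1, 2, 3):
            shuffled = list(cands)
            np.random.default_rng(s).shuffle(shuffled)
            assert clump(shuffled, ld) == ref

    def test_window_excludes_far_and_other_chrom(self):
        a = rec("rsA", 1e-9, pos=0)
        far = rec("rsB", 1e-8, pos=1_000_000)           # outside 500 kb
        other = rec("rsC", 1e-7, pos=100, chrom="2")     # other chromosome
        m = np.ones((3, 3))
        ld = LdMatrix(["rsA", "rsB", "rsC"], m)
        assert set(clump([a, far, other], ld)) == {"rsA", "rsB", "rsC"}

    def test_missing_ld_raises(self):
        a, b = rec("rsA", 1e-9, 0), rec("rsB", 1e-8, 1000)
        ld = LdMatrix(["rsA"], np.eye(1))
        with pytest.raises(MissingLdError):
            clump([a, b], ld)


def _universe(n=10, p_out=0.5):
    exp = GwasTable("e", "quantitative",
                    [rec(f"rs{i}", p=1e-8, pos=i * 10**6, n=10_000)
                     for i in range(n)])
    out = GwasTable("o", "binary",
                    [rec(f"rs{i}", p=p_out, pos=i * 10**6, beta=0.001, se=0.01,
                         n=30_000) for i in range(n)],
                    n_total=30_000, n_cases=12_000)
    ld = LdMatrix([f"rs{i}" for i in range(n)], np.eye(n))
    return exp, out, ld


class TestSelectInstruments:
    def test_clean_selection(self):
        exp, out, ld = _universe()
        res = select_instruments(exp, out, ld)
        assert res.sufficient and res.n_instruments == 10
        assert res.n_significant == 10
        # strong instruments: z = 10 at n = 10k → F ≈ 100
        assert all(i.f_stat > 90 for i in res.instruments)
        assert res.aggregate_f is not None and res.aggregate_f > 0

    def test_outcome_associated_exclusion_flags_insufficient(self):
        exp, out, ld = _universe()
        recs = list(out.records)
        for i in range(8):
            r = recs[i]
            recs[i] = VariantAssociation(
                snp_id=r.snp_id, effect_allele=r.effect_allele,
                other_allele=r.other_allele, beta=0.2, se=0.01, pvalue=1e-9,
                n=r.n, chrom=r.chrom, pos=r.pos, eaf=r.eaf)
        out2 = GwasTable("o", "binary", recs, n_total=30_000, n_cases=12_000)
        res = select_instruments(exp, out2, ld)
        assert not res.sufficient and res.n_instruments == 2
        assert len(res.audit["outcome_associated"]) == 8

    def test_audit_is_exhaustive(self):
        # stage-by-stage construction: planted removals at each filter
        recs = []
        # 3 clean instruments
        recs += [rec(f"ok{i}", p=1e-8, pos=i * 10**6) for i in range(3)]
        # 2 in LD with ok0 (within window, r² = 0.9)
        recs += [rec(f"ld{i}", p=1e-7, pos=1000 + i) for i in range(2)]
        # 2 weak (tiny effect → F < 10)
        recs += [rec(f"weak{i}", p=9e-6, pos=(10 + i) * 10**6, beta=0.001,
                     se=0.001) for i in range(2)]
        # 1 not significant
        recs += [rec("ns", p=1e-3, pos=20 * 10**6)]
        exp = GwasTable("e", "quantitative", recs)
        ids = [r.snp_id for r in recs]
        m = np.eye(len(ids))
        for i, s in enumerate(ids):
            if s.startswith("ld"):
                m[0, i] = m[i, 0] = 0.9
        ld = LdMatrix(ids, m)
        out_recs = [rec(s, p=0.5, pos=r.pos, beta=0.001, se=0.01, n=30_000)
                    for s, r in zip(ids, recs) if s != "ok2"]  # ok2 missing
        out = GwasTable("o", "binary", out_recs, n_total=30_000, n_cases=12_000)
        res = select_instruments(exp, out, ld)
        removed = sum(len(v) for v in res.audit.values())
        assert res.n_instruments + removed == res.n_significant == 7
        assert set(res.audit["clumped"]) == {"ld0", "ld1"}
        assert set(res.audit["weak_f"]) == {"weak0", "weak1"}
        assert res.audit["harmonization"] == ["ok2"]
        assert {i.snp_id for i in res.instruments} == {"ok0", "ok1"}
        assert not res.sufficient  # 2 < min_snps

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SelectionConfig(p_exposure=0.0)
        with pytest.raises(ValueError):
            SelectionConfig(min_snps=0)


class TestFilterConfounders:
    def _h(self, n=10):
        exp, out, ld = _universe(n)
        return select_instruments(exp, out, ld).harmonized

    def test_empty_table_identity(self):
        h = self._h()
        h2, removed = filter_confounders(h, None)
        assert h2.snp_ids == h.snp_ids and len(removed) == 0

    def test_planted_removed_with_trait_names(self):
        h = self._h()
        table = simulate_confounder_table(
            h.snp_ids, [("rs1", "bmi"), ("rs4", "smoking")], seed=3, n_benign=3)
        h2, removed = filter_confounders(h, table)
        assert set(h2.snp_ids) == set(h.snp_ids) - {"rs1", "rs4"}
        assert set(removed["trait"]) == {"bmi", "smoking"}

    def test_benign_rows_never_remove(self):
        h = self._h()
        table = simulate_confounder_table(h.snp_ids, [], seed=3, n_benign=5)
        h2, removed = filter_confounders(h, table)
        assert h2.snp_ids == h.snp_ids and len(removed) == 0
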