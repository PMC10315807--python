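"""Causal direction, statistical power, colocalization, and LDSC.

The screening stack includes checks that go beyond effect estimation:
Steiger directionality, analytic power for a binary outcome, regional
colocalization, and a lean LD-score regression for heritability and
genetic correlation.
"""

from mrscreen.coloc import coloc_abf
from mrscreen.direction_power import ldsc_h2, ldsc_rg, mr_power, steiger_test
from mrscreen.gwas_data import harmonize_pair
from mrscreen.synthetic_data import (
    SimConfig,
    simulate_ld_region,
    simulate_ldsc_panel,
    simulate_two_sample,
)

# --- Steiger: do the instruments explain more variance in the exposure? ---
exposure, outcome, _ = simulate_two_sample(SimConfig(n_snps=15, theta=0.3, seed=14))
h = harmonize_pair(exposure, outcome)
st = steiger_test(h, n_exp=7824, n_out=32072)
print(f"Steiger: r2(exposure) = {st.r2_exposure:.4f}, "
      f"r2(outcome) = {st.r2_outcome:.5f}, forward = {st.direction_forward}, "
      f"p = {st.pvalue:.2e}")

# --- analytic power for a binary outcome at fixed instrument strength ---
pw = mr_power(n=32072, case_fraction=19938 / 32072, r2_instrument=0.01,
              or_alt=0.75)
print(f"power to detect OR 0.75 with r2 = 1% in the primary cohort: "
      f"{pw.power:.2f}")

# --- colocalization of two traits in one LD region ---
t1, t2, truth = simulate_ld_region(m_snps=100, rho=0.8, causal_mode="shared",
                                   effect_r2=0.01, seed=14)
res = coloc_abf(t1, t2)
print(f"\ncoloc (shared causal variant planted): PP.H4 = {res.pp_h4:.3f}, "
      f"decision = {res.decision}, top shared SNP = {res.top_shared_snp}")

t1, t2, _ = simulate_ld_region(m_snps=100, rho=0.2, causal_mode="distinct",
                               effect_r2=0.01, seed=15)
res = coloc_abf(t1, t2)
print(f"coloc (distinct causal variants): PP.H3 = {res.pp[3]:.3f}, "
      f"PP.H4 = {res.pp_h4:.3f}")

# --- lean LD-score regression ---
panel, truth = simulate_ldsc_panel(m_snps=50_000, h2_1=0.3, h2_2=0.3,
                                   rg=0.5, seed=16)
res_h2 = ldsc_h2(panel)
res_rg = ldsc_rg(panel)
print(f"\nLDSC: h2 = {res_h2.h2:.3f} (se {res_h2.h2_se:.3f}, truth 0.3), "
      f"intercept = {res_h2.intercept:.2f}")
print(f"LDSC: rg = {res_rg.rg:.3f} (se {res_rg.rg_se:.3f}, truth 0.5)")
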