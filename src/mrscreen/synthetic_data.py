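"""Synthetic GWAS summary statistics with known ground truth.

Every pipeline stage is validated by parameter recovery on data generated
here.  The two-sample generator works directly on the summary-statistic
scale: per-SNP exposure effects γ_j (unit-variance quantitative trait) give
observed bx_j ~ N(γ_j, se_x,j) with se_x,j = 1/sqrt(2·n_exp·EAF(1−EAF)),
and outcome effects by_j ~ N(θ·γ_j + α_j, se_y,j) on the log-odds scale with
the binary-trait factor 1/sqrt(K(1−K)) in the SE.  The pleiotropy term α_j
is zero (``none``), mean-zero (``balanced``), has a nonzero mean
(``directional``), or is correlated with γ_j (``inside_violating``); it can
hit all SNPs or a fraction, so a planted minority of invalid instruments is
available as a positive control for the robust estimators and outlier tests.

Defaults mirror the study conditions: a 7,824-person metabolite cohort and a
32,072-person case-control outcome cohort with case fraction 0.622
(replication: 8,554 with case fraction 0.519).  Instrument effects are drawn
from N(0, 0.15²) truncated away from zero at 0.075, emulating genome-wide
selection at p < 1e-5 in the exposure cohort; the resulting per-SNP F
statistics (median ≈ 100) and total variance explained (≈ 1% per SNP) match
the strong metabolite instruments the screen operates on.

Regional association statistics for colocalization come from a multivariate
normal with AR(1) LD (z ~ MVN(sqrt(n)·R·λ, R)), and LD-score panels from the
bivariate generative law Var(z_t) = 1 + N_t·h²_t·ℓ_j/M with cross-trait
covariance sqrt(N1·N2)·rg·sqrt(h²_1·h²_2)·ℓ_j/M.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import RegionalAssoc
from .direction_power import LdscPanel
from .gwas_data import GwasTable, VariantAssociation
from .instruments import LdMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "RegionTruth",
    "LdscTruth",
    "simulate_two_sample",
    "simulate_ld_region",
    "simulate_ldsc_panel",
    "simulate_confounder_table",
    "simulate_universe",
    "UniverseTruth",
]

# study-scale cohort constants
N_EXPOSURE = 7824
N_OUTCOME_PRIMARY = 32072
CASES_PRIMARY = 19938
N_OUTCOME_REPLICATION = 8554
CASES_REPLICATION = 4439

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class SimConfig:
    """Generative law for one exposure/outcome summary-statistic pair."""

    n_snps: int = 15
    n_exposure: float = N_EXPOSURE
    n_outcome: float = N_OUTCOME_PRIMARY
    case_fraction: float = CASES_PRIMARY / N_OUTCOME_PRIMARY
    theta: float = 0.0
    gamma_sd: float = 0.15
    gamma_min: float = 0.075        # truncation emulating p<1e-5 instrument discovery
    pleiotropy: str = "none"        # none | balanced | directional | inside_violating
    pleiotropy_scale: float = 0.05
    pleiotropy_frac: float = 1.0
    eaf_range: tuple[float, float] = (0.05, 0.95)
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"
    snp_prefix: str = "rs"
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_exposure < 2 or self.n_outcome < 2:
            raise ValueError("sizes must be positive")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must lie in (0,1)")
        if self.pleiotropy not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        if not (0.0 <= self.pleiotropy_frac <= 1.0):
            raise ValueError("pleiotropy_frac must lie in [0,1]")


@dataclass
class SimTruth:
    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    invalid_idx: np.ndarray
    config: SimConfig

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "gamma": list(map(float, self.gamma)),
            "alpha": list(map(float, self.alpha)),
            "invalid_idx": list(map(int, self.invalid_idx)),
        }


def _draw_gamma(rng, j: int, sd: float, min_abs: float) -> np.ndarray:
    # Half-normal: instruments oriented to the exposure-raising allele, the
    # usual convention; directional pleiotropy is only directional relative
    # to a common instrument orientation.
    gamma = np.abs(rng.normal(0.0, sd, size=j))
    for _ in range(1000):
        weak = gamma < min_abs
        if not weak.any():
            break
        gamma[weak] = np.abs(rng.normal(0.0, sd, size=weak.sum()))
    else:
        raise RuntimeError("gamma truncation failed to converge")
    return gamma


def _draw_alpha(rng, cfg: SimConfig, gamma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    j = cfg.n_snps
    alpha = np.zeros(j)
    n_invalid = int(round(cfg.pleiotropy_frac * j)) if cfg.pleiotropy != "none" else 0
    invalid = rng.choice(j, size=n_invalid, replace=False) if n_invalid else np.array([], int)
    s = cfg.pleiotropy_scale
    if cfg.pleiotropy == "balanced":
        alpha[invalid] = rng.normal(0.0, s, size=n_invalid)
    elif cfg.pleiotropy == "directional":
        alpha[invalid] = rng.normal(s, s / 2.0, size=n_invalid)
    elif cfg.pleiotropy == "inside_violating":
        # pleiotropic effects correlated with instrument strength
        eps = rng.normal(0.0, 1.0, size=n_invalid)
        alpha[invalid] = s * (0.7 * gamma[invalid] / cfg.gamma_sd
                              + np.sqrt(1.0 - 0.49) * eps)
    return alpha, np.sort(invalid)


def simulate_two_sample(config: SimConfig) -> tuple[GwasTable, GwasTable, SimTruth]:
    """Generate harmonizable exposure and outcome summary tables plus truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    j = cfg.n_snps
    gamma = _draw_gamma(rng, j, cfg.gamma_sd, cfg.gamma_min)
    alpha, invalid = _draw_alpha(rng, cfg, gamma)
    eaf = rng.uniform(*cfg.eaf_range, size=j)
    se_x = 1.0 / np.sqrt(2.0 * cfg.n_exposure * eaf * (1.0 - eaf))
    bx = gamma + se_x * rng.standard_normal(j)
    px = 2.0 * stats.norm.sf(np.abs(bx) / se_x)
    k = cfg.case_fraction
    se_y = 1.0 / np.sqrt(2.0 * cfg.n_outcome * eaf * (1.0 - eaf) * k * (1.0 - k))
    by = cfg.theta * gamma + alpha + se_y * rng.standard_normal(j)
    py = 2.0 * stats.norm.sf(np.abs(by) / se_y)

    allele_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=j)
    exp_records, out_records = [], []
    for i in range(j):
        ea, oa = _NONPALINDROMIC_PAIRS[allele_idx[i]]
        common = dict(
            snp_id=f"{cfg.snp_prefix}{i + 1}", effect_allele=ea, other_allele=oa,
            chrom=cfg.chrom, pos=(i + 1) * 2_000_000, eaf=float(eaf[i]),
        )
        exp_records.append(VariantAssociation(
            beta=float(bx[i]), se=float(se_x[i]), pvalue=float(px[i]),
            n=cfg.n_exposure, **common))
        out_records.append(VariantAssociation(
            beta=float(by[i]), se=float(se_y[i]), pvalue=float(py[i]),
            n=cfg.n_outcome, **common))
    exposure = GwasTable(trait_id=cfg.exposure_id, trait_type="quantitative",
                         records=exp_records, n_total=cfg.n_exposure)
    outcome = GwasTable(trait_id=cfg.outcome_id, trait_type="binary",
                        records=out_records, n_total=cfg.n_outcome,
                        n_cases=cfg.case_fraction * cfg.n_outcome)
    return exposure, outcome, SimTruth(theta=cfg.theta, gamma=gamma, alpha=alpha,
                                       invalid_idx=invalid, config=cfg)


@dataclass
class RegionTruth:
    causal_mode: str
    causal_idx_t1: int | None
    causal_idx_t2: int | None
    shared: bool
    rho: float
    effect_r2: float


def simulate_ld_region(
    m_snps: int = 100,
    rho: float = 0.8,
    causal_mode: str = "shared",
    effect_r2: float = 0.01,
    n1: float = 50_000,
    n2: float = 50_000,
    seed: int = 0,
    snp_prefix: str = "rs",
) -> tuple[RegionalAssoc, RegionalAssoc, RegionTruth]:
    """Two regional association signals over AR(1)-correlated SNPs.

    The LD correlation matrix has R_ij = rho^|i−j|.  Marginal z-scores are
    drawn as z_t ~ MVN(sqrt(n_t)·R·λ_t, R) where λ_t places a single causal
    effect of size sqrt(effect_r2) per trait: at the same SNP (``shared``),
    at well-separated SNPs (``distinct``), for trait 1 only
    (``trait1_only``), or nowhere (``null``).
    """
    if m_snps < 2:
        raise ValueError("need at least 2 SNPs")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if causal_mode not in ("shared", "distinct", "null", "trait1_only"):
        raise ValueError(f"unknown causal_mode {causal_mode!r}")
    rng = np.random.default_rng(seed)
    idx = np.arange(m_snps)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(corr)
    b = np.sqrt(effect_r2)

    c1 = c2 = None
    if causal_mode in ("shared", "distinct", "trait1_only"):
        c1 = int(rng.integers(0, m_snps))
    if causal_mode == "shared":
        c2 = c1
    elif causal_mode == "distinct":
        # well-separated second causal
        far = [i for i in idx if abs(i - c1) >= m_snps // 2] or \
              [i for i in idx if i != c1]
        c2 = int(rng.choice(far))

    def draw(causal_idx, n):
        lam = np.zeros(m_snps)
        if causal_idx is not None:
            lam[causal_idx] = b
        mean = np.sqrt(n) * corr @ lam
        return mean + chol @ rng.standard_normal(m_snps)

    z1 = draw(c1, n1)
    z2 = draw(c2, n2)
    maf = rng.uniform(0.05, 0.5, size=m_snps)
    snps = [f"{snp_prefix}{i + 1}" for i in range(m_snps)]
    t1 = RegionalAssoc.from_z(snps, z1, maf, n1)
    t2 = RegionalAssoc.from_z(snps, z2, maf, n2)
    truth = RegionTruth(causal_mode=causal_mode, causal_idx_t1=c1, causal_idx_t2=c2,
                        shared=(causal_mode == "shared"), rho=rho, effect_r2=effect_r2)
    return t1, t2, truth


@dataclass
class LdscTruth:
    h2_1: float
    h2_2: float
    rg: float


def simulate_ldsc_panel(
    m_snps: int = 50_000,
    m_ref: float | None = None,
    n1: float = 50_000,
    n2: float = 50_000,
    h2_1: float = 0.3,
    h2_2: float = 0.3,
    rg: float = 0.5,
    seed: int = 0,
) -> tuple[LdscPanel, LdscTruth]:
    """Bivariate z-score panel under the LD-score regression generative law.

    LD scores are 1 plus Gamma-distributed excess (shape 3, scale 30; mean
    ≈ 91, the genome-wide ballpark).  Per SNP, (z1, z2) is bivariate normal
    with Var(z_t) = 1 + N_t·h²_t·ℓ/M and Cov = sqrt(N1·N2)·rg·
    sqrt(h²_1·h²_2)·ℓ/M.
    """
    if not (0.0 <= h2_1 < 1.0 and 0.0 <= h2_2 < 1.0):
        raise ValueError("heritabilities must lie in [0,1)")
    if abs(rg) > 1.0:
        raise ValueError("|rg| must be <= 1")
    rng = np.random.default_rng(seed)
    if m_ref is None:
        m_ref = float(m_snps)
    l2 = 1.0 + rng.gamma(shape=3.0, scale=30.0, size=m_snps)
    v1 = 1.0 + n1 * h2_1 * l2 / m_ref
    v2 = 1.0 + n2 * h2_2 * l2 / m_ref
    cov = np.sqrt(n1 * n2) * rg * np.sqrt(h2_1 * h2_2) * l2 / m_ref
    det = v1 * v2 - cov**2
    if np.any(det <= 0):
        raise ValueError("per-SNP covariance matrix not positive definite")
    e1 = rng.standard_normal(m_snps)
    e2 = rng.standard_normal(m_snps)
    z1 = np.sqrt(v1) * e1
    # conditional draw preserving the target covariance
    z2 = cov / np.sqrt(v1) * e1 + np.sqrt(v2 - cov**2 / v1) * e2
    panel = LdscPanel(l2=l2, z1=z1, z2=z2, m_ref=m_ref, n1=n1, n2=n2)
    return panel, LdscTruth(h2_1=h2_1, h2_2=h2_2, rg=rg)


def simulate_confounder_table(
    instrument_ids: list[str],
    planted: list[tuple[str, str]],
    seed: int = 0,
    n_benign: int = 0,
    p_threshold: float = 1e-5,
) -> pd.DataFrame:
    """A confounder-association table with known planted hits.

    ``planted`` pairs (snp_id, trait) receive p-values below the removal
    threshold; optionally ``n_benign`` additional instruments get
    above-threshold rows, which must never trigger removal.
    """
    for snp, _ in planted:
        if snp not in instrument_ids:
            raise ValueError(f"planted SNP {snp} is not among the instruments")
    rng = np.random.default_rng(seed)
    rows = [
        {"snp": snp, "trait": trait,
         "pvalue": float(10.0 ** (-rng.uniform(6.0, 12.0)))}
        for snp, trait in planted
    ]
    planted_ids = {s for s, _ in planted}
    benign_pool = [s for s in instrument_ids if s not in planted_ids]
    for snp in benign_pool[:n_benign]:
        rows.append({"snp": snp, "trait": "benign_trait",
                     "pvalue": float(rng.uniform(10 * p_threshold, 1.0))})
    return pd.DataFrame(rows, columns=["snp", "trait", "pvalue"])


@dataclass
class UniverseTruth:
    causal_ids: list[str]
    thetas: dict[str, float]
    sim_truths: dict[str, SimTruth]


def simulate_universe(
    n_exposures: int = 20,
    n_causal: int = 3,
    theta_causal: float = -0.7,
    n_snps_range: tuple[int, int] = (12, 30),
    seed: int = 0,
) -> dict:
    """A multi-metabolite screening universe with planted causal exposures.

    Returns exposure tables, primary and replication outcome tables (shared
    SNPs, independent cohort noise), an identity LD matrix over all SNPs,
    and the ground truth.  Exposures occupy separate chromosome labels with
    SNPs 2 Mb apart, so instruments are independent by construction.
    """
    rng = np.random.default_rng(seed)
    exposure_records: dict[str, list[VariantAssociation]] = {}
    truths: dict[str, SimTruth] = {}
    causal_pos = rng.choice(n_exposures, size=n_causal, replace=False)
    thetas = {}
    out_primary_records: list[VariantAssociation] = []
    out_repl_records: list[VariantAssociation] = []
    k_rep = CASES_REPLICATION / N_OUTCOME_REPLICATION

    all_snp_ids: list[str] = []
    for e in range(n_exposures):
        eid = f"metab_{e + 1:02d}"
        theta = theta_causal if e in causal_pos else 0.0
        thetas[eid] = theta
        j = int(rng.integers(n_snps_range[0], n_snps_range[1] + 1))
        cfg = SimConfig(
            n_snps=j, theta=theta, exposure_id=eid, outcome_id="crc_primary",
            snp_prefix=f"rs{e + 1}_", chrom=str(e + 1),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        exposure, outcome, truth = simulate_two_sample(cfg)
        exposure_records[eid] = list(exposure.records)
        truths[eid] = truth
        out_primary_records.extend(outcome.records)
        all_snp_ids.extend(r.snp_id for r in outcome.records)

        # replication cohort: same true effects, independent noise, smaller n
        eaf = np.array([r.eaf for r in outcome.records])
        se_rep = 1.0 / np.sqrt(2.0 * N_OUTCOME_REPLICATION * eaf * (1.0 - eaf)
                               * k_rep * (1.0 - k_rep))
        mean = theta * truth.gamma + truth.alpha
        by_rep = mean + se_rep * rng.standard_normal(j)
        py_rep = 2.0 * stats.norm.sf(np.abs(by_rep) / se_rep)
        for i, rec in enumerate(outcome.records):
            out_repl_records.append(VariantAssociation(
                snp_id=rec.snp_id, effect_allele=rec.effect_allele,
                other_allele=rec.other_allele, beta=float(by_rep[i]),
                se=float(se_rep[i]), pvalue=float(py_rep[i]),
                n=N_OUTCOME_REPLICATION, chrom=rec.chrom, pos=rec.pos, eaf=rec.eaf))

    # Each metabolite GWAS reports the whole SNP panel, so every exposure
    # table also carries (null-effect) records for the other exposures'
    # instruments; multivariable MR needs these complete rows.
    exposures: dict[str, GwasTable] = {}
    for eid, own in exposure_records.items():
        own_ids = {r.snp_id for r in own}
        cross: list[VariantAssociation] = []
        for rec in out_primary_records:
            if rec.snp_id in own_ids:
                continue
            se_x = 1.0 / np.sqrt(2.0 * N_EXPOSURE * rec.eaf * (1.0 - rec.eaf))
            bx = se_x * rng.standard_normal()
            cross.append(VariantAssociation(
                snp_id=rec.snp_id, effect_allele=rec.effect_allele,
                other_allele=rec.other_allele, beta=float(bx), se=float(se_x),
                pvalue=float(2.0 * stats.norm.sf(abs(bx) / se_x)),
                n=N_EXPOSURE, chrom=rec.chrom, pos=rec.pos, eaf=rec.eaf))
        exposures[eid] = GwasTable(trait_id=eid, trait_type="quantitative",
                                   records=own + cross, n_total=N_EXPOSURE)

    outcome_primary = GwasTable(
        trait_id="crc_primary", trait_type="binary", records=out_primary_records,
        n_total=N_OUTCOME_PRIMARY, n_cases=CASES_PRIMARY)
    outcome_replication = GwasTable(
        trait_id="crc_replication", trait_type="binary", records=out_repl_records,
        n_total=N_OUTCOME_REPLICATION, n_cases=CASES_REPLICATION)
    ld = LdMatrix(all_snp_ids, np.eye(len(all_snp_ids)))
    causal_ids = sorted(f"metab_{int(e) + 1:02d}" for e in causal_pos)
    return {
        "exposures": exposures,
        "outcome_primary": outcome_primary,
        "outcome_replication": outcome_replication,
        "ld": ld,
        "truth": UniverseTruth(causal_ids=causal_ids, thetas=thetas, sim_truths=truths),
    }
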