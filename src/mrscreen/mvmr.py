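"""Multivariable MR: direct effects of several exposures on one outcome.

With SNP-exposure effect matrix BX (J SNPs × m exposures) and outcome
effects by, the multivariable IVW estimate regresses by on the columns of
BX without intercept, weighting by 1/sy².  Each coefficient is the direct
effect of its exposure conditional on the others.  SEs carry a
multiplicative overdispersion factor sqrt(max(1, Q/(J−m))) and p-values use
t(J−m).  A multivariable MR-PRESSO flags pleiotropic outliers via the same
leave-one-out residual simulation as the univariable test and reports a
corrected fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_data import GwasTable, orient_effect
from .instruments import SelectionConfig, clump, select_instruments
from .mr_estimators import to_or

__all__ = [
    "MvmrInputs",
    "MvmrEstimate",
    "MvmrPressoResult",
    "CollinearityError",
    "InsufficientInstrumentsError",
    "build_mvmr_inputs",
    "mvmr_ivw",
    "mvmr_presso",
]


class CollinearityError(np.linalg.LinAlgError):
    pass


class InsufficientInstrumentsError(ValueError):
    pass


@dataclass
class MvmrInputs:
    """Joint instrument set with complete exposure and outcome effects."""

    snp_ids: list[str]
    exposure_ids: list[str]
    bx: np.ndarray        # J x m
    sx: np.ndarray        # J x m
    by: np.ndarray
    sy: np.ndarray
    audit: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bx = np.asarray(self.bx, dtype=float)
        self.sx = np.asarray(self.sx, dtype=float)
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        j, m = self.bx.shape
        if self.sx.shape != (j, m) or len(self.by) != j or len(self.sy) != j:
            raise ValueError("inconsistent MVMR input shapes")
        if len(self.exposure_ids) != m:
            raise ValueError("exposure_ids length disagrees with BX columns")

    @property
    def n_snp(self) -> int:
        return self.bx.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.bx.shape[1]

    def subset(self, keep_idx) -> "MvmrInputs":
        keep_idx = np.asarray(keep_idx)
        return MvmrInputs(
            snp_ids=[self.snp_ids[i] for i in keep_idx],
            exposure_ids=list(self.exposure_ids),
            bx=self.bx[keep_idx], sx=self.sx[keep_idx],
            by=self.by[keep_idx], sy=self.sy[keep_idx],
            audit=dict(self.audit),
        )


@dataclass
class MvmrEstimate:
    """Per-exposure direct effects from one multivariable fit."""

    table: pd.DataFrame  # exposure, nsnp, b_direct, se, p, OR, ci_low, ci_high, method
    n_snp: int
    re_scale: float
    q: float


def build_mvmr_inputs(
    exposure_tables: dict[str, GwasTable],
    outcome: GwasTable,
    ld,
    config: SelectionConfig | None = None,
) -> MvmrInputs:
    """Assemble the joint instrument set for several exposures.

    Takes the union of each exposure's univariable instruments, jointly
    clumps it ranking SNPs by their minimum p across exposures, requires a
    complete row (every exposure and the outcome) for each retained SNP, and
    harmonizes all effects to a common effect allele.  Incomplete or
    non-harmonizable SNPs are dropped with the reason audited.
    """
    cfg = config or SelectionConfig()
    audit: dict[str, list[str]] = {}
    exposure_ids = list(exposure_tables)
    if len(exposure_ids) < 2:
        raise ValueError("multivariable MR needs at least 2 exposures")

    union: dict[str, dict] = {}
    for eid in exposure_ids:
        sel = select_instruments(exposure_tables[eid], outcome, ld, cfg)
        for inst in sel.instruments:
            rec = inst.variant
            entry = union.setdefault(rec.snp_id, {"pmin": rec.pvalue, "rec": rec})
            if rec.pvalue < entry["pmin"]:
                entry.update(pmin=rec.pvalue, rec=rec)
    if not union:
        raise InsufficientInstrumentsError("no instruments survive univariable selection")

    # joint clumping ranked by minimum p across exposures
    from .gwas_data import VariantAssociation
    candidates = []
    for snp, entry in union.items():
        r = entry["rec"]
        candidates.append(VariantAssociation(
            snp_id=snp, effect_allele=r.effect_allele, other_allele=r.other_allele,
            beta=r.beta, se=r.se, pvalue=entry["pmin"], n=r.n,
            chrom=r.chrom, pos=r.pos, eaf=r.eaf))
    kept = set(clump(candidates, ld, cfg.clump_r2, cfg.clump_window_kb))
    audit["joint_clumped"] = sorted(set(union) - kept)

    rows = []
    audit["incomplete"] = []
    audit["harmonization"] = []
    for snp in sorted(kept):
        ref = union[snp]["rec"]
        out = outcome.get(snp)
        if out is None:
            audit["incomplete"].append(snp)
            continue
        bx_row, sx_row = [], []
        ok = True
        for eid in exposure_ids:
            rec = exposure_tables[eid].get(snp)
            if rec is None:
                audit["incomplete"].append(snp)
                ok = False
                break
            b, _, status = orient_effect(ref.effect_allele, ref.other_allele,
                                         rec.effect_allele, rec.other_allele,
                                         rec.beta, rec.eaf)
            if status in ("palindromic", "incompatible_alleles"):
                audit["harmonization"].append(snp)
                ok = False
                break
            bx_row.append(b)
            sx_row.append(rec.se)
        if not ok:
            continue
        by, _, status = orient_effect(ref.effect_allele, ref.other_allele,
                                      out.effect_allele, out.other_allele,
                                      out.beta, out.eaf)
        if status in ("palindromic", "incompatible_alleles"):
            audit["harmonization"].append(snp)
            continue
        rows.append((snp, bx_row, sx_row, by, out.se))

    m = len(exposure_ids)
    if len(rows) < m + 2:
        raise InsufficientInstrumentsError(
            f"only {len(rows)} complete SNPs for {m} exposures (need >= {m + 2})")
    return MvmrInputs(
        snp_ids=[r[0] for r in rows],
        exposure_ids=exposure_ids,
        bx=np.array([r[1] for r in rows]),
        sx=np.array([r[2] for r in rows]),
        by=np.array([r[3] for r in rows]),
        sy=np.array([r[4] for r in rows]),
        audit=audit,
    )


def _mv_wls(bx: np.ndarray, by: np.ndarray, w: np.ndarray):
    """Weighted no-intercept least squares; returns (coef, cov_unit, q)."""
    xw = bx * w[:, None]
    xtx = bx.T @ xw
    xty = xw.T @ by
    try:
        cov_unit = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(str(exc)) from exc
    coef = cov_unit @ xty
    resid = by - bx @ coef
    q = float(np.sum(w * resid**2))
    return coef, cov_unit, q


def mvmr_ivw(inputs: MvmrInputs, method_label: str = "mvmr_ivw") -> MvmrEstimate:
    """Multivariable IVW: WLS of by on the BX columns, weights 1/sy².

    SEs are inflated by sqrt(max(1, Q/(J−m))); p-values use t(J−m).
    Rank-deficient BX raises :class:`CollinearityError` naming redundant
    columns.
    """
    bx, by, sy = inputs.bx, inputs.by, inputs.sy
    j, m = bx.shape
    if j <= m:
        raise InsufficientInstrumentsError("need more SNPs than exposures")
    rank = np.linalg.matrix_rank(bx)
    if rank < m:
        redundant = [
            inputs.exposure_ids[k] for k in range(m)
            if np.linalg.matrix_rank(np.delete(bx, k, axis=1)) == rank
        ]
        raise CollinearityError(
            f"exposure effect matrix is rank-deficient; redundant columns: {redundant}")
    w = 1.0 / sy**2
    coef, cov_unit, q = _mv_wls(bx, by, w)
    scale = max(1.0, q / (j - m))
    se = np.sqrt(scale * np.diag(cov_unit))
    rows = []
    for k, eid in enumerate(inputs.exposure_ids):
        or_, lo, hi, p = to_or(coef[k], se[k], df=j - m)
        rows.append({
            "exposure": eid, "nsnp": j, "b_direct": float(coef[k]),
            "se": float(se[k]), "p": p, "OR": or_, "ci_low": lo, "ci_high": hi,
            "method": method_label,
        })
    return MvmrEstimate(table=pd.DataFrame(rows), n_snp=j,
                        re_scale=float(np.sqrt(scale)), q=q)


@dataclass
class MvmrPressoResult:
    rss_observed: float
    global_p: float
    outliers: list[str]
    outlier_p: pd.DataFrame
    distortion_p: float | None
    estimate_raw: MvmrEstimate
    estimate_outlier_corrected: MvmrEstimate | None
    n_sim: int
    seed: int


def _mv_loo_expected(bx, by, w):
    """Leave-one-out multivariable fits; returns expected by per SNP."""
    j, m = bx.shape
    xw = bx * w[:, None]
    xtx = bx.T @ xw
    xty = xw.T @ by
    # rank-one downdates, solved per SNP
    a = np.broadcast_to(xtx, (j, m, m)) - w[:, None, None] * bx[:, :, None] * bx[:, None, :]
    b = xty[None, :] - (w * by)[:, None] * bx
    coefs = np.linalg.solve(a, b[..., None])[..., 0]
    return np.einsum("jm,jm->j", bx, coefs)


def mvmr_presso(inputs: MvmrInputs, n_sim: int = 1000,
                outlier_alpha: float = 0.05, seed: int | None = None) -> MvmrPressoResult:
    """Multivariable MR-PRESSO: simulation-based pleiotropy and outlier tests.

    Mirrors the univariable test with leave-one-out multivariable fits
    supplying the expected outcome effects.  Flagged SNPs are removed and
    the corrected :func:`mvmr_ivw` fit reported.
    """
    if seed is None:
        raise ValueError("mvmr_presso requires an explicit seed")
    bx, sx, by, sy = inputs.bx, inputs.sx, inputs.by, inputs.sy
    j, m = bx.shape
    if j < m + 3:
        raise InsufficientInstrumentsError("MVMR-PRESSO needs at least m + 3 SNPs")
    w = 1.0 / sy**2
    expected = _mv_loo_expected(bx, by, w)
    rss_j = w * (by - expected) ** 2
    rss_obs = float(rss_j.sum())

    rng = np.random.default_rng(seed)
    rss_sim = np.empty(n_sim)
    rss_sim_j = np.empty((n_sim, j))
    for i in range(n_sim):
        bx_s = bx + sx * rng.standard_normal((j, m))
        by_s = expected + sy * rng.standard_normal(j)
        exp_s = _mv_loo_expected(bx_s, by_s, w)
        r = w * (by_s - exp_s) ** 2
        rss_sim_j[i] = r
        rss_sim[i] = r.sum()

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + np.sum(rss_sim_j >= rss_j[None, :], axis=0)) / (n_sim + 1)
    p_bonf = np.minimum(1.0, p_raw * j)
    outlier_df = pd.DataFrame({"snp_id": inputs.snp_ids,
                               "p_raw": p_raw, "p_bonferroni": p_bonf})
    outliers = [s for s, p in zip(inputs.snp_ids, p_bonf) if p < outlier_alpha]

    est_raw = mvmr_ivw(inputs, method_label="mvmr_ivw")
    est_corr = None
    distortion_p = None
    if outliers:
        keep = [i for i, s in enumerate(inputs.snp_ids) if s not in set(outliers)]
        if len(keep) <= m:
            raise ValueError("degenerate removal: too few SNPs remain after outliers")
        est_corr = mvmr_ivw(inputs.subset(keep), method_label="mvmr_presso")
        raw_b = est_raw.table["b_direct"].to_numpy()
        corr_b = est_corr.table["b_direct"].to_numpy()
        denom = np.where(raw_b != 0, np.abs(raw_b), 1.0)
        d_obs = float(np.max(np.abs((corr_b - raw_b) / denom)))
        n_boot = 1000
        d_boot = np.empty(n_boot)
        idx = np.arange(j)
        for b in range(n_boot):
            drop = rng.choice(idx, size=len(outliers), replace=False)
            mask = np.ones(j, bool)
            mask[drop] = False
            coef_b, _, _ = _mv_wls(bx[mask], by[mask], w[mask])
            d_boot[b] = float(np.max(np.abs((coef_b - raw_b) / denom)))
        distortion_p = float((1 + np.sum(d_boot >= d_obs)) / (n_boot + 1))

    return MvmrPressoResult(
        rss_observed=rss_obs, global_p=global_p, outliers=outliers,
        outlier_p=outlier_df, distortion_p=distortion_p,
        estimate_raw=est_raw, estimate_outlier_corrected=est_corr,
        n_sim=n_sim, seed=seed,
    )
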