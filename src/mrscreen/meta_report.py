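"""Cross-cohort meta-analysis and the end-to-end screening pipeline.

The pipeline reproduces a metabolome-wide MR screen: for every exposure,
select instruments, remove radial outliers, estimate with IVW (primary),
MR-Egger and weighted median, run the heterogeneity/pleiotropy/leave-one-out
diagnostics, and apply the four-criterion screen.  Screen survivors are
replicated against a second outcome cohort with IVW only, pooled by a
DerSimonian–Laird random-effects meta-analysis of the log-OR estimates,
checked for directionality (Steiger) and power, and re-estimated after
confounder-associated instruments are removed.  A final candidate must be
direction-consistent in the replication cohort and meta-significant.
Optionally, a multivariable MR over the final candidates estimates each
exposure's direct effect.

All randomness derives deterministically from the run seed, and the report
serializes to canonical JSON/TSV so identical configurations yield
byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .direction_power import mr_power, steiger_test
from .gwas_data import GwasTable, HarmonizedSet, harmonize_pair
from .instruments import SelectionConfig, filter_confounders, select_instruments
from .mr_estimators import MrEstimate, ivw, mr_egger, to_or, weighted_median
from .mvmr import (
    InsufficientInstrumentsError,
    build_mvmr_inputs,
    mvmr_ivw,
    mvmr_presso,
)
from .sensitivity import (
    cochran_q,
    leave_one_out,
    mr_presso,
    radial_outliers,
    screen_candidates,
)

__all__ = [
    "MetaResult",
    "PipelineConfig",
    "PipelineReport",
    "meta_random_effects",
    "run_pipeline",
]


@dataclass
class MetaResult:
    """DerSimonian–Laird random-effects pooled estimate."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    tau2: float
    q_meta: float
    k_studies: int


def meta_random_effects(estimates: list[tuple[float, float]],
                        alpha: float = 0.05) -> MetaResult:
    """Pool (beta, se) study estimates with the DerSimonian–Laird model.

    tau² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)) with fixed weights w = 1/se²;
    the pooled estimate reweights by 1/(se² + tau²).  Pooling is on the
    log-OR scale.  A single study is returned unchanged with tau² = 0.
    """
    if not estimates:
        raise ValueError("no estimates to pool")
    b = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("study SEs must be > 0")
    k = len(b)
    crit = stats.norm.ppf(1 - alpha / 2)
    if k == 1:
        p = 2 * stats.norm.sf(abs(b[0]) / se[0])
        return MetaResult(beta=float(b[0]), se=float(se[0]),
                          ci_low=float(b[0] - crit * se[0]),
                          ci_high=float(b[0] + crit * se[0]),
                          pvalue=float(p), tau2=0.0, q_meta=0.0, k_studies=1)
    w = 1.0 / se**2
    b_fixed = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - b_fixed) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom)
    w_star = 1.0 / (se**2 + tau2)
    beta = float(np.sum(w_star * b) / np.sum(w_star))
    se_pool = float(np.sqrt(1.0 / np.sum(w_star)))
    p = float(2 * stats.norm.sf(abs(beta) / se_pool))
    return MetaResult(beta=beta, se=se_pool,
                      ci_low=beta - crit * se_pool, ci_high=beta + crit * se_pool,
                      pvalue=p, tau2=float(tau2), q_meta=q, k_studies=k)


@dataclass
class PipelineConfig:
    """Inputs and settings for one metabolome-wide screening run."""

    exposures: dict[str, GwasTable]
    outcome_primary: GwasTable
    outcome_replication: GwasTable | None
    ld: object
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    confounder_table: pd.DataFrame | None = None
    seed: int = 0
    alpha: float = 0.05
    wm_n_boot: int = 1000
    presso_n_sim: int = 1000
    radial_prefilter: bool = True
    run_mvmr: bool = True
    confounder_p: float = 1e-5


@dataclass
class PipelineReport:
    """Per-exposure results plus the retained/final candidate sets."""

    rows: pd.DataFrame
    retained: list[str]
    final: list[str]
    mvmr_table: pd.DataFrame | None
    provenance: dict

    def forest_table(self) -> pd.DataFrame:
        """Exposure × cohort OR/CI rows for external forest plotting."""
        recs = []
        for _, r in self.rows.iterrows():
            if not np.isnan(r.get("ivw_b", np.nan)):
                recs.append({"exposure": r["exposure"], "cohort": "primary",
                             "OR": r["ivw_or"], "ci_low": r["ivw_ci_low"],
                             "ci_high": r["ivw_ci_high"]})
            if not np.isnan(r.get("repl_b", np.nan)):
                or_, lo, hi, _ = to_or(r["repl_b"], r["repl_se"])
                recs.append({"exposure": r["exposure"], "cohort": "replication",
                             "OR": or_, "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(recs, columns=["exposure", "cohort", "OR", "ci_low", "ci_high"])

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "retained": self.retained,
            "final": self.final,
            "rows": json.loads(self.rows.to_json(orient="records", double_precision=15)),
            "mvmr": (json.loads(self.mvmr_table.to_json(orient="records",
                                                        double_precision=15))
                     if self.mvmr_table is not None else None),
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))

    def report_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


_ROW_FIELDS = [
    "exposure", "status", "n_significant", "n_instruments", "n_radial_outliers",
    "ivw_b", "ivw_se", "ivw_p", "ivw_or", "ivw_ci_low", "ivw_ci_high",
    "egger_b", "egger_p", "egger_intercept", "egger_intercept_p",
    "wm_b", "wm_p", "q", "q_p", "presso_global_p", "loo_sign_flip",
    "screen_retained", "p_bonferroni", "p_fdr",
    "repl_b", "repl_se", "repl_p", "meta_b", "meta_se", "meta_p", "meta_tau2",
    "steiger_forward", "steiger_p", "power", "r2_sum", "f_aggregate",
    "n_confounder_removed", "confounder_b", "confounder_p", "final",
]


def _blank_row(exposure: str, status: str) -> dict:
    row = {k: np.nan for k in _ROW_FIELDS}
    row.update(exposure=exposure, status=status, screen_retained=False, final=False,
               loo_sign_flip=False, steiger_forward=False, n_confounder_removed=0)
    return row


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full screen over every exposure; per-exposure failures are
    recorded in the report rather than raised."""
    cfg = config
    rows: list[dict] = []
    retained: list[str] = []
    final: list[str] = []
    survivors_h: dict[str, HarmonizedSet] = {}
    exposure_ids = sorted(cfg.exposures)
    seed_root = np.random.SeedSequence(cfg.seed)
    child_seeds = {eid: s.generate_state(2) % (2**31 - 1)
                   for eid, s in zip(exposure_ids,
                                     seed_root.spawn(len(exposure_ids)))}

    for eid in exposure_ids:
        row = _blank_row(eid, "ok")
        wm_seed, presso_seed = (int(x) for x in child_seeds[eid])
        try:
            sel = select_instruments(cfg.exposures[eid], cfg.outcome_primary,
                                     cfg.ld, cfg.selection)
            row["n_significant"] = sel.n_significant
            row["f_aggregate"] = sel.aggregate_f if sel.aggregate_f is not None else np.nan
            if not sel.sufficient:
                row["status"] = "insufficient_instruments"
                row["n_instruments"] = sel.n_instruments
                rows.append(row)
                continue
            h = sel.harmonized

            n_out = 0
            if cfg.radial_prefilter and h.n_snp >= 3:
                rad = radial_outliers(h, alpha=cfg.alpha, iterate=True)
                n_out = len(rad.outliers)
                if n_out:
                    h = h.subset([s for s in h.snp_ids if s not in set(rad.outliers)],
                                 dropped_reason="outlier")
            row["n_radial_outliers"] = n_out
            row["n_instruments"] = h.n_snp
            if h.n_snp < cfg.selection.min_snps:
                row["status"] = "insufficient_instruments"
                rows.append(row)
                continue

            est_ivw = ivw(h, model="random")
            est_egger = mr_egger(h)
            est_wm = weighted_median(h, n_boot=cfg.wm_n_boot, seed=wm_seed)
            het = cochran_q(h, est_ivw)
            loo = leave_one_out(h, alpha=cfg.alpha)
            presso = (mr_presso(h, n_sim=cfg.presso_n_sim, seed=presso_seed)
                      if h.n_snp >= 4 else None)

            row.update(
                ivw_b=est_ivw.beta, ivw_se=est_ivw.se, ivw_p=est_ivw.pvalue,
                ivw_or=est_ivw.or_, ivw_ci_low=est_ivw.ci_low, ivw_ci_high=est_ivw.ci_high,
                egger_b=est_egger.beta, egger_p=est_egger.pvalue,
                egger_intercept=est_egger.extras["intercept"],
                egger_intercept_p=est_egger.extras["intercept_p"],
                wm_b=est_wm.beta, wm_p=est_wm.pvalue,
                q=het.Q, q_p=het.pvalue,
                presso_global_p=presso.global_p if presso is not None else np.nan,
                loo_sign_flip=loo.any_sign_flip,
            )

            decision = screen_candidates(eid, est_ivw, est_egger, est_wm, het, loo,
                                         alpha=cfg.alpha)
            row["screen_retained"] = decision.retained
            if not decision.retained:
                rows.append(row)
                continue
            retained.append(eid)
            survivors_h[eid] = h

            # replication + meta
            repl_dir_ok = True
            meta_ok = True
            if cfg.outcome_replication is not None:
                h_rep = harmonize_pair(cfg.exposures[eid], cfg.outcome_replication,
                                       h.snp_ids)
                est_rep = ivw(h_rep, model="random")
                row.update(repl_b=est_rep.beta, repl_se=est_rep.se, repl_p=est_rep.pvalue)
                meta = meta_random_effects([(est_ivw.beta, est_ivw.se),
                                            (est_rep.beta, est_rep.se)])
                row.update(meta_b=meta.beta, meta_se=meta.se, meta_p=meta.pvalue,
                           meta_tau2=meta.tau2)
                repl_dir_ok = np.sign(est_rep.beta) == np.sign(est_ivw.beta)
                meta_ok = meta.pvalue < cfg.alpha

            st = steiger_test(h, n_exp=cfg.exposures[eid].n_total,
                              n_out=cfg.outcome_primary.n_total)
            row.update(steiger_forward=st.direction_forward, steiger_p=st.pvalue)

            r2_sum = float(np.sum((h.df["bx"] ** 2 /
                                   (h.df["bx"] ** 2 + cfg.exposures[eid].n_total
                                    * h.df["sx"] ** 2))))
            row["r2_sum"] = r2_sum
            kfrac = cfg.outcome_primary.case_fraction
            if kfrac is not None:
                pw = mr_power(cfg.outcome_primary.n_total, kfrac, r2_sum,
                              est_ivw.or_, alpha=cfg.alpha)
                row["power"] = pw.power

            if cfg.confounder_table is not None:
                h_cf, removed = filter_confounders(h, cfg.confounder_table,
                                                   cfg.confounder_p)
                row["n_confounder_removed"] = int(removed["snp"].nunique()) if len(removed) else 0
                if h_cf.n_snp >= 2 and h_cf.n_snp < h.n_snp:
                    est_cf = ivw(h_cf, model="random")
                    row.update(confounder_b=est_cf.beta, confounder_p=est_cf.pvalue)

            is_final = bool(repl_dir_ok and meta_ok)
            row["final"] = is_final
            if is_final:
                final.append(eid)
            rows.append(row)
        except Exception as exc:  # per-exposure failures never kill the screen
            row["status"] = f"error: {type(exc).__name__}: {exc}"
            rows.append(row)

    df = pd.DataFrame(rows, columns=_ROW_FIELDS)
    # multiple-testing columns for transparency (the screen itself uses raw p)
    pvals = df["ivw_p"].to_numpy(float)
    ok = ~np.isnan(pvals)
    bonf = np.full(len(df), np.nan)
    fdr = np.full(len(df), np.nan)
    if ok.sum():
        m = int(ok.sum())
        bonf[ok] = np.minimum(1.0, pvals[ok] * m)
        order = np.argsort(pvals[ok])
        ranked = pvals[ok][order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        tmp = np.empty(m)
        tmp[order] = np.minimum(1.0, ranked)
        fdr[ok] = tmp
    df["p_bonferroni"] = bonf
    df["p_fdr"] = fdr

    mvmr_table = None
    if cfg.run_mvmr and len(final) >= 2:
        try:
            inputs = build_mvmr_inputs({eid: cfg.exposures[eid] for eid in final},
                                       cfg.outcome_primary, cfg.ld, cfg.selection)
            parts = [mvmr_ivw(inputs).table]
            if inputs.n_snp >= inputs.n_exposures + 3:
                mv_seed = int(seed_root.generate_state(1)[0] % (2**31 - 1))
                pres = mvmr_presso(inputs, n_sim=cfg.presso_n_sim, seed=mv_seed)
                if pres.estimate_outlier_corrected is not None:
                    parts.append(pres.estimate_outlier_corrected.table)
            mvmr_table = pd.concat(parts, ignore_index=True)
        except (InsufficientInstrumentsError, ValueError):
            mvmr_table = None

    provenance = {
        "package_version": _pkg_version,
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "selection": {
            "p_exposure": cfg.selection.p_exposure,
            "clump_r2": cfg.selection.clump_r2,
            "clump_window_kb": cfg.selection.clump_window_kb,
            "f_min": cfg.selection.f_min,
            "p_outcome_exclude": cfg.selection.p_outcome_exclude,
            "min_snps": cfg.selection.min_snps,
        },
        "wm_n_boot": cfg.wm_n_boot,
        "presso_n_sim": cfg.presso_n_sim,
        "n_exposures": len(exposure_ids),
    }
    return PipelineReport(rows=df, retained=retained, final=final,
                          mvmr_table=mvmr_table, provenance=provenance)
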