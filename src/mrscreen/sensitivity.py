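"""Heterogeneity and pleiotropy diagnostics, and the candidate screen.

Instruments acting on the outcome through pathways other than the exposure
(horizontal pleiotropy) show up as excess dispersion of the per-SNP Wald
ratios.  Four complementary checks are implemented:

* Cochran's Q over the ratios (chi-square on J−1 df; J−2 around an Egger fit);
* Radial MR: the IVW fit re-expressed as a regression of ratio·sqrt(w) on
  sqrt(w) through the origin, whose per-SNP squared residuals q_j partition
  Q exactly and are each chi-square(1) under homogeneity — SNPs with
  q_j-p below alpha are outliers, removed iteratively;
* MR-PRESSO: a seeded parametric simulation of the leave-one-out residual
  sum of squares giving a global pleiotropy p-value, per-SNP outlier tests
  (Bonferroni-adjusted), and a distortion test comparing the raw and
  outlier-corrected estimates;
* leave-one-out: J refits each excluding one SNP, flagging sign flips and
  loss of significance.

:func:`screen_candidates` combines these into the four-criterion decision
used to retain an exposure: significant IVW, direction-consistent IVW/Egger/
weighted-median, no heterogeneity (Q p > 0.05) or directional pleiotropy
(Egger intercept p > 0.05), and no single-SNP sign flip in leave-one-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mr_estimators import MrEstimate, _arrays, ivw

__all__ = [
    "HeterogeneityResult",
    "RadialResult",
    "PressoResult",
    "LooTable",
    "CandidateDecision",
    "cochran_q",
    "radial_outliers",
    "mr_presso",
    "leave_one_out",
    "screen_candidates",
    "IncompleteBundleError",
]


class IncompleteBundleError(ValueError):
    """The screen was asked to decide without all required components."""


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    pvalue: float
    context: str  # "ivw" | "egger"


@dataclass
class RadialResult:
    per_snp: pd.DataFrame          # snp_id, q, pvalue (first iteration)
    outliers: list[str]
    iterations: int
    final_estimate: MrEstimate | None
    total_q: float


@dataclass
class PressoResult:
    rss_observed: float
    global_p: float
    outlier_p: pd.DataFrame | None   # snp_id, p_raw, p_bonferroni
    outliers: list[str]
    distortion_p: float | None
    estimate_raw: MrEstimate
    estimate_outlier_corrected: MrEstimate | None
    n_sim: int
    seed: int


@dataclass
class LooTable:
    rows: pd.DataFrame  # excluded_snp, b, se, p, sign_flip, significance_loss
    full: MrEstimate

    @property
    def any_sign_flip(self) -> bool:
        return bool(self.rows["sign_flip"].any())


@dataclass
class CandidateDecision:
    exposure_id: str
    ivw_significant: bool
    directions_consistent: bool
    no_heterogeneity: bool
    no_pleiotropy: bool
    loo_stable: bool
    retained: bool = field(init=False)

    def __post_init__(self) -> None:
        self.retained = (self.ivw_significant and self.directions_consistent
                         and self.no_heterogeneity and self.no_pleiotropy
                         and self.loo_stable)


def _ratio_stats(h):
    bx, sx, by, sy = _arrays(h)
    w = bx**2 / sy**2
    ratios = by / bx
    return bx, sx, by, sy, w, ratios


def cochran_q(h, estimate: MrEstimate | None = None) -> HeterogeneityResult:
    """Cochran's Q over per-SNP Wald ratios with first-order weights.

    Around an IVW fit Q uses J−1 df; around an Egger fit the residuals
    include the intercept and Q uses J−2 df.
    """
    bx, sx, by, sy, w, ratios = _ratio_stats(h)
    j = len(bx)
    if j < 2:
        raise ValueError("Cochran Q requires at least 2 instruments")
    if estimate is not None and estimate.method == "egger":
        a = estimate.extras["intercept"]
        b = estimate.beta
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        resid = by * flip - a - b * bx * flip
        q = float(np.sum(resid**2 / sy**2))
        df = j - 2
        context = "egger"
    else:
        beta = estimate.beta if estimate is not None else float(
            np.sum(w * ratios) / np.sum(w))
        q = float(np.sum(w * (ratios - beta) ** 2))
        df = j - 1
        context = "ivw"
    return HeterogeneityResult(Q=q, df=df, pvalue=float(stats.chi2.sf(q, df)), context=context)


def radial_outliers(h, alpha: float = 0.05, iterate: bool = True) -> RadialResult:
    """Radial-MR outlier detection with first-order weights.

    The radial IVW slope equals the fixed-effect IVW estimate; each SNP's
    contribution q_j = w_j (ratio_j − slope)² is chi-square(1) under the
    null, and the q_j sum to Cochran's Q exactly.  SNPs with p < alpha are
    removed and the fit repeated until no new outliers appear or fewer than
    3 SNPs would remain.
    """
    if h.n_snp < 3:
        raise ValueError("radial MR requires at least 3 instruments")
    df_all = h.df.reset_index(drop=True)

    def fit(frame):
        bx = frame["bx"].to_numpy(float)
        by = frame["by"].to_numpy(float)
        sy = frame["sy"].to_numpy(float)
        w = bx**2 / sy**2
        ratios = by / bx
        beta = float(np.sum(w * ratios) / np.sum(w))
        q = w * (ratios - beta) ** 2
        return beta, q

    beta0, q0 = fit(df_all)
    first = pd.DataFrame({
        "snp_id": df_all["snp_id"],
        "q": q0,
        "pvalue": stats.chi2.sf(q0, 1),
    })

    outliers: list[str] = []
    current = df_all
    iterations = 0
    while True:
        iterations += 1
        _, q = fit(current)
        p = stats.chi2.sf(q, 1)
        flagged = current.loc[p < alpha, "snp_id"].tolist()
        if not flagged or len(current) - len(flagged) < 3:
            # never reduce below 3 instruments
            if flagged and len(current) - len(flagged) < 3:
                keep_n = len(current) - 3
                if keep_n > 0:
                    worst = current.loc[np.argsort(p)[:keep_n], "snp_id"].tolist()
                    outliers.extend(worst)
                    current = current[~current["snp_id"].isin(worst)].reset_index(drop=True)
            break
        outliers.extend(flagged)
        current = current[~current["snp_id"].isin(flagged)].reset_index(drop=True)
        if not iterate:
            break

    final_h = h.subset(current["snp_id"], dropped_reason="outlier")
    final_est = ivw(final_h, model="random") if final_h.n_snp >= 2 else None
    return RadialResult(
        per_snp=first, outliers=outliers, iterations=iterations,
        final_estimate=final_est, total_q=float(q0.sum()),
    )


def _loo_ivw_beta(bx, by, w):
    """Leave-one-out fixed-effect IVW estimates, vectorized over SNPs."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def mr_presso(h, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: int | None = None) -> PressoResult:
    """MR-PRESSO global, outlier, and distortion tests.

    Observed RSS = Σ_j w_j (by_j − β̂_(−j)·bx_j)² with β̂_(−j) the
    leave-one-out IVW estimate and w_j = 1/sy_j².  The null distribution is
    generated by drawing bx*_j ~ N(bx_j, sx_j) and by*_j ~ N(β̂_(−j)·bx_j,
    sy_j) ``n_sim`` times and recomputing the statistic on each draw;
    global_p = (1 + #{RSS* >= RSS_obs}) / (n_sim + 1).  Per-SNP empirical
    p-values are Bonferroni-adjusted over J; SNPs below ``outlier_alpha``
    are outliers, and the distortion test bootstraps the change in estimate
    expected from removing that many SNPs at random.
    """
    if seed is None:
        raise ValueError("mr_presso requires an explicit seed")
    bx, sx, by, sy = _arrays(h)
    j = len(bx)
    if j < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments")
    w = 1.0 / sy**2
    beta_loo = _loo_ivw_beta(bx, by, w)
    rss_j = w * (by - beta_loo * bx) ** 2
    rss_obs = float(rss_j.sum())

    rng = np.random.default_rng(seed)
    bx_s = bx + sx * rng.standard_normal((n_sim, j))
    by_s = beta_loo * bx + sy * rng.standard_normal((n_sim, j))
    w_row = w[None, :]
    sxy = np.sum(w_row * bx_s * by_s, axis=1, keepdims=True)
    sxx = np.sum(w_row * bx_s**2, axis=1, keepdims=True)
    beta_loo_s = (sxy - w_row * bx_s * by_s) / (sxx - w_row * bx_s**2)
    rss_sj = w_row * (by_s - beta_loo_s * bx_s) ** 2
    rss_sim = rss_sj.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + np.sum(rss_sj >= rss_j[None, :], axis=0)) / (n_sim + 1)
    p_bonf = np.minimum(1.0, p_raw * j)
    snp_ids = h.snp_ids
    outlier_df = pd.DataFrame({"snp_id": snp_ids, "p_raw": p_raw, "p_bonferroni": p_bonf})
    outliers = [s for s, p in zip(snp_ids, p_bonf) if p < outlier_alpha]

    est_raw = ivw(h, model="random")
    est_corr = None
    distortion_p = None
    if outliers:
        if len(outliers) == j:
            raise ValueError("degenerate removal: every SNP flagged as an outlier")
        kept = [s for s in snp_ids if s not in set(outliers)]
        h_corr = h.subset(kept, dropped_reason="outlier")
        if h_corr.n_snp >= 2:
            est_corr = ivw(h_corr, model="random")
            # distortion: expected shift from removing |outliers| random SNPs
            n_out = len(outliers)
            n_boot = 1000
            d_obs = (est_corr.beta - est_raw.beta) / abs(est_raw.beta) if est_raw.beta != 0 else 0.0
            d_boot = np.empty(n_boot)
            idx = np.arange(j)
            for b in range(n_boot):
                drop = rng.choice(idx, size=n_out, replace=False)
                mask = np.ones(j, bool)
                mask[drop] = False
                bb = float(np.sum(w[mask] * bx[mask] * by[mask]) /
                           np.sum(w[mask] * bx[mask] ** 2))
                d_boot[b] = (bb - est_raw.beta) / abs(est_raw.beta) if est_raw.beta != 0 else 0.0
            distortion_p = float((1 + np.sum(np.abs(d_boot) >= abs(d_obs))) / (n_boot + 1))

    return PressoResult(
        rss_observed=rss_obs, global_p=global_p, outlier_p=outlier_df,
        outliers=outliers, distortion_p=distortion_p,
        estimate_raw=est_raw, estimate_outlier_corrected=est_corr,
        n_sim=n_sim, seed=seed,
    )


def leave_one_out(h, alpha: float = 0.05) -> LooTable:
    """Random-effects IVW refits each excluding one SNP.

    Flags a row when the excluded SNP flips the estimate's sign or when a
    significant full-sample estimate loses significance without it.
    """
    if h.n_snp < 2:
        raise ValueError("leave-one-out requires at least 2 instruments")
    full = ivw(h, model="random")
    rows = []
    ids = h.snp_ids
    for snp in ids:
        sub = h.subset([s for s in ids if s != snp])
        if sub.n_snp == 1:
            d = sub.df.iloc[0]
            b = d["by"] / d["bx"]
            se = d["sy"] / abs(d["bx"])
            p = 2 * stats.norm.sf(abs(b) / se)
        else:
            est = ivw(sub, model="random")
            b, se, p = est.beta, est.se, est.pvalue
        rows.append({
            "excluded_snp": snp, "b": b, "se": se, "p": p,
            "sign_flip": bool(np.sign(b) != np.sign(full.beta)) and full.beta != 0 and b != 0,
            "significance_loss": bool(full.pvalue < alpha and p >= alpha),
        })
    return LooTable(rows=pd.DataFrame(rows), full=full)


def screen_candidates(
    exposure_id: str,
    ivw_estimate: MrEstimate | None,
    egger_estimate: MrEstimate | None,
    wm_estimate: MrEstimate | None,
    heterogeneity: HeterogeneityResult | None,
    loo: LooTable | None,
    alpha: float = 0.05,
) -> CandidateDecision:
    """Apply the four-criterion candidate screen to one exposure's results.

    Retained iff IVW p < alpha, the three estimators agree in sign, Q p >
    alpha, the Egger intercept p > alpha, and no leave-one-out sign flip.
    "Consistent direction and magnitude" is operationalized as sign
    agreement only; magnitude agreement has no quantitative definition here.
    """
    components = {
        "ivw": ivw_estimate, "egger": egger_estimate, "weighted_median": wm_estimate,
        "heterogeneity": heterogeneity, "leave_one_out": loo,
    }
    missing = [k for k, v in components.items() if v is None]
    if missing:
        raise IncompleteBundleError(f"screen for {exposure_id} missing: {', '.join(missing)}")
    signs = {np.sign(ivw_estimate.beta), np.sign(egger_estimate.beta),
             np.sign(wm_estimate.beta)}
    return CandidateDecision(
        exposure_id=exposure_id,
        ivw_significant=bool(ivw_estimate.pvalue < alpha),
        directions_consistent=(len(signs) == 1 and 0.0 not in signs),
        no_heterogeneity=bool(heterogeneity.pvalue > alpha),
        no_pleiotropy=bool(egger_estimate.extras["intercept_p"] > alpha),
        loo_stable=not loo.any_sign_flip,
    )
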