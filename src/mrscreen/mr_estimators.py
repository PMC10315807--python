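"""Core two-sample MR estimators on a harmonized exposure/outcome set.

All estimators operate on per-SNP summary pairs (bx, sx) and (by, sy) and
first-order Wald weights w_j = bx_j²/sy_j² (equivalently, inverse variances
of the per-SNP ratio estimates by_j/bx_j with se sy_j/|bx_j|):

* IVW: inverse-variance-weighted mean of Wald ratios, identical to a
  no-intercept WLS of by on bx with weights 1/sy².  The random-effects
  variant inflates the SE by sqrt(max(1, Q/(J−1))) (multiplicative
  overdispersion), never deflating it.
* MR-Egger: the same regression with a free intercept after orienting every
  SNP to bx >= 0.  A nonzero intercept estimates directional pleiotropy; the
  slope is consistent under the InSIDE assumption.  SEs carry the
  sqrt(max(1, Q/(J−2))) factor and p-values use t(J−2).
* Weighted median: consistent when valid instruments carry a majority of the
  weight (< 50% of SNPs may be invalid); SE by seeded parametric bootstrap.

Binary-outcome effects are on the log-odds scale; :func:`to_or` converts an
estimate to an odds ratio with its confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_data import HarmonizedSet

__all__ = [
    "MrEstimate",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "to_or",
]


@dataclass
class MrEstimate:
    """One causal-effect estimate (log-odds scale for a binary outcome)."""

    method: str  # wald | ivw_fe | ivw_re | egger | weighted_median
    n_snp: int
    beta: float
    se: float
    pvalue: float
    or_: float
    ci_low: float
    ci_high: float
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "method": self.method, "nsnp": self.n_snp, "b": self.beta,
            "se": self.se, "p": self.pvalue, "OR": self.or_,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        }


def _arrays(h) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(h, HarmonizedSet):
        return h.arrays()
    if isinstance(h, pd.DataFrame):
        return (h["bx"].to_numpy(float), h["sx"].to_numpy(float),
                h["by"].to_numpy(float), h["sy"].to_numpy(float))
    raise TypeError("expected HarmonizedSet or DataFrame with bx/sx/by/sy")


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> tuple[float, float]:
    """Per-SNP causal estimate by/bx with first-order delta SE sy/|bx|."""
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for bx = 0")
    return by / bx, sy / abs(bx)


def to_or(beta: float, se: float, alpha: float = 0.05,
          df: float | None = None) -> tuple[float, float, float, float]:
    """(OR, CI low, CI high, two-sided p).  Normal by default, t with df for Egger."""
    if se < 0:
        raise ValueError("se must be >= 0")
    if df is None:
        crit = stats.norm.ppf(1 - alpha / 2)
        p = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else (0.0 if beta != 0 else 1.0)
    else:
        crit = stats.t.ppf(1 - alpha / 2, df)
        p = 2 * stats.t.sf(abs(beta) / se, df) if se > 0 else (0.0 if beta != 0 else 1.0)
    return float(np.exp(beta)), float(np.exp(beta - crit * se)), float(np.exp(beta + crit * se)), float(p)


def _finish(method: str, n_snp: int, beta: float, se: float,
            df: float | None = None, extras: dict | None = None,
            alpha: float = 0.05) -> MrEstimate:
    or_, lo, hi, p = to_or(beta, se, alpha=alpha, df=df)
    return MrEstimate(method=method, n_snp=n_snp, beta=float(beta), se=float(se),
                      pvalue=p, or_=or_, ci_low=lo, ci_high=hi, extras=extras or {})


def ivw(h, model: str = "random") -> MrEstimate:
    """Inverse-variance-weighted estimate over all instruments.

    beta = Σ(bx·by/sy²) / Σ(bx²/sy²); fixed se = sqrt(1/Σ(bx²/sy²)); the
    random-effects model multiplies the SE by sqrt(max(1, Q/(J−1))).
    A single SNP degrades to the Wald ratio with a warning.
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    bx, sx, by, sy = _arrays(h)
    j = len(bx)
    if j == 0:
        raise ValueError("empty instrument set")
    if j == 1:
        warnings.warn("single instrument: IVW degrades to the Wald ratio", stacklevel=2)
        b, s = wald_ratio(bx[0], sx[0], by[0], sy[0])
        return _finish("wald", 1, b, s)
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx**2))
    if sxx == 0:
        raise np.linalg.LinAlgError("all exposure effects are zero: IVW is singular")
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = np.sqrt(1.0 / sxx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    scale = max(1.0, q / (j - 1))
    extras = {"Q": q, "Q_df": j - 1, "re_scale": np.sqrt(scale)}
    if model == "fixed":
        return _finish("ivw_fe", j, beta, se_fixed, extras=extras)
    return _finish("ivw_re", j, beta, se_fixed * np.sqrt(scale), extras=extras)


def mr_egger(h) -> MrEstimate:
    """MR-Egger regression: weighted fit of by on bx with a free intercept.

    Rows are oriented so bx >= 0 (both effects negated when bx < 0).  The
    returned estimate is the slope; the intercept triple lives in
    ``extras['intercept'/'intercept_se'/'intercept_p']``.  Both SEs use the
    estimated residual scale sqrt(Q/(J−2)) and t(J−2) p-values — standard
    weighted-regression inference, which keeps the intercept (pleiotropy)
    test calibrated under the null.
    """
    bx, sx, by, sy = _arrays(h)
    j = len(bx)
    if j < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    y = by * flip
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("no spread in exposure effects: Egger fit is singular")
    w = 1.0 / sy**2
    # closed-form weighted regression with intercept
    sw = w.sum()
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    q = float(np.sum(w * resid**2))
    scale = q / (j - 2)
    se_slope = np.sqrt(scale / sxx)
    se_int = np.sqrt(scale * (1.0 / sw + xbar**2 / sxx))
    p_int = 2 * stats.t.sf(abs(intercept) / se_int, j - 2)
    extras = {
        "intercept": float(intercept), "intercept_se": float(se_int),
        "intercept_p": float(p_int), "Q": q, "Q_df": j - 2,
        "re_scale": float(np.sqrt(scale)),
    }
    return _finish("egger", j, slope, se_slope, df=j - 2, extras=extras)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2.0  # midpoint positions
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    k = np.searchsorted(s, 0.5, side="right") - 1
    # linear interpolation between adjacent midpoints
    return float(r[k] + (r[k + 1] - r[k]) * (0.5 - s[k]) / (s[k + 1] - s[k]))


def weighted_median(h, n_boot: int = 1000, seed: int | None = None) -> MrEstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Per-SNP Wald ratios are ordered; with normalized inverse-variance weights
    w' the cumulative midpoints are S_j = Σ_{i<=j} w'_i − w'_j/2 and the
    estimate interpolates linearly at S = 0.5.  The SE is the SD of the
    estimate over ``n_boot`` resamples of (bx, by) from their sampling
    normals; ``seed`` is required for reproducibility.
    """
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    bx, sx, by, sy = _arrays(h)
    j = len(bx)
    if j < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    ratios = by / bx
    weights = bx**2 / sy**2
    est = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_b = bx + sx * rng.standard_normal((n_boot, j))
    by_b = by + sy * rng.standard_normal((n_boot, j))
    ratios_b = by_b / bx_b
    weights_b = bx_b**2 / sy**2
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _weighted_median(ratios_b[i], weights_b[i])
    se = float(np.std(boots, ddof=1))
    return _finish("weighted_median", j, est, se,
                   extras={"n_boot": n_boot, "seed": seed})
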