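"""Directionality (Steiger), binary-outcome power, and lean LD-score regression.

The Steiger test asks whether the instruments explain more variance in the
exposure than in the outcome: if not, the estimated effect may reflect
reverse causation.  Trait-level correlations r = sqrt(Σ per-SNP R²) are
compared via Fisher's z.

:func:`mr_power` is the asymptotic power approximation for detecting a
causal odds ratio with instruments explaining R² of a continuous exposure
against a binary outcome with case fraction K:

    power = Φ( |log OR| · sqrt(N · R² · K(1−K)) − z_{1−α/2} )

LD-score regression exploits E[χ²_j] = 1 + N·a + N·h²·ℓ_j/M: the slope of
chi-square statistics on LD scores estimates SNP-heritability while
confounding inflation loads on the intercept.  Cross-trait products z1·z2
regressed on ℓ estimate the genetic covariance, and rg = ρ_g/sqrt(h²_1·h²_2).
This is a deliberately lean single-component implementation with a free
intercept, intended for synthetic-panel validation rather than production
genome-wide use.  SEs come from a delete-block jackknife (default 200
contiguous blocks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .instruments import variance_explained

__all__ = [
    "SteigerResult",
    "PowerResult",
    "LdscPanel",
    "LdscResult",
    "steiger_test",
    "mr_power",
    "ldsc_h2",
    "ldsc_rg",
]


@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_forward: bool
    z: float
    pvalue: float
    ambiguous: bool = False


@dataclass
class PowerResult:
    n: float
    case_fraction: float
    r2_instrument: float
    or_alt: float
    alpha: float
    power: float


@dataclass
class LdscPanel:
    """Per-SNP z-scores and LD scores for one or two traits.

    ``l2`` are the LD scores ℓ_j (conventionally >= 1), ``M`` the number of
    SNPs in the reference from which they were computed, ``n1``/``n2`` the
    GWAS sample sizes.
    """

    l2: np.ndarray
    z1: np.ndarray
    m_ref: float
    n1: float
    z2: np.ndarray | None = None
    n2: float | None = None

    def __post_init__(self) -> None:
        self.l2 = np.asarray(self.l2, dtype=float)
        self.z1 = np.asarray(self.z1, dtype=float)
        if len(self.l2) != len(self.z1):
            raise ValueError("l2 and z1 lengths disagree")
        if self.z2 is not None:
            self.z2 = np.asarray(self.z2, dtype=float)
            if len(self.z2) != len(self.z1):
                raise ValueError("z2 length disagrees with z1")
            if self.n2 is None:
                raise ValueError("n2 required when z2 supplied")
        if np.any(self.l2 < 0):
            raise ValueError("LD scores must be non-negative")

    @property
    def m_snps(self) -> int:
        return len(self.l2)


@dataclass
class LdscResult:
    h2: float
    h2_se: float
    intercept: float
    gencov: float | None = None
    rg: float | None = None
    rg_se: float | None = None
    pvalue: float | None = None
    extras: dict = field(default_factory=dict)


def steiger_test(h, n_exp: float, n_out: float) -> SteigerResult:
    """Compare instrument variance explained in exposure vs outcome.

    Per-SNP R² uses the frequency-free reduced form on each trait; the
    trait-level correlations r = sqrt(Σ R²) (clipped below 1) are compared
    with Fisher's z:  z = (atanh r_x − atanh r_y) /
    sqrt(1/(n_exp−3) + 1/(n_out−3)).  Forward means the exposure explains
    strictly more; equality is flagged ambiguous.
    """
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("sample sizes must exceed 3")
    bx, sx, by, sy = h.arrays() if hasattr(h, "arrays") else (
        h["bx"].to_numpy(float), h["sx"].to_numpy(float),
        h["by"].to_numpy(float), h["sy"].to_numpy(float))
    r2_exp = float(np.sum(variance_explained(bx, sx, n_exp)))
    r2_out = float(np.sum(variance_explained(by, sy, n_out)))
    eps = 1e-12
    r_exp = np.sqrt(min(r2_exp, 1.0 - eps))
    r_out = np.sqrt(min(r2_out, 1.0 - eps))
    denom = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / denom
    return SteigerResult(
        r2_exposure=r2_exp, r2_outcome=r2_out,
        direction_forward=bool(r2_exp > r2_out),
        z=float(z), pvalue=float(2 * stats.norm.sf(abs(z))),
        ambiguous=bool(r2_exp == r2_out),
    )


def mr_power(n: float, case_fraction: float, r2_instrument: float,
             or_alt: float, alpha: float = 0.05) -> PowerResult:
    """Asymptotic power to detect ``or_alt`` with a binary outcome."""
    if not (0.0 < case_fraction < 1.0):
        raise ValueError("case_fraction must lie in (0, 1)")
    if not (0.0 <= r2_instrument < 1.0):
        raise ValueError("r2_instrument must lie in [0, 1)")
    if or_alt <= 0 or n <= 0 or not (0.0 < alpha < 1.0):
        raise ValueError("invalid power inputs")
    ncp = abs(np.log(or_alt)) * np.sqrt(n * r2_instrument * case_fraction * (1 - case_fraction))
    power = float(stats.norm.cdf(ncp - stats.norm.ppf(1 - alpha / 2)))
    return PowerResult(n=n, case_fraction=case_fraction, r2_instrument=r2_instrument,
                       or_alt=or_alt, alpha=alpha, power=power)


def _block_bounds(m: int, n_blocks: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(n_blocks) if edges[i + 1] > edges[i]]


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray,
              blocks: list[tuple[int, int]]):
    """Weighted straight-line fit y = a + b·x with delete-block jackknife.

    Returns (slope, intercept, slopes_jack, intercepts_jack).
    """
    stats_full = np.array([w.sum(), (w * x).sum(), (w * x * x).sum(),
                           (w * y).sum(), (w * x * y).sum()])
    block_stats = np.array([
        [w[i:j].sum(), (w[i:j] * x[i:j]).sum(), (w[i:j] * x[i:j] ** 2).sum(),
         (w[i:j] * y[i:j]).sum(), (w[i:j] * x[i:j] * y[i:j]).sum()]
        for i, j in blocks
    ])

    def solve(s):
        sw, sx, sxx, sy, sxy = s
        det = sw * sxx - sx * sx
        if det <= 0:
            raise np.linalg.LinAlgError("degenerate design: LD scores have no spread")
        slope = (sw * sxy - sx * sy) / det
        intercept = (sy - slope * sx) / sw
        return slope, intercept

    slope, intercept = solve(stats_full)
    jack = np.array([solve(stats_full - bs) for bs in block_stats])
    return slope, intercept, jack[:, 0], jack[:, 1]


def _resolve_blocks(m: int, n_blocks: int) -> int:
    if m < n_blocks:
        warnings.warn(f"only {m} SNPs: reducing jackknife blocks from {n_blocks}",
                      stacklevel=3)
        return max(2, m // 2)
    return n_blocks


def _h2_fit(l2, chi2, n, m_ref, n_blocks):
    """Two-pass WLS of chi-square on LD score; returns slope-derived h2 pieces."""
    x = l2
    # first pass: weights 1/max(l2,1) (oversampling of high-LD regions)
    w0 = 1.0 / np.maximum(x, 1.0)
    blocks = _block_bounds(len(x), n_blocks)
    s0, _, _, _ = _wls_line(x, chi2, w0, blocks)
    h2_0 = np.clip(s0 * m_ref / n, 0.0, 1.0)
    # second pass: variance weights Var(chi2) ∝ 2·E[chi2]²
    mean_chi2 = 1.0 + n * h2_0 * x / m_ref
    w = 1.0 / (np.maximum(x, 1.0) * 2.0 * mean_chi2**2)
    slope, intercept, slopes_j, ints_j = _wls_line(x, chi2, w, blocks)
    return slope, intercept, slopes_j, ints_j


def ldsc_h2(panel: LdscPanel, trait: int = 1, n_blocks: int = 200) -> LdscResult:
    """SNP-heritability from the regression of χ² on LD score.

    Fits E[χ²_j] = intercept + N·h²·ℓ_j/M with a free intercept that absorbs
    confounding inflation.  The jackknife SE uses ``n_blocks`` contiguous
    blocks (auto-reduced with a warning when SNPs are scarce).
    """
    if trait == 1:
        z, n = panel.z1, panel.n1
    elif trait == 2:
        if panel.z2 is None:
            raise ValueError("panel has no second trait")
        z, n = panel.z2, panel.n2
    else:
        raise ValueError("trait must be 1 or 2")
    if panel.m_ref <= 0:
        raise ValueError("M must be positive")
    n_blocks = _resolve_blocks(panel.m_snps, n_blocks)
    slope, intercept, slopes_j, _ = _h2_fit(panel.l2, z**2, n, panel.m_ref, n_blocks)
    h2 = slope * panel.m_ref / n
    h2_j = slopes_j * panel.m_ref / n
    b = len(h2_j)
    h2_se = float(np.sqrt((b - 1) / b * np.sum((h2_j - h2_j.mean()) ** 2)))
    return LdscResult(h2=float(h2), h2_se=h2_se, intercept=float(intercept))


def ldsc_rg(panel: LdscPanel, n_blocks: int = 200) -> LdscResult:
    """Cross-trait genetic correlation from LD-score regression.

    The slope of z1·z2 on ℓ estimates sqrt(N1·N2)·ρ_g/M; dividing the
    genetic covariance ρ_g by sqrt(h²_1·h²_2) (each from :func:`ldsc_h2`'s
    fit) gives rg, clamped to [−1, 1].  The jackknife recomputes the whole
    ratio per deleted block, so the SE reflects uncertainty in all three
    slopes.
    """
    if panel.z2 is None:
        raise ValueError("genetic correlation requires two traits on shared SNPs")
    n_blocks = _resolve_blocks(panel.m_snps, n_blocks)
    x = panel.l2
    s1, _, s1_j, _ = _h2_fit(x, panel.z1**2, panel.n1, panel.m_ref, n_blocks)
    s2, _, s2_j, _ = _h2_fit(x, panel.z2**2, panel.n2, panel.m_ref, n_blocks)
    h2_1 = s1 * panel.m_ref / panel.n1
    h2_2 = s2 * panel.m_ref / panel.n2

    y = panel.z1 * panel.z2
    # variance weights from the product-normal approximation
    v1 = 1.0 + panel.n1 * max(h2_1, 0.0) * x / panel.m_ref
    v2 = 1.0 + panel.n2 * max(h2_2, 0.0) * x / panel.m_ref
    w = 1.0 / (np.maximum(x, 1.0) * v1 * v2)
    blocks = _block_bounds(panel.m_snps, n_blocks)
    sc, intercept, sc_j, _ = _wls_line(x, y, w, blocks)
    scale = np.sqrt(panel.n1 * panel.n2)
    gencov = sc * panel.m_ref / scale
    denom = np.sqrt(max(h2_1, 1e-12) * max(h2_2, 1e-12))
    rg_raw = gencov / denom

    h2_1j = s1_j * panel.m_ref / panel.n1
    h2_2j = s2_j * panel.m_ref / panel.n2
    gencov_j = sc_j * panel.m_ref / scale
    denom_j = np.sqrt(np.maximum(h2_1j, 1e-12) * np.maximum(h2_2j, 1e-12))
    rg_j = gencov_j / denom_j
    b = len(rg_j)
    rg_se = float(np.sqrt((b - 1) / b * np.sum((rg_j - rg_j.mean()) ** 2)))
    pvalue = float(2 * stats.norm.sf(abs(rg_raw) / rg_se)) if rg_se > 0 else 0.0
    return LdscResult(
        h2=float(h2_1), h2_se=float("nan"), intercept=float(intercept),
        gencov=float(gencov), rg=float(np.clip(rg_raw, -1.0, 1.0)),
        rg_se=rg_se, pvalue=pvalue,
        extras={"h2_trait2": float(h2_2), "rg_unclamped": float(rg_raw)},
    )
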