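"""Bayesian colocalization of two regional association signals.

Given summary statistics for two traits across one genomic region and
assuming at most one causal variant per trait, five hypotheses are compared:
H0 no association, H1/H2 association with one trait only, H3 both traits
associated through distinct variants, H4 a shared causal variant.  Evidence
per SNP is the Wakefield approximate Bayes factor

    log ABF = ½·log(V/(V+W)) + z²/2 · W/(V+W)

with V = se², z = beta/se, and W the prior variance of true effects
(sd 0.2 for quantitative traits, 0.15 for binary).  Hypothesis weights sum
single-SNP configurations — H3 over ordered pairs of distinct SNPs — scaled
by per-configuration priors p1, p2, p12; all sums run in log space.
PP.H4 > 0.8 is the conventional decision rule for a shared variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "RegionalAssoc",
    "ColocConfig",
    "ColocResult",
    "log_abf",
    "coloc_abf",
]

_PRIOR_SD = {"quantitative": 0.2, "binary": 0.15}


@dataclass
class RegionalAssoc:
    """Per-SNP summary statistics for one trait across one genomic region."""

    snp_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    maf: np.ndarray | None = None
    n: float | None = None
    trait_type: str = "quantitative"
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not (len(self.snp_ids) == len(self.beta) == len(self.se)):
            raise ValueError("snp_ids, beta, se lengths disagree")
        if np.any(self.se <= 0):
            raise ValueError("se must be > 0")
        if self.maf is not None:
            self.maf = np.asarray(self.maf, dtype=float)
            if np.any((self.maf <= 0) | (self.maf > 0.5)):
                raise ValueError("maf must lie in (0, 0.5]")
        if self.trait_type not in _PRIOR_SD:
            raise ValueError(f"unknown trait_type {self.trait_type!r}")

    @classmethod
    def from_z(cls, snp_ids, z, maf, n, trait_type="quantitative",
               case_fraction=None) -> "RegionalAssoc":
        """Reconstruct beta/se from z-scores via the standard single-SNP
        approximation se = 1/sqrt(2·n·maf(1−maf)·[K(1−K) if binary])."""
        z = np.asarray(z, dtype=float)
        maf = np.asarray(maf, dtype=float)
        var_factor = 2.0 * n * maf * (1.0 - maf)
        if trait_type == "binary":
            if case_fraction is None:
                raise ValueError("binary trait needs case_fraction")
            var_factor = var_factor * case_fraction * (1.0 - case_fraction)
        se = 1.0 / np.sqrt(var_factor)
        return cls(snp_ids=list(snp_ids), beta=z * se, se=se, maf=maf, n=n,
                   trait_type=trait_type, case_fraction=case_fraction)

    @classmethod
    def from_tsv(cls, path, trait_type="quantitative", case_fraction=None) -> "RegionalAssoc":
        df = pd.read_csv(path, sep="\t")
        return cls(snp_ids=list(df["snp"].astype(str)),
                   beta=df["beta"].to_numpy(float), se=df["se"].to_numpy(float),
                   maf=df["maf"].to_numpy(float) if "maf" in df else None,
                   n=float(df["n"].iloc[0]) if "n" in df else None,
                   trait_type=trait_type, case_fraction=case_fraction)

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "snp": self.snp_ids, "beta": self.beta, "se": self.se,
            "maf": self.maf if self.maf is not None else np.nan,
            "n": self.n,
        }).to_csv(path, sep="\t", index=False)


@dataclass
class ColocConfig:
    """Per-configuration priors: p1/p2 a SNP is causal for one trait, p12 for both."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd_quantitative: float = 0.2
    prior_sd_binary: float = 0.15

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ValueError("priors must be positive")

    def prior_sd(self, trait: RegionalAssoc) -> float:
        return (self.prior_sd_binary if trait.trait_type == "binary"
                else self.prior_sd_quantitative)

    def check_sanity(self, m: int) -> None:
        total = self.p1 * m + self.p2 * m + self.p12 * m + self.p1 * self.p2 * m**2
        if total >= 1:
            warnings.warn(
                f"prior mass across configurations is {total:.3f} >= 1 at M={m}; "
                "priors are likely too large for this region", stacklevel=3)


@dataclass
class ColocResult:
    pp: np.ndarray                 # [pp_h0, pp_h1, pp_h2, pp_h3, pp_h4]
    labf1: np.ndarray
    labf2: np.ndarray
    snp_ids: list[str]
    n_snps: int
    extras: dict = field(default_factory=dict)

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])

    @property
    def decision(self) -> bool:
        """Strong evidence for a shared causal variant (PP.H4 > 0.8)."""
        return self.pp_h4 > 0.8

    def as_dict(self) -> dict:
        return {f"pp_h{i}": float(self.pp[i]) for i in range(5)}

    @property
    def top_shared_snp(self) -> str:
        """SNP with the largest joint evidence under H4."""
        return self.snp_ids[int(np.argmax(self.labf1 + self.labf2))]


def log_abf(beta, se, prior_sd: float):
    """Wakefield log approximate Bayes factor for one association."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    shrink = w / (v + w)
    out = 0.5 * np.log(v / (v + w)) + 0.5 * z2 * shrink
    return out.item() if out.ndim == 0 else out


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) − exp(b)); −inf with a warning when cancellation is total."""
    if b >= a:
        warnings.warn("H3 weight vanished by numerical cancellation; clamped at 0",
                      stacklevel=3)
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(t1: RegionalAssoc, t2: RegionalAssoc,
              config: ColocConfig | None = None) -> ColocResult:
    """Five-hypothesis colocalization posterior over a shared SNP panel.

    SNPs are inner-joined by id.  With S1 = Σ_j ABF1_j, S2 = Σ_j ABF2_j and
    S12 = Σ_j ABF1_j·ABF2_j, the unnormalized weights are H0: 1, H1: p1·S1,
    H2: p2·S2, H3: p1·p2·(S1·S2 − S12), H4: p12·S12, evaluated in log space.
    """
    cfg = config or ColocConfig()
    common = [s for s in t1.snp_ids if s in set(t2.snp_ids)]
    if not common:
        raise ValueError("no shared SNPs between the two regional tables")
    idx1 = {s: i for i, s in enumerate(t1.snp_ids)}
    idx2 = {s: i for i, s in enumerate(t2.snp_ids)}
    i1 = np.array([idx1[s] for s in common])
    i2 = np.array([idx2[s] for s in common])
    cfg.check_sanity(len(common))

    l1 = log_abf(t1.beta[i1], t1.se[i1], cfg.prior_sd(t1))
    l2 = log_abf(t2.beta[i2], t2.se[i2], cfg.prior_sd(t2))
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)

    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)

    lw = np.array([
        0.0,
        np.log(cfg.p1) + ls1,
        np.log(cfg.p2) + ls2,
        np.log(cfg.p1) + np.log(cfg.p2) + _logdiffexp(ls1 + ls2, ls12),
        np.log(cfg.p12) + ls12,
    ])
    pp = np.exp(lw - logsumexp(lw))
    pp = pp / pp.sum()
    return ColocResult(pp=pp, labf1=l1, labf2=l2, snp_ids=common,
                       n_snps=len(common),
                       extras={"S1_log": float(ls1), "S2_log": float(ls2),
                               "S12_log": float(ls12)})
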